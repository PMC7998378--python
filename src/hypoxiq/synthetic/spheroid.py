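"""Synthetic two-channel 3D FUCCI spheroid stacks.

Nuclei are planted on a jittered grid inside a sphere; cells within the
green rim depth of the surface are green-dominant, deeper cells are
red-dominant. The ground truth records every nucleus's exact 3D distance
to the spherical surface and its color class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..spheroid3d import SpheroidStack


def generate_spheroid_stack(
    radius_um: float = 200.0,
    green_rim_depth_um: float = 50.0,
    z_step_um: float = 10.0,
    cfg: SimulationConfig | None = None,
    nucleus_radius_um: float = 8.0,
    spacing_um: float = 18.0,
    green_levels: tuple[float, float] = (100.0, 15.0),  # (g, r) of green cells
    red_levels: tuple[float, float] = (10.0, 100.0),
    background: float = 3.0,
    noise_sd: float = 1.0,
) -> tuple[SpheroidStack, pd.DataFrame]:
    """(stack, truth) for a spherical FUCCI spheroid.

    Slices are taken at ``z_step_um`` spacing through the sphere; nuclei
    sit on an in-plane jittered grid inside each section disk. Truth rows:
    slice, centroid (px), planted class, exact 3D surface distance (um).
    """
    cfg = cfg or SimulationConfig()
    if z_step_um <= 0:
        raise ValueError("z_step_um must be > 0")
    if radius_um < 3 * z_step_um:
        raise ValueError("radius must span several z-steps")
    if not (0 <= green_rim_depth_um <= radius_um):
        raise ValueError("green rim depth must be in [0, radius]")
    rng = cfg.rng(salt=606)
    px = cfg.pixel_size_um
    radius_px = radius_um / px
    nucleus_r_px = nucleus_radius_um / px

    side = int(np.ceil(2 * radius_px + 16))
    center_px = side / 2
    # slice planes through the sphere, offset half a step from the poles
    z_c = radius_um + z_step_um
    z_positions = np.arange(
        z_c - radius_um + z_step_um / 2, z_c + radius_um, z_step_um
    )

    n_z = len(z_positions)
    green = np.full((n_z, side, side), background, dtype=float)
    red = np.full((n_z, side, side), background, dtype=float)

    yy, xx = np.mgrid[:side, :side]
    rows = []
    for k, z in enumerate(z_positions):
        dz = z - z_c
        r_z_um = float(np.sqrt(max(radius_um**2 - dz**2, 0.0)))
        r_z_px = r_z_um / px
        if r_z_px < nucleus_r_px * 1.5:
            continue
        step_px = spacing_um / px
        coords = np.arange(-r_z_px, r_z_px + step_px, step_px)
        for gy in coords:
            for gx in coords:
                jy = gy + rng.uniform(-0.15, 0.15) * step_px
                jx = gx + rng.uniform(-0.15, 0.15) * step_px
                in_plane_px = float(np.hypot(jy, jx))
                # rim nuclei may touch the section edge; only their centers
                # must stay inside the sphere
                if in_plane_px > r_z_px - 1:
                    continue
                r_um = np.hypot(in_plane_px * px, dz)
                d3_um = radius_um - r_um
                cls = "green" if d3_um <= green_rim_depth_um else "red"
                g_lvl, r_lvl = green_levels if cls == "green" else red_levels
                cy, cx = center_px + jy, center_px + jx
                d2 = (yy - cy) ** 2 + (xx - cx) ** 2
                disk = d2 <= nucleus_r_px**2
                # peaked radial profile (chromatin-like) keeps touching
                # nuclei separable for watershed seeding
                profile = np.exp(-d2[disk] / (2 * (nucleus_r_px / 1.6) ** 2))
                green[k][disk] = np.maximum(
                    green[k][disk], background + g_lvl * profile
                )
                red[k][disk] = np.maximum(
                    red[k][disk], background + r_lvl * profile
                )
                rows.append(
                    {
                        "slice": k,
                        "z_um": float(z),
                        "row": cy,
                        "col": cx,
                        "cls": cls,
                        "d3_um": float(d3_um),
                    }
                )
    green += rng.normal(0, noise_sd, green.shape)
    red += rng.normal(0, noise_sd, red.shape)
    np.clip(green, 0, None, out=green)
    np.clip(red, 0, None, out=red)

    stack = SpheroidStack(
        green=green, red=red, z_um=z_positions, pixel_size_um=px
    )
    truth = pd.DataFrame.from_records(rows)
    truth.attrs["radius_um"] = radius_um
    truth.attrs["z_center_um"] = z_c
    truth.attrs["green_rim_depth_um"] = green_rim_depth_um
    return stack, truth
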