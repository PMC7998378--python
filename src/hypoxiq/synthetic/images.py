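"""Synthetic two-channel nuclear images: DNA-damage foci and CDK2 reporter."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..foci import LabeledImage


class PlacementError(RuntimeError):
    """Requested object density admits no non-overlapping placement."""


def _place_points(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    min_dist_px: float,
    margin_px: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample ``n`` points with pairwise separation >= min_dist_px."""
    points: list[tuple[float, float]] = []
    tries = 0
    while len(points) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} objects with separation {min_dist_px:.1f} px "
                f"in a {shape} raster after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(margin_px, shape[0] - margin_px)
        c = rng.uniform(margin_px, shape[1] - margin_px)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist_px**2 for pr, pc in points):
            points.append((r, c))
    return np.array(points)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _paint_labels(shape, centers, radius_px) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int32)
    for i, center in enumerate(centers, start=1):
        labels[_disk_mask(shape, center, radius_px)] = i
    return labels


def generate_foci_image(
    n_nuclei: int,
    foci_mean: float,
    cfg: SimulationConfig | None = None,
    nucleus_radius_um: float = 5.0,
    focus_diameter_um: float = 1.0,
    well_separated: bool = True,
    fixed_counts: list[int] | None = None,
    nuclear_level: float = 100.0,
    focus_amplitude: float = 200.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
) -> tuple[LabeledImage, pd.DataFrame]:
    """Two-channel nuclear image with punctate foci and per-nucleus truth.

    Channel ``dapi`` holds nuclear disks, channel ``foci`` Gaussian spots
    planted inside the nuclei. In ``well_separated`` mode spots are kept
    at least two focus diameters apart and away from the nuclear rim.
    Returns the image and a truth table (label, planted_count) whose
    ``attrs['focus_coords']`` lists every planted spot.
    """
    cfg = cfg or SimulationConfig()
    rng = cfg.rng(salt=202)
    px = cfg.pixel_size_um
    nucleus_r_px = nucleus_radius_um / px
    focus_d_px = focus_diameter_um / px

    spacing = 2 * nucleus_r_px * 1.4
    side = int(np.ceil(np.sqrt(n_nuclei) * spacing * 1.6 + 4 * nucleus_r_px))
    shape = (side, side)
    centers = _place_points(
        rng, shape, n_nuclei, min_dist_px=spacing, margin_px=2 * nucleus_r_px
    )
    labels = _paint_labels(shape, centers, nucleus_r_px)

    dapi = np.full(shape, background, dtype=float)
    dapi[labels > 0] = nuclear_level
    dapi += rng.normal(0, noise_sd, shape)

    foci_ch = np.full(shape, background, dtype=float)
    sigma_px = focus_d_px / 3.0
    min_sep = 2 * focus_d_px if well_separated else focus_d_px
    margin = focus_d_px if well_separated else focus_d_px / 2

    def paint_spot(img: np.ndarray, r: float, c: float) -> None:
        half = int(np.ceil(4 * sigma_px))
        r0, r1 = max(0, int(r) - half), min(shape[0], int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(shape[1], int(c) + half + 1)
        wy, wx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += focus_amplitude * np.exp(
            -((wy - r) ** 2 + (wx - c) ** 2) / (2 * sigma_px**2)
        )

    rows, coords = [], []
    for i, center in enumerate(centers, start=1):
        want = (
            int(fixed_counts[i - 1])
            if fixed_counts is not None
            else int(rng.poisson(foci_mean))
        )
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < want and tries < 4000:
            tries += 1
            rad = rng.uniform(0, nucleus_r_px - margin)
            ang = rng.uniform(0, 2 * np.pi)
            r = center[0] + rad * np.sin(ang)
            c = center[1] + rad * np.cos(ang)
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed
            ):
                placed.append((r, c))
        if fixed_counts is not None and len(placed) < want:
            raise PlacementError(
                f"could not plant {want} foci in nucleus {i} (placed {len(placed)})"
            )
        for r, c in placed:
            paint_spot(foci_ch, r, c)
            coords.append((i, r, c))
        rows.append({"label": i, "planted_count": len(placed)})
    foci_ch += rng.normal(0, noise_sd, shape)

    image = LabeledImage(
        channels={"dapi": dapi, "foci": foci_ch}, labels=labels, pixel_size_um=px
    )
    truth = pd.DataFrame.from_records(rows)
    truth.attrs["focus_coords"] = pd.DataFrame(
        coords, columns=["label", "row", "col"]
    )
    truth.attrs["centers"] = centers
    return image, truth


def generate_reporter_image(
    ratio: float,
    n_cells: int,
    cfg: SimulationConfig | None = None,
    ratios: list[float] | None = None,
    nucleus_radius_um: float = 6.0,
    ring_width_um: float = 4.0,
    nuclear_level: float = 100.0,
    background: float = 5.0,
    noise_sd: float = 1.0,
) -> tuple[LabeledImage, pd.DataFrame]:
    """Reporter image: nuclei at a fixed level, cytoplasmic rings at
    ``ratio`` times that level, over a constant background.

    ``ratios`` optionally plants a per-cell ratio (overrides ``ratio``).
    Channels: ``nuclei`` (segmentation stain) and ``reporter``.
    """
    cfg = cfg or SimulationConfig()
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    rng = cfg.rng(salt=303)
    px = cfg.pixel_size_um
    nucleus_r_px = nucleus_radius_um / px
    ring_px = ring_width_um / px
    cell_r_px = nucleus_r_px + ring_px

    per_cell = (
        np.asarray(ratios, dtype=float)
        if ratios is not None
        else np.full(n_cells, float(ratio))
    )
    if len(per_cell) != n_cells:
        raise ValueError("ratios must have length n_cells")

    spacing = 2 * cell_r_px + 6
    side = int(np.ceil(np.sqrt(n_cells) * spacing * 1.5 + 2 * spacing))
    shape = (side, side)
    centers = _place_points(rng, shape, n_cells, spacing, margin_px=cell_r_px + 2)

    labels = _paint_labels(shape, centers, nucleus_r_px)
    nuclei_ch = np.full(shape, background, dtype=float)
    nuclei_ch[labels > 0] = nuclear_level
    nuclei_ch += rng.normal(0, noise_sd, shape)

    reporter = np.full(shape, background, dtype=float)
    rows = []
    for i, center in enumerate(centers, start=1):
        nuc = _disk_mask(shape, center, nucleus_r_px)
        cell = _disk_mask(shape, center, cell_r_px)
        reporter[cell & ~nuc] = background + per_cell[i - 1] * nuclear_level
        reporter[nuc] = background + nuclear_level
        rows.append({"label": i, "planted_ratio": float(per_cell[i - 1])})
    reporter += rng.normal(0, noise_sd, shape)

    image = LabeledImage(
        channels={"nuclei": nuclei_ch, "reporter": reporter},
        labels=labels,
        pixel_size_um=px,
    )
    truth = pd.DataFrame.from_records(rows)
    truth.attrs["centers"] = centers
    return image, truth
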