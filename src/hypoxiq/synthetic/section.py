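"""Synthetic AEC/hematoxylin-stained spheroid cross-sections.

Produces a BrdU-stained and a pimonidazole-stained RGB image of the same
circular section, composited with the same stain-vector matrix the
deconvolution defaults to, so unmixing is exactly invertible on noiseless
output. Pimonidazole positivity starts beyond the hypoxia onset depth
(toward the core); BrdU positivity is confined within the proliferative
rim depth.
"""

from __future__ import annotations

import numpy as np

from ..config import SimulationConfig
from ..section2d import HAEC_DEFAULT, StainMatrix, mix_haec


def generate_section_image(
    radius_um: float = 250.0,
    hypoxia_onset_um: float = 100.0,
    proliferation_depth_um: float = 80.0,
    cfg: SimulationConfig | None = None,
    stains: StainMatrix = HAEC_DEFAULT,
    hema_od: float = 0.35,
    positive_aec_od: float = 0.8,
    negative_aec_od: float = 0.02,
    noise_od: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """(brdu_rgb, pimo_rgb, truth) for a circular stained section.

    Truth carries ``section_mask``, ``pimo_mask`` (depth > onset),
    ``brdu_mask`` (depth < proliferation depth) and the per-pixel
    ``depth_um`` map. RGB images are float transmittance in (0, 1];
    ``noise_od`` > 0 adds Gaussian OD noise after stain mixing.
    """
    cfg = cfg or SimulationConfig()
    if hypoxia_onset_um >= radius_um:
        raise ValueError("hypoxia onset depth must be < section radius")
    px = cfg.pixel_size_um
    radius_px = radius_um / px
    side = int(np.ceil(2 * radius_px + 20))
    center = side / 2

    rr, cc = np.mgrid[:side, :side]
    dist_center_um = np.hypot(rr - center, cc - center) * px
    section = dist_center_um <= radius_um
    depth_um = np.where(section, radius_um - dist_center_um, np.nan)

    pimo_mask = section & (depth_um > hypoxia_onset_um)
    brdu_mask = section & (depth_um < proliferation_depth_um)

    hema = np.where(section, hema_od, 0.0)
    pimo_aec = np.where(section, negative_aec_od, 0.0)
    pimo_aec[pimo_mask] = positive_aec_od
    brdu_aec = np.where(section, negative_aec_od, 0.0)
    brdu_aec[brdu_mask] = positive_aec_od

    pimo_rgb = mix_haec(hema, pimo_aec, stains)
    brdu_rgb = mix_haec(hema, brdu_aec, stains)
    if noise_od > 0:
        rng = cfg.rng(salt=505)
        for img in (pimo_rgb, brdu_rgb):
            od = -np.log10(np.clip(img, 1e-6, 1.0))
            od += rng.normal(0, noise_od, od.shape)
            img[:] = np.power(10.0, -np.clip(od, 0, None))

    truth = {
        "section_mask": section,
        "pimo_mask": pimo_mask,
        "brdu_mask": brdu_mask,
        "depth_um": depth_um,
    }
    return brdu_rgb, pimo_rgb, truth
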