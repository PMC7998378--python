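"""CDK2-activity reporter quantification.

Per cell: median reporter intensity in the nucleus and in a thin
cytoplasmic band around it, their ratio (cytoplasmic / nuclear), and the
fraction of cells whose ratio falls strictly below the quiescence
threshold (default 0.55). Background is removed beforehand by a
rolling-ball-style subtraction (default radius 50 um), realized as a
grayscale morphological opening with a disk of the stated physical radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

__all__ = [
    "ReporterParams",
    "ReporterMeasurement",
    "subtract_background",
    "cytoplasm_band",
    "measure_ratio",
    "quiescent_fraction",
]


@dataclass(frozen=True)
class ReporterParams:
    band_width_um: float = 1.5
    rollball_radius_um: float = 50.0
    quiescence_threshold: float = 0.55

    def __post_init__(self) -> None:
        if min(self.band_width_um, self.rollball_radius_um,
               self.quiescence_threshold) <= 0:
            raise ValueError("all reporter parameters must be > 0")


@dataclass(frozen=True)
class ReporterMeasurement:
    label: int
    nuclear_median: float
    cytoplasmic_median: float
    ratio: float
    excluded: bool = False


def subtract_background(
    image: np.ndarray, radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """Remove smooth background by grayscale opening at a physical radius.

    The opening never exceeds the input, so the result is >= 0 everywhere;
    structures smaller than the ball survive subtraction unchanged.
    """
    radius_px = radius_um / pixel_size_um
    if radius_px < 1:
        raise ValueError(
            f"rolling-ball radius {radius_um} um is < 1 px at "
            f"{pixel_size_um} um/px"
        )
    footprint = morphology.disk(int(round(radius_px)), decomposition="sequence")
    background = morphology.opening(np.asarray(image, dtype=float), footprint)
    return np.clip(image - background, 0, None)


def cytoplasm_band(
    labels: np.ndarray, band_width_um: float, pixel_size_um: float
) -> np.ndarray:
    """Per-nucleus cytoplasmic ring of the given physical width.

    Each background pixel within the band width of some nucleus is assigned
    the label of its nearest nucleus pixel, so rings of adjacent cells stay
    disjoint. Nuclear pixels are never part of any band.
    """
    labels = np.asarray(labels)
    if labels.max() == 0:
        raise ValueError("label mask is empty")
    width_px = band_width_um / pixel_size_um
    distance, (ri, ci) = ndimage.distance_transform_edt(
        labels == 0, return_indices=True
    )
    nearest = labels[ri, ci]
    band = np.where((distance > 0) & (distance <= width_px), nearest, 0)
    return band.astype(labels.dtype)


def measure_ratio(
    reporter: np.ndarray,
    labels: np.ndarray,
    bands: np.ndarray,
    params: ReporterParams | None = None,
) -> list[ReporterMeasurement]:
    """Cytoplasmic/nuclear median-intensity ratio per cell.

    Assumes the reporter image is already background subtracted. Cells
    with a zero nuclear median (or an empty band) are flagged ``excluded``
    and carry a NaN ratio.
    """
    reporter = np.asarray(reporter, dtype=float)
    out = []
    for label in range(1, int(labels.max()) + 1):
        nuc = reporter[labels == label]
        cyt = reporter[bands == label]
        nuc_med = float(np.median(nuc)) if len(nuc) else 0.0
        cyt_med = float(np.median(cyt)) if len(cyt) else float("nan")
        if nuc_med <= 0 or not np.isfinite(cyt_med):
            out.append(ReporterMeasurement(label, nuc_med, cyt_med, float("nan"), True))
        else:
            out.append(ReporterMeasurement(label, nuc_med, cyt_med, cyt_med / nuc_med))
    return out


def quiescent_fraction(
    measurements: list[ReporterMeasurement], threshold: float = 0.55
) -> tuple[float, int]:
    """Fraction (and count) of cells with ratio strictly below ``threshold``."""
    ratios = [m.ratio for m in measurements if not m.excluded]
    if not ratios:
        raise ValueError("no usable measurements")
    count = sum(1 for r in ratios if r < threshold)
    return count / len(ratios), count


def measurements_to_frame(
    measurements: list[ReporterMeasurement],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": m.label,
                "nuclear_median": m.nuclear_median,
                "cytoplasmic_median": m.cytoplasmic_median,
                "ratio": m.ratio,
                "excluded": m.excluded,
            }
            for m in measurements
        ]
    )
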