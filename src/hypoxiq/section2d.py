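"""Zonal analysis of chromogen-stained spheroid cross-sections.

Workflow: outline the section rim, unmix hematoxylin/AEC optical densities
by color deconvolution, threshold the pimonidazole (AEC) signal with
2-cluster k-means into a hypoxia mask, assign concentric 10 um distance
zones from the section edge, and profile positive-pixel fractions and mean
OD per marker per zone. An automated phase-correlation aligner replaces
the manual registration of the two serial sections.

Optical density follows Beer-Lambert: ``OD = -log10(I)`` with transmitted
intensity I in (0, 1] (8-bit input is mapped to ``(pixel + 1) / 256``).
Default stain vectors are the published hematoxylin and AEC OD vectors
(Ruifrok-Johnston convention); the matrix is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, registration
from sklearn.cluster import KMeans

__all__ = [
    "StainMatrix",
    "HAEC_DEFAULT",
    "outline_section",
    "deconvolve_haec",
    "mix_haec",
    "hypoxia_mask",
    "distance_zones",
    "zonal_profile",
    "align_sections",
]

# Ruifrok-Johnston OD vectors (RGB) for hematoxylin and AEC
_H_VECTOR = (0.650, 0.704, 0.286)
_AEC_VECTOR = (0.2743, 0.6796, 0.6803)


@dataclass(frozen=True)
class StainMatrix:
    """Columns are unit OD vectors for hematoxylin, AEC and a residual."""

    matrix: np.ndarray  # 3x3

    @classmethod
    def from_vectors(cls, hematoxylin, aec, residual=None) -> "StainMatrix":
        h = np.asarray(hematoxylin, dtype=float)
        a = np.asarray(aec, dtype=float)
        h = h / np.linalg.norm(h)
        a = a / np.linalg.norm(a)
        if residual is None:
            r = np.cross(h, a)
        else:
            r = np.asarray(residual, dtype=float)
        norm = np.linalg.norm(r)
        if norm == 0:
            raise ValueError("degenerate stain pair: residual vector is zero")
        r = r / norm
        m = np.column_stack([h, a, r])
        if abs(np.linalg.det(m)) < 1e-8:
            raise ValueError("singular stain matrix")
        return cls(matrix=m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


HAEC_DEFAULT = StainMatrix.from_vectors(_H_VECTOR, _AEC_VECTOR)


def _to_transmittance(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.dtype == np.uint8:
        return (rgb.astype(float) + 1.0) / 256.0
    out = rgb.astype(float)
    return np.clip(out, 1e-6, 1.0)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    return -np.log10(_to_transmittance(rgb))


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Float transmittance image in (0, 1] from an OD image."""
    return np.power(10.0, -np.asarray(od, dtype=float))


def outline_section(rgb: np.ndarray, smooth_sigma_px: float = 2.0) -> np.ndarray:
    """Binary mask of the tissue section (largest component, holes filled)."""
    od_sum = rgb_to_od(rgb).sum(axis=-1)
    smooth = filters.gaussian(od_sum, sigma=smooth_sigma_px)
    # three-class split keeps strongly stained regions from stealing the
    # background/tissue threshold; the lowest cut separates glass from tissue
    try:
        thr = float(filters.threshold_multiotsu(smooth, classes=3)[0])
    except ValueError:
        thr = float(filters.threshold_otsu(smooth))
    mask = smooth > thr
    if not mask.any():
        raise ValueError("no section found: empty mask after thresholding")
    labeled = measure.label(mask)
    largest = np.argmax(np.bincount(labeled.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labeled == largest)


def deconvolve_haec(
    rgb: np.ndarray, stains: StainMatrix = HAEC_DEFAULT
) -> tuple[np.ndarray, np.ndarray]:
    """Unmix an RGB image into hematoxylin and AEC OD rasters (clipped at 0)."""
    od = rgb_to_od(rgb)
    concentrations = od @ stains.inverse.T
    hema = np.clip(concentrations[..., 0], 0, None)
    aec = np.clip(concentrations[..., 1], 0, None)
    return hema, aec


def mix_haec(
    hema_od: np.ndarray, aec_od: np.ndarray, stains: StainMatrix = HAEC_DEFAULT
) -> np.ndarray:
    """Forward stain mixing: per-stain OD maps -> float RGB transmittance.

    Exact inverse of :func:`deconvolve_haec` on noiseless input.
    """
    conc = np.stack(
        [hema_od, aec_od, np.zeros_like(np.asarray(hema_od, dtype=float))], axis=-1
    )
    od = conc @ stains.matrix.T
    return od_to_rgb(od)


def hypoxia_mask(
    aec_od: np.ndarray, section_mask: np.ndarray, seed: int = 0, n_clusters: int = 2
) -> np.ndarray:
    """Positive-staining mask by k-means clustering of in-section OD values.

    The cluster with the highest mean OD is called positive. Constant OD
    yields an empty mask with a warning.
    """
    if not section_mask.any():
        raise ValueError("section mask is empty")
    values = aec_od[section_mask].reshape(-1, 1)
    if np.ptp(values) == 0:
        warnings.warn("constant OD within section: empty hypoxia mask")
        return np.zeros_like(section_mask, dtype=bool)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assignment = km.fit_predict(values)
    positive_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    mask = np.zeros_like(section_mask, dtype=bool)
    mask[section_mask] = assignment == positive_cluster
    return mask


def distance_zones(
    section_mask: np.ndarray, pixel_size_um: float, zone_width_um: float = 10.0
) -> np.ndarray:
    """Concentric distance-zone labels from the section edge inward.

    Zone index = floor(depth_um / zone_width_um); pixels outside the
    section get -1.
    """
    if not section_mask.any():
        raise ValueError("section mask is empty")
    # pad so the image border counts as section edge too
    padded = np.pad(section_mask, 1, constant_values=False)
    depth_um = (
        ndimage.distance_transform_edt(padded)[1:-1, 1:-1] * pixel_size_um
    )
    zones = np.floor(depth_um / zone_width_um).astype(int)
    zones[~section_mask] = -1
    return zones


def zonal_profile(
    markers: dict[str, np.ndarray],
    zones: np.ndarray,
    od_rasters: dict[str, np.ndarray] | None = None,
    zone_width_um: float = 10.0,
) -> pd.DataFrame:
    """Per-zone positive-pixel fraction (and mean OD) for each marker.

    ``markers`` maps name -> binary positivity mask; ``od_rasters``
    optionally maps name -> OD raster for per-zone mean intensity.
    """
    od_rasters = od_rasters or {}
    inside = zones >= 0
    records = []
    for zone in range(int(zones.max()) + 1):
        sel = zones == zone
        n_px = int(sel.sum())
        rec = {
            "zone": zone,
            "inner_um": zone * zone_width_um,
            "outer_um": (zone + 1) * zone_width_um,
            "pixel_count": n_px,
        }
        for name, mask in markers.items():
            rec[f"{name}_fraction"] = (
                float(mask[sel].sum()) / n_px if n_px else float("nan")
            )
        for name, od in od_rasters.items():
            rec[f"{name}_mean_od"] = float(od[sel].mean()) if n_px else float("nan")
        records.append(rec)
    profile = pd.DataFrame.from_records(records)
    assert profile["pixel_count"].sum() == int(inside.sum())
    return profile


def align_sections(
    fixed_mask: np.ndarray, moving_mask: np.ndarray, min_confidence: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Translation registering ``moving`` onto ``fixed`` by phase correlation.

    Returns (shift as (dy, dx), registered moving mask). A weak correlation
    peak falls back to the identity with a warning.
    """
    fixed = fixed_mask.astype(float)
    moving = moving_mask.astype(float)
    shift, error, _ = registration.phase_cross_correlation(
        fixed, moving, normalization=None
    )
    confidence = 1.0 - error
    if confidence < min_confidence:
        warnings.warn("weak correlation peak: returning identity transform")
        return np.zeros(2), moving_mask
    registered = ndimage.shift(moving, shift, order=0, mode="constant")
    return shift, registered.astype(moving_mask.dtype)
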