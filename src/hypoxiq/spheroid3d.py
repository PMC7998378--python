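"""3D FUCCI spheroid analysis from two-channel z-stacks.

Per-slice preprocessing (rolling-ball background subtraction at 100 um,
red-normalized green, channel sum), slice outlining by median filter +
Gaussian blur + Huang autothreshold, per-slice nuclear segmentation with
per-nucleus green/red intensities, sphere fitting from section areas,
recalculation of 2D rim distances to shortest 3D distances to the spheroid
surface, green/red classification at normalized-green threshold 0.225, and
radial green-fraction histograms in 10 um bins.

Geometry: with fitted radius R and equatorial plane z_c, a nucleus at
in-plane rim distance d2 on the slice at height z sits at in-plane radius
rho = r_z - d2 (r_z the section radius), so its shortest distance to the
sphere surface is ``R - sqrt(rho^2 + (z - z_c)^2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from . import foci as _foci

__all__ = [
    "SpheroidStack",
    "SphereGeometry",
    "threshold_huang",
    "preprocess_stack",
    "slice_outline",
    "segment_slice_nuclei",
    "fit_sphere",
    "fit_sphere_radii",
    "distance_3d",
    "classify_green",
    "radial_histogram",
    "analyze_stack",
]


@dataclass
class SpheroidStack:
    green: np.ndarray  # (z, y, x)
    red: np.ndarray
    z_um: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red stacks must share a shape")
        if len(self.z_um) != self.green.shape[0]:
            raise ValueError("z positions must match the number of slices")
        if np.any(np.diff(self.z_um) <= 0):
            raise ValueError("z positions must be strictly increasing")


@dataclass
class SphereGeometry:
    radius_um: float
    z_center_um: float
    slice_radii_um: np.ndarray = field(default_factory=lambda: np.array([]))
    rss: float = 0.0

    def section_radius(self, z_um: float) -> float:
        dz = z_um - self.z_center_um
        if abs(dz) > self.radius_um:
            raise ValueError(
                f"slice at z={z_um} um lies outside the fitted sphere"
            )
        return float(np.sqrt(self.radius_um**2 - dz**2))


def threshold_huang(image: np.ndarray, nbins: int = 256) -> float:
    """Huang's fuzzy-entropy threshold.

    Minimizes the Shannon entropy of fuzzy membership, where a pixel's
    membership to its assigned class decays with distance from the class
    mean over the gray-level range.
    """
    values = np.asarray(image, dtype=float).ravel()
    if np.ptp(values) == 0:
        raise ValueError("cannot threshold a constant image")
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    nz = np.flatnonzero(hist)
    first, last = nz[0], nz[-1]
    span = centers[last] - centers[first]
    if span == 0:
        return float(centers[first])

    w = np.cumsum(hist.astype(float))
    s = np.cumsum(hist * centers)
    total_w, total_s = w[-1], s[-1]

    best_entropy, best_thr = np.inf, centers[first]
    for t in range(first, last):
        if w[t] == 0 or total_w - w[t] == 0:
            continue
        mu0 = s[t] / w[t]
        mu1 = (total_s - s[t]) / (total_w - w[t])
        # membership of every gray level under this split
        member = np.empty(nbins)
        member[: t + 1] = 1.0 / (1.0 + np.abs(centers[: t + 1] - mu0) / span)
        member[t + 1 :] = 1.0 / (1.0 + np.abs(centers[t + 1 :] - mu1) / span)
        member = np.clip(member, 1e-12, 1 - 1e-12)
        fuzz = -(member * np.log(member) + (1 - member) * np.log(1 - member))
        entropy = float((hist * fuzz).sum())
        if entropy < best_entropy:
            best_entropy, best_thr = entropy, centers[t]
    return float(best_thr)


def _rollball(image: np.ndarray, radius_um: float, pixel_size_um: float) -> np.ndarray:
    radius_px = max(1, int(round(radius_um / pixel_size_um)))
    footprint = morphology.disk(radius_px, decomposition="sequence")
    background = morphology.opening(image, footprint)
    return np.clip(image - background, 0, None)


def preprocess_stack(
    stack: SpheroidStack, rollball_um: float = 100.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Background-subtract, normalize green to red, and combine channels.

    Returns (combined, green_corrected, red_corrected, normalization
    factor). The factor is mean red over red-positive voxels (global Otsu)
    divided by mean green over green-positive voxels; empty positive sets
    give factor 1 with a warning.
    """
    green = np.stack(
        [_rollball(sl, rollball_um, stack.pixel_size_um) for sl in stack.green]
    )
    red = np.stack(
        [_rollball(sl, rollball_um, stack.pixel_size_um) for sl in stack.red]
    )

    def positive_mean(channel: np.ndarray) -> float | None:
        if np.ptp(channel) == 0:
            return None
        thr = filters.threshold_otsu(channel)
        positives = channel[channel > thr]
        return float(positives.mean()) if len(positives) else None

    red_mean = positive_mean(red)
    green_mean = positive_mean(green)
    if red_mean is None or green_mean is None or green_mean == 0:
        warnings.warn("empty positive voxel set: normalization factor 1")
        factor = 1.0
    else:
        factor = red_mean / green_mean
    green = green * factor
    combined = green + red
    return combined, green, red, factor


def slice_outline(
    combined_slice: np.ndarray,
    pixel_size_um: float,
    filter_radius_um: float = 5.0,
) -> np.ndarray | None:
    """Section mask for one slice (median + Gaussian + Huang threshold).

    Returns None for slices where no usable outline exists.
    """
    if np.ptp(combined_slice) == 0:
        return None
    radius_px = max(1, int(round(filter_radius_um / pixel_size_um)))
    med = ndimage.median_filter(combined_slice, footprint=morphology.disk(radius_px))
    blurred = filters.gaussian(med, sigma=radius_px)
    if np.ptp(blurred) == 0:
        return None
    thr = threshold_huang(blurred)
    mask = blurred > thr
    if not mask.any():
        return None
    labeled = measure.label(mask)
    largest = np.argmax(np.bincount(labeled.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labeled == largest)


def segment_slice_nuclei(
    combined_slice: np.ndarray,
    green_slice: np.ndarray,
    red_slice: np.ndarray,
    section_mask: np.ndarray,
    pixel_size_um: float,
    backend: str = "classic",
    min_area_um2: float = 20.0,
) -> pd.DataFrame:
    """Label nuclei in one slice and measure per-nucleus mean g and r.

    Labels are restricted to the section mask. Returns a table with
    ``label``, centroid rows/cols, ``g``, ``r``.
    """
    if not section_mask.any():
        raise ValueError("section mask is empty")
    masked = np.where(section_mask, combined_slice, 0.0)
    labels = _foci.segment_nuclei(
        masked, pixel_size_um, backend=backend, min_area_um2=min_area_um2,
        markers_from="intensity",
    )
    labels[~section_mask] = 0
    records = []
    for region in measure.regionprops(labels):
        sel = labels == region.label
        records.append(
            {
                "label": region.label,
                "row": region.centroid[0],
                "col": region.centroid[1],
                "g": float(green_slice[sel].mean()),
                "r": float(red_slice[sel].mean()),
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["label", "row", "col", "g", "r"]
    )


def fit_sphere_radii(radii_um: np.ndarray, z_um: np.ndarray) -> SphereGeometry:
    """Fit sphere radius and equatorial plane from per-slice section radii.

    ``r_i^2 + z_i^2 = (R^2 - z_c^2) + 2 z_c z_i`` is linear in
    (intercept, z_c) and solved by least squares; exact on noiseless input.
    """
    radii = np.asarray(radii_um, dtype=float)
    zs = np.asarray(z_um, dtype=float)
    if len(radii) < 3:
        raise ValueError("need >= 3 usable slices to fit a sphere")
    if np.ptp(zs) == 0:
        raise ValueError("degenerate fit: all slices at the same z")
    y = radii**2 + zs**2
    X = np.column_stack([np.ones_like(zs), 2 * zs])
    (intercept, z_c), res, *_ = np.linalg.lstsq(X, y, rcond=None)
    r2 = intercept + z_c**2
    if r2 <= 0:
        raise ValueError("sphere fit failed: non-positive radius squared")
    rss = float(res[0]) if len(res) else 0.0
    return SphereGeometry(
        radius_um=float(np.sqrt(r2)),
        z_center_um=float(z_c),
        slice_radii_um=radii,
        rss=rss,
    )


def fit_sphere(
    masks: list[np.ndarray | None], z_um: np.ndarray, pixel_size_um: float
) -> SphereGeometry:
    """Sphere fit from per-slice section masks via equivalent radii.

    Each usable slice contributes an equivalent radius r_i = sqrt(area/pi)
    from its mask area; see :func:`fit_sphere_radii`.
    """
    z_um = np.asarray(z_um, dtype=float)
    radii, zs = [], []
    for mask, z in zip(masks, z_um):
        if mask is None or not mask.any():
            continue
        area_um2 = float(mask.sum()) * pixel_size_um**2
        radii.append(np.sqrt(area_um2 / np.pi))
        zs.append(z)
    return fit_sphere_radii(np.array(radii), np.array(zs))


def distance_3d(
    d2_um: float, z_um: float, geom: SphereGeometry
) -> tuple[float, bool]:
    """Shortest 3D distance to the spheroid surface from a 2D rim distance.

    Returns (distance, clamped). Centroids falling numerically outside the
    fitted sphere are clamped to distance 0 and flagged.
    """
    if d2_um < 0:
        raise ValueError("2D rim distance must be >= 0")
    r_z = geom.section_radius(z_um)  # raises if slice outside sphere
    rho = r_z - d2_um
    radial = np.hypot(rho, z_um - geom.z_center_um)
    if radial > geom.radius_um:
        return 0.0, True
    d3 = geom.radius_um - radial
    return float(min(max(d3, 0.0), geom.radius_um)), False


def classify_green(g: float, r: float, threshold: float = 0.225) -> str | None:
    """'green' iff g/(g+r) > threshold (strict), else 'red'; None if g+r=0."""
    if g < 0 or r < 0:
        raise ValueError("intensities must be >= 0")
    total = g + r
    if total == 0:
        return None
    return "green" if g / total > threshold else "red"


def radial_histogram(cells: pd.DataFrame, bin_um: float = 10.0) -> pd.DataFrame:
    """Per-10-um-bin green/red cell fractions along 3D surface distance.

    ``cells`` needs columns ``d3_um`` and ``cls`` ('green'/'red'). Empty
    bins get count 0 and NaN fractions.
    """
    if "d3_um" not in cells or "cls" not in cells:
        raise ValueError("cells table needs d3_um and cls columns")
    usable = cells.dropna(subset=["d3_um", "cls"])
    bins = np.floor(usable["d3_um"].to_numpy() / bin_um).astype(int)
    n_bins = int(bins.max()) + 1 if len(bins) else 0
    records = []
    for b in range(n_bins):
        sel = bins == b
        n = int(sel.sum())
        if n == 0:
            records.append(
                {
                    "bin": b,
                    "inner_um": b * bin_um,
                    "outer_um": (b + 1) * bin_um,
                    "n_cells": 0,
                    "green_fraction": float("nan"),
                    "red_fraction": float("nan"),
                }
            )
            continue
        green = int((usable["cls"].to_numpy()[sel] == "green").sum())
        records.append(
            {
                "bin": b,
                "inner_um": b * bin_um,
                "outer_um": (b + 1) * bin_um,
                "n_cells": n,
                "green_fraction": green / n,
                "red_fraction": 1 - green / n,
            }
        )
    return pd.DataFrame.from_records(records)


def analyze_stack(
    stack: SpheroidStack,
    rollball_um: float = 100.0,
    green_threshold: float = 0.225,
    bin_um: float = 10.0,
    backend: str = "classic",
    min_cells_per_slice: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SphereGeometry]:
    """End-to-end spheroid profiling: (cells table, histogram, geometry)."""
    combined, green, red, _ = preprocess_stack(stack, rollball_um=rollball_um)
    masks = [
        slice_outline(sl, stack.pixel_size_um) for sl in combined
    ]
    geom = fit_sphere(masks, stack.z_um, stack.pixel_size_um)

    all_cells = []
    for k, mask in enumerate(masks):
        if mask is None:
            continue
        z = float(stack.z_um[k])
        if abs(z - geom.z_center_um) >= geom.radius_um:
            continue
        cells = segment_slice_nuclei(
            combined[k], green[k], red[k], mask, stack.pixel_size_um,
            backend=backend,
        )
        if len(cells) < min_cells_per_slice:
            continue
        if not len(cells):
            continue
        edt = ndimage.distance_transform_edt(mask) * stack.pixel_size_um
        rows = cells["row"].round().astype(int).to_numpy()
        cols = cells["col"].round().astype(int).to_numpy()
        d2 = edt[rows, cols]
        r_z = geom.section_radius(z)
        d3, cls = [], []
        for d2_i, g_i, r_i in zip(d2, cells["g"], cells["r"]):
            dist, _ = distance_3d(min(float(d2_i), r_z), z, geom)
            d3.append(dist)
            cls.append(classify_green(g_i, r_i, threshold=green_threshold))
        cells = cells.assign(slice=k, z_um=z, d2_um=d2, d3_um=d3, cls=cls)
        all_cells.append(cells)
    cells = (
        pd.concat(all_cells, ignore_index=True)
        if all_cells
        else pd.DataFrame(columns=["label", "row", "col", "g", "r", "d3_um", "cls"])
    )
    hist = radial_histogram(cells, bin_um=bin_um)
    return cells, hist, geom
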