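"""Label-free reflectance segmentation of intracellular nanoparticle clusters.

Metallic nanoparticles scatter strongly in reflectance confocal images, so
gold-nanoparticle clusters appear as bright puncta against the weaker
cytoplasmic reflectance.  Segmentation is K-means clustering of pixel
intensities combined with an intensity-quantile threshold: a pixel is
foreground only if it belongs to the brightest K-means cluster AND exceeds
the quantile threshold.  Connected components below a minimum pixel count
are discarded as noise.  Cluster "size" is the equivalent circular diameter
``2 * sqrt(area / pi)`` in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from sklearn.cluster import KMeans
import statsmodels.api as sm

from .sizing import DiameterSample, LogNormalFit, SizeHistogram, fit_lognormal, histogram_diameters

__all__ = [
    "ReflectanceImage",
    "SegmentationMask",
    "ClusterSizeSummary",
    "RegressionResult",
    "normalize_image",
    "segment_gnp",
    "extract_clusters",
    "summarize_group",
    "percent_reduction",
    "fit_cluster_histogram",
    "exposure_regression",
]


@dataclass(frozen=True)
class ReflectanceImage:
    """A single-channel reflectance image with physical pixel size (um/px)."""

    intensities: np.ndarray
    pixel_size: float
    group_min: float = 0.0
    image_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities, dtype=float)
        if a.ndim != 2:
            raise ValueError("intensities must be 2-D")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "intensities", a)


@dataclass(frozen=True)
class SegmentationMask:
    """Labeled components, 0 = background; same shape as the source image."""

    labels: np.ndarray
    pixel_size: float
    image_id: str = ""

    @property
    def n_components(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ClusterSizeSummary:
    """Pooled cluster-size statistics for one exposure group (um)."""

    group_min: float
    n_clusters: int
    mean: float
    sd: float
    max: float
    histogram: SizeHistogram


@dataclass(frozen=True)
class RegressionResult:
    """Polynomial OLS of cluster size on ultrasound exposure time."""

    degree: int
    coefficients: np.ndarray  # highest power first
    r_squared: float
    p_model: float
    n_points: int
    pearson_r: float = float("nan")  # degree-1 fits only


def normalize_image(img: ReflectanceImage) -> ReflectanceImage:
    """Min-max rescale to [0, 1]; a constant image maps to all zeros."""
    a = img.intensities
    lo, hi = float(a.min()), float(a.max())
    scaled = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    return ReflectanceImage(scaled, img.pixel_size, img.group_min, img.image_id)


def segment_gnp(
    img: ReflectanceImage,
    k_clusters: int = 3,
    threshold_quantile: float = 0.95,
    min_cluster_pixels: int = 4,
    seed: int = 0,
) -> SegmentationMask:
    """K-means + intensity-quantile segmentation of bright nanoparticle regions.

    K-means (10 restarts, seeded) partitions pixel intensities into
    ``k_clusters`` levels; the foreground is the intersection of the
    brightest cluster with pixels above the ``threshold_quantile`` intensity
    quantile.  8-connected components with fewer than ``min_cluster_pixels``
    pixels are removed and the remainder labeled consecutively.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    if not 0 <= threshold_quantile <= 1:
        raise ValueError("threshold_quantile must be in [0, 1]")
    a = img.intensities
    distinct = np.unique(a)
    if distinct.size == 1:
        # constant (all-background) image: trivially no foreground
        return SegmentationMask(labels=np.zeros(a.shape, dtype=int),
                                pixel_size=img.pixel_size, image_id=img.image_id)
    if distinct.size < k_clusters:
        raise ValueError(
            f"image has {distinct.size} distinct intensities < k_clusters={k_clusters}"
        )
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed)
    assign = km.fit_predict(a.reshape(-1, 1)).reshape(a.shape)
    bright = int(np.argmax(km.cluster_centers_.ravel()))
    fg = (assign == bright) & (a > np.quantile(a, threshold_quantile))
    labels = measure.label(fg, connectivity=2)
    if min_cluster_pixels > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        too_small = np.flatnonzero(counts < min_cluster_pixels)
        labels[np.isin(labels, too_small[too_small > 0])] = 0
        labels = measure.label(labels > 0, connectivity=2)
    return SegmentationMask(labels=labels, pixel_size=img.pixel_size,
                            image_id=img.image_id)


def extract_clusters(mask: SegmentationMask, pixel_size: float | None = None) -> pd.DataFrame:
    """One row per labeled component with area and equivalent diameter (um)."""
    px = mask.pixel_size if pixel_size is None else pixel_size
    cols = ["image_id", "label", "pixel_count", "equivalent_diameter_um",
            "centroid_x_um", "centroid_y_um"]
    if mask.labels.max() == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for rp in measure.regionprops(mask.labels):
        rows.append({
            "image_id": mask.image_id,
            "label": rp.label,
            "pixel_count": rp.area,
            "equivalent_diameter_um": 2.0 * math.sqrt(rp.area / math.pi) * px,
            "centroid_x_um": rp.centroid[1] * px,
            "centroid_y_um": rp.centroid[0] * px,
        })
    return pd.DataFrame(rows, columns=cols)


def summarize_group(
    tables: Iterable[pd.DataFrame],
    group_min: float,
    bin_width_um: float = 0.1,
) -> ClusterSizeSummary:
    """Pool cluster sizes across a group's images and summarize.

    The SD is the sample SD of the pooled per-cluster sizes (not of per-image
    means), matching the mean +/- SD convention for cluster-size reporting.
    """
    arrays = [
        t["equivalent_diameter_um"].to_numpy(dtype=float)
        for t in tables if len(t)
    ]
    sizes = np.concatenate(arrays) if arrays else np.array([])
    if sizes.size == 0:
        raise ValueError(f"group {group_min}: no clusters to summarize")
    hist = histogram_diameters(DiameterSample(sizes), bin_width_um)
    return ClusterSizeSummary(
        group_min=group_min,
        n_clusters=int(sizes.size),
        mean=float(sizes.mean()),
        sd=float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0,
        max=float(sizes.max()),
        histogram=hist,
    )


def percent_reduction(control_mean: float, treated_mean: float) -> float:
    """Percent decrease of the treated mean relative to the control mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (control_mean - treated_mean) / control_mean


def fit_cluster_histogram(summary: ClusterSizeSummary) -> LogNormalFit:
    """Log-normal fit of a group's cluster-size histogram (um units)."""
    return fit_lognormal(summary.histogram)


def exposure_regression(
    x: Sequence[float],
    y: Sequence[float],
    degree: int = 1,
) -> RegressionResult:
    """OLS of size on a polynomial in exposure time, with F-test p-value.

    For degree 1 the Pearson correlation of x and y is reported alongside,
    and ``r_squared == pearson_r**2`` by construction.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    # degree+1 points give a saturated fit (R^2 = 1, no model p-value);
    # degree+2 are needed for a finite F-test.
    if x.size < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for a degree-{degree} model")
    design = sm.add_constant(np.column_stack([x**p for p in range(1, degree + 1)]))
    fit = sm.OLS(y, design).fit()
    coefs = np.concatenate([fit.params[1:][::-1], fit.params[:1]])
    pearson = float(stats.pearsonr(x, y).statistic) if degree == 1 else float("nan")
    return RegressionResult(
        degree=degree,
        coefficients=coefs,
        r_squared=float(fit.rsquared),
        p_model=float(fit.f_pvalue),
        n_points=int(x.size),
        pearson_r=pearson,
    )
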