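"""Host–microbiome boundary extraction and distance-referenced profiles.

The boundary is traced from a greyscale tissue image: box-average
smoothing with a kernel specified in µm (100 µm default), binarization
at an 8-bit threshold (80 for normal tissue, 100 for tumour-laden
tissue as working defaults), and contour extraction of the foreground
mask.  Distances from molecules, spots or cells to the traced polyline
then parameterize density profiles, genus abundance profiles and
cell-position rescaling between sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter
from skimage import measure

log = logging.getLogger(__name__)


@dataclass
class BoundaryContour:
    """Traced foreground boundary: one or more polylines in µm."""

    polylines: list  # each an (m, 2) array of (x, y) µm
    pixel_size: float
    kernel_um: float
    threshold: int

    def as_multilinestring(self):
        return shapely.MultiLineString([p.tolist() for p in self.polylines])

    @property
    def n_vertices(self) -> int:
        return sum(len(p) for p in self.polylines)


def detect_boundary(
    image: np.ndarray,
    pixel_size: float,
    kernel_um: float = 100.0,
    threshold: int = 80,
    min_vertices: int = 3,
    min_length_um: float = 0.0,
    trim_border: bool = True,
) -> BoundaryContour:
    """Extract tissue-boundary contours from an 8-bit greyscale image.

    The kernel is rounded to the nearest odd pixel count.  Foreground is
    pixels at or above the threshold after smoothing.  Contours shorter
    than ``min_length_um`` or with fewer than ``min_vertices`` vertices
    are dropped.  With ``trim_border`` (default), contour runs lying on
    the image frame are removed — a mask clipped by the field of view
    otherwise contributes frame segments that are not tissue boundary.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D greyscale image")
    k = max(1, int(round(kernel_um / pixel_size)))
    if k % 2 == 0:
        k += 1
    blurred = uniform_filter(img, size=k, mode="nearest")
    mask = blurred >= threshold
    if not mask.any():
        raise ValueError(
            f"empty foreground at threshold {threshold}; lower the threshold"
        )
    if mask.all():
        raise ValueError(
            f"entire image is foreground at threshold {threshold}; raise the threshold"
        )
    nrow, ncol = mask.shape
    pieces = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        if trim_border:
            margin = 1.0
            interior = (
                (contour[:, 0] > margin) & (contour[:, 0] < nrow - 1 - margin)
                & (contour[:, 1] > margin) & (contour[:, 1] < ncol - 1 - margin)
            )
            # split the polyline at frame-touching runs
            breaks = np.nonzero(~interior)[0]
            segments = np.split(contour, breaks) if len(breaks) else [contour]
            for seg in segments:
                seg = seg[1:] if len(seg) and not interior[0] else seg
                pieces.append(seg)
        else:
            pieces.append(contour)
    polylines = []
    for contour in pieces:
        keep = np.ones(len(contour), dtype=bool)
        if trim_border and len(contour):
            keep = (
                (contour[:, 0] > 1.0) & (contour[:, 0] < nrow - 2.0)
                & (contour[:, 1] > 1.0) & (contour[:, 1] < ncol - 2.0)
            )
        xy = np.column_stack([contour[keep, 1], contour[keep, 0]]) * pixel_size
        if len(xy) < min_vertices:
            continue
        length = float(np.sqrt((np.diff(xy, axis=0) ** 2).sum(axis=1)).sum())
        if length < min_length_um:
            continue
        polylines.append(xy)
    if not polylines:
        raise ValueError("no contours survive the length filter")
    return BoundaryContour(
        polylines=polylines, pixel_size=pixel_size,
        kernel_um=kernel_um, threshold=threshold,
    )


def distance_to_boundary(entities: np.ndarray, contour: BoundaryContour) -> np.ndarray:
    """Minimum point-to-segment distance (µm) from each entity to the contour."""
    pts = np.asarray(entities, dtype=float).reshape(-1, 2)
    if not contour.polylines:
        raise ValueError("empty contour")
    mls = contour.as_multilinestring()
    return shapely.distance(shapely.points(pts), mls)


@dataclass
class DistanceProfile:
    """Probability density of entities over distance to the boundary."""

    grid: np.ndarray
    density: np.ndarray
    mode: float
    bandwidth: float | None = None


def density_profile(
    distances: np.ndarray,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    n_grid: int = 512,
) -> DistanceProfile:
    """Gaussian kernel density of boundary distances (Silverman bandwidth).

    The density is renormalized on its evaluation grid so it integrates
    to 1 there; the mode is the grid point of maximum density.  A
    degenerate sample (all distances equal) collapses to a single-point
    spike at that distance.
    """
    from scipy.stats import gaussian_kde

    d = np.asarray(distances, dtype=float).ravel()
    if len(d) < 10:
        raise ValueError("need at least 10 entities for a density profile")
    if np.ptp(d) == 0:
        g = np.array([d[0]])
        return DistanceProfile(grid=g, density=np.array([np.inf]), mode=float(d[0]))
    kde = gaussian_kde(d, bw_method=bandwidth if bandwidth else "silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    if grid is None:
        grid = np.linspace(d.min() - 4 * bw, d.max() + 4 * bw, n_grid)
    dens = kde(grid)
    area = np.trapezoid(dens, grid)
    if area > 0:
        dens = dens / area
    return DistanceProfile(
        grid=grid, density=dens, mode=float(grid[int(np.argmax(dens))]), bandwidth=bw
    )


def genus_distance_profile(
    tm,
    distances: pd.Series,
    bins: np.ndarray | int = 10,
    conditions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-condition relative genus abundance vs distance to the boundary.

    All conditions share identical bin edges so profiles are directly
    comparable; a condition with no microbial counts is omitted with a
    warning.  Returns percent abundance indexed by (condition, bin).
    """
    d = distances.reindex(tm.spot_ids).to_numpy(dtype=float)
    if conditions is None:
        conditions = pd.Series("all", index=tm.spot_ids)
    cond = conditions.reindex(tm.spot_ids).to_numpy()
    ok = np.isfinite(d) & pd.notna(cond)
    edges = (
        np.histogram_bin_edges(d[ok], bins=bins)
        if np.isscalar(bins)
        else np.asarray(bins, dtype=float)
    )
    n_bins = len(edges) - 1
    bin_idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)

    frames = {}
    for c in pd.unique(cond[ok]):
        sel = ok & (cond == c)
        counts = np.zeros((n_bins, tm.n_taxa), dtype=np.int64)
        np.add.at(counts, bin_idx[sel], tm.counts[sel])
        total = counts.sum()
        if total == 0:
            log.warning("condition %r has zero microbial counts; omitted", c)
            continue
        bin_tot = counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * counts / bin_tot
        pct[bin_tot[:, 0] == 0] = np.nan
        frames[c] = pd.DataFrame(pct, index=pd.RangeIndex(n_bins, name="bin"),
                                 columns=tm.taxa.index)
    if not frames:
        raise ValueError("no condition has microbial counts")
    out = pd.concat(frames, names=["condition"])
    out.attrs["bin_edges"] = edges
    return out


def rescale_positions(
    source: Mapping[str, np.ndarray],
    target: Mapping[str, np.ndarray],
    reference_type: str,
    mode: str = "scale",
) -> tuple[dict[str, np.ndarray], float, float]:
    """Map one section's cell distances onto another's coordinate scale.

    The affine map x -> a·x + b is chosen from the reference cell type
    (for example mature enterocytes) and applied to every cell type of
    the source section.  ``mode="scale"`` (default) fixes b = 0 and
    matches the reference medians; ``mode="affine"`` matches the 25th
    and 75th percentiles of the reference type exactly.
    """
    if reference_type not in source or reference_type not in target:
        raise ValueError(f"reference type {reference_type!r} absent from a section")
    src = np.asarray(source[reference_type], dtype=float)
    tgt = np.asarray(target[reference_type], dtype=float)
    if mode == "scale":
        m_src, m_tgt = np.median(src), np.median(tgt)
        if m_src == 0:
            raise ValueError("source reference median is 0; cannot form a pure scaling")
        a, b = m_tgt / m_src, 0.0
    elif mode == "affine":
        q_src = np.percentile(src, [25, 75])
        q_tgt = np.percentile(tgt, [25, 75])
        span = q_src[1] - q_src[0]
        if span == 0:
            raise ValueError("source reference has zero IQR; affine map undefined")
        a = (q_tgt[1] - q_tgt[0]) / span
        b = q_tgt[0] - a * q_src[0]
    else:
        raise ValueError("mode must be 'scale' or 'affine'")
    rescaled = {ct: a * np.asarray(v, dtype=float) + b for ct, v in source.items()}
    return rescaled, float(a), float(b)
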