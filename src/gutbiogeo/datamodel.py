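"""Core in-memory containers for spatial host–microbiome data.

The package works with four kinds of objects:

``SpatialSection``
    The geometry of one tissue section: barcoded capture locations
    (spots or bins) with planar coordinates in micrometres and a
    region label (``tissue`` / ``lumen`` / ``background``).

``TaxonMatrix``
    Spot-by-taxon unique-molecule counts with a rank-aware taxonomy
    lineage per taxon (superkingdom … species).

``HostMatrix``
    Spot-by-gene counts with optional spliced/unspliced layers and a
    biotype annotation per gene.

``PointPattern``
    A planar point set (one taxon's molecule locations) inside a
    rectangular observation window; the substrate for Ripley-type
    statistics.

Coordinates are micrometres, origin at the image top-left with y
increasing downward (raster convention); all distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

#: Taxonomic ranks recognised by :func:`aggregate_rank`, coarse to fine.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

REGIONS = ("tissue", "lumen", "background")

BIOTYPES = ("coding", "lncRNA", "snoRNA", "snRNA", "miRNA", "miscRNA", "rRNA", "other")

#: Biotypes counted as non-coding in ratio maps.
NONCODING_BIOTYPES = frozenset(BIOTYPES) - {"coding"}


class ReadClassificationRecord(NamedTuple):
    """One read's taxonomic classification, tagged with barcode and UMI.

    ``status`` is ``"C"`` (classified) or ``"U"`` (unclassified),
    following the Kraken2 standard-output convention.
    """

    status: str
    taxid: int
    barcode: str
    umi: str


def convex_hull_area(xy: np.ndarray) -> float:
    """Area (µm²) of the convex hull of a point set; 0 for degenerate sets."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # "volume" is area in 2D
    except QhullError:
        return 0.0


@dataclass
class SpatialSection:
    """Spot/bin geometry of one section.

    Parameters
    ----------
    spots
        DataFrame indexed by barcode with columns ``x``, ``y`` (µm) and
        ``region`` (one of :data:`REGIONS`).
    platform
        ``"low_res"`` (array spots, ~55 µm pitch) or ``"high_res"``
        (sub-micrometre pixels aggregated into bins).
    pixel_size
        µm per raw pixel; meaningful for high-resolution platforms.
    window_area
        Observation-window area A (µm²) used by Ripley statistics.  If
        not given it defaults to the convex-hull area of the annotated
        (non-background) spots.
    """

    spots: pd.DataFrame
    platform: str = "low_res"
    pixel_size: float | None = None
    window_area: float | None = None

    def __post_init__(self) -> None:
        required = {"x", "y", "region"}
        missing = required - set(self.spots.columns)
        if missing:
            raise ValueError(f"spots table missing columns: {sorted(missing)}")
        if self.spots.index.has_duplicates:
            dups = self.spots.index[self.spots.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate barcodes: {dups}")
        xy = self.spots[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite spot coordinates")
        bad = set(self.spots["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        if self.window_area is None:
            annotated = self.spots[self.spots["region"] != "background"]
            self.window_area = convex_hull_area(annotated[["x", "y"]].to_numpy())
        if self.window_area < 0:
            raise ValueError("window_area must be >= 0")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def barcodes(self) -> pd.Index:
        return self.spots.index

    def coords(self, barcodes: Iterable[str] | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally for a barcode subset."""
        df = self.spots if barcodes is None else self.spots.loc[list(barcodes)]
        return df[["x", "y"]].to_numpy(dtype=float)

    def subset(self, regions: Iterable[str]) -> "SpatialSection":
        keep = self.spots["region"].isin(list(regions))
        return replace(self, spots=self.spots.loc[keep].copy(), window_area=self.window_area)


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (spots x features)")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return counts.astype(np.int64)


@dataclass
class TaxonMatrix:
    """Spot × taxon unique-molecule counts with lineage annotation.

    ``taxa`` is indexed by taxid (or by rank-level name after
    aggregation) and carries ``name``, ``rank`` and one column per
    lineage rank in :data:`RANKS` (empty string where unannotated).
    """

    counts: np.ndarray
    spot_ids: pd.Index
    taxa: pd.DataFrame
    section: SpatialSection | None = None

    def __post_init__(self) -> None:
        self.counts = _check_counts(self.counts)
        self.spot_ids = pd.Index(self.spot_ids)
        if self.counts.shape != (len(self.spot_ids), len(self.taxa)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.spot_ids)} spots x {len(self.taxa)} taxa"
            )
        if self.spot_ids.has_duplicates:
            raise ValueError("duplicate spot ids")
        if self.taxa.index.has_duplicates:
            raise ValueError("duplicate taxa")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def taxon_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.taxa.index, name="count")

    def spot_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.spot_ids, name="count")

    def superkingdom_totals(self) -> pd.Series:
        """Unique molecules per superkingdom (unannotated taxa -> '')."""
        sk = self.taxa.get("superkingdom", pd.Series("", index=self.taxa.index))
        return self.taxon_totals().groupby(sk.to_numpy()).sum()

    def drop_taxa(self, taxa: Iterable) -> "TaxonMatrix":
        drop = set(taxa)
        keep = np.array([t not in drop for t in self.taxa.index])
        return TaxonMatrix(
            counts=self.counts[:, keep],
            spot_ids=self.spot_ids,
            taxa=self.taxa.loc[keep].copy(),
            section=self.section,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.spot_ids, columns=self.taxa.index)

    def to_anndata(self):
        """AnnData view: barcodes as obs, taxa as var (counts in X)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.astype(np.float64),
            obs=pd.DataFrame(index=self.spot_ids.astype(str)),
            var=self.taxa.copy().set_axis(self.taxa.index.astype(str)),
        )
        if self.section is not None:
            common = self.spot_ids.intersection(self.section.barcodes)
            if len(common) == len(self.spot_ids):
                adata.obsm["spatial"] = self.section.coords(self.spot_ids)
        return adata


@dataclass
class HostMatrix:
    """Spot × gene counts with spliced/unspliced layers and biotypes."""

    counts: np.ndarray
    spot_ids: pd.Index
    genes: pd.DataFrame  # indexed by gene, column "biotype"
    layers: dict = field(default_factory=dict)  # {"spliced": arr, "unspliced": arr}
    section: SpatialSection | None = None

    def __post_init__(self) -> None:
        self.counts = _check_counts(self.counts)
        self.spot_ids = pd.Index(self.spot_ids)
        if self.counts.shape != (len(self.spot_ids), len(self.genes)):
            raise ValueError("counts shape does not match spots x genes")
        if "biotype" not in self.genes.columns:
            raise ValueError("genes table must carry a 'biotype' column")
        for name, layer in self.layers.items():
            layer = _check_counts(layer)
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape mismatch")
            self.layers[name] = layer
        if "spliced" in self.layers and "unspliced" in self.layers:
            if (self.layers["spliced"] + self.layers["unspliced"] > self.counts).any():
                raise ValueError("spliced + unspliced exceeds total counts")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PointPattern:
    """Planar point set in a rectangular observation window.

    ``window`` is ``(x0, y0, x1, y1)`` in µm.  ``area`` overrides the
    rectangle area when the analysed window is not the bounding
    rectangle (symbol A in the Ripley estimator).
    """

    points: np.ndarray
    window: tuple[float, float, float, float]
    mark: str | None = None
    area: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ValueError("window must have positive extent")
        if len(self.points):
            inside = (
                (self.points[:, 0] >= x0)
                & (self.points[:, 0] <= x1)
                & (self.points[:, 1] >= y0)
                & (self.points[:, 1] <= y1)
            )
            if not inside.all():
                raise ValueError("points outside the stated window")
        if self.area is not None and self.area <= 0:
            raise ValueError("window area must be > 0")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def window_area(self) -> float:
        if self.area is not None:
            return float(self.area)
        x0, y0, x1, y1 = self.window
        return float((x1 - x0) * (y1 - y0))


@dataclass
class BinnedGrid:
    """Square-binned counts on a regular grid.

    Bin (i, j) covers the half-open square
    ``[i*s, (i+1)*s) x [j*s, (j+1)*s)`` offset by ``origin`` (in bin
    units), where ``s`` is ``bin_size`` in µm.
    """

    counts: np.ndarray  # (nx, ny) integer counts
    bin_size: float
    origin: tuple[int, int]  # index of bin (0, 0) in absolute bin units

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ox, oy = self.origin
        s = self.bin_size
        cx = (np.arange(self.counts.shape[0]) + ox + 0.5) * s
        cy = (np.arange(self.counts.shape[1]) + oy + 0.5) * s
        return cx, cy


def bin_indices(x: np.ndarray, y: np.ndarray, bin_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Half-open square-bin indices: coordinate c falls in bin floor(c/s)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    ix = np.floor(np.asarray(x, dtype=float) / bin_size).astype(np.int64)
    iy = np.floor(np.asarray(y, dtype=float) / bin_size).astype(np.int64)
    return ix, iy


def bin_points(pattern: PointPattern, bin_size: float) -> BinnedGrid:
    """Assign each point of a pattern to a square bin of side ``bin_size`` µm.

    Bins use half-open intervals [k·s, (k+1)·s) so every point lands in
    exactly one bin and the total count is conserved.
    """
    if pattern.n == 0:
        return BinnedGrid(np.zeros((0, 0), dtype=np.int64), float(bin_size), (0, 0))
    ix, iy = bin_indices(pattern.points[:, 0], pattern.points[:, 1], bin_size)
    ox, oy = int(ix.min()), int(iy.min())
    nx, ny = int(ix.max()) - ox + 1, int(iy.max()) - oy + 1
    counts = np.zeros((nx, ny), dtype=np.int64)
    np.add.at(counts, (ix - ox, iy - oy), 1)
    return BinnedGrid(counts, float(bin_size), (ox, oy))


def aggregate_rank(tm: TaxonMatrix, rank: str) -> TaxonMatrix:
    """Collapse a taxon matrix to a taxonomic rank.

    Taxa whose lineage is unannotated at ``rank`` (classified at an
    internal node above it, or simply missing) are pooled into a single
    ``unresolved@<rank>`` bucket so per-spot totals are conserved
    exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {list(RANKS)}")
    lineage = tm.taxa.get(rank)
    if lineage is None:
        labels = np.array([f"unresolved@{rank}"] * tm.n_taxa, dtype=object)
    else:
        labels = lineage.fillna("").astype(str).to_numpy(dtype=object)
        labels[labels == ""] = f"unresolved@{rank}"
    order = pd.Index(pd.unique(labels))
    pos = order.get_indexer(labels)
    out = np.zeros((tm.n_spots, len(order)), dtype=np.int64)
    np.add.at(out.T, pos, tm.counts.T)

    # keep the coarser lineage columns that are constant within each group
    keep_ranks = RANKS[: RANKS.index(rank) + 1]
    rows = []
    for name in order:
        members = tm.taxa.loc[labels == name]
        row = {"name": name, "rank": rank}
        for r in keep_ranks:
            if r in members.columns:
                vals = set(members[r].fillna("").astype(str)) - {""}
                row[r] = vals.pop() if len(vals) == 1 else ""
            else:
                row[r] = ""
        row[rank] = name if not name.startswith("unresolved@") else ""
        rows.append(row)
    taxa = pd.DataFrame(rows, index=order)
    return TaxonMatrix(counts=out, spot_ids=tm.spot_ids, taxa=taxa, section=tm.section)
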