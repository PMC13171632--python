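"""Composition statistics: relative abundance, richness, transverse
profiles and host splice/biotype maps.

The transverse axis runs from tissue to lumen; spots are ordered by
their minimum Euclidean distance to the lumen-associated region and cut
into equal-width distance bins (five by default), within which taxon
relative abundances are aggregated and z-scored across bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datamodel import HostMatrix, NONCODING_BIOTYPES, SpatialSection, TaxonMatrix, bin_indices
from .datamodel import aggregate_rank


def relative_abundance(tm: TaxonMatrix, rank: str | None = None) -> pd.Series:
    """Per-taxon fraction of bacterial unique molecules.

    Restricts to taxa annotated as Bacteria when superkingdom
    annotation exists; fractions sum to 1 over taxa at the requested
    rank.
    """
    sub = tm
    sk = tm.taxa.get("superkingdom")
    if sk is not None and (sk == "Bacteria").any():
        sub = tm.drop_taxa(tm.taxa.index[sk != "Bacteria"])
    if rank is not None:
        sub = aggregate_rank(sub, rank)
    totals = sub.taxon_totals().astype(float)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("zero bacterial total; cannot form relative abundances")
    return totals / grand


def richness_per_spot(tm: TaxonMatrix, min_fraction: float = 1e-4) -> pd.Series:
    """Unique taxa per spot after the whole-sample rare-taxon filter.

    Taxa accounting for ``min_fraction`` (default 0.01%) **or less** of
    the sample's total molecules are removed before counting, so only
    taxa strictly above the threshold contribute to richness.
    """
    total = tm.total
    if total == 0:
        return pd.Series(0, index=tm.spot_ids, dtype=int)
    frac = tm.taxon_totals().to_numpy(dtype=float) / total
    keep = frac > min_fraction
    richness = (tm.counts[:, keep] > 0).sum(axis=1)
    return pd.Series(richness.astype(int), index=tm.spot_ids, name="richness")


def distance_to_region(section: SpatialSection, target_region: str = "lumen") -> pd.Series:
    """Minimum Euclidean distance (µm) from each spot to the target region."""
    targets = section.spots[section.spots["region"] == target_region]
    if targets.empty:
        raise ValueError(f"no spots labelled {target_region!r}")
    tree = cKDTree(targets[["x", "y"]].to_numpy(dtype=float))
    d, _ = tree.query(section.spots[["x", "y"]].to_numpy(dtype=float))
    return pd.Series(d, index=section.barcodes, name=f"dist_to_{target_region}")


@dataclass
class TransverseProfile:
    """Binned tissue→lumen composition profile.

    ``abundance`` is percent relative abundance per (bin, taxon);
    ``z`` the per-taxon z-score of that abundance across bins
    (0 everywhere for taxa with zero across-bin variance).  Bin 0 is
    the tissue-most bin.
    """

    bin_edges: np.ndarray  # distance-to-lumen edges, descending bins
    abundance: pd.DataFrame  # bins x taxa, percent
    z: pd.DataFrame  # bins x taxa


def transverse_profile(
    tm: TaxonMatrix,
    section: SpatialSection,
    n_bins: int = 5,
    rank: str | None = "phylum",
    axis_region: str = "lumen",
) -> TransverseProfile:
    """Relative abundance per distance bin along the tissue→lumen axis.

    Spots are ordered by minimum distance to ``axis_region`` and cut
    into equal-width bins; bin 0 is always the tissue-most bin.  The
    default axis (distance to the lumen-associated region) matches the
    low-resolution convention where microbial signal spreads into
    tissue-covered spots; ``axis_region="tissue"`` spreads lumen-
    resident signal over distinct distances instead.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sub = tm
    sk = tm.taxa.get("superkingdom")
    if sk is not None and (sk == "Bacteria").any():
        sub = tm.drop_taxa(tm.taxa.index[sk != "Bacteria"])
    if rank is not None:
        sub = aggregate_rank(sub, rank)

    dist = distance_to_region(section, axis_region).reindex(sub.spot_ids)
    annotated = section.spots["region"].reindex(sub.spot_ids) != "background"
    ok = annotated.to_numpy() & dist.notna().to_numpy()
    d = dist.to_numpy(dtype=float)[ok]
    counts = sub.counts[ok]
    if len(np.unique(d)) < n_bins:
        raise ValueError(
            f"only {len(np.unique(d))} distinct spot distances; "
            f"use fewer than {n_bins} bins"
        )
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    if axis_region == "lumen":
        # large distance-to-lumen = tissue side; flip so bin 0 = tissue-most
        idx = (n_bins - 1) - idx

    binned = np.zeros((n_bins, counts.shape[1]), dtype=np.int64)
    np.add.at(binned, idx, counts)
    bin_tot = binned.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * binned / bin_tot
    pct[bin_tot[:, 0] == 0] = np.nan

    mean = np.nanmean(pct, axis=0)
    sd = np.nanstd(pct, axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (pct - mean) / sd
    z[:, sd == 0] = 0.0
    z = np.nan_to_num(z, nan=0.0) if np.isnan(pct).any() else z
    cols = sub.taxa.index
    bins = pd.RangeIndex(n_bins, name="bin")
    return TransverseProfile(
        bin_edges=edges[::-1].copy() if axis_region == "lumen" else edges,
        abundance=pd.DataFrame(pct, index=bins, columns=cols),
        z=pd.DataFrame(z, index=bins, columns=cols),
    )


def splice_outliers(hm: HostMatrix, n_sd: float = 5.0) -> pd.DataFrame:
    """Flag coding genes far from the spliced = unspliced diagonal.

    The residual is the signed perpendicular distance from the
    (spliced, unspliced) totals to the line y = x, i.e.
    (unspliced − spliced)/√2; a gene is an outlier when its absolute
    residual exceeds ``n_sd`` population standard deviations.
    """
    if "spliced" not in hm.layers or "unspliced" not in hm.layers:
        raise ValueError("spliced and unspliced layers are required")
    coding = (hm.genes["biotype"] == "coding").to_numpy()
    if coding.sum() < 3:
        raise ValueError("need at least 3 coding genes")
    s = hm.layers["spliced"][:, coding].sum(axis=0).astype(float)
    u = hm.layers["unspliced"][:, coding].sum(axis=0).astype(float)
    residual = (u - s) / np.sqrt(2.0)
    sd = residual.std(ddof=0)
    outlier = np.abs(residual) > n_sd * sd if sd > 0 else np.zeros(len(s), bool)
    return pd.DataFrame(
        {"spliced": s.astype(int), "unspliced": u.astype(int),
         "residual": residual, "outlier": outlier},
        index=hm.genes.index[coding],
    )


def biotype_ratio_map(
    hm: HostMatrix, section: SpatialSection, bin_size: float = 20.0
) -> pd.DataFrame:
    """Non-coding and unspliced molecule ratios per square spatial bin.

    Each spot's molecules are assigned to the 20 µm (default) square
    bin containing the spot; bins with zero molecules are omitted.
    """
    xy = section.coords(hm.spot_ids)
    ix, iy = bin_indices(xy[:, 0], xy[:, 1], bin_size)
    keys = pd.MultiIndex.from_arrays([ix, iy], names=["bin_x", "bin_y"])
    total = hm.counts.sum(axis=1).astype(float)
    noncoding_mask = hm.genes["biotype"].isin(NONCODING_BIOTYPES).to_numpy()
    noncoding = hm.counts[:, noncoding_mask].sum(axis=1).astype(float)
    df = pd.DataFrame({"total": total, "noncoding": noncoding}, index=keys)
    if "unspliced" in hm.layers:
        df["unspliced"] = hm.layers["unspliced"].sum(axis=1).astype(float)
    agg = df.groupby(level=["bin_x", "bin_y"]).sum()
    agg = agg[agg["total"] > 0]
    out = pd.DataFrame(index=agg.index)
    out["total"] = agg["total"].astype(int)
    out["noncoding_ratio"] = agg["noncoding"] / agg["total"]
    if "unspliced" in agg.columns:
        out["unspliced_ratio"] = agg["unspliced"] / agg["total"]
    return out
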