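"""Build spot × taxon matrices from read-level classifications.

Covers UMI-collapsing demultiplexing of classified reads, the sterile
control contaminant filter (parts-per-million threshold on unique
molecules), microbial library fractions per superkingdom, paired
with/without in-situ-polyadenylation enrichment, and Gram-stain
aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import RANKS, ReadClassificationRecord, SpatialSection, TaxonMatrix

log = logging.getLogger(__name__)

#: Superkingdoms accounted as microbial in enrichment and fraction math.
MICROBIAL_SUPERKINGDOMS = ("Bacteria", "Archaea", "Viruses")


def _default_taxa(taxids: Iterable[int]) -> pd.DataFrame:
    idx = pd.Index(list(taxids), name="taxid")
    taxa = pd.DataFrame(
        {"name": [f"taxid:{t}" for t in idx], "rank": "species"}, index=idx
    )
    for r in RANKS:
        taxa[r] = ""
    return taxa


def demux_classified_reads(
    records: Iterable[ReadClassificationRecord],
    section: SpatialSection,
    taxonomy: pd.DataFrame | None = None,
    max_malformed_fraction: float = 0.01,
) -> TaxonMatrix:
    """Collapse classified reads into unique molecules per (spot, taxon).

    One unique molecule per distinct (barcode, UMI, taxid) triple.
    Unclassified reads are dropped; reads whose barcode is not in the
    section are dropped with a logged count.  Malformed records are
    skipped, but more than ``max_malformed_fraction`` of the stream
    malformed is an error.

    With ``taxonomy`` given, its full taxid set defines the feature
    axis (taxa with zero observed molecules keep an all-zero column);
    otherwise the observed taxids do.
    """
    known = set(section.barcodes)
    triples: set[tuple[str, str, int]] = set()
    n_total = n_malformed = n_unknown_barcode = 0
    for rec in records:
        n_total += 1
        try:
            status, taxid, barcode, umi = rec.status, int(rec.taxid), rec.barcode, rec.umi
            if status not in ("C", "U") or not barcode or not umi:
                raise ValueError
            if status == "C" and taxid <= 0:
                raise ValueError
        except (ValueError, TypeError, AttributeError):
            n_malformed += 1
            continue
        if status != "C":
            continue
        if barcode not in known:
            n_unknown_barcode += 1
            continue
        triples.add((barcode, umi, taxid))
    if n_total and n_malformed / n_total > max_malformed_fraction:
        raise ValueError(
            f"{n_malformed}/{n_total} records malformed "
            f"(> {max_malformed_fraction:.0%} of stream)"
        )
    if n_unknown_barcode:
        log.info("dropped %d classified reads with barcodes absent from section", n_unknown_barcode)

    if taxonomy is not None:
        observed = {t for _, _, t in triples}
        extra = sorted(observed - set(taxonomy.index))
        taxids = list(taxonomy.index) + extra
        taxa = pd.concat([taxonomy, _default_taxa(extra)]) if extra else taxonomy.copy()
    else:
        taxids = sorted({t for _, _, t in triples})
        taxa = _default_taxa(taxids)
    tax_pos = {t: j for j, t in enumerate(taxids)}
    bc_pos = {b: i for i, b in enumerate(section.barcodes)}
    counts = np.zeros((section.n_spots, len(taxids)), dtype=np.int64)
    for barcode, _umi, taxid in triples:
        counts[bc_pos[barcode], tax_pos[taxid]] += 1
    return TaxonMatrix(counts=counts, spot_ids=section.barcodes, taxa=taxa, section=section)


@dataclass
class ExclusionList:
    """Contaminant taxa identified in a sterile control.

    A taxid is listed iff its unique-molecule frequency in the control
    reached ``threshold_ppm`` parts per million.
    """

    taxids: set = field(default_factory=set)
    threshold_ppm: float = 1.0
    inclusive: bool = True


def build_exclusion_list(
    control: TaxonMatrix, threshold_ppm: float = 1.0, inclusive: bool = True
) -> ExclusionList:
    """Taxa at >= ``threshold_ppm`` unique molecules per million in a control.

    ``inclusive`` keeps the boundary case (exactly the threshold) on the
    excluded side, the stricter reading of the filter.
    """
    total = control.total
    if total == 0:
        log.warning("empty sterile control: no taxa excluded")
        return ExclusionList(set(), threshold_ppm, inclusive)
    ppm = 1e6 * control.taxon_totals().to_numpy(dtype=float) / total
    hit = ppm >= threshold_ppm if inclusive else ppm > threshold_ppm
    return ExclusionList(set(control.taxa.index[hit]), threshold_ppm, inclusive)


def apply_exclusion(tm: TaxonMatrix, ex: ExclusionList) -> TaxonMatrix:
    """Drop excluded taxa; remaining counts are untouched."""
    return tm.drop_taxa(ex.taxids)


def microbial_fraction(
    tm: TaxonMatrix, host_unique_molecules: int,
    superkingdoms: Iterable[str] = MICROBIAL_SUPERKINGDOMS,
) -> dict[str, float]:
    """Percent of the total library per microbial superkingdom.

    The denominator is total library size: host-aligned plus all
    classified unique molecules.
    """
    if host_unique_molecules < 0:
        raise ValueError("host_unique_molecules must be >= 0")
    denom = host_unique_molecules + tm.total
    if denom == 0:
        raise ValueError("zero total library size")
    sk_totals = tm.superkingdom_totals()
    return {
        sk: 100.0 * float(sk_totals.get(sk, 0)) / denom for sk in superkingdoms
    }


@dataclass
class EnrichmentResult:
    """Per-superkingdom microbial percentages of paired libraries.

    ``fold`` is pct_pap / pct_std; ``None`` where the standard library
    has no signal for that superkingdom.
    """

    per_superkingdom: dict[str, dict]

    def fold(self, superkingdom: str):
        return self.per_superkingdom[superkingdom]["fold"]


def enrichment(
    pap: tuple[TaxonMatrix, int],
    std: tuple[TaxonMatrix, int],
    superkingdoms: Iterable[str] = MICROBIAL_SUPERKINGDOMS,
) -> EnrichmentResult:
    """Fold-change of microbial library fraction: with vs without
    in situ polyadenylation, per superkingdom."""
    pct_pap = microbial_fraction(pap[0], pap[1], superkingdoms)
    pct_std = microbial_fraction(std[0], std[1], superkingdoms)
    out = {}
    for sk in superkingdoms:
        fold = pct_pap[sk] / pct_std[sk] if pct_std[sk] > 0 else None
        out[sk] = {"pct_pap": pct_pap[sk], "pct_std": pct_std[sk], "fold": fold}
    return EnrichmentResult(out)


def gram_summary(tm: TaxonMatrix, labels: Mapping[str, str]) -> dict[str, float]:
    """Percent of genus-level molecules that are Gram-positive/negative.

    ``tm`` must be aggregated to genus rank.  Genera absent from the
    label table are reported as ``unclassified``; percentages sum
    to 100.
    """
    if not (tm.taxa["rank"] == "genus").all():
        raise ValueError("gram_summary requires a genus-rank matrix")
    totals = tm.taxon_totals()
    grand = float(totals.sum())
    if grand == 0:
        return {"positive": 0.0, "negative": 0.0, "unknown": 0.0, "unclassified": 0.0}
    acc = {"positive": 0.0, "negative": 0.0, "unknown": 0.0, "unclassified": 0.0}
    for genus, count in totals.items():
        label = labels.get(str(genus), "unclassified")
        if label not in acc:
            label = "unclassified"
        acc[label] += float(count)
    return {k: 100.0 * v / grand for k, v in acc.items()}
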