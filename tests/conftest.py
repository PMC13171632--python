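import numpy as np
import pandas as pd
import pytest

from gutbiogeo import SimConfig, SpatialSection, TaxonMatrix, simulate_section
from gutbiogeo.datamodel import RANKS


def make_section(n_side: int = 5, pitch: float = 1.0, region: str = "tissue") -> SpatialSection:
    """Small square-lattice section, all spots in one region."""
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    spots = pd.DataFrame(
        {"x": xs.ravel() * pitch, "y": ys.ravel() * pitch, "region": region},
        index=pd.Index([f"BC{i}" for i in range(n_side * n_side)], name="barcode"),
    )
    return SpatialSection(spots=spots)


def make_taxa(names, **lineage_cols) -> pd.DataFrame:
    """Taxonomy table with optional per-rank lineage lists."""
    idx = pd.Index(range(100, 100 + len(names)), name="taxid")
    taxa = pd.DataFrame({"name": list(names), "rank": "species"}, index=idx)
    for r in RANKS:
        taxa[r] = lineage_cols.get(r, [""] * len(names))
    return taxa


def make_tm(counts, names=None, section=None, **lineage_cols) -> TaxonMatrix:
    counts = np.asarray(counts)
    names = names or [f"t{j}" for j in range(counts.shape[1])]
    spot_ids = (
        section.barcodes[: counts.shape[0]]
        if section is not None
        else pd.Index([f"BC{i}" for i in range(counts.shape[0])])
    )
    return TaxonMatrix(
        counts=counts,
        spot_ids=spot_ids,
        taxa=make_taxa(names, **lineage_cols),
        section=section,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One simulated section reused across read-only tests."""
    cfg = SimConfig(seed=7, width_um=600.0, height_um=600.0, spot_pitch_um=40.0)
    return simulate_section(cfg)
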