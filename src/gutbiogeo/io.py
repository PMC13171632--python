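"""Readers and writers for the on-disk formats the pipeline consumes.

Everything is plain text: coordinate and region TSVs, MatrixMarket
triplets with barcode/feature TSVs, Kraken2 standard output joined with
a (read_id, barcode, umi) tag table, a taxonomy lineage TSV, greyscale
PNG/TIFF images with a JSON sidecar holding the pixel size, and YAML
configs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .datamodel import (
    RANKS,
    HostMatrix,
    ReadClassificationRecord,
    SpatialSection,
    TaxonMatrix,
)


# ---------------------------------------------------------------- sections

def read_section(
    coords_path,
    regions_path=None,
    platform: str = "low_res",
    pixel_size: float | None = None,
    window_area: float | None = None,
) -> SpatialSection:
    """Read spot coordinates (barcode, x, y) and region labels.

    Barcodes missing from the regions table are labelled ``background``.
    The observation-window area defaults to the convex hull of the
    annotated (tissue + lumen) spots unless ``window_area`` overrides it.
    """
    coords = pd.read_csv(coords_path, sep="\t", dtype=str)
    for col in ("barcode", "x", "y"):
        if col not in coords.columns:
            raise ValueError(f"{coords_path}: missing column {col!r}")
    dup = coords["barcode"][coords["barcode"].duplicated()]
    if len(dup):
        raise ValueError(f"{coords_path}: duplicate barcode(s): {sorted(set(dup))}")
    for col in ("x", "y"):
        vals = pd.to_numeric(coords[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if len(bad):
            # +2: 1-based line numbers with a header line
            raise ValueError(
                f"{coords_path}: non-numeric {col} value at line {bad[0] + 2}"
            )
        coords[col] = vals
    spots = coords.set_index("barcode")[["x", "y"]]

    region = pd.Series("background", index=spots.index, name="region")
    if regions_path is not None:
        reg = pd.read_csv(regions_path, sep="\t", dtype=str)
        if not {"barcode", "region"} <= set(reg.columns):
            raise ValueError(f"{regions_path}: need columns barcode, region")
        reg = reg.set_index("barcode")["region"]
        common = spots.index.intersection(reg.index)
        region.loc[common] = reg.loc[common]
    spots["region"] = region
    return SpatialSection(
        spots=spots, platform=platform, pixel_size=pixel_size, window_area=window_area
    )


def write_section(section: SpatialSection, coords_path, regions_path) -> None:
    df = section.spots.reset_index()
    df.columns = ["barcode", "x", "y", "region"]
    df[["barcode", "x", "y"]].to_csv(coords_path, sep="\t", index=False)
    df[["barcode", "region"]].to_csv(regions_path, sep="\t", index=False)


# ---------------------------------------------------------------- matrices

def _read_tsv_index(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    if df.index.str.fullmatch(r"\d+").all():
        df.index = df.index.astype(int)
    return df


def read_matrix(mtx_path, barcodes_path, features_path, section=None):
    """Read a MatrixMarket triplet matrix with barcode/feature sidecars.

    Returns a :class:`TaxonMatrix` when the feature table carries a
    ``rank`` column (taxonomy), else a :class:`HostMatrix`.
    Orientation is spots x features.
    """
    mat = mmread(mtx_path)
    counts = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
    barcodes = _read_tsv_index(barcodes_path)
    features = _read_tsv_index(features_path)
    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"{mtx_path}: matrix is {counts.shape}, expected "
            f"({len(barcodes)} barcodes, {len(features)} features)"
        )
    counts = np.rint(counts).astype(np.int64)
    if "rank" in features.columns:
        return TaxonMatrix(counts=counts, spot_ids=barcodes.index, taxa=features, section=section)
    if "biotype" not in features.columns:
        features = features.assign(biotype="coding")
    return HostMatrix(counts=counts, spot_ids=barcodes.index, genes=features, section=section)


def write_matrix(m, mtx_path, barcodes_path, features_path) -> None:
    mmwrite(str(mtx_path), coo_matrix(m.counts))
    pd.DataFrame(index=m.spot_ids).rename_axis("barcode").reset_index().to_csv(
        barcodes_path, sep="\t", index=False
    )
    feats = m.taxa if isinstance(m, TaxonMatrix) else m.genes
    feats.rename_axis(feats.index.name or "feature").reset_index().to_csv(
        features_path, sep="\t", index=False
    )


# ------------------------------------------------------- classification IO

def read_kraken_records(kraken_path, tags_path) -> Iterator[ReadClassificationRecord]:
    """Join Kraken2 standard output with a (read_id, barcode, umi) table.

    Kraken2 standard output is 5 columns: C/U, read id, taxid, length,
    LCA mapping.  Reads absent from the tag table are skipped (no spot
    assignment is possible without a barcode).
    """
    tags = pd.read_csv(tags_path, sep="\t", dtype=str).set_index("read_id")
    with open(kraken_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            status, read_id, taxid = parts[0], parts[1], parts[2]
            if read_id not in tags.index:
                continue
            row = tags.loc[read_id]
            yield ReadClassificationRecord(
                status=status,
                taxid=int(taxid) if taxid.isdigit() else 0,
                barcode=str(row["barcode"]),
                umi=str(row["umi"]),
            )


def read_records_tsv(path) -> Iterator[ReadClassificationRecord]:
    """Pre-joined 4-column TSV: status, taxid, barcode, umi (with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"status": str, "barcode": str, "umi": str})
    for row in df.itertuples(index=False):
        yield ReadClassificationRecord(
            status=str(row.status), taxid=int(row.taxid), barcode=str(row.barcode), umi=str(row.umi)
        )


def write_records_tsv(records, path) -> None:
    pd.DataFrame(records, columns=["status", "taxid", "barcode", "umi"]).to_csv(
        path, sep="\t", index=False
    )


def read_lineage(path) -> pd.DataFrame:
    """Taxonomy table: taxid, name, rank, then one column per rank."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("taxid")
    df.index = df.index.astype(int)
    for r in RANKS:
        if r not in df.columns:
            df[r] = ""
    return df.fillna("")


def write_lineage(taxa: pd.DataFrame, path) -> None:
    taxa.rename_axis("taxid").reset_index().to_csv(path, sep="\t", index=False)


def read_gram_labels(path) -> dict[str, str]:
    """Genus -> {positive, negative, unknown} table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["genus"], df["label"]))


# ------------------------------------------------------------------ images

def read_image(image_path, sidecar_path=None) -> tuple[np.ndarray, float]:
    """8-bit greyscale image plus pixel size (µm) from its JSON sidecar."""
    import imageio.v3 as iio

    img = iio.imread(image_path)
    if img.ndim == 3:
        img = img[..., 0]
    img = img.astype(np.uint8)
    sidecar = Path(sidecar_path) if sidecar_path else Path(str(image_path) + ".json")
    pixel_size = 1.0
    if sidecar.exists():
        pixel_size = float(json.loads(sidecar.read_text())["pixel_size_um"])
    return img, pixel_size


def write_image(img: np.ndarray, image_path, pixel_size_um: float) -> None:
    import imageio.v3 as iio

    iio.imwrite(image_path, np.asarray(img, dtype=np.uint8))
    Path(str(image_path) + ".json").write_text(
        json.dumps({"pixel_size_um": pixel_size_um})
    )
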