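"""Synthetic spatial host–microbiome data with known ground truth.

The generator emulates the statistical structure the downstream
analyses assume: a tissue/lumen section split by a known boundary,
per-genus microbial point processes (homogeneous Poisson for dispersed
taxa, Thomas cluster processes for colony-forming taxa, whose cluster
dispersion sigma is the colony-radius quantity Ripley's H estimates),
exponential transverse abundance gradients, read-level records with UMI
duplication and unclassified reads, a paired "standard" library related
by per-superkingdom thinning (emulating capture without in situ
polyadenylation), a host expression matrix with spliced/unspliced
layers and biotypes, and a greyscale image of the tissue mask.

Every simulated quantity is recorded in a :class:`GroundTruth` so
recovery tests never re-derive what the generator knows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .datamodel import (
    RANKS,
    HostMatrix,
    PointPattern,
    ReadClassificationRecord,
    SpatialSection,
    TaxonMatrix,
)

# --------------------------------------------------------------- configs


@dataclass
class GenusSpec:
    """One genus's generative process.

    ``process`` is ``"csr"`` (homogeneous Poisson at ``intensity``
    points/µm²) or ``"thomas"`` (Poisson parents at
    ``parent_intensity``/µm², Poisson(``mean_offspring``) offspring per
    parent, isotropic Gaussian dispersion ``sigma_um``).
    ``gradient_scale_um`` applies exponential thinning with distance
    from the tissue boundary into the lumen (``gradient_toward =
    "tissue"`` peaks at the boundary, ``"lumen"`` peaks deep in the
    lumen); ``None`` disables the gradient.
    """

    name: str
    process: str = "csr"
    intensity: float = 1e-4
    parent_intensity: float = 5e-5
    mean_offspring: float = 40.0
    sigma_um: float = 10.0
    gradient_scale_um: float | None = None
    gradient_toward: str = "tissue"
    superkingdom: str = "Bacteria"
    phylum: str = "Bacillota"
    family: str = ""
    leakage: float = 0.0  # fraction of points allowed on the tissue side


@dataclass
class HostSpec:
    n_genes: int = 100
    total_molecules: int = 200_000
    unspliced_fraction: float = 0.225
    noncoding_fraction: float = 0.08
    zonation_scale_um: float = 150.0


@dataclass
class SimConfig:
    """Study conditions for one simulated section."""

    seed: int = 0
    width_um: float = 1000.0
    height_um: float = 1000.0
    boundary_shape: str = "line"  # line | sinusoid | disc
    boundary_y_um: float = 300.0  # tissue above (y < boundary), lumen below
    boundary_amplitude_um: float = 50.0
    boundary_period_um: float = 400.0
    disc_radius_um: float = 250.0
    platform: str = "low_res"
    spot_pitch_um: float = 50.0
    genera: list = field(default_factory=list)
    thinning: dict = field(default_factory=lambda: {"Bacteria": 0.01, "Archaea": 0.2, "Viruses": 0.1})
    umi_duplication: float = 0.3
    unclassified_fraction: float = 0.1
    host: HostSpec = field(default_factory=HostSpec)
    image_pixel_um: float = 2.0
    image_noise: float = 0.0  # salt-and-pepper pixel flip fraction

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        raw = yaml.safe_load(open(path))
        genera = [GenusSpec(**g) for g in raw.pop("genera", [])]
        host = HostSpec(**raw.pop("host", {}))
        return cls(genera=genera, host=host, **raw)


def default_genera() -> list[GenusSpec]:
    """A community mirroring the observed colony-size classes.

    Small colonies (sigma ~5 µm, Lactobacillus-like), medium (~10 µm,
    Turicimonas-like), large (>30 µm, Clostridium-like), one dispersed
    CSR genus, and a tissue-proximal gradient genus.
    """
    return [
        GenusSpec("Lactobacillus", process="thomas", parent_intensity=4e-5,
                  mean_offspring=30, sigma_um=5.0, phylum="Bacillota",
                  family="Lactobacillaceae"),
        GenusSpec("Turicimonas", process="thomas", parent_intensity=4e-5,
                  mean_offspring=30, sigma_um=10.0, phylum="Pseudomonadota",
                  family="Sutterellaceae"),
        GenusSpec("Clostridium", process="thomas", parent_intensity=2e-5,
                  mean_offspring=60, sigma_um=30.0, phylum="Bacillota",
                  family="Clostridiaceae"),
        GenusSpec("Bacteroides", process="csr", intensity=1.5e-3,
                  phylum="Bacteroidota", family="Bacteroidaceae"),
        GenusSpec("Eggerthella", process="csr", intensity=1e-3,
                  gradient_scale_um=150.0, gradient_toward="lumen",
                  phylum="Actinomycetota", family="Eggerthellaceae"),
    ]


# ------------------------------------------------------------ primitives


def sample_csr(intensity: float, window, rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson process in a rectangular window."""
    x0, y0, x1, y1 = window
    area = (x1 - x0) * (y1 - y0)
    n = rng.poisson(intensity * area)
    pts = rng.random((n, 2))
    pts[:, 0] = x0 + pts[:, 0] * (x1 - x0)
    pts[:, 1] = y0 + pts[:, 1] * (y1 - y0)
    return pts


def sample_thomas(
    parent_intensity: float,
    mean_offspring: float,
    sigma_um: float,
    window,
    rng: np.random.Generator,
    clip: bool = True,
) -> np.ndarray:
    """Thomas cluster process: Poisson parents, Gaussian offspring."""
    x0, y0, x1, y1 = window
    parents = sample_csr(parent_intensity, window, rng)
    if len(parents) == 0:
        return np.empty((0, 2))
    counts = rng.poisson(mean_offspring, size=len(parents))
    pts = np.repeat(parents, counts, axis=0) + rng.normal(
        0.0, sigma_um, size=(int(counts.sum()), 2)
    )
    if clip:
        inside = (
            (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
            & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        )
        pts = pts[inside]
    return pts


def sar_community_intensities(
    n_genera: int,
    area_grid: np.ndarray,
    target_exponent: float = 0.5,
    lambda_max: float = 0.2,
) -> np.ndarray:
    """Per-genus CSR intensities whose expected genus–area curve follows
    a power law with the requested exponent.

    Intensities sit at quantiles of a truncated Pareto tail
    P(lambda > x) = (lambda_min / x)^z, for which the expected number of
    genera present in area a, E[S(a)] = sum_i (1 - exp(-lambda_i a)),
    scales as a^z over the span where 1/a lies inside the intensity
    support.  lambda_min is solved deterministically so the analytic
    log–log slope over ``area_grid`` equals ``target_exponent``.
    """
    z = target_exponent
    u = (np.arange(n_genera) + 0.5) / n_genera  # tail quantiles

    def intensities(lambda_min: float) -> np.ndarray:
        return np.minimum(lambda_min * u ** (-1.0 / z), lambda_max)

    la = np.log10(area_grid)

    def slope_err(log_lambda_min: float) -> float:
        lam = intensities(10.0 ** log_lambda_min)
        s = np.array([np.sum(1.0 - np.exp(-lam * a)) for a in area_grid])
        fit = np.polyfit(la, np.log10(s), 1)
        return fit[0] - z

    log_lmin = brentq(slope_err, -9.0, -2.0, xtol=1e-10)
    return intensities(10.0 ** log_lmin)


def simulate_sar_community(
    n_genera: int,
    window,
    area_grid: np.ndarray,
    target_exponent: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a multi-genus CSR community calibrated to a species–area
    power-law exponent.

    Returns (points, genus marks, per-genus intensities).  Each genus is
    an independent homogeneous Poisson process at the calibrated
    intensity (see :func:`sar_community_intensities`).
    """
    lam = sar_community_intensities(n_genera, np.asarray(area_grid, float), target_exponent)
    rng = np.random.default_rng(seed)
    pts, marks = [], []
    for i, intensity in enumerate(lam):
        p = sample_csr(intensity, window, rng)
        pts.append(p)
        marks.append(np.full(len(p), i))
    return np.vstack(pts), np.concatenate(marks), lam


# --------------------------------------------------------------- geometry


def boundary_offset(cfg: SimConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signed offset from the tissue boundary: negative in tissue, positive in lumen."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if cfg.boundary_shape == "line":
        return y - cfg.boundary_y_um
    if cfg.boundary_shape == "sinusoid":
        yb = cfg.boundary_y_um + cfg.boundary_amplitude_um * np.sin(
            2 * np.pi * x / cfg.boundary_period_um
        )
        return y - yb
    if cfg.boundary_shape == "disc":
        cx, cy = cfg.width_um / 2, cfg.height_um / 2
        return np.hypot(x - cx, y - cy) - cfg.disc_radius_um
    raise ValueError(f"unknown boundary shape {cfg.boundary_shape!r}")


def true_boundary_polyline(cfg: SimConfig, n: int = 400) -> np.ndarray:
    if cfg.boundary_shape == "disc":
        t = np.linspace(0, 2 * np.pi, n)
        cx, cy = cfg.width_um / 2, cfg.height_um / 2
        return np.column_stack([cx + cfg.disc_radius_um * np.cos(t),
                                cy + cfg.disc_radius_um * np.sin(t)])
    x = np.linspace(0, cfg.width_um, n)
    if cfg.boundary_shape == "line":
        y = np.full(n, cfg.boundary_y_um)
    else:
        y = cfg.boundary_y_um + cfg.boundary_amplitude_um * np.sin(
            2 * np.pi * x / cfg.boundary_period_um
        )
    return np.column_stack([x, y])


def _build_taxonomy(genera: list[GenusSpec]) -> pd.DataFrame:
    rows = []
    for i, g in enumerate(genera):
        taxid = 1000 + i
        row = {"name": f"{g.name} sp.", "rank": "species"}
        for r in RANKS:
            row[r] = ""
        row.update(
            superkingdom=g.superkingdom,
            phylum=g.phylum,
            family=g.family or f"{g.name}aceae",
            genus=g.name,
            species=f"{g.name} sp.",
        )
        rows.append((taxid, row))
    return pd.DataFrame([r for _, r in rows], index=pd.Index([t for t, _ in rows], name="taxid"))


def _encode_umi(i: int, width: int = 10) -> str:
    alphabet = "ACGT"
    out = []
    for _ in range(width):
        out.append(alphabet[i & 3])
        i >>= 2
    return "".join(out)


# ------------------------------------------------------------- main entry


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-derivation."""

    config: SimConfig
    boundary: np.ndarray  # true boundary polyline (µm)
    genus_sigma: dict  # genus -> Thomas sigma (None for CSR)
    genus_n_points: dict
    thinning: dict
    unspliced_fraction: float
    host_unique_molecules: int
    n_unique_molecules: int
    n_reads: int


@dataclass
class SimulatedSection:
    section: SpatialSection
    taxonomy: pd.DataFrame
    taxon_matrix: TaxonMatrix  # PAP library, ground-truth unique molecules
    std_taxon_matrix: TaxonMatrix  # paired standard library (thinned)
    host_matrix: HostMatrix
    patterns: dict  # genus -> PointPattern
    records: list  # read-level records reproducing taxon_matrix under demux
    image: np.ndarray
    image_pixel_um: float
    ground_truth: GroundTruth


def simulate_section(cfg: SimConfig) -> SimulatedSection:
    """Generate one section with all pipeline inputs and ground truth.

    The same seed yields bit-identical outputs.  The read records
    reproduce the taxon matrix exactly under the (barcode, UMI, taxid)
    dedup rule; the standard library is a per-superkingdom binomial
    thinning of the same unique molecules.
    """
    rng = np.random.default_rng(cfg.seed)
    genera = cfg.genera or default_genera()
    window = (0.0, 0.0, cfg.width_um, cfg.height_um)

    # ---- spot lattice and regions
    pitch = cfg.spot_pitch_um
    gx = np.arange(pitch / 2, cfg.width_um, pitch)
    gy = np.arange(pitch / 2, cfg.height_um, pitch)
    sx, sy = np.meshgrid(gx, gy, indexing="ij")
    sx, sy = sx.ravel(), sy.ravel()
    side = boundary_offset(cfg, sx, sy)
    region = np.where(side < 0, "tissue", "lumen")
    barcodes = pd.Index([f"BC{i:05d}" for i in range(len(sx))], name="barcode")
    spots = pd.DataFrame({"x": sx, "y": sy, "region": region}, index=barcodes)
    section = SpatialSection(spots=spots, platform=cfg.platform,
                             pixel_size=cfg.image_pixel_um)
    if not (region == "lumen").any() or not (region == "tissue").any():
        raise ValueError("boundary leaves no tissue or no lumen spots; adjust config")

    # ---- microbial point patterns
    taxonomy = _build_taxonomy(genera)
    max_depth = float(np.max(boundary_offset(cfg, sx, sy)))
    patterns: dict[str, PointPattern] = {}
    genus_sigma, genus_n = {}, {}
    for g in genera:
        if g.process == "csr":
            pts = sample_csr(g.intensity, window, rng)
        elif g.process == "thomas":
            pts = sample_thomas(g.parent_intensity, g.mean_offspring, g.sigma_um,
                                window, rng)
        else:
            raise ValueError(f"unknown process {g.process!r} for {g.name}")
        off = boundary_offset(cfg, pts[:, 0], pts[:, 1]) if len(pts) else np.empty(0)
        keep = off >= 0
        if g.leakage > 0:
            keep |= rng.random(len(pts)) < g.leakage
        pts = pts[keep]
        off = off[keep]
        if g.gradient_scale_um:
            depth = np.clip(off, 0.0, None)
            if g.gradient_toward == "tissue":
                p_keep = np.exp(-depth / g.gradient_scale_um)
            elif g.gradient_toward == "lumen":
                p_keep = np.exp(-(max_depth - depth) / g.gradient_scale_um)
            else:
                raise ValueError("gradient_toward must be 'tissue' or 'lumen'")
            pts = pts[rng.random(len(pts)) < p_keep]
        patterns[g.name] = PointPattern(pts, window=window, mark=g.name)
        genus_sigma[g.name] = g.sigma_um if g.process == "thomas" else None
        genus_n[g.name] = len(pts)

    # ---- molecules -> spots -> unique molecules
    tree = cKDTree(np.column_stack([sx, sy]))
    taxids = taxonomy.index.to_numpy()
    mol_spot, mol_taxid = [], []
    for g, taxid in zip(genera, taxids):
        pts = patterns[g.name].points
        if len(pts):
            _, nearest = tree.query(pts)
            mol_spot.append(nearest)
            mol_taxid.append(np.full(len(pts), taxid))
    if mol_spot:
        mol_spot = np.concatenate(mol_spot)
        mol_taxid = np.concatenate(mol_taxid)
    else:
        mol_spot = np.empty(0, dtype=int)
        mol_taxid = np.empty(0, dtype=int)
    n_mol = len(mol_spot)

    counts = np.zeros((len(barcodes), len(taxids)), dtype=np.int64)
    tax_pos = {t: j for j, t in enumerate(taxids)}
    col = np.array([tax_pos[t] for t in mol_taxid], dtype=int) if n_mol else np.empty(0, int)
    np.add.at(counts, (mol_spot, col), 1)
    taxon_matrix = TaxonMatrix(counts=counts, spot_ids=barcodes, taxa=taxonomy,
                               section=section)

    # ---- read records with UMI duplication and unclassified reads
    dup = cfg.umi_duplication
    if not 0 <= dup < 1:
        raise ValueError("umi_duplication must lie in [0, 1)")
    reads_per_mol = np.ones(n_mol, dtype=np.int64)
    if dup > 0:
        reads_per_mol += rng.poisson(dup / (1 - dup), size=n_mol)
    umis = [_encode_umi(i) for i in range(n_mol)]
    records: list[ReadClassificationRecord] = []
    for i in range(n_mol):
        rec = ReadClassificationRecord(
            status="C", taxid=int(mol_taxid[i]),
            barcode=str(barcodes[mol_spot[i]]), umi=umis[i],
        )
        records.extend([rec] * int(reads_per_mol[i]))
    n_classified_reads = len(records)
    n_uncl = int(round(cfg.unclassified_fraction * n_classified_reads))
    for i in range(n_uncl):
        records.append(
            ReadClassificationRecord(
                status="U", taxid=0,
                barcode=str(barcodes[rng.integers(len(barcodes))]),
                umi=_encode_umi(n_mol + i),
            )
        )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    # ---- paired standard library: per-superkingdom thinning of molecules
    sk_per_taxon = taxonomy["superkingdom"].to_numpy()
    thin = np.array([cfg.thinning.get(sk, 1.0) for sk in sk_per_taxon])
    std_counts = rng.binomial(counts, thin[None, :])
    std_taxon_matrix = TaxonMatrix(counts=std_counts.astype(np.int64),
                                   spot_ids=barcodes, taxa=taxonomy, section=section)

    # ---- host matrix with zonation, biotypes, spliced/unspliced layers
    host = cfg.host
    tissue_mask = region == "tissue"
    t_idx = np.nonzero(tissue_mask)[0]
    depth_in_tissue = -side[t_idx]  # distance from boundary into tissue
    n_genes = host.n_genes
    gene_names = pd.Index([f"gene{j:04d}" for j in range(n_genes)], name="gene")
    n_noncoding = int(round(host.noncoding_fraction * n_genes))
    biotype = np.array(["coding"] * n_genes, dtype=object)
    nc_classes = ["lncRNA", "snoRNA", "snRNA", "miRNA", "miscRNA", "rRNA"]
    for j in range(n_noncoding):
        biotype[n_genes - 1 - j] = nc_classes[j % len(nc_classes)]
    genes = pd.DataFrame({"biotype": biotype}, index=gene_names)

    base = rng.lognormal(0.0, 1.0, size=n_genes)
    group = np.arange(n_genes) % 2  # 0: villus-tip (boundary-proximal), 1: crypt
    zs = host.zonation_scale_um
    prof = np.where(
        group[None, :] == 0,
        np.exp(-depth_in_tissue[:, None] / zs),
        np.exp(-(depth_in_tissue.max() - depth_in_tissue)[:, None] / zs),
    )
    rate = prof * base[None, :]
    rate *= host.total_molecules / rate.sum()
    h_counts = np.zeros((len(barcodes), n_genes), dtype=np.int64)
    h_counts[t_idx] = rng.poisson(rate)
    unspliced = rng.binomial(h_counts, host.unspliced_fraction)
    layers = {"spliced": (h_counts - unspliced), "unspliced": unspliced}
    host_matrix = HostMatrix(counts=h_counts, spot_ids=barcodes, genes=genes,
                             layers=layers, section=section)

    # ---- image of the tissue mask
    px = cfg.image_pixel_um
    ny, nxp = int(np.ceil(cfg.height_um / px)), int(np.ceil(cfg.width_um / px))
    yy = (np.arange(ny) + 0.5) * px
    xx = (np.arange(nxp) + 0.5) * px
    XX, YY = np.meshgrid(xx, yy)
    img = np.where(boundary_offset(cfg, XX, YY) < 0, 255, 0).astype(np.uint8)
    if cfg.image_noise > 0:
        flip = rng.random(img.shape) < cfg.image_noise
        img[flip] = rng.choice([0, 255], size=int(flip.sum()))

    gt = GroundTruth(
        config=cfg,
        boundary=true_boundary_polyline(cfg),
        genus_sigma=genus_sigma,
        genus_n_points=genus_n,
        thinning=dict(cfg.thinning),
        unspliced_fraction=host.unspliced_fraction,
        host_unique_molecules=int(h_counts.sum()),
        n_unique_molecules=n_mol,
        n_reads=len(records),
    )
    return SimulatedSection(
        section=section, taxonomy=taxonomy, taxon_matrix=taxon_matrix,
        std_taxon_matrix=std_taxon_matrix, host_matrix=host_matrix,
        patterns=patterns, records=records, image=img,
        image_pixel_um=px, ground_truth=gt,
    )


def simulate_control(
    total_molecules: int = 1_000_000,
    contaminants: dict | None = None,
    n_spots: int = 50,
    seed: int = 0,
) -> TaxonMatrix:
    """Sterile-control taxon matrix with configured contaminant frequencies.

    ``contaminants`` maps taxon name -> frequency in ppm of unique
    molecules; counts are binomial draws at those frequencies, and the
    remainder is assigned to a single dominant background taxon so the
    matrix totals ``total_molecules`` exactly.
    """
    rng = np.random.default_rng(seed)
    contaminants = contaminants if contaminants is not None else {"Cutibacterium": 2.0}
    names = list(contaminants) + ["Background"]
    taxids = pd.Index(np.arange(9000, 9000 + len(names)), name="taxid")
    taxa = pd.DataFrame({"name": names, "rank": "genus"}, index=taxids)
    for r in RANKS:
        taxa[r] = ""
    taxa["superkingdom"] = "Bacteria"
    taxa["genus"] = names

    totals = np.array(
        [rng.binomial(total_molecules, ppm * 1e-6) for ppm in contaminants.values()],
        dtype=np.int64,
    )
    totals = np.append(totals, total_molecules - totals.sum()).astype(np.int64)
    barcodes = pd.Index([f"CTL{i:04d}" for i in range(n_spots)], name="barcode")
    counts = np.zeros((n_spots, len(names)), dtype=np.int64)
    for j, tot in enumerate(totals):
        if tot > 0:
            spots_for = rng.integers(0, n_spots, size=tot)
            np.add.at(counts[:, j], spots_for, 1)
    return TaxonMatrix(counts=counts, spot_ids=barcodes, taxa=taxa)
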