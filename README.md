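# gutbiogeo

Spatial biogeography of the gut microbiome from spatial total-RNA
sequencing.

Spatial RNA-seq arrays capture polyadenylated transcripts at barcoded
locations; with enzymatic in situ polyadenylation they also capture
microbial RNA, turning one tissue section into a joint map of host gene
expression and microbial taxa. `gutbiogeo` implements the downstream
analysis of such data for gut tissue: it builds spot × taxon
unique-molecule matrices from read-level taxonomic classifications,
removes sterile-control contaminants, quantifies microbial enrichment,
composition and richness, infers microbial colony structure with
point-pattern statistics, profiles composition along the tissue→lumen
and boundary-distance axes, and fits species–area and
sequencing-saturation models. A synthetic-data generator with known
ground truth stands in for deposited sequencing data, so every analysis
is exercised end to end with recoverable parameters.

Intended users: computational microbiome and spatial-transcriptomics
researchers who have spot coordinates, Kraken2-style read
classifications tagged with cell barcode and UMI, and (optionally)
paired sections with/without in situ polyadenylation.

## Core statistics

**Unique molecules.** One molecule per distinct (barcode, UMI, taxid)
triple among classified reads; contaminant taxa at ≥ 1 ppm of a sterile
control's unique molecules are excluded.

**Enrichment.** Per superkingdom k,
pct_k = 100 · UMI_k / (host + classified UMI), and the fold change is
the ratio of those percentages between paired sections with and without
in situ polyadenylation.

**Ripley K/L/H** (no edge correction), on a point pattern of N
molecule locations in a window of area A:

    K(r) = 2A / (N(N−1)) · Σ_{i<j} 1(d_ij ≤ r)
    L(r) = √(K(r)/π),   H(r) = L(r) − r

H(r) > 0 indicates aggregation at scale r; H is z-scored against
complete spatial randomness (CSR) Monte-Carlo with matched N, and the
argmax of H serves as a colony-radius proxy. Genera are screened first
by abundance (> 0.01%) and Moran's I (k = 4 nearest-neighbour weights,
permutation p < 0.05).

**Species–area relationship.** Mean unique genera S in random square
quadrats of area A follows S ∝ A^z; z is the slope of log₁₀S on
log₁₀A over 16 µm²–0.16 mm².

**Sequencing saturation.** saturation = 1 − unique/reads, modelled as
Michaelis–Menten y = v_max·x/(k + x) with v_max ≤ 1, inverted in closed
form for the depth reaching a target saturation.

**Boundary geometry.** The host–microbiome boundary is traced from a
greyscale image (100 µm box blur, 8-bit threshold, contour extraction);
entity distances to the traced polyline parameterize density and
abundance profiles and cell-position rescaling between sections.

## Worked example

```python
import numpy as np
import gutbiogeo as gb

# simulate one ileum-like section: tissue above a sinusoidal boundary,
# five genera with known colony structure, paired thinned library
cfg = gb.SimConfig(seed=11, width_um=1000, height_um=1000,
                   boundary_shape="sinusoid", spot_pitch_um=50)
sim = gb.simulate_section(cfg)

tm = gb.demux_classified_reads(iter(sim.records), sim.section,
                               taxonomy=sim.taxonomy)
print("unique microbial molecules:", tm.total)

host = sim.ground_truth.host_unique_molecules
res = gb.enrichment((sim.taxon_matrix, host), (sim.std_taxon_matrix, host))
print("bacterial fold enrichment: %.1f" % res.fold("Bacteria"))

r_grid = np.arange(2.0, 150.0, 2.0)
for genus in ("Lactobacillus", "Clostridium"):
    pat = sim.patterns[genus]
    rip = gb.ripley_z(pat, r_grid, n_sim=99, seed=1)
    print(f"{genus}: n={pat.n}, colony radius {rip.colony_radius:.0f} um, "
          f"max z = {np.nanmax(rip.z):.1f}")

pts = np.vstack([p.points for p in sim.patterns.values()])
marks = np.concatenate([[g] * p.n for g, p in sim.patterns.items()])
sar = gb.sar_curve(pts, marks, (0, 0, 1000, 1000),
                   area_grid=np.geomspace(16, 0.16e6, 9), seed=2)
print("species-area exponent z = %.2f (r2 = %.3f)" % (sar.exponent, sar.r2))
```

prints

```
unique microbial molecules: 2951
bacterial fold enrichment: 93.8
Lactobacillus: n=521, colony radius 18 um, max z = 142.6
Clostridium: n=760, colony radius 80 um, max z = 149.9
species-area exponent z = 0.49 (r2 = 0.916)
```

The demultiplexed matrix reproduces the generator's unique molecules
exactly. The simulated 1% bacterial thinning of the standard library
yields a measured fold of ~94 (the host-dominated library puts the
attainable fold slightly below 1/thinning). Both Thomas-process genera
show overwhelming aggregation vs CSR (z ≫ 3); the larger cluster
dispersion of *Clostridium* (σ = 30 µm vs 5 µm) gives the larger colony
radius — the argmax-of-H radius is a cluster-*scale* proxy, at ≈2–3×
the Gaussian dispersion σ. The genus accumulation curve recovers a
power-law exponent near the configured community structure.

There is also a CLI mirroring the pipeline stages:

```sh
gutbiogeo simulate --out demo --seed 3
gutbiogeo spatial --mtx demo/taxa.mtx --barcodes demo/barcodes.tsv \
    --features demo/taxa_features.tsv --coords demo/coords.tsv \
    --regions demo/regions.tsv --out demo/spatial --seed 1
gutbiogeo run --out demo/full --seed 1     # full analysis graph
```

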