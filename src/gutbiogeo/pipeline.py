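"""End-to-end orchestration of the analysis stages with a run manifest.

A single config dict (typically loaded from YAML) drives the stages
ingest → filter → composition → transverse → saturation → spatial →
colonies → colocalization → SAR → boundary, each writing tidy TSV/JSON
outputs into the run directory.  A manifest records the config hash,
seed, package version and per-stage parameters so identical manifests
imply identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import relative_abundance, richness_per_spot, splice_outliers, transverse_profile
from .datamodel import aggregate_rank
from .boundary import density_profile, detect_boundary, distance_to_boundary
from .ingest import apply_exclusion, build_exclusion_list, demux_classified_reads, enrichment
from .saturation import depth_for_saturation, fit_mm, subsample_counts
from .simulate import SimConfig, simulate_control, simulate_section
from .spatial import PointPattern, call_colonies, colocalization, ripley_z, sar_curve, screen_genera

DEFAULT_STAGES = (
    "ingest", "filter", "compose", "transverse", "saturation",
    "spatial", "colonies", "colocalize", "sar", "boundary",
)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Run the enabled stages on a simulated section; return the manifest.

    ``config`` keys: ``sim`` (SimConfig fields), ``stages`` (stage-name
    -> bool), and per-stage parameter blocks (``filter.threshold_ppm``,
    ``transverse.n_bins``, ``spatial.min_abundance`` ...).  Defaults are
    the study parameters: 1 ppm contaminant filter, 0.01% abundance
    screen, five transverse bins, k=4 Moran weights, p<0.05, 20 µm
    colocalization kernel, 100 µm boundary blur.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {s: True for s in DEFAULT_STAGES}
    stages.update(config.get("stages", {}))
    params: dict[str, dict] = {}

    sim_cfg = SimConfig(**{**config.get("sim", {}), "seed": seed})
    sim = simulate_section(sim_cfg)
    section = sim.section

    # ingest: rebuild the matrix from read records
    if stages["ingest"]:
        tm = demux_classified_reads(iter(sim.records), section, taxonomy=sim.taxonomy)
        params["ingest"] = {"n_records": len(sim.records)}
    else:
        tm = sim.taxon_matrix

    if stages["filter"]:
        p = config.get("filter", {})
        ppm = p.get("threshold_ppm", 1.0)
        control = simulate_control(seed=seed + 1, **p.get("control", {}))
        ex = build_exclusion_list(control, threshold_ppm=ppm)
        tm = apply_exclusion(tm, ex)
        params["filter"] = {"threshold_ppm": ppm, "n_excluded": len(ex.taxids)}

    genus_tm = aggregate_rank(tm, "genus")

    if stages["compose"]:
        rel = relative_abundance(tm, rank="family")
        rel.rename("abundance").to_csv(out / "relative_abundance_family.tsv", sep="\t")
        rich = richness_per_spot(genus_tm)
        rich.to_csv(out / "richness_per_spot.tsv", sep="\t")
        spl = splice_outliers(sim.host_matrix)
        spl.to_csv(out / "splice_outliers.tsv", sep="\t")
        params["compose"] = {"min_fraction": 1e-4, "n_splice_outliers": int(spl["outlier"].sum())}

    if stages["transverse"]:
        tcfg = config.get("transverse", {})
        n_bins = tcfg.get("n_bins", 5)
        # synthetic microbes sit on the lumen side, so the tissue-distance
        # axis spreads them over distinct bins
        axis_region = tcfg.get("axis_region", "tissue")
        prof = transverse_profile(tm, section, n_bins=n_bins, rank="phylum",
                                  axis_region=axis_region)
        prof.abundance.to_csv(out / "transverse_abundance.tsv", sep="\t")
        prof.z.to_csv(out / "transverse_z.tsv", sep="\t")
        params["transverse"] = {"n_bins": n_bins}

    if stages["saturation"]:
        curve = subsample_counts(sim.records, seed=seed)
        curve.table.to_csv(out / "rarefaction.tsv", sep="\t", index=False)
        ok = curve.table["reads"] > 0
        fit = fit_mm(curve.table["reads"][ok], curve.table["saturation"][ok], vmax_bound=1.0)
        report = {"vmax": fit.vmax, "k": fit.k, "r2": fit.r2,
                  "depth_at_0.9": depth_for_saturation(fit, 0.9)}
        (out / "saturation_fit.json").write_text(json.dumps(report, indent=2))
        params["saturation"] = report

    screened = None
    if stages["spatial"]:
        p = config.get("spatial", {})
        screened = screen_genera(
            genus_tm, section,
            min_abundance=p.get("min_abundance", 1e-4),
            moran_p=p.get("moran_p", 0.05),
            n_perm=p.get("n_perm", 199), seed=seed,
        )
        screened.to_csv(out / "moran_screen.tsv", sep="\t", index=False)
        r_grid = np.asarray(p.get("r_grid", np.arange(2.0, 80.0, 2.0)), dtype=float)
        rows = []
        for genus in screened.loc[screened["selected"], "genus"]:
            pat = sim.patterns.get(genus)
            if pat is None or pat.n < 10:
                continue
            res = ripley_z(pat, r_grid, n_sim=p.get("n_sim", 49), seed=seed)
            rows.append({"genus": genus, "colony_radius": res.colony_radius,
                         "max_H": float(np.max(res.H))})
        pd.DataFrame(rows, columns=["genus", "colony_radius", "max_H"]).to_csv(
            out / "colony_radius.tsv", sep="\t", index=False
        )
        params["spatial"] = {"n_selected": int(screened["selected"].sum())}

    if stages["colonies"]:
        rows = []
        for genus, pat in sim.patterns.items():
            if pat.n < 30:
                continue
            res = call_colonies(pat)
            rows.append({"genus": genus, "n_clusters": res.n_clusters,
                         "silhouette": res.silhouette, "flagged": res.flagged})
        pd.DataFrame(rows, columns=["genus", "n_clusters", "silhouette", "flagged"]).to_csv(
            out / "colony_calls.tsv", sep="\t", index=False
        )
        params["colonies"] = {"n_genera": len(rows)}

    if stages["colocalize"]:
        p = config.get("colocalize", {})
        cor = colocalization(genus_tm, section, sigma_um=p.get("sigma_um", 20.0),
                             bin_size_um=p.get("bin_size_um", 20.0))
        cor.to_csv(out / "colocalization.tsv", sep="\t")
        params["colocalize"] = {"sigma_um": p.get("sigma_um", 20.0)}

    if stages["sar"]:
        pts = np.vstack([p.points for p in sim.patterns.values() if p.n])
        marks = np.concatenate(
            [[g] * p.n for g, p in sim.patterns.items() if p.n]
        )
        window = (0.0, 0.0, sim_cfg.width_um, sim_cfg.height_um)
        amax = min(0.16e6, (min(sim_cfg.width_um, sim_cfg.height_um) * 0.8) ** 2)
        sar = sar_curve(pts, marks, window, area_grid=np.geomspace(16.0, amax, 9),
                        n_quadrats=config.get("sar", {}).get("n_quadrats", 100), seed=seed)
        sar.table.assign(exponent=sar.exponent, r2=sar.r2).to_csv(
            out / "sar_curve.tsv", sep="\t", index=False
        )
        params["sar"] = {"exponent": sar.exponent, "r2": sar.r2}

    if stages["boundary"]:
        p = config.get("boundary", {})
        contour = detect_boundary(
            sim.image, sim.image_pixel_um,
            kernel_um=p.get("kernel_um", 100.0), threshold=p.get("threshold", 80),
        )
        all_pts = np.vstack([pp.points for pp in sim.patterns.values() if pp.n])
        d = distance_to_boundary(all_pts, contour)
        prof = density_profile(d)
        pd.DataFrame({"distance": prof.grid, "density": prof.density}).to_csv(
            out / "boundary_density.tsv", sep="\t", index=False
        )
        params["boundary"] = {"mode_um": prof.mode,
                              "n_polylines": len(contour.polylines)}

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {s: bool(v) for s, v in stages.items()},
        "params": params,
        "taxa_after_filter": sorted(map(str, tm.taxa["name"])),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
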