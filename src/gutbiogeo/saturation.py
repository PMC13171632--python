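"""Rarefaction and sequencing-saturation modelling.

Saturation of a library modality (host, microbial or total) is

    saturation = 1 - unique molecules / reads with valid barcode,

computed at a ladder of read-subsampling fractions and modelled with
Michaelis–Menten kinetics y = vmax * x / (k + x), with vmax bounded by 1
on the saturation scale.  The fitted curve is inverted in closed form
to report the depth needed to reach a target saturation (0.9 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datamodel import ReadClassificationRecord


def saturation_stat(unique: int, reads: int) -> float:
    """1 − unique/reads; the fraction of reads that were duplicates."""
    if reads <= 0:
        raise ValueError("reads must be > 0")
    if not 0 <= unique <= reads:
        raise ValueError("need 0 <= unique <= reads")
    return 1.0 - unique / reads


def _unique_molecules(records: Sequence[ReadClassificationRecord]) -> int:
    return len({(r.barcode, r.umi, r.taxid) for r in records if r.status == "C"})


@dataclass
class RarefactionCurve:
    """Unique molecules and saturation at each subsampling fraction."""

    table: pd.DataFrame  # columns: fraction, reads, unique, saturation
    modality: str = "microbial"
    seed: int | None = None


def subsample_counts(
    records: Sequence[ReadClassificationRecord],
    fractions: Iterable[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    seed: int = 0,
    modality: str = "microbial",
) -> RarefactionCurve:
    """Bernoulli read subsampling with unique molecules re-deduplicated.

    Each read is kept independently with probability ``fraction``; the
    unique-molecule count is recomputed at every level with the same
    (barcode, UMI, taxid) dedup rule used at full depth.  Fraction 1.0
    reproduces the full library exactly.
    """
    records = list(records)
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        if f == 1.0:
            kept = records
        else:
            mask = rng.random(len(records)) < f
            kept = [r for r, m in zip(records, mask) if m]
        reads = len(kept)
        unique = _unique_molecules(kept)
        rows.append(
            {
                "fraction": f,
                "reads": reads,
                "unique": unique,
                "saturation": saturation_stat(unique, reads) if reads else np.nan,
            }
        )
    return RarefactionCurve(pd.DataFrame(rows), modality=modality, seed=seed)


@dataclass
class MMFit:
    """Michaelis–Menten fit y = vmax·x/(k + x)."""

    vmax: float
    k: float
    r2: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.vmax * x / (self.k + x)


def fit_mm(
    depth: np.ndarray,
    y: np.ndarray,
    vmax_bound: float | None = 1.0,
) -> MMFit:
    """Nonlinear least-squares Michaelis–Menten fit.

    ``vmax_bound`` caps the asymptote (1.0 for saturation-scale fits;
    pass ``None`` for unbounded fits of unique molecules vs depth).
    Initialisation is the standard heuristic: vmax₀ = max(y), k₀ = the
    depth where y first reaches half of max(y).
    """
    x = np.asarray(depth, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 points to fit")
    ymax = float(y.max())
    if ymax <= 0:
        raise ValueError("all responses are <= 0; nothing to fit")
    upper_v = vmax_bound if vmax_bound is not None else np.inf
    v0 = min(ymax, upper_v) if np.isfinite(upper_v) else ymax
    half = np.nonzero(y >= ymax / 2)[0]
    k0 = float(x[half[0]]) if len(half) else float(np.median(x))
    k0 = max(k0, np.finfo(float).tiny)

    def model(x, vmax, k):
        return vmax * x / (k + x)

    try:
        popt, _ = curve_fit(
            model, x, y, p0=[v0 * 0.999999, k0],
            bounds=([0.0, 0.0], [upper_v, np.inf]), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"Michaelis–Menten fit did not converge (n={len(x)}, "
            f"y range [{y.min():.3g}, {ymax:.3g}]): {err}"
        ) from err
    vmax, k = float(popt[0]), float(popt[1])
    resid = y - model(x, vmax, k)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return MMFit(vmax=vmax, k=k, r2=r2)


def depth_for_saturation(fit: MMFit, target: float = 0.9) -> float:
    """Depth at which the fitted curve reaches ``target``.

    Closed-form inversion x = k·target/(vmax − target); returns ``inf``
    when the target is at or beyond the asymptote (unreachable).
    """
    if target >= fit.vmax:
        return float("inf")
    return fit.k * target / (fit.vmax - target)
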