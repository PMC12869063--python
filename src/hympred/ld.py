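"""Linkage disequilibrium: pairwise r2 and hyperbolic decay fitting.

r2 is the squared sample correlation of allele-count codes between two
loci (composite LD, the convention for unphased genotype data), computed
over individuals non-missing at both loci.  Decay with physical distance
x is summarised by least-squares fitting of r2 = 1 / (1 + p x); the
half-decay distance, where the fitted curve crosses 0.5, is 1/p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from hympred.containers import MISSING, GenotypeMatrix

__all__ = ["DecayFit", "LdSummary", "pairwise_r2", "fit_decay", "summarize_ld"]


@dataclass
class DecayFit:
    p: float  # decay rate per bp
    half_decay_bp: float  # 1/p
    rss: float
    n_pairs: int


@dataclass
class LdSummary:
    n_pairs: int
    mean_r2: float
    se: float

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def pairwise_r2(
    gm: GenotypeMatrix,
    max_distance_bp: int = 1_000_000,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """All same-chromosome locus pairs within ``max_distance_bp``.

    Pairs where either locus has zero genotype variance over the shared
    non-missing individuals are skipped.  Returns a DataFrame with columns
    chrom, pos1, pos2, dist, r2.
    """
    codes = gm.codes.astype(float)
    codes[gm.codes == MISSING] = np.nan
    chrom = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy(dtype=np.int64)
    out_chrom, out_p1, out_p2, out_d, out_r2 = [], [], [], [], []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        cpos = pos[idx]
        x = codes[:, idx]
        valid = ~np.isnan(x)
        for a in range(idx.size - 1):
            hi = np.searchsorted(cpos, cpos[a] + max_distance_bp, side="right")
            if hi <= a + 1:
                continue
            xa = x[:, a]
            block = x[:, a + 1:hi]
            both = valid[:, a][:, None] & valid[:, a + 1:hi]
            n = both.sum(axis=0)
            xa_m = np.where(both, xa[:, None], 0.0)
            xb_m = np.where(both, block, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sa = xa_m.sum(axis=0)
                sb = xb_m.sum(axis=0)
                saa = (xa_m**2).sum(axis=0)
                sbb = (xb_m**2).sum(axis=0)
                sab = (xa_m * xb_m).sum(axis=0)
                cov = sab - sa * sb / n
                va = saa - sa**2 / n
                vb = sbb - sb**2 / n
                r2 = cov**2 / (va * vb)
            ok = (n >= min_overlap) & (va > 1e-12) & (vb > 1e-12)
            for k in np.flatnonzero(ok):
                out_chrom.append(c)
                out_p1.append(int(cpos[a]))
                out_p2.append(int(cpos[a + 1 + k]))
                out_d.append(int(cpos[a + 1 + k] - cpos[a]))
                out_r2.append(float(min(r2[k], 1.0)))
    return pd.DataFrame(
        {"chrom": out_chrom, "pos1": out_p1, "pos2": out_p2,
         "dist": out_d, "r2": out_r2}
    )


def _fit_one(dist: np.ndarray, r2: np.ndarray) -> tuple[float, float]:
    """Least-squares p for r2 = 1/(1+p x); returns (p, rss)."""
    mean_r2 = float(np.clip(r2.mean(), 1e-6, 1 - 1e-6))
    p0 = max((1.0 / mean_r2 - 1.0) / max(dist.mean(), 1.0), 1e-12)
    popt, _ = curve_fit(
        lambda x, p: 1.0 / (1.0 + p * x),
        dist, r2, p0=[p0], bounds=(1e-15, np.inf), maxfev=10_000,
    )
    p = float(popt[0])
    rss = float(np.sum((r2 - 1.0 / (1.0 + p * dist)) ** 2))
    return p, rss


def fit_decay(pairs: pd.DataFrame, per_focal: bool = False) -> DecayFit:
    """Fit the hyperbolic decay curve to observed (distance, r2) pairs.

    Default is one pooled fit over all pairs.  ``per_focal=True`` instead
    fits the curve separately for every focal SNP (grouping pairs by their
    left locus) and reports the median decay rate, mirroring tools that
    fit per focal marker.
    """
    if len(pairs) < 2 or pairs["dist"].nunique() < 2:
        raise ValueError("need >= 2 pairs with distinct distances")
    dist = pairs["dist"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if not per_focal:
        p, rss = _fit_one(dist, r2)
        return DecayFit(p=p, half_decay_bp=1.0 / p, rss=rss, n_pairs=len(pairs))
    rates = []
    for (_, _), grp in pairs.groupby(["chrom", "pos1"]):
        if len(grp) >= 3 and grp["dist"].nunique() >= 2:
            try:
                p, _ = _fit_one(grp["dist"].to_numpy(float),
                                grp["r2"].to_numpy(float))
                rates.append(p)
            except RuntimeError:
                continue
    if not rates:
        raise ValueError("no focal SNP had enough pairs for a per-focal fit")
    p = float(np.median(rates))
    rss = float(np.sum((r2 - 1.0 / (1.0 + p * dist)) ** 2))
    return DecayFit(p=p, half_decay_bp=1.0 / p, rss=rss, n_pairs=len(pairs))


def summarize_ld(pairs: pd.DataFrame, window_bp: int = 1_000_000) -> LdSummary:
    """Mean and standard error of r2 for pairs within ``window_bp``.

    An empty window yields an explicit empty summary (n_pairs=0) rather
    than NaN propagation errors.
    """
    sel = pairs.loc[pairs["dist"] <= window_bp, "r2"].to_numpy(dtype=float)
    if sel.size == 0:
        return LdSummary(n_pairs=0, mean_r2=float("nan"), se=float("nan"))
    se = float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else 0.0
    return LdSummary(n_pairs=int(sel.size), mean_r2=float(sel.mean()), se=se)
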