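"""Genomic relationship matrix (VanRaden Method I) and derived quantities.

G = W W' / (2 * sum_j p_j (1 - p_j)), where W holds allele counts centered
by twice the allele frequency.  Missing genotypes are mean-imputed to
2 p_j before centering (i.e. they contribute 0 to W).  The module also
provides PCA on G and the effective number of chromosome segments
Me = 1 / Var(G_ij, i != j), which drives expected prediction accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hympred.containers import GenotypeMatrix

__all__ = [
    "GRM",
    "allele_frequencies",
    "build_grm",
    "grm_pca",
    "compute_me",
    "me_from_sd",
    "bend",
    "write_grm",
]


@dataclass
class GRM:
    matrix: np.ndarray
    ids: list[str]
    freqs: np.ndarray
    denominator: float
    freq_source: str = "observed"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Strictly off-diagonal elements, each unordered pair once."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]


def allele_frequencies(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency per locus from coded genotypes.

    p_j = (mean non-missing code)/2.  Returns (p, monomorphic flags);
    loci with no calls are flagged monomorphic with p = NaN.
    """
    dose = np.asarray(codes, dtype=float)
    dose[np.asarray(codes) == -1] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dose, axis=0) / 2.0
    mono = np.isnan(p) | (p <= 0.0) | (p >= 1.0)
    return p, mono


def build_grm(
    gm: GenotypeMatrix | np.ndarray,
    freqs: np.ndarray | None = None,
    freq_source: str = "observed",
) -> GRM:
    """VanRaden Method-I genomic relationship matrix.

    Loci monomorphic at the supplied frequencies are dropped from both
    numerator and denominator; missing genotypes are imputed to 2p.
    """
    if isinstance(gm, GenotypeMatrix):
        codes, ids = gm.codes, gm.ids
    else:
        codes = np.asarray(gm)
        ids = [f"ind{i}" for i in range(codes.shape[0])]
    if freqs is None:
        freqs, _ = allele_frequencies(codes)
    freqs = np.asarray(freqs, dtype=float)
    keep = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    if not np.any(keep):
        raise ValueError("all loci monomorphic: GRM denominator would be zero")
    p = freqs[keep]
    w = codes[:, keep].astype(float)
    w[codes[:, keep] == -1] = np.nan
    w -= 2.0 * p
    w = np.nan_to_num(w, nan=0.0)  # mean imputation: missing -> 2p -> 0 after centering
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("GRM denominator is zero")
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0
    return GRM(matrix=g, ids=list(ids), freqs=freqs, denominator=denom,
               freq_source=freq_source)


def grm_pca(grm: GRM | np.ndarray, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of G by eigendecomposition.

    Returns (scores, pct_variance): scores are eigenvectors scaled by the
    square root of their (non-negative) eigenvalues, ordered by decreasing
    eigenvalue; pct_variance_i = 100 * eigenvalue_i / trace(G).
    """
    g = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = float(np.trace(g))
    if trace <= 0:
        raise ValueError("G has non-positive trace; PCA variance shares undefined")
    k = min(k, g.shape[0])
    pct = 100.0 * vals / trace
    scores = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    return scores, pct[:k]


def compute_me(grm: GRM | np.ndarray) -> float:
    """Effective number of chromosome segments, 1 / Var(G_ij, i != j).

    Uses the sample variance (ddof=1) of the strictly off-diagonal
    relationships, each unordered pair counted once.
    """
    if isinstance(grm, GRM):
        off = grm.off_diagonal()
    else:
        g = np.asarray(grm)
        off = g[np.triu_indices(g.shape[0], k=1)]
    if off.size < 2:
        raise ValueError("need at least 2 individuals (>=1 off-diagonal pair)")
    var = float(np.var(off, ddof=1))
    if var <= 0:
        raise ValueError("off-diagonal relationships are constant; Me undefined")
    return 1.0 / var


def me_from_sd(sd: float) -> float:
    """Me implied by a reported off-diagonal standard deviation."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return 1.0 / sd**2


def bend(g: np.ndarray, eps: float = 1e-6, min_eig: float = 1e-8) -> np.ndarray:
    """Add ``eps`` to the diagonal if the smallest eigenvalue is < ``min_eig``.

    Keeps G invertible for mixed-model equations; a no-op for comfortably
    positive-definite matrices.
    """
    smallest = float(np.linalg.eigvalsh(g)[0])
    if smallest < min_eig:
        return g + np.eye(g.shape[0]) * (eps + max(0.0, -smallest))
    return g


def write_grm(grm: GRM, matrix_path: str, ids_path: str) -> None:
    """Write the full matrix (whitespace-delimited) and the id list."""
    np.savetxt(matrix_path, grm.matrix, fmt="%.6g")
    pd.Series(grm.ids).to_csv(ids_path, index=False, header=False)
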