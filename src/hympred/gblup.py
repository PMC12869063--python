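"""GBLUP mixed model with a one-generation host effect and heterogeneous residuals.

The model is

    y = X b + Zg g + [0; Zc] c + [e1; e2]

with g ~ N(0, G sigma_g^2) for all individuals (phenotyped or not),
c ~ N(0, I sigma_c^2) a common-environment (host/brood) effect defined
only for individuals of the generation whose host identities were
recorded, and generation-specific residual variances e_k ~ N(0, I
sigma_ek^2).  Separating the residuals matters because host variance that
cannot be fitted for the generation without host records is absorbed into
that generation's residual.

Variance components are estimated by restricted maximum likelihood using
average-information (AI) updates with an EM fallback and step-halving;
breeding values and host effects are the BLUPs at the converged
components.  GEBVs are produced for every individual in G, including
those whose phenotypes were masked, via g_hat = sigma_g^2 G[:, train] P y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from hympred.containers import SampleTable
from hympred.grm import GRM, bend

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "VarianceComponents",
    "FitResult",
    "build_design",
    "reml_loglik",
    "reml_fit",
    "heritability",
    "fit_gblup",
]


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: trait, fixed effects, host generation, masking."""

    trait: str
    host_generation: str | None = None
    fixed_effects: tuple[str, ...] = ("intercept", "generation")
    masked_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if "intercept" not in self.fixed_effects:
            raise ValueError("the model always carries an intercept")


@dataclass
class DesignMatrices:
    """Observation-level structures for one fit.

    ``g_index`` maps each observation row to its row in G; ``Zc`` (when
    present) has a one-hot row for each host-generation observation and an
    all-zero row for every other observation — the zero block of the model.
    """

    y: np.ndarray
    X: np.ndarray
    g_index: np.ndarray
    Zc: np.ndarray | None
    host_labels: list[str]
    resid_group: np.ndarray  # int group per observation
    resid_labels: list[str]
    obs_ids: list[str]


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_c2: float | None  # None when no host structure was fit
    sigma_e2: dict  # residual variance per generation label
    loglik: float
    converged: bool
    n_iter: int
    boundary: list = field(default_factory=list)


@dataclass
class FitResult:
    vc: VarianceComponents
    beta: np.ndarray
    fixed_names: list[str]
    gebv: pd.Series  # indexed by every id in G
    host_blups: pd.Series
    design: DesignMatrices


def build_design(
    samples: SampleTable | pd.DataFrame,
    spec: ModelSpec,
    g_ids: list[str],
) -> DesignMatrices:
    """Assemble y, X, Zg (as an index into G) and Zc for one trait.

    Rows are the phenotyped, unmasked individuals present in G.  Masked
    individuals contribute no observation but keep their GEBV slot through
    G.  A host-generation individual without a host id is an error.
    """
    frame = samples.frame if isinstance(samples, SampleTable) else samples
    if spec.trait not in frame.columns:
        raise ValueError(f"trait column '{spec.trait}' not in sample table")
    pos_in_g = {ind: i for i, ind in enumerate(g_ids)}
    obs = frame[
        frame[spec.trait].notna()
        & frame["id"].isin(pos_in_g)
        & ~frame["id"].isin(spec.masked_ids)
    ].reset_index(drop=True)
    if len(obs) == 0:
        raise ValueError("no phenotyped, unmasked observations")

    y = obs[spec.trait].to_numpy(dtype=float)
    g_index = np.array([pos_in_g[i] for i in obs["id"]], dtype=int)

    cols = [np.ones(len(obs))]
    names = ["intercept"]
    gens = sorted(obs["generation"].unique())
    if "generation" in spec.fixed_effects and len(gens) > 1:
        for gen in gens[1:]:
            cols.append((obs["generation"] == gen).to_numpy(dtype=float))
            names.append(f"generation[{gen}]")
    X = np.column_stack(cols)

    Zc, host_labels = None, []
    if spec.host_generation is not None:
        in_host_gen = obs["generation"] == spec.host_generation
        if in_host_gen.any():
            if obs.loc[in_host_gen, "host"].isna().any():
                raise ValueError(
                    f"individuals of generation '{spec.host_generation}' "
                    "lack host ids"
                )
            host_labels = sorted(obs.loc[in_host_gen, "host"].unique())
            col_of = {h: j for j, h in enumerate(host_labels)}
            Zc = np.zeros((len(obs), len(host_labels)))
            for r in np.flatnonzero(in_host_gen.to_numpy()):
                Zc[r, col_of[obs.at[r, "host"]]] = 1.0

    resid_labels = gens
    group_of = {g: k for k, g in enumerate(resid_labels)}
    resid_group = obs["generation"].map(group_of).to_numpy(dtype=int)
    return DesignMatrices(
        y=y, X=X, g_index=g_index, Zc=Zc, host_labels=host_labels,
        resid_group=resid_group, resid_labels=resid_labels,
        obs_ids=list(obs["id"]),
    )


def _components(design: DesignMatrices, G: np.ndarray) -> tuple[list, list]:
    """Dense covariance-structure matrices and their names.

    Only identifiable components enter the parameter vector: the host
    component requires >= 2 hosts with observations, and each residual
    group requires >= 2 observations.
    """
    n = design.y.size
    comps = [G[np.ix_(design.g_index, design.g_index)]]
    names = ["g"]
    if design.Zc is not None and len(design.host_labels) >= 2:
        comps.append(design.Zc @ design.Zc.T)
        names.append("c")
    for k, label in enumerate(design.resid_labels):
        members = design.resid_group == k
        if members.sum() < 2:
            raise ValueError(
                f"residual group '{label}' has fewer than 2 observations"
            )
        comps.append(np.diag(members.astype(float)))
        names.append(f"e[{label}]")
    if n != comps[0].shape[0]:
        raise AssertionError("component dimension mismatch")
    return comps, names


def _reml_pieces(theta, comps, X, y):
    """(loglik, P, w=Py, Vinv) for variance components ``theta``."""
    V = sum(t * C for t, C in zip(theta, comps))
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vinv = cho_solve(cf, np.eye(V.shape[0]))
    VX = Vinv @ X
    XtVX = X.T @ VX
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return None
    P = Vinv - VX @ np.linalg.solve(XtVX, VX.T)
    w = P @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ w))
    return ll, P, w, Vinv


def reml_loglik(
    theta: np.ndarray, design: DesignMatrices, G: np.ndarray
) -> float:
    """Restricted log-likelihood (constant terms dropped) at ``theta``.

    ``theta`` is ordered (sigma_g2[, sigma_c2], sigma_e2 per generation in
    sorted label order).  Exposed so the REML path can be checked against
    direct likelihood maximisation.
    """
    comps, _ = _components(design, G)
    pieces = _reml_pieces(np.asarray(theta, dtype=float), comps, design.X,
                          design.y)
    if pieces is None:
        return -np.inf
    return pieces[0]


def _ai_loop(theta0, comps, names, X, y, n, floor, max_iter, tol, verbose):
    """One AI-REML run: returns (theta, ll, P, w, n_iter, converged) or None."""
    theta = np.maximum(np.asarray(theta0, dtype=float), floor)
    pieces = _reml_pieces(theta, comps, X, y)
    if pieces is None:
        return None
    ll, P, w, _ = pieces
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Cw = [C @ w for C in comps]
        quad = np.array([float(w @ cw) for cw in Cw])
        traces = np.array([float(np.sum(P * C)) for C in comps])
        scores = -0.5 * (traces - quad)
        U = np.column_stack(Cw)
        AI = 0.5 * (U.T @ P @ U)
        # EM step (GCTA-style), used when the AI step fails to improve.
        em_theta = theta + theta**2 * (quad - traces) / n
        proposal = None
        try:
            delta = np.linalg.solve(AI + np.eye(len(theta)) * 1e-10, scores)
        except np.linalg.LinAlgError:
            delta = None
        step = 1.0
        if delta is not None:
            for _ in range(12):
                cand = np.maximum(theta + step * delta, floor)
                cand_pieces = _reml_pieces(cand, comps, X, y)
                if cand_pieces is not None and cand_pieces[0] >= ll - 1e-10:
                    proposal = (cand, cand_pieces)
                    break
                step *= 0.5
        if proposal is None:
            cand = np.maximum(em_theta, floor)
            cand_pieces = _reml_pieces(cand, comps, X, y)
            if cand_pieces is None:
                break
            proposal = (cand, cand_pieces)
        new_theta, (new_ll, new_P, new_w, _) = proposal
        dll = new_ll - ll
        theta, ll, P, w = new_theta, new_ll, new_P, new_w
        if verbose:
            print(f"iter {it}: ll={ll:.6f} theta={theta}")
        if abs(dll) < tol * (1.0 + abs(ll)):
            converged = True
            break
    return theta, ll, P, w, it, converged


def _polish(theta, comps, X, y, floor):
    """Derivative-free refinement on log-components for tiny systems."""
    from scipy.optimize import minimize

    def neg_ll(log_t):
        pieces = _reml_pieces(np.maximum(np.exp(log_t), floor), comps, X, y)
        return np.inf if pieces is None else -pieces[0]

    res = minimize(neg_ll, np.log(np.maximum(theta, floor)),
                   method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    if not np.isfinite(res.fun):
        return None
    refined = np.maximum(np.exp(res.x), floor)
    pieces = _reml_pieces(refined, comps, X, y)
    if pieces is None:
        return None
    return refined, pieces


def reml_fit(
    design: DesignMatrices,
    G: np.ndarray | GRM,
    g_ids: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    verbose: bool = False,
) -> FitResult:
    """Average-information REML with EM fallback, then BLUP solutions.

    Components are constrained non-negative by projection to a small
    floor (1e-6 x var(y)); converged when the relative log-likelihood
    change drops below ``tol``.  A fit that exhausts ``max_iter`` is
    returned with ``converged=False``.
    """
    if isinstance(G, GRM):
        g_ids = G.ids
        G = G.matrix
    if g_ids is None:
        g_ids = [f"ind{i}" for i in range(G.shape[0])]
    G = bend(np.asarray(G, dtype=float))
    comps, names = _components(design, G)
    y, X = design.y, design.X
    n = y.size
    vy = float(np.var(y, ddof=1))
    if vy <= 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-6 * vy

    # Small systems have genuinely multimodal restricted likelihoods, so
    # run the AI loop from several starting decompositions there; large
    # systems are well conditioned and a single start suffices.
    k = len(comps)
    starts = [np.full(k, vy / k)]
    if n <= 200:
        resid = np.array([name.startswith("e[") for name in names])
        heavy_resid = np.where(resid, 0.9 * vy / max(resid.sum(), 1),
                               0.1 * vy / max(k - resid.sum(), 1))
        heavy_gen = np.full(k, 0.2 * vy / max(k - 1, 1))
        heavy_gen[names.index("g")] = 0.8 * vy
        starts += [heavy_resid, heavy_gen]

    best = None
    for theta0 in starts:
        state = _ai_loop(theta0, comps, names, X, y, n, floor, max_iter, tol,
                         verbose)
        if state is not None and (best is None or state[1] > best[1]):
            best = state
    if best is None:
        raise np.linalg.LinAlgError(
            "singular starting system; consider bending G"
        )
    theta, ll, P, w, it, converged = best

    if n <= 60:
        polished = _polish(theta, comps, X, y, floor)
        if polished is not None and polished[1][0] > ll + 1e-12:
            theta, (ll, P, w, _) = polished
            converged = True

    boundary = [names[i] for i in range(len(theta)) if theta[i] <= floor * 1.01]
    idx = {name: i for i, name in enumerate(names)}
    sigma_g2 = float(theta[idx["g"]])
    sigma_c2 = float(theta[idx["c"]]) if "c" in idx else None
    sigma_e2 = {
        label: float(theta[idx[f"e[{label}]"]]) for label in design.resid_labels
    }
    vc = VarianceComponents(
        sigma_g2=sigma_g2, sigma_c2=sigma_c2, sigma_e2=sigma_e2,
        loglik=float(ll), converged=converged, n_iter=it, boundary=boundary,
    )

    # Fixed effects and BLUPs at the converged components.
    V = sum(t * C for t, C in zip(theta, comps))
    cf = cho_factor(V, lower=True)
    Vinv_y = cho_solve(cf, y)
    Vinv_X = cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    # w = P y = Vinv (y - X beta)
    gebv_all = sigma_g2 * (G[:, design.g_index] @ w)
    host_blups = pd.Series(dtype=float)
    if sigma_c2 is not None and design.Zc is not None:
        host_blups = pd.Series(
            sigma_c2 * (design.Zc.T @ w), index=design.host_labels
        )
    return FitResult(
        vc=vc,
        beta=beta,
        fixed_names=_fixed_names(design),
        gebv=pd.Series(gebv_all, index=g_ids),
        host_blups=host_blups,
        design=design,
    )


def _fixed_names(design: DesignMatrices) -> list[str]:
    k = design.X.shape[1]
    names = ["intercept"]
    extra = [g for g in design.resid_labels[1:]]
    names += [f"generation[{g}]" for g in extra[: k - 1]]
    return names[:k]


def heritability(vc: VarianceComponents, host_generation: str | None = None) -> float:
    """h2 = sigma_g2 / (sigma_g2 + sigma_c2 + sigma_e2[host generation]).

    The phenotypic variance in the denominator is that of the generation
    with host records, whose residual is free of unmodelled host variance.
    When no generation is named, the last residual group of the fit is
    used (the host generation in the two-cohort design).
    """
    sigma_c2 = vc.sigma_c2 or 0.0
    if host_generation is None:
        host_generation = list(vc.sigma_e2)[-1]
    sigma_p2 = vc.sigma_g2 + sigma_c2 + vc.sigma_e2[host_generation]
    if sigma_p2 <= 0:
        raise ValueError("phenotypic variance is zero")
    return vc.sigma_g2 / sigma_p2


def fit_gblup(
    samples: SampleTable | pd.DataFrame,
    grm: GRM,
    spec: ModelSpec,
    **kwargs,
) -> FitResult:
    """Convenience wrapper: build the design and run REML in one call."""
    design = build_design(samples, spec, grm.ids)
    return reml_fit(design, grm.matrix, g_ids=grm.ids, **kwargs)
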