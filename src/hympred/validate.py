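"""Validation of genomic predictions: schemes, accuracy, dispersion, theory.

Three schemes are supported:

* ``AGFV`` — across-generation forward validation: train on the earlier
  generation, predict the later one;
* ``AGBV`` — backward: train on the later generation, predict the earlier;
* ``KFOLD`` — repeated k-fold cross-validation over the whole cohort,
  each individual validated exactly once per repeat.

Per split the validation phenotypes are masked, the GBLUP model is
refitted on the training set, and the predicted GEBVs of validation
individuals are compared with their observed phenotypes.  Accuracy is the
correlation divided by the square root of the (full-data) heritability;
dispersion is the OLS slope of phenotype on GEBV, with 1 the theoretical
value for correctly scaled GEBVs.  The module also implements the
expected accuracy of genomic prediction given the effective number of
chromosome segments Me, sqrt(Np h2 / (Np h2 + Me)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hympred.containers import SampleTable
from hympred.gblup import FitResult, ModelSpec, fit_gblup, heritability
from hympred.grm import GRM

__all__ = [
    "ValidationScheme",
    "SplitResult",
    "ValidationResult",
    "make_splits",
    "accuracy",
    "dispersion",
    "expected_accuracy",
    "run_validation",
    "describe_traits",
]


@dataclass(frozen=True)
class ValidationScheme:
    kind: str  # "AGFV", "AGBV" or "KFOLD"
    k: int = 5
    n_repeats: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("AGFV", "AGBV", "KFOLD"):
            raise ValueError("kind must be AGFV, AGBV or KFOLD")
        if self.kind == "KFOLD" and self.k < 2:
            raise ValueError("k-fold needs k >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class SplitResult:
    repeat: int
    correlation: float
    accuracy: float
    dispersion: float
    n_validation: int


@dataclass
class ValidationResult:
    scheme: ValidationScheme
    trait: str
    h2: float
    replicates: list[SplitResult]
    mean_accuracy: float = field(init=False)
    se_accuracy: float = field(init=False)
    mean_dispersion: float = field(init=False)
    se_dispersion: float = field(init=False)
    mean_correlation: float = field(init=False)

    def __post_init__(self) -> None:
        acc = np.array([r.accuracy for r in self.replicates])
        disp = np.array([r.dispersion for r in self.replicates])
        cor = np.array([r.correlation for r in self.replicates])
        self.mean_accuracy = float(acc.mean())
        self.mean_dispersion = float(disp.mean())
        self.mean_correlation = float(cor.mean())
        if acc.size > 1:
            self.se_accuracy = float(acc.std(ddof=1) / np.sqrt(acc.size))
            self.se_dispersion = float(disp.std(ddof=1) / np.sqrt(disp.size))
        else:
            self.se_accuracy = 0.0
            self.se_dispersion = 0.0


def make_splits(
    samples: SampleTable | pd.DataFrame,
    scheme: ValidationScheme,
) -> list[list[tuple[list[str], list[str]]]]:
    """Training/validation id splits, grouped by repeat.

    KFOLD: each repeat is a random partition into ``k`` near-equal folds,
    each used once for validation.  AGFV/AGBV: a single deterministic
    generation split (the repeat list has length 1).
    """
    frame = samples.frame if isinstance(samples, SampleTable) else samples
    gens = sorted(frame["generation"].unique())
    if scheme.kind in ("AGFV", "AGBV"):
        if len(gens) != 2:
            raise ValueError("across-generation validation needs exactly 2 generations")
        first = frame.loc[frame["generation"] == gens[0], "id"].tolist()
        second = frame.loc[frame["generation"] == gens[1], "id"].tolist()
        if scheme.kind == "AGFV":
            return [[(first, second)]]
        return [[(second, first)]]
    rng = np.random.default_rng(scheme.seed)
    ids = np.asarray(frame["id"], dtype=object)
    repeats = []
    for _ in range(scheme.n_repeats):
        perm = rng.permutation(ids.size)
        folds = np.array_split(perm, scheme.k)
        splits = []
        for f in folds:
            val = set(ids[f].tolist())
            train = [i for i in ids if i not in val]
            splits.append((train, list(ids[f])))
        repeats.append(splits)
    return repeats


def accuracy(correlation: float, h2: float) -> float:
    """Prediction accuracy: correlation with phenotype divided by sqrt(h2)."""
    if h2 <= 0:
        raise ValueError("accuracy requires h2 > 0")
    return correlation / np.sqrt(h2)


def dispersion(gebv: np.ndarray, y: np.ndarray) -> float:
    """OLS slope of observed phenotype on predicted GEBV.

    1 means correctly scaled GEBVs; > 1 underdispersion (GEBVs should be
    upscaled), < 1 overdispersion.
    """
    gebv = np.asarray(gebv, dtype=float)
    y = np.asarray(y, dtype=float)
    var = gebv.var()
    if var <= 1e-30:
        raise ValueError("GEBVs are constant; dispersion slope undefined")
    return float(np.cov(y, gebv, ddof=0)[0, 1] / var)


def expected_accuracy(n_p: float, h2: float, me: float) -> float:
    """Expected accuracy sqrt(Np h2 / (Np h2 + Me)) for unrelated training sets.

    ``n_p`` is the training-population size and ``me`` the effective
    number of independent chromosome segments; family structure in real
    populations makes this an upper bound in practice.
    """
    if n_p <= 0 or h2 < 0 or me < 0:
        raise ValueError("need n_p > 0, h2 >= 0, me >= 0")
    num = n_p * h2
    if num + me <= 0:
        raise ValueError("Np*h2 + Me must be positive")
    return float(np.sqrt(num / (num + me)))


def run_validation(
    samples: SampleTable | pd.DataFrame,
    grm: GRM,
    spec: ModelSpec,
    scheme: ValidationScheme,
    h2_source: str = "full_data",
    full_fit: FitResult | None = None,
) -> ValidationResult:
    """Run one validation scheme for one trait.

    Per repeat, validation predictions are pooled over folds before the
    correlation/accuracy/dispersion are computed; repeat-level statistics
    are then averaged.  ``h2_source='full_data'`` (default) divides by
    the heritability from a fit on all phenotypes; ``'per_fold'`` uses
    each training fit's own h2 (averaged over the folds of a repeat).
    """
    frame = (samples.frame if isinstance(samples, SampleTable) else samples)
    if full_fit is None:
        full_fit = fit_gblup(samples, grm, spec)
    h2_full = heritability(full_fit.vc, spec.host_generation)
    pheno = frame.set_index("id")[spec.trait]

    replicates: list[SplitResult] = []
    for rep, splits in enumerate(make_splits(samples, scheme)):
        preds: dict[str, float] = {}
        fold_h2: list[float] = []
        for train_ids, val_ids in splits:
            masked = frozenset(val_ids)
            fold_spec = ModelSpec(
                trait=spec.trait,
                host_generation=spec.host_generation,
                fixed_effects=spec.fixed_effects,
                masked_ids=spec.masked_ids | masked,
            )
            fit = fit_gblup(samples, grm, fold_spec)
            fold_h2.append(_safe_h2(fit, spec.host_generation))
            for ind in val_ids:
                preds[ind] = float(fit.gebv[ind])
        val_ids_all = [i for i in preds if not pd.isna(pheno.get(i, np.nan))]
        y_val = pheno[val_ids_all].to_numpy(dtype=float)
        g_val = np.array([preds[i] for i in val_ids_all])
        if y_val.size < 3 or y_val.var() <= 0:
            continue  # degenerate replicate: no phenotypic variance
        corr = float(np.corrcoef(g_val, y_val)[0, 1])
        h2 = h2_full if h2_source == "full_data" else float(np.mean(fold_h2))
        replicates.append(
            SplitResult(
                repeat=rep,
                correlation=corr,
                accuracy=accuracy(corr, h2),
                dispersion=dispersion(g_val, y_val),
                n_validation=int(y_val.size),
            )
        )
    if not replicates:
        raise ValueError("every replicate was degenerate; nothing to report")
    return ValidationResult(
        scheme=scheme, trait=spec.trait, h2=h2_full, replicates=replicates
    )


def _safe_h2(fit: FitResult, host_generation: str | None) -> float:
    labels = list(fit.vc.sigma_e2)
    if host_generation is not None and host_generation in labels:
        return heritability(fit.vc, host_generation)
    return heritability(fit.vc, labels[-1])


def describe_traits(
    samples: SampleTable | pd.DataFrame,
    trait_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive statistics per trait and group (each generation + combined).

    CV is the coefficient of phenotypic variation, 100 * SD / mean, with
    SD the sample standard deviation; a constant trait reports SD = CV = 0.
    """
    if isinstance(samples, SampleTable):
        frame = samples.frame
        trait_columns = trait_columns or samples.trait_columns
    else:
        frame = samples
        if trait_columns is None:
            reserved = {"id", "generation", "host"}
            trait_columns = [c for c in frame.columns if c not in reserved]
    groups = [(g, frame[frame["generation"] == g])
              for g in sorted(frame["generation"].unique())]
    groups.append(("combined", frame))
    rows = []
    for trait in trait_columns:
        for label, sub in groups:
            vals = sub[trait].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            cv = 100.0 * sd / mean if mean != 0 else float("nan")
            rows.append(
                {"trait": trait, "group": label, "n": int(vals.size),
                 "mean": mean, "sd": sd, "cv": cv,
                 "min": float(vals.min()), "max": float(vals.max())}
            )
    return pd.DataFrame(rows)
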