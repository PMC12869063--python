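"""End-to-end orchestration: simulate-or-load, QC, GRM, LD, GBLUP, validation.

A single :class:`RunConfig` drives the whole workflow and every output is
recorded in a manifest with a content hash, so a run is reproducible from
its config and master seed alone.  The headline outputs are a descriptive
trait table (mean/SD/CV/min/max per generation and combined) and a
per-trait report of h2 with accuracy and dispersion for each validation
scheme.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from hympred.containers import GenotypeMatrix, SampleTable
from hympred.gblup import ModelSpec, fit_gblup, heritability
from hympred.grm import build_grm, compute_me, grm_pca, write_grm
from hympred.ld import fit_decay, pairwise_r2, summarize_ld
from hympred.simdata import (
    SimConfig,
    read_samples_csv,
    simulate,
    write_samples_csv,
    write_vcf,
)
from hympred.validate import (
    ValidationScheme,
    describe_traits,
    expected_accuracy,
    run_validation,
)
from hympred.variant_qc import QcThresholds, read_vcf, run_qc, write_audit

logger = logging.getLogger("hympred")

__all__ = ["RunConfig", "run", "load_config"]


def _package_version() -> str:
    from importlib.metadata import version

    try:
        return version("hympred")
    except Exception:
        return "unknown"


@dataclass
class RunConfig:
    """One of ``sim`` / (``vcf`` + ``samples``) selects the input mode."""

    out_dir: str
    seed: int = 0
    sim: SimConfig | None = None
    vcf: str | None = None
    samples: str | None = None
    qc: QcThresholds = field(default_factory=QcThresholds)
    host_generation: str | None = None
    traits: list[str] | None = None
    fixed_effects: tuple[str, ...] = ("intercept", "generation")
    schemes: list[ValidationScheme] = field(default_factory=list)
    ld_max_distance_bp: int = 1_000_000
    run_ld: bool = True

    def __post_init__(self) -> None:
        simulate_mode = self.sim is not None
        load_mode = self.vcf is not None or self.samples is not None
        if simulate_mode == load_mode:
            raise ValueError("set exactly one of 'sim' or 'vcf'+'samples'")
        if load_mode and (self.vcf is None or self.samples is None):
            raise ValueError("load mode needs both 'vcf' and 'samples'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig, out: Path) -> tuple[GenotypeMatrix, SampleTable]:
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        logger.info("simulating cohort: %d SNPs, cohorts %s",
                    sim_cfg.n_snps, sim_cfg.n_females_sampled)
        result = simulate(sim_cfg)
        write_vcf(result.genotypes, str(out / "genotypes.vcf"))
        write_samples_csv(result.samples, str(out / "samples.csv"))
        return result.genotypes, result.samples
    logger.info("loading genotypes from %s", config.vcf)
    gm = read_vcf(config.vcf)
    samples = read_samples_csv(config.samples)
    return gm, samples


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, samples = _load_inputs(config, out)

    host_generation = config.host_generation
    if host_generation is None and samples.frame["host"].notna().any():
        with_host = samples.frame.loc[samples.frame["host"].notna(), "generation"]
        host_generation = sorted(with_host.unique())[-1]
    if host_generation is not None:
        in_gen = samples.frame["generation"] == host_generation
        if samples.frame.loc[in_gen, "host"].isna().all():
            raise ValueError(
                f"host effects requested for generation '{host_generation}' "
                "but the sample table has no host ids for it"
            )

    qc_result = run_qc(gm, config.qc)
    write_audit(qc_result, str(out / "qc_audit.tsv"))
    gm_f = qc_result.genotypes
    logger.info("QC: %d/%d sites, %d/%d individuals kept",
                gm_f.n_variants, gm.n_variants,
                gm_f.n_individuals, gm.n_individuals)
    samples_f = SampleTable(
        frame=samples.frame[samples.frame["id"].isin(gm_f.ids)].reset_index(drop=True),
        trait_columns=samples.trait_columns,
    )

    grm = build_grm(gm_f)
    write_grm(grm, str(out / "grm.txt"), str(out / "grm_ids.txt"))
    scores, pct = grm_pca(grm, k=10)
    pca_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
    pca_df.insert(0, "id", grm.ids)
    pca_df.to_csv(out / "pca_scores.csv", index=False)
    me = compute_me(grm)

    ld_report = None
    if config.run_ld:
        pairs = pairwise_r2(gm_f, max_distance_bp=config.ld_max_distance_bp)
        pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        if len(pairs) >= 2 and pairs["dist"].nunique() >= 2:
            decay = fit_decay(pairs)
            summary = summarize_ld(pairs, window_bp=config.ld_max_distance_bp)
            ld_report = {
                "decay_rate_per_bp": decay.p,
                "half_decay_bp": decay.half_decay_bp,
                "mean_r2": summary.mean_r2,
                "se_r2": summary.se,
                "n_pairs": summary.n_pairs,
            }
            with open(out / "ld_fit.json", "w") as fh:
                json.dump(ld_report, fh, indent=2)

    traits = config.traits or samples.trait_columns
    table1 = describe_traits(samples_f, traits)
    table1.to_csv(out / "trait_descriptives.csv", index=False)

    report_rows = []
    for trait in traits:
        spec = ModelSpec(
            trait=trait,
            host_generation=host_generation,
            fixed_effects=config.fixed_effects,
        )
        fit = fit_gblup(samples_f, grm, spec)
        h2 = heritability(fit.vc, host_generation)
        fit.gebv.rename("gebv").to_csv(out / f"gebv_{trait}.tsv", sep="\t",
                                       header=True, index_label="id")
        fit_report = {
            "trait": trait,
            "sigma_g2": fit.vc.sigma_g2,
            "sigma_c2": fit.vc.sigma_c2,
            "sigma_e2": fit.vc.sigma_e2,
            "h2": h2,
            "loglik": fit.vc.loglik,
            "converged": fit.vc.converged,
            "n_iter": fit.vc.n_iter,
        }
        with open(out / f"fit_{trait}.json", "w") as fh:
            json.dump(fit_report, fh, indent=2)
        row = {"trait": trait, "h2": h2}
        for scheme in config.schemes:
            scheme_seeded = dataclasses.replace(
                scheme, seed=(config.seed * 1000 + scheme.seed) % (2**31 - 1)
            )
            vres = run_validation(samples_f, grm, spec, scheme_seeded,
                                  full_fit=fit)
            tag = scheme.kind.lower()
            row[f"{tag}_accuracy"] = vres.mean_accuracy
            row[f"{tag}_dispersion"] = vres.mean_dispersion
            pd.DataFrame(
                [dataclasses.asdict(r) for r in vres.replicates]
            ).to_csv(out / f"validation_{trait}_{tag}.csv", index=False)
        report_rows.append(row)
    report = pd.DataFrame(report_rows)
    report.to_csv(out / "prediction_report.csv", index=False)

    n_train_kfold = int(round(len(samples_f) * 4 / 5))
    mean_h2 = float(report["h2"].mean()) if len(report) else float("nan")
    manifest = {
        "version": _package_version(),
        "seed": config.seed,
        "mode": "simulate" if config.sim is not None else "load",
        "n_individuals": gm_f.n_individuals,
        "n_snps": gm_f.n_variants,
        "qc_audit": qc_result.site_audit,
        "me": me,
        "pca_pct_variance": [float(v) for v in pct[:2]],
        "ld": ld_report,
        "expected_accuracy_kfold": (
            expected_accuracy(n_train_kfold, mean_h2, me)
            if mean_h2 > 0 else None
        ),
        "headline": report.to_dict(orient="records"),
        "outputs": {},
    }
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _scheme_from_dict(d: dict) -> ValidationScheme:
    return ValidationScheme(
        kind=d["kind"].upper(), k=int(d.get("k", 5)),
        n_repeats=int(d.get("n_repeats", 50)), seed=int(d.get("seed", 0)),
    )


def load_config(path: str) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim = None
    if "sim" in raw:
        sim_raw = dict(raw["sim"])
        if "traits" in sim_raw:
            from hympred.simdata import TraitArchitecture

            sim_raw["traits"] = tuple(
                TraitArchitecture(**t) for t in sim_raw["traits"]
            )
        for key in ("chrom_lengths_cm", "n_females_sampled", "founder_freq_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimConfig(**sim_raw)
    qc = QcThresholds(**raw.get("qc", {}))
    schemes = [_scheme_from_dict(s) for s in raw.get("schemes", [])]
    return RunConfig(
        out_dir=raw["out_dir"],
        seed=int(raw.get("seed", 0)),
        sim=sim,
        vcf=raw.get("vcf"),
        samples=raw.get("samples"),
        qc=qc,
        host_generation=raw.get("host_generation"),
        traits=raw.get("traits"),
        fixed_effects=tuple(raw.get("fixed_effects", ("intercept", "generation"))),
        schemes=schemes,
        ld_max_distance_bp=int(raw.get("ld_max_distance_bp", 1_000_000)),
        run_ld=bool(raw.get("run_ld", True)),
    )
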