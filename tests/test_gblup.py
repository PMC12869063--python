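"""REML variance components and BLUP breeding values."""

import numpy as np
import pandas as pd
import pytest

from _oracles import restricted_loglik, single_variance_gblup_reml
from conftest import small_config
from hympred.containers import SampleTable
from hympred.gblup import (
    ModelSpec,
    build_design,
    fit_gblup,
    heritability,
    reml_fit,
    reml_loglik,
)
from hympred.grm import build_grm
from hympred.simdata import SimConfig, TraitArchitecture, simulate


def tiny_system(seed=3, n=6, n_hosts=2):
    """A small two-generation data set with a well-conditioned G."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(n, 40)).astype(np.int8)
    grm = build_grm(codes)
    half = n // 2
    frame = pd.DataFrame(
        {
            "id": grm.ids,
            "generation": ["G1"] * half + ["G2"] * (n - half),
            "host": [pd.NA] * half
            + [f"h{i % n_hosts}" for i in range(n - half)],
            "y": rng.normal(0, 1, n),
        }
    )
    return SampleTable(frame=frame), grm


class TestBuildDesign:
    def test_intercept_only_design(self):
        samples, grm = tiny_system()
        spec = ModelSpec(trait="y", fixed_effects=("intercept",))
        d = build_design(samples, spec, grm.ids)
        assert np.array_equal(d.X, np.ones((6, 1)))

    def test_host_incidence_column_sums_are_brood_sizes(self):
        samples, grm = tiny_system(n=8, n_hosts=2)
        spec = ModelSpec(trait="y", host_generation="G2")
        d = build_design(samples, spec, grm.ids)
        assert d.Zc is not None
        assert np.all(d.Zc.sum(axis=1)[d.resid_group == 0] == 0)  # zero block
        assert sorted(d.Zc.sum(axis=0).tolist()) == [2, 2]

    def test_masked_individual_has_no_row_but_keeps_gebv_slot(self):
        samples, grm = tiny_system(n=8)
        masked = samples.frame["id"].iloc[0]
        spec = ModelSpec(trait="y", masked_ids=frozenset([masked]))
        d = build_design(samples, spec, grm.ids)
        assert masked not in d.obs_ids
        fit = reml_fit(d, grm.matrix, g_ids=grm.ids)
        assert masked in fit.gebv.index

    def test_missing_host_in_host_generation_is_an_error(self):
        samples, grm = tiny_system(n=8)
        samples.frame.loc[samples.frame["generation"] == "G2", "host"] = pd.NA
        with pytest.raises(ValueError, match="host"):
            build_design(samples, ModelSpec(trait="y", host_generation="G2"),
                         grm.ids)


class TestHeritability:
    def test_arithmetic(self):
        from hympred.gblup import VarianceComponents

        vc = VarianceComponents(sigma_g2=1.0, sigma_c2=1.0,
                                sigma_e2={"G1": 9.0, "G2": 2.0},
                                loglik=0.0, converged=True, n_iter=1)
        assert heritability(vc, "G2") == pytest.approx(0.25)

    def test_zero_genetic_variance(self):
        from hympred.gblup import VarianceComponents

        vc = VarianceComponents(sigma_g2=0.0, sigma_c2=0.5,
                                sigma_e2={"G2": 1.0}, loglik=0.0,
                                converged=True, n_iter=1)
        assert heritability(vc) == 0.0

    def test_reduces_to_classic_without_host_term(self):
        from hympred.gblup import VarianceComponents

        vc = VarianceComponents(sigma_g2=1.0, sigma_c2=None,
                                sigma_e2={"G1": 3.0}, loglik=0.0,
                                converged=True, n_iter=1)
        assert heritability(vc) == pytest.approx(0.25)


class TestRemlAgainstOracles:
    def test_loglik_matches_direct_formula(self):
        samples, grm = tiny_system(n=8)
        spec = ModelSpec(trait="y", host_generation="G2")
        d = build_design(samples, spec, grm.ids)
        from hympred.gblup import _components

        comps, _ = _components(d, grm.matrix + np.eye(8) * 1e-6)
        for theta in ([0.5, 0.3, 0.8, 0.6], [1.0, 0.1, 0.2, 2.0]):
            assert reml_loglik(theta, d, grm.matrix + np.eye(8) * 1e-6) == (
                pytest.approx(restricted_loglik(theta, comps, d.X, d.y))
            )

    def test_fit_attains_grid_search_maximum_on_tiny_system(self):
        samples, grm = tiny_system(n=6)
        spec = ModelSpec(trait="y", host_generation="G2",
                         fixed_effects=("intercept",))
        d = build_design(samples, spec, grm.ids)
        G = grm.matrix + np.eye(6) * 1e-6
        fit = reml_fit(d, G, g_ids=grm.ids)
        from hympred.gblup import _components

        comps, _ = _components(d, G)
        vy = float(np.var(d.y, ddof=1))
        grid = vy * np.geomspace(0.01, 4.0, 8)
        best = -np.inf
        for a in grid:
            for b in grid:
                for c in grid:
                    for e in grid:
                        best = max(best, restricted_loglik(
                            [a, b, c, e], comps, d.X, d.y))
        assert fit.vc.loglik >= best - 1e-6

    def test_matches_single_variance_oracle(self):
        # Without a host term and with one residual group the model is
        # standard GBLUP; compare against an eigenbasis REML oracle.
        rng = np.random.default_rng(9)
        n = 40
        codes = rng.integers(0, 3, size=(n, 120)).astype(np.int8)
        grm = build_grm(codes)
        G = grm.matrix + np.eye(n) * 1e-6
        L = np.linalg.cholesky(G)
        y = L @ rng.normal(0, 1, n) + rng.normal(0, 1, n) + 5.0
        frame = pd.DataFrame({"id": grm.ids, "generation": "G1",
                              "host": pd.NA, "y": y})
        spec = ModelSpec(trait="y", fixed_effects=("intercept",))
        d = build_design(SampleTable(frame=frame), spec, grm.ids)
        fit = reml_fit(d, G, g_ids=grm.ids)
        sg2, se2, ll, ll_at = single_variance_gblup_reml(y, d.X, G)
        assert fit.vc.sigma_c2 is None
        # The two likelihood implementations must agree where evaluated...
        assert ll_at(fit.vc.sigma_g2, fit.vc.sigma_e2["G1"]) == pytest.approx(
            fit.vc.loglik, abs=1e-6
        )
        # ...and the fit must attain (or beat) the oracle's maximum.
        assert fit.vc.loglik >= ll - 1e-6
        assert fit.vc.sigma_g2 == pytest.approx(sg2, rel=0.05, abs=1e-3)
        assert fit.vc.sigma_e2["G1"] == pytest.approx(se2, rel=0.05, abs=1e-3)

    def test_score_vanishes_at_interior_convergence(self):
        rng = np.random.default_rng(4)
        n = 60
        codes = rng.integers(0, 3, size=(n, 150)).astype(np.int8)
        grm = build_grm(codes)
        G = grm.matrix + np.eye(n) * 1e-6
        L = np.linalg.cholesky(G)
        y = L @ rng.normal(0, 1, n) + rng.normal(0, 1.2, n)
        frame = pd.DataFrame({"id": grm.ids, "generation": "G1",
                              "host": pd.NA, "y": y})
        d = build_design(SampleTable(frame=frame),
                         ModelSpec(trait="y", fixed_effects=("intercept",)),
                         grm.ids)
        fit = reml_fit(d, G, g_ids=grm.ids)
        if not fit.vc.boundary:
            theta = np.array([fit.vc.sigma_g2, fit.vc.sigma_e2["G1"]])
            eps = 1e-5
            for i in range(2):
                t_hi, t_lo = theta.copy(), theta.copy()
                t_hi[i] += eps
                t_lo[i] -= eps
                grad = (reml_loglik(t_hi, d, G) - reml_loglik(t_lo, d, G)) / (2 * eps)
                assert abs(grad) < 0.05


class TestFitBehaviour:
    def test_null_signal_shrinks_everything(self, small_sim, small_grm, rng):
        frame = small_sim.samples.frame.copy()
        frame["noise"] = rng.normal(0, 1, len(frame))
        samples = SampleTable(frame=frame, trait_columns=["t", "noise"])
        fit = fit_gblup(samples, small_grm,
                        ModelSpec(trait="noise", host_generation="G2"))
        assert fit.vc.sigma_g2 < 0.1
        assert fit.gebv.var() < 0.05

    def test_gebv_variance_bounded_by_genomic_variance(self, small_sim, small_grm):
        fit = fit_gblup(small_sim.samples, small_grm,
                        ModelSpec(trait="t", host_generation="G2"))
        bound = fit.vc.sigma_g2 * small_grm.matrix.diagonal().mean()
        assert fit.gebv.var() <= bound * (1 + 1e-9)

    def test_recovers_components_on_fully_specified_cohort(self):
        # Single generation with recorded hosts: all three components are
        # identifiable.  Simulated at (sg2, sc2, se2) = (1, 1, 2).
        cfg = SimConfig(
            n_snps=500, n_females_sampled=(2000,), hosts_per_generation=400,
            n_burnin_generations=50,
            traits=(TraitArchitecture(
                "t", h2_target=0.25, host_variance_fraction=0.25,
                phenotype_sd=2.0),),
            seed=42,
        )
        sim = simulate(cfg)
        grm = build_grm(sim.genotypes)
        fit = fit_gblup(sim.samples, grm,
                        ModelSpec(trait="t", host_generation="G1"))
        assert fit.vc.converged
        assert fit.vc.sigma_g2 == pytest.approx(1.0, abs=0.35)
        assert fit.vc.sigma_c2 == pytest.approx(1.0, abs=0.35)
        assert fit.vc.sigma_e2["G1"] == pytest.approx(2.0, abs=0.4)
        assert heritability(fit.vc, "G1") == pytest.approx(0.25, abs=0.08)
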