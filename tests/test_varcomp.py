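"""ML variance decomposition: oracles, calibration, screening, liability model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedigrowth.pedigree import household_matrix, kinship_matrix
from pedigrowth.simulate import SimConfig, adult_phenotyped_ids, simulate_trait
from pedigrowth.varcomp import (CovariateDesign, LiabilityThresholdModel,
                                PolygenicModel, VarianceComponentModel,
                                lrt_variance_component, screen_covariates)


def colony_setup(tiny_colony, tiny_colony_kinship):
    cfg, ped = tiny_colony
    order, phi_full = tiny_colony_kinship
    ids = adult_phenotyped_ids(ped, cfg)
    pos = {v: k for k, v in enumerate(order)}
    idx = [pos[i] for i in ids]
    return cfg, ped, ids, (order, phi_full), phi_full[np.ix_(idx, idx)]


class TestGridOracle:
    def test_ml_matches_dense_grid_search(self, fullsib_mating_ped):
        """On n<=8, the optimiser's maximum must match a brute-force grid
        over (sigma2_g, sigma2_e) within 1e-3 log-likelihood."""
        ped = Pedigree = fullsib_mating_ped
        ids, phi = kinship_matrix(ped)
        # extend to 8 individuals by adding a second trio
        rng = np.random.default_rng(0)
        A = 2 * phi
        L = np.linalg.cholesky(A + 1e-10 * np.eye(len(ids)))
        y = L @ rng.normal(size=len(ids)) * 0.8 + rng.normal(size=len(ids)) * 0.6
        model = VarianceComponentModel(y, None, {"additive": A})
        fit = model.fit()
        best = -np.inf
        for sg in np.linspace(0.0, 3.0, 61):
            for se in np.linspace(0.01, 3.0, 60):
                best = max(best, model.loglik({"additive": sg}, se))
        assert fit.loglik >= best - 1e-3

    def test_two_component_grid(self, tiny_colony):
        _, ped = tiny_colony
        ids = ped.ids[:8]
        _, phi = kinship_matrix(ped, ids=ids)
        _, hmat = household_matrix(ped, ids)
        rng = np.random.default_rng(1)
        y = rng.normal(size=8)
        model = VarianceComponentModel(y, None,
                                       {"additive": 2 * phi, "household": hmat})
        fit = model.fit()
        best = -np.inf
        grid = np.linspace(0.0, 2.5, 26)
        for sg in grid:
            for sc in grid:
                for se in np.linspace(0.05, 2.5, 25):
                    ll = model.loglik({"additive": sg, "household": sc}, se)
                    best = max(best, ll)
        assert fit.loglik >= best - 1e-3


class TestPolygenicFit:
    def test_h2_recovery_on_colony(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        rng = np.random.default_rng(11)
        y, _ = simulate_trait(ped, SimConfig(seed=0, h2=0.65), rng, ids=ids,
                              phi=phi_full)
        sex = np.array([1.0 if ped[i].sex == "M" else 0.0 for i in ids])
        X = np.column_stack([np.ones(len(ids)), sex])
        fit = PolygenicModel(y.to_numpy(), X, phi=phi).fit()
        assert abs(fit.h2 - 0.65) < 3 * fit.se_h2
        assert fit.identifiable

    def test_unrelated_individuals_flagged_unidentifiable(self):
        n = 40
        phi = 0.5 * np.eye(n)
        y = np.random.default_rng(2).normal(size=n)
        fit = PolygenicModel(y, None, phi=phi).fit()
        assert not fit.identifiable

    def test_exact_linear_trait_gives_zero_variance(self):
        n = 30
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        y = 2.0 + 3.0 * x
        phi = 0.5 * np.eye(n)
        phi[0, 1] = phi[1, 0] = 0.25
        fit = PolygenicModel(y, np.column_stack([np.ones(n), x]), phi=phi).fit()
        assert fit.total_variance < 1e-6
        assert fit.beta == pytest.approx([2.0, 3.0], abs=1e-4)

    def test_scale_equivariance(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        rng = np.random.default_rng(4)
        y, _ = simulate_trait(ped, SimConfig(seed=0, h2=0.5), rng, ids=ids,
                              phi=phi_full)
        y = y.to_numpy()
        f1 = PolygenicModel(y, None, phi=phi).fit()
        f2 = PolygenicModel(10.0 * y, None, phi=phi).fit()
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-6)
        for name in f1.variances:
            assert f2.variances[name] == pytest.approx(100 * f1.variances[name],
                                                       rel=1e-4, abs=1e-6)

    def test_h2_plus_c2_bounded(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        _, hmat = household_matrix(ped, ids)
        rng = np.random.default_rng(5)
        y, _ = simulate_trait(ped, SimConfig(seed=0, h2=0.4, c2=0.2), rng, ids=ids,
                              phi=phi_full)
        fit = PolygenicModel(y.to_numpy(), None, phi=phi, hmat=hmat).fit()
        assert 0 <= fit.h2 <= 1 and 0 <= fit.c2 <= 1
        assert fit.h2 + fit.c2 <= 1 + 1e-9


class TestLRT:
    def test_equal_likelihoods_give_half(self):
        class F:  # minimal stand-ins
            loglik = -10.0
            variances = {"additive": 0.5}
        class R:
            loglik = -10.0
            variances = {}
        assert lrt_variance_component(F, R) == pytest.approx(0.5)

    def test_boundary_mixture_quantile(self):
        """Lambda = 2.706 corresponds to p = 0.05 under 0.5chi2_0 + 0.5chi2_1."""
        class F:
            loglik = 0.0
            variances = {"additive": 1.0}
        class R:
            loglik = -2.706 / 2
            variances = {}
        p = lrt_variance_component(F, R)
        # independent oracle for the mixture tail
        oracle = 0.5 * (1 - stats.chi2.cdf(2.706, 1))
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_rejected(self):
        class F:
            loglik = 0.0
            variances = {"additive": 1.0}
        class R:
            loglik = -1.0
            variances = {"additive": 0.5}
        with pytest.raises(ValueError):
            lrt_variance_component(F, R, component="additive")

    def test_null_calibration_small(self, tiny_colony, tiny_colony_kinship):
        """Under sigma2_g = 0 the LRT p-values should be conservative-to-
        uniform; check the 5% tail over 120 fast replicates."""
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        A = 2 * phi
        w, U = np.linalg.eigh(A)
        rng = np.random.default_rng(6)
        hits = 0
        reps = 120
        for _ in range(reps):
            y = rng.normal(size=len(ids))
            full = VarianceComponentModel(y, None, {"additive": A}, eig=(w, U)).fit()
            red = VarianceComponentModel(y, None, {}).fit()
            hits += lrt_variance_component(full, red) < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rate < 0.05 + 3 * se


class TestCovariateScreening:
    def build(self, ped, ids, phi_full, rng, beta_sex=1.0):
        y, _ = simulate_trait(ped, SimConfig(seed=0, h2=0.4, beta_sex=beta_sex),
                              rng, ids=ids, phi=phi_full)
        df = pd.DataFrame({
            "sex": [1.0 if ped[i].sex == "M" else 0.0 for i in ids],
            "diet": rng.integers(0, 2, len(ids)).astype(float),
        })
        return y.to_numpy(), df

    def test_planted_effect_kept_null_dropped(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        rng = np.random.default_rng(7)
        y, df = self.build(ped, ids, phi_full, rng, beta_sex=3.0)
        design = CovariateDesign.from_dataframe(df, main=["sex", "diet"])
        out = screen_covariates(y, design, phi)
        assert "sex" in out.names
        assert "diet" not in out.names

    def test_hierarchy_keeps_main_effects(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        rng = np.random.default_rng(8)
        y, df = self.build(ped, ids, phi_full, rng, beta_sex=0.0)
        # plant a pure interaction effect
        y = y + 2.0 * df["sex"].to_numpy() * df["diet"].to_numpy()
        design = CovariateDesign.from_dataframe(df, main=["sex", "diet"],
                                                interactions=["sex*diet"])
        out = screen_covariates(y, design, phi)
        assert "sex*diet" in out.names
        assert {"sex", "diet"} <= set(out.names)

    def test_null_retention_rate_near_alpha(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        rng = np.random.default_rng(9)
        kept = 0
        reps = 40
        for _ in range(reps):
            y = rng.normal(size=len(ids))
            df = pd.DataFrame({"z": rng.normal(size=len(ids))})
            design = CovariateDesign.from_dataframe(df, main=["z"])
            out = screen_covariates(y, design, phi)
            kept += "z" in out.names
        rate = kept / reps
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestLiabilityThreshold:
    def test_h2_recovery(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        rng = np.random.default_rng(10)
        liab, _ = simulate_trait(ped, SimConfig(seed=0, h2=0.5, beta_sex=0.0),
                                 rng, ids=ids, phi=phi_full)
        thr = np.quantile(liab, 0.8)  # prevalence 0.2
        y = (liab.to_numpy() > thr).astype(float)
        fit = LiabilityThresholdModel(y, None, phi=phi).fit()
        assert fit.h2 == pytest.approx(0.5, abs=max(3 * fit.se_h2, 0.25))
        assert fit.p_h2 < 0.2

    def test_permuted_labels_near_zero(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        rng = np.random.default_rng(11)
        y = (rng.random(len(ids)) < 0.2).astype(float)  # independent of pedigree
        fit = LiabilityThresholdModel(y, None, phi=phi).fit()
        assert fit.h2 < 0.35
        assert fit.p_h2 > 0.01

    def test_single_class_rejected(self, tiny_colony, tiny_colony_kinship):
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        with pytest.raises(ValueError):
            LiabilityThresholdModel(np.ones(len(ids)), None, phi=phi)

    def test_unrelated_flagged_boundary(self):
        n = 60
        rng = np.random.default_rng(12)
        y = (rng.random(n) < 0.3).astype(float)
        fit = LiabilityThresholdModel(y, None, phi=0.5 * np.eye(n)).fit()
        assert fit.boundary


class TestRecoverySweep:
    @pytest.mark.parametrize("h2,c2", [(0.2, 0.0), (0.5, 0.1), (0.7, 0.0)])
    def test_bias_small(self, tiny_colony, tiny_colony_kinship, h2, c2):
        """Short in-suite sweep (3 reps each); the full 20-rep colony-scale
        sweep runs in the acceptance suite."""
        cfg, ped, ids, phi_full, phi = colony_setup(tiny_colony, tiny_colony_kinship)
        _, hmat = household_matrix(ped, ids)
        ests = []
        for rep in range(3):
            rng = np.random.default_rng(100 * rep + 13)
            y, _ = simulate_trait(ped, SimConfig(seed=0, h2=h2, c2=c2), rng,
                                  ids=ids, phi=phi_full)
            fit = PolygenicModel(y.to_numpy(), None, phi=phi,
                                 hmat=hmat if c2 > 0 else None).fit()
            ests.append(fit.h2)
        assert abs(np.mean(ests) - h2) < 0.2  # loose at this small n
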