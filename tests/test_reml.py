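"""REML variance components: closed-form and grid-search oracles, boundary
behaviour, ratio arithmetic, and the likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from conftest import anova_reml_oneway, make_tank_data
from gutherit.grm import vanraden_grm
from gutherit.reml import (RemlError, fit_animal_model, heritability,
                           lr_test_genetic, reml, restricted_loglik,
                           tank_fraction, AnimalModelSpec)
from gutherit.simulate import SimTruth, simulate_otu_phenotypes


def _tank_structure(tank):
    k = tank.max() + 1
    Z = np.eye(k)[tank]
    return Z @ Z.T


class TestRemlOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_balanced_tank_design_matches_anova_closed_form(self, seed):
        """Balanced one-way REML equals the ANOVA estimators to 1e-6."""
        y, tank = make_tank_data(n_tanks=10, fish_per_tank=6, seed=seed)
        fit = reml(y, np.ones((len(y), 1)),
                   [("tank", _tank_structure(tank))], ridge=0.0)
        sig_t, sig_e = anova_reml_oneway(y, tank)
        assert fit.components["tank"] == pytest.approx(sig_t, abs=1e-6)
        assert fit.components["residual"] == pytest.approx(sig_e, abs=1e-6)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_agrees_with_direct_likelihood_maximiser(self, seed):
        """50-animal full-sib instances: AI-REML matches an independent
        numerical maximiser of the restricted likelihood to ~1e-3."""
        rng = np.random.default_rng(seed)
        n_fam, fam_size = 10, 5
        n = n_fam * fam_size
        fam = np.repeat(np.arange(n_fam), fam_size)
        # G = 2 * pedigree kinship for full sibs (0.5 within, 0 between)
        G = np.where(fam[:, None] == fam[None, :], 0.5, 0.0)
        np.fill_diagonal(G, 1.0)
        L = np.linalg.cholesky(G)
        y = (L @ rng.normal(0, np.sqrt(0.5), n)
             + rng.normal(0, np.sqrt(0.7), n))
        X = np.ones((n, 1))
        structures = [G, np.eye(n)]

        fit = reml(y, X, [("animal", G)], ridge=0.0)

        def neg_ll(theta):
            if (theta <= 1e-8).any():
                return np.inf
            try:
                return -restricted_loglik(theta, y, X, structures)
            except np.linalg.LinAlgError:
                return np.inf

        best = None
        for start in ([0.3, 0.8], [0.6, 0.4], [0.1, 1.0]):
            res = optimize.minimize(neg_ll, start, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        assert fit.components["animal"] == pytest.approx(best.x[0], abs=2e-3)
        assert fit.components["residual"] == pytest.approx(best.x[1], abs=2e-3)
        assert fit.loglik == pytest.approx(-best.fun, abs=1e-4)

    def test_estimates_are_local_optimum(self):
        """Perturbing the estimates never increases the likelihood."""
        y, tank = make_tank_data(n_tanks=12, fish_per_tank=5, seed=3)
        X = np.ones((len(y), 1))
        T = _tank_structure(tank)
        fit = reml(y, X, [("tank", T)], ridge=0.0)
        theta = np.array([fit.components["tank"], fit.components["residual"]])
        structures = [T, np.eye(len(y))]
        ll_hat = restricted_loglik(np.maximum(theta, 1e-10), y, X, structures)
        rng = np.random.default_rng(0)
        for _ in range(20):
            pert = theta * (1 + rng.uniform(-0.3, 0.3, 2)) + 1e-6
            assert restricted_loglik(pert, y, X, structures) <= ll_hat + 1e-8


class TestBoundary:
    def test_iid_data_genetic_variance_indistinguishable_from_zero(self):
        """With G = I and i.i.d. data the genetic term adds nothing: the
        LR statistic against the no-genetics null is ~0 in >= 90% of
        replicates (the variance split itself is non-identifiable)."""
        n = 200
        indistinct = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            y = rng.normal(size=n)
            X = np.ones((n, 1))
            fit1 = reml(y, X, [("animal", np.eye(n))])
            fit0 = reml(y, X, [])
            lr, p = lr_test_genetic(fit1, fit0)
            if lr < 0.01:
                indistinct += 1
        assert indistinct >= 18

    def test_boundary_flag_reported(self):
        rng = np.random.default_rng(5)
        n = 120
        y = rng.normal(size=n)
        tank = np.arange(n) % 10
        fit = reml(y, np.ones((n, 1)), [("animal", np.eye(n)),
                                        ("tank", _tank_structure(tank))])
        assert set(fit.boundary) == {"animal", "tank", "residual"}
        assert not fit.boundary["residual"]


class TestRatios:
    def test_heritability_table_row(self):
        """Components 0.007/0.009/0.25 give h2 = c2 = 0.03 at 2 dp."""
        assert round(heritability(0.007, 0.009, 0.25), 2) == 0.03
        assert round(tank_fraction(0.007, 0.009, 0.25), 2) == 0.03

    @pytest.mark.parametrize("func,args,expected", [
        (heritability, (0.0, 0.4, 0.6), 0.0),
        (heritability, (1.0, 0.0, 0.0), 1.0),
        (tank_fraction, (0.3, 0.0, 0.7), 0.0),
        (tank_fraction, (0.2, 0.2, 0.6), 0.2),
    ])
    def test_ratio_arithmetic(self, func, args, expected):
        assert func(*args) == pytest.approx(expected)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0, 0.0)


class TestLrTest:
    def _fits(self, ll1, ll0, n=100):
        from gutherit.reml import VarCompFit
        mk = lambda ll: VarCompFit(components={"residual": 1.0}, se={},
                                   h2=None, c2=None, h2_se=None, c2_se=None,
                                   loglik=ll, boundary={}, iterations=1,
                                   converged=True, n=n)
        return mk(ll1), mk(ll0)

    def test_equal_likelihoods_give_p_one(self):
        lr, p = lr_test_genetic(*self._fits(-50.0, -50.0))
        assert lr == 0.0 and p == 1.0

    @pytest.mark.parametrize("chi2,expected_p", [(1.72, 0.19), (0.13, 0.72)])
    def test_chi_square_p_values(self, chi2, expected_p):
        lr, p = lr_test_genetic(*self._fits(-50.0, -50.0 - chi2 / 2))
        assert lr == pytest.approx(chi2)
        assert round(p, 2) == expected_p

    def test_boundary_mixture_halves_p(self):
        _, p1 = lr_test_genetic(*self._fits(-50.0, -51.0))
        _, p2 = lr_test_genetic(*self._fits(-50.0, -51.0),
                                boundary_mixture=True)
        assert p2 == pytest.approx(p1 / 2)

    def test_mismatched_data_rejected(self):
        f1, f0 = self._fits(-50.0, -51.0)
        f0.n = 99
        with pytest.raises(ValueError):
            lr_test_genetic(f1, f0)


class TestAnimalModel:
    def test_h2_recovery_at_04(self, small_genotypes):
        """Planted h2 = 0.4 recovered on the latent log-abundance."""
        geno, fam = small_genotypes
        pheno_map = fam[fam.role == "phenotyped"]
        idx = np.array([geno.ids.index(a) for a in pheno_map["animal"]])
        G = vanraden_grm(geno.subset_individuals(idx))
        ests = []
        for rep in range(5):
            truth = SimTruth(h2=[0.4], c2=[0.05], seed=300 + rep)
            _, _, ln = simulate_otu_phenotypes(geno, fam, truth)
            df = pheno_map[["animal", "tank", "day"]].copy()
            df["y"] = ln.loc[df["animal"]].to_numpy()
            fit = fit_animal_model(AnimalModelSpec("y", df, G))
            ests.append(fit.h2)
        assert abs(np.mean(ests) - 0.4) < 0.2  # n=100, 5 reps: wide band

    def test_profile_likelihood_unimodal(self):
        """Profile in the residual variance is unimodal on a grid."""
        y, tank = make_tank_data(n_tanks=8, fish_per_tank=5, seed=9)
        X = np.ones((len(y), 1))
        T = _tank_structure(tank)
        fit = reml(y, X, [("tank", T)], ridge=0.0)
        st_hat = max(fit.components["tank"], 1e-8)
        structures = [T, np.eye(len(y))]
        grid = np.linspace(0.2, 3.0, 40)
        lls = [restricted_loglik(np.array([st_hat, v]), y, X, structures)
               for v in grid]
        signs = np.sign(np.diff(lls))
        # one sign change at most: increases then decreases
        changes = np.sum(np.abs(np.diff(signs[signs != 0])) > 0)
        assert changes <= 1

    def test_nonpositive_design_errors(self):
        with pytest.raises(RemlError):
            reml(np.zeros(5), np.ones((5, 1)), [])
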