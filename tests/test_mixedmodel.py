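import itertools

import numpy as np
import pandas as pd
import pytest

from domgblup import (
    ModelSpec,
    PhenotypeRecords,
    VarianceComponents,
    build_incidence,
    mixture_lrt,
    reml_fit,
    reml_loglik,
    solve_blup,
    variance_ratios,
)
from domgblup.mixedmodel import _Reduced, _Workspace, _mean_level_mats

from _oracles import blup_dense, reml_loglik_dense

from scipy import stats


def make_records(animal_ids, values):
    return PhenotypeRecords(pd.DataFrame({
        "animal_id": animal_ids, "sire_id": "S1", "trait": "sim", "value": values,
    }))


class TestIncidence:
    def test_repeated_records_map_to_same_column(self):
        rec = make_records(["a1", "a1"], [1.0, 2.0])
        inc = build_incidence(rec, ["a0", "a1", "a2"])
        W = inc.dense()
        assert W.shape == (2, 3)
        np.testing.assert_array_equal(W[:, 1], [1, 1])
        np.testing.assert_array_equal(W.sum(axis=1), [1, 1])

    def test_product_matches_lookup(self, rng):
        animals = [f"a{i}" for i in range(6)]
        ids = rng.choice(animals, size=15)
        rec = make_records(ids, rng.normal(size=15))
        inc = build_incidence(rec, animals)
        v = rng.normal(size=6)
        lookup = np.array([v[animals.index(a)] for a in ids])
        np.testing.assert_allclose(inc.dense() @ v, lookup)

    def test_unknown_animal_rejected(self):
        rec = make_records(["zz"], [1.0])
        with pytest.raises(ValueError, match="zz"):
            build_incidence(rec, ["a0"])


class TestRemlLoglik:
    def test_matches_dense_oracle(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, D = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        y = records.values
        for comp in (
            VarianceComponents(0.3, 0.07, 0.12, 0.5),
            VarianceComponents(0.1, None, 0.2, 0.9),
            VarianceComponents(0.5, 0.2, 0.0, 0.3),
        ):
            expected = reml_loglik_dense(
                y, inc.dense(), G.values, D.values if comp.sigma_d2 is not None else None,
                comp.sigma_a2, comp.sigma_d2 or 0.0, comp.sigma_pe2, comp.sigma_e2,
            )
            got = reml_loglik(y, inc, G, D if comp.sigma_d2 is not None else None, comp)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_invariant_to_constant_shift(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, D = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        comp = VarianceComponents(0.3, 0.07, 0.12, 0.5)
        a = reml_loglik(records.values, inc, G, D, comp)
        b = reml_loglik(records.values + 123.4, inc, G, D, comp)
        assert a == pytest.approx(b, abs=1e-6)

    def test_all_zero_components_rejected(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, _ = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        with pytest.raises(ValueError, match="zero"):
            reml_loglik(records.values, inc, G, None,
                        VarianceComponents(0.0, None, 0.0, 0.0))


class TestRemlFit:
    def test_constant_phenotype_all_boundary(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, _ = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        fit = reml_fit(np.full(len(records), 7.0), inc, G, None,
                       ModelSpec(include_dominance=False))
        assert fit.sigma_a2 == fit.sigma_pe2 == fit.sigma_e2 == 0.0
        assert fit.mu == pytest.approx(7.0)

    def test_matches_grid_search_oracle(self):
        """REML estimates on a 30-animal single-record instance agree with a
        dense grid search over an independently coded restricted likelihood."""
        from domgblup import SimConfig, simulate_dataset, estimate_allele_frequencies
        from domgblup import build_additive_grm

        cfg = SimConfig(n_sires=6, daughters_per_sire=5, n_snps=200,
                        records_per_animal=1, true_sigma_d2=0.0,
                        true_sigma_pe2=0.0, seed=17)
        genotypes, _, records = simulate_dataset(cfg)
        G = build_additive_grm(genotypes)
        inc = build_incidence(records, list(G.animal_ids))
        y = records.values
        # single records: pe and e are confounded, so fix pe at 0 in the
        # grid and compare against sigma_pe2 + sigma_e2 from the fit
        grid = np.linspace(0.01, 1.5, 40)
        best, best_ll = None, -np.inf
        for sa, se in itertools.product(grid, grid):
            ll = reml_loglik_dense(y, inc.dense(), G.values, None, sa, 0.0, 0.0, se)
            if ll > best_ll:
                best, best_ll = (sa, se), ll
        fit = reml_fit(y, inc, G, None, ModelSpec(include_dominance=False))
        step = grid[1] - grid[0]
        assert fit.loglik >= best_ll - 1e-6
        assert abs(fit.sigma_a2 - best[0]) <= step
        assert abs((fit.sigma_pe2 + fit.sigma_e2) - best[1]) <= step

    def test_loglik_maximised_at_fit(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, D = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        y = records.values
        fit = reml_fit(y, inc, G, D, ModelSpec(include_dominance=True))
        ll_hat = reml_loglik(y, inc, G, D, fit)
        assert ll_hat == pytest.approx(fit.loglik, abs=1e-8)
        rng = np.random.default_rng(0)
        for _ in range(10):
            pert = VarianceComponents(
                max(1e-6, fit.sigma_a2 * rng.uniform(0.5, 1.5)),
                max(1e-6, (fit.sigma_d2 or 0.0) + rng.uniform(0.0, 0.2)),
                max(1e-6, fit.sigma_pe2 + rng.uniform(0.0, 0.2)),
                max(1e-6, fit.sigma_e2 * rng.uniform(0.5, 1.5)),
            )
            assert reml_loglik(y, inc, G, D, pert) <= ll_hat + 1e-6

    def test_em_warmup_monotone_loglik(self, small_dataset, small_grms):
        """EM iterations never decrease the restricted likelihood."""
        _, _, _, records = small_dataset
        _, G, D = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        y = records.values
        red = _Reduced(y, inc)
        mats = _mean_level_mats(red, G, D, True)
        theta = np.full(4, np.var(y) / 4)
        ws = _Workspace(red, mats, theta)
        for _ in range(8):
            ws_new = _Workspace(red, mats, ws.em_update())
            assert ws_new.loglik >= ws.loglik - 1e-10 * (1 + abs(ws.loglik))
            ws = ws_new

    def test_zero_dominance_truth_estimated_near_zero(self, rng):
        from domgblup import SimConfig, simulate_dataset, build_additive_grm
        from domgblup import build_dominance_grm, estimate_allele_frequencies

        cfg = SimConfig(n_sires=10, daughters_per_sire=20, n_snps=400,
                        records_per_animal=2, true_sigma_d2=0.0, seed=29)
        genotypes, _, records = simulate_dataset(cfg)
        freqs = estimate_allele_frequencies(genotypes)
        G = build_additive_grm(genotypes, freqs)
        D = build_dominance_grm(genotypes, freqs)
        inc = build_incidence(records, list(G.animal_ids))
        fit = reml_fit(records.values, inc, G, D, ModelSpec(include_dominance=True))
        se_d = fit.se.get("d", 0.1)
        assert fit.sigma_d2 <= max(2 * se_d, 0.05)


class TestSolveBlup:
    def test_constant_phenotype_gives_zero_solutions(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, D = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        comp = VarianceComponents(0.3, 0.05, 0.1, 0.55)
        sol = solve_blup(comp, np.full(len(records), 5.0), inc, G, D)
        assert np.abs(sol.table.to_numpy()).max() < 1e-10

    def test_matches_gls_oracle(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, D = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        y = records.values
        comp = VarianceComponents(0.3, 0.07, 0.12, 0.5)
        sol = solve_blup(comp, y, inc, G, D)
        u, d, pe = blup_dense(y, inc.dense(), G.values, D.values, 0.3, 0.07, 0.12, 0.5)
        np.testing.assert_allclose(sol.bv.to_numpy(), u, atol=1e-8)
        np.testing.assert_allclose(sol.dv.to_numpy(), d, atol=1e-8)
        np.testing.assert_allclose(sol.pe.to_numpy(), pe, atol=1e-8)
        np.testing.assert_allclose(sol.tgv.to_numpy(), u + d, atol=1e-12)

    def test_unphenotyped_animals_predicted_through_g(self, small_dataset, small_grms):
        """Animals in G without records get predictions via genomic
        covariances; dropping their records from y must reproduce the dense
        oracle on the full W with zero columns."""
        _, _, _, records = small_dataset
        _, G, D = small_grms
        keep = ~records.data["animal_id"].isin(set(G.animal_ids[:5]))
        sub = PhenotypeRecords(records.data[keep])
        inc = build_incidence(sub, list(G.animal_ids))
        y = sub.values
        comp = VarianceComponents(0.3, 0.07, 0.12, 0.5)
        sol = solve_blup(comp, y, inc, G, D)
        u, d, _ = blup_dense(y, inc.dense(), G.values, D.values, 0.3, 0.07, 0.12, 0.5)
        np.testing.assert_allclose(sol.bv.to_numpy(), u, atol=1e-8)
        assert np.abs(sol.bv.to_numpy()[:5]).max() > 0  # genuinely predicted
        assert np.all(sol.pe.to_numpy()[:5] == 0)

    def test_dv_recovery_direction(self, medium_dataset):
        """Predicted dominance deviations correlate positively with truth on
        a dominance-containing simulation."""
        from domgblup import build_additive_grm, build_dominance_grm
        from domgblup import estimate_allele_frequencies

        cfg, genotypes, truth, records = medium_dataset
        freqs = estimate_allele_frequencies(genotypes)
        G = build_additive_grm(genotypes, freqs)
        D = build_dominance_grm(genotypes, freqs)
        inc = build_incidence(records, list(G.animal_ids))
        fit = reml_fit(records.values, inc, G, D, ModelSpec(include_dominance=True))
        sol = solve_blup(fit, records.values, inc, G, D)
        r = np.corrcoef(sol.dv.loc[truth.animals.index].to_numpy(),
                        truth.dv.to_numpy())[0, 1]
        assert r > 0

    def test_zero_residual_with_repeats_rejected(self, small_dataset, small_grms):
        _, _, _, records = small_dataset
        _, G, D = small_grms
        inc = build_incidence(records, list(G.animal_ids))
        comp = VarianceComponents(0.3, 0.05, 0.1, 0.0)
        with pytest.raises(ValueError, match="residual"):
            solve_blup(comp, records.values, inc, G, D)


class TestMixtureLRT:
    def test_equal_logl_gives_p_one(self):
        res = mixture_lrt(-100.0, -100.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_negative_difference_clipped(self):
        res = mixture_lrt(-100.0, -101.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_statistic_ten(self):
        res = mixture_lrt(-50.0, -45.0)
        assert res.statistic == 10.0
        assert res.p_value == pytest.approx(0.5 * stats.chi2.sf(10.0, 1), rel=1e-12)
        assert res.p_value == pytest.approx(7.8e-4, rel=0.01)


class TestVarianceRatios:
    def test_zero_dominance(self):
        r = variance_ratios(VarianceComponents(0.3, 0.0, 0.1, 0.6))
        assert r.h_d2 == 0.0 and r.dominance_share == 0.0
        assert r.repeatability == pytest.approx(0.4)

    def test_model_a_treated_as_no_dominance(self):
        r = variance_ratios(VarianceComponents(0.2, None, 0.2, 0.6))
        assert r.h_a2 == pytest.approx(0.2)
        assert r.dominance_share == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            variance_ratios(VarianceComponents(0.0, 0.0, 0.0, 0.0))
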