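"""Order-statistic repeatability test, empirical null, FDR and attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from statsmodels.stats.multitest import multipletests

from repadapt.repeatability import (
    EmpiricalNull,
    attribute_species,
    bh_adjust,
    bh_reject_count,
    collapse_paralogues,
    dunn_sidak,
    estimate_n_eff,
    leave_one_out,
    n_eff_from_scores,
    permutation_enrichment,
    picmin_raw,
    picmin_raw_matrix,
    picmin_scan,
)
from repadapt.synthetic import simulate_orthogroup_pvalues


class TestCollapse:
    def test_dunn_sidak_closed_forms(self):
        assert dunn_sidak(0.05, 1) == pytest.approx(0.05)
        assert dunn_sidak(0.2, 3) == pytest.approx(1 - 0.8**3)

    def test_collapse_takes_minimum_and_corrects(self):
        ogs = {"OG1": {"spA": ["g1", "g2"], "spB": ["g3"]}}
        scores = pd.DataFrame(
            {
                "species": ["spA", "spA", "spB"],
                "gene_id": ["g1", "g2", "g3"],
                "variable": "bio1",
                "ep_wza": [0.5, 0.9, 0.05],
            }
        )
        out = collapse_paralogues(scores, ogs).set_index("species")
        assert out.loc["spA", "ep_collapsed"] == pytest.approx(1 - 0.5**2)  # = 0.75
        assert out.loc["spA", "best_gene"] == "g1"
        assert out.loc["spB", "ep_collapsed"] == pytest.approx(0.05)

    def test_species_without_scores_absent(self):
        ogs = {"OG1": {"spA": ["g1"], "spB": ["g2"]}}
        scores = pd.DataFrame(
            {"species": ["spA"], "gene_id": ["g1"], "variable": ["bio1"], "ep_wza": [0.3]}
        )
        out = collapse_paralogues(scores, ogs)
        assert list(out["species"]) == ["spA"]


class TestPicMinRaw:
    def test_all_ones_gives_p_one(self):
        raw, _ = picmin_raw(np.ones(5), 2.0)
        assert raw == pytest.approx(1.0)

    def test_closed_form_example(self):
        # order-statistic CDFs: q1 = 1-(1-0.01)^2 = 0.0199, q2 = 0.9^2 = 0.81
        raw, a_star = picmin_raw([0.001, 0.01, 0.9], 2.0)
        assert raw == pytest.approx(1 - 0.9801**2, abs=1e-6)
        assert a_star == 1

    def test_null_bias_upward(self, rng):
        raw, _ = picmin_raw_matrix(rng.random((20_000, 22)), 7.0)
        assert raw.mean() > 0.5  # the documented conservative bias

    def test_monotonicity_in_single_ep(self, rng):
        eps = rng.random(21)
        base, _ = picmin_raw(eps, 7.0)
        for i in range(21):
            lowered = eps.copy()
            lowered[i] *= 0.5
            low, _ = picmin_raw(lowered, 7.0)
            assert low <= base + 1e-12

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            picmin_raw([0.0, 0.5, 0.5], 2.0)
        with pytest.raises(ValueError):
            picmin_raw([0.5, 0.5], 2.0)


class TestNEff:
    def test_limit_cases(self, rng):
        independent = rng.random((5_000, 10))
        assert n_eff_from_scores(independent) == pytest.approx(10, rel=0.05)
        col = rng.random((5_000, 1))
        duplicated = np.repeat(col, 6, axis=1)
        assert n_eff_from_scores(duplicated) == pytest.approx(1.0, abs=0.05)

    def test_order_statistics_are_positively_correlated(self):
        n_eff = estimate_n_eff(22, 20_000, seed=3)
        assert 1 < n_eff < 21

    def test_too_few_sims_rejected(self):
        with pytest.raises(ValueError):
            estimate_n_eff(20, 500)


class TestEmpiricalNullStore:
    def test_determinism_and_monotone_quantiles(self, null_store):
        assert list(null_store.configurations()) == list(range(20, 26))
        for n in null_store.configurations():
            q = null_store.sorted_null[n]
            assert (np.diff(q) >= 0).all()
        # ECDF at 0.5 below 0.5: raw p mass pushed toward 1 under the null
        frac_below_half = np.searchsorted(null_store.sorted_null[22], 0.5) / null_store.sorted_null[22].size
        assert frac_below_half < 0.5

    def test_roundtrip(self, null_store, tmp_path):
        path = tmp_path / "null.npz"
        null_store.save(path)
        loaded = EmpiricalNull.load(path)
        assert loaded.n_eff == null_store.n_eff
        np.testing.assert_array_equal(loaded.sorted_null[20], null_store.sorted_null[20])

    def test_calibration_boundary(self, null_store):
        n = null_store.sorted_null[20].size
        assert null_store.calibrate(np.array([0.0]), 20)[0] == pytest.approx(1 / (1 + n))

    def test_picmin_matches_monte_carlo_rank_null(self, null_store, rng):
        """Calibrated p equals the rank of the raw statistic in an
        independently simulated null, to within binomial error (spot checks)."""
        n = 22
        n_eff = null_store.n_eff[n]
        fresh, _ = picmin_raw_matrix(rng.random((200_000, n)), n_eff)
        fresh.sort()
        spots = rng.random((20, n))
        spots[:5, :8] *= 0.05  # include some signal-like rows
        raw, _ = picmin_raw_matrix(spots, n_eff)
        cal = null_store.calibrate(raw, n)
        mc = (1 + np.searchsorted(fresh, raw, side="right")) / (1 + fresh.size)
        for c, m in zip(cal, mc):
            se = np.sqrt(m * (1 - m) * (1 / 200_000 + 1 / null_store.sorted_null[n].size))
            assert abs(c - m) < 5 * se + 1e-4


class TestBH:
    def test_stepup_by_hand(self):
        assert bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])) == pytest.approx([0.04] * 4)

    def test_matches_statsmodels(self, rng):
        p = rng.random(500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(ref, rel=1e-10)
        assert bh_reject_count(p, 0.3) == int(multipletests(p, alpha=0.3, method="fdr_bh")[0].sum())


class TestScanAndAttribution:
    def test_calibrated_null_uniform_within_scan(self, null_store, rng):
        table, _ = simulate_orthogroup_pvalues(3_000, (20, 25), seed=rng)
        table = table.rename(columns={"ep": "ep_collapsed"}).assign(variable="bio1")
        res = picmin_scan(table, null_store)
        assert len(res) == 3_000
        assert kstest(res["calibrated_p"], "uniform").statistic < 0.03

    def test_attribution_matches_example(self):
        species = np.array(["a", "b", "c"])
        raw, a_star = picmin_raw([0.001, 0.01, 0.9], 2.0)
        assert attribute_species([0.001, 0.01, 0.9], species, a_star) == ["a", "b"]
        # a_star = n-1 -> everyone contributes
        assert attribute_species([0.1, 0.2, 0.3], species, 2) == ["a", "b", "c"]

    def test_tie_across_boundary_enlarges_set(self):
        species = np.array(["a", "b", "c", "d"])
        out = attribute_species([0.01, 0.2, 0.2, 0.9], species, 1)
        assert out == ["a", "b", "c"]  # tie at the boundary pulls both in


class TestPermutationAndLoo:
    def test_permutation_p_extremes(self, null_store, rng):
        counts = rng.integers(20, 26, size=300)
        enr = permutation_enrichment(0, counts, 2, null_store, n_perm=100, seed=1)
        assert enr["p"] == pytest.approx(1.0)
        huge = permutation_enrichment(10_000, counts, 2, null_store, n_perm=100, seed=1)
        assert huge["p"] == pytest.approx(1 / 101)

    def test_low_n_perm_warns(self, null_store):
        with pytest.warns(UserWarning, match="unstable"):
            permutation_enrichment(1, np.full(50, 20), 1, null_store, n_perm=50, seed=0)

    def test_leave_one_out_counts_and_sensitivity(self, null_store, rng):
        """Dropping a species that carries the implanted signal must reduce
        the RAO count; dropping an uninvolved species must not."""
        species = [f"sp{i:02d}" for i in range(1, 26)]
        rows = []
        for og_idx in range(300):
            present = species[:21]
            eps = rng.random(21)
            if og_idx < 15:  # implants driven by exactly sp01, sp02, sp03
                eps[:3] = 0.005
            for sp, ep in zip(present, eps):
                rows.append({"orthogroup": f"OG{og_idx:04d}", "species": sp,
                             "variable": "bio1", "ep_collapsed": ep})
        collapsed = pd.DataFrame(rows)
        loo = leave_one_out(collapsed, null_store, min_species=20)
        assert len(loo) == 21  # one row per dropped species
        col = loo.set_index("dropped_species")["raos_q0.5"]
        full = picmin_scan(collapsed, null_store)["rao"].sum()
        assert col["sp01"] < full  # removing a signal carrier loses RAOs
        assert col["sp21"] >= col["sp01"]
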