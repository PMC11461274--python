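"""Interaction-permutation and hypergeometric GO enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from repadapt.enrichment import (
    build_orthogroup_annotation,
    go_enrichment,
    interaction_enrichment,
)


def _single_copy_ogs(n, prefix="OG"):
    return {f"{prefix}{i}": {"ath": [f"g{i}"]} for i in range(n)}


class TestInteractionEnrichment:
    def test_clique_detected(self):
        ogs = _single_copy_ogs(30)
        rao = [f"OG{i}" for i in range(5)]
        background = [f"OG{i}" for i in range(5, 30)]
        clique = pd.DataFrame(
            [(f"g{i}", f"g{j}", 0.9) for i, j in itertools.combinations(range(5), 2)],
            columns=["gene_a", "gene_b", "score"],
        )
        out = interaction_enrichment(rao, background, clique, ogs, "ath",
                                     n_gene_draws=10, n_perm=200, seed=0)
        assert out["observed_mean"] == pytest.approx(10.0)  # C(5,2) edges
        assert out["p"] == pytest.approx(1 / 201)

    def test_edgeless_network(self):
        ogs = _single_copy_ogs(10)
        empty = pd.DataFrame(columns=["gene_a", "gene_b", "score"])
        out = interaction_enrichment(
            [f"OG{i}" for i in range(3)], [f"OG{i}" for i in range(3, 10)],
            empty, ogs, "ath", n_gene_draws=5, n_perm=50, seed=0,
        )
        assert out["observed_mean"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_within_orthogroup_edges_never_counted(self):
        ogs = {"OG0": {"ath": ["a1", "a2"]}, "OG1": {"ath": ["b1"]}, "OG2": {"ath": ["c1"]}}
        net = pd.DataFrame({"gene_a": ["a1"], "gene_b": ["a2"], "score": [0.99]})
        out = interaction_enrichment(["OG0", "OG1"], ["OG1", "OG2"], net, ogs, "ath",
                                     n_gene_draws=50, n_perm=50, seed=0)
        assert out["observed_mean"] == 0.0

    def test_score_threshold_applied(self):
        ogs = _single_copy_ogs(6)
        net = pd.DataFrame({"gene_a": ["g0"], "gene_b": ["g1"], "score": [0.4]})  # not > 0.4
        out = interaction_enrichment(["OG0", "OG1"], ["OG2", "OG3", "OG4", "OG5"],
                                     net, ogs, "ath", n_gene_draws=5, n_perm=20, seed=0)
        assert out["observed_mean"] == 0.0

    def test_background_smaller_than_set_rejected(self):
        ogs = _single_copy_ogs(4)
        net = pd.DataFrame(columns=["gene_a", "gene_b", "score"])
        with pytest.raises(ValueError, match="background"):
            interaction_enrichment(["OG0", "OG1", "OG2"], ["OG3"], net, ogs, "ath")

    def test_type_one_error_uniformity(self, rng):
        """A random RAO set from the background gives a uniform-ish p."""
        ogs = _single_copy_ogs(40)
        edges = [
            (f"g{i}", f"g{j}", 0.8)
            for i, j in itertools.combinations(range(40), 2)
            if rng.random() < 0.08
        ]
        net = pd.DataFrame(edges, columns=["gene_a", "gene_b", "score"])
        all_ogs = list(ogs)
        ps = []
        for rep in range(60):
            pick = rng.choice(40, size=8, replace=False)
            rao = [all_ogs[i] for i in pick]
            bg = [o for o in all_ogs if o not in rao]
            out = interaction_enrichment(rao, bg, net, ogs, "ath",
                                         n_gene_draws=1, n_perm=60, seed=rng)
            ps.append(out["p"])
        # no systematic inflation: mean p near 0.5, few tiny p-values
        assert 0.3 < np.mean(ps) < 0.7
        assert np.mean(np.array(ps) < 0.05) < 0.2


def _exhaustive_go_p(carrier_flags, n_draw, k_obs):
    """P(>= k_obs carriers) over all equally likely draws of size n_draw."""
    idx = range(len(carrier_flags))
    hits = total = 0
    for combo in itertools.combinations(idx, n_draw):
        total += 1
        if sum(carrier_flags[i] for i in combo) >= k_obs:
            hits += 1
    return hits / total


class TestGoEnrichment:
    def test_reference_values(self):
        annotation = {f"og{i}": ({"T"} if i < 5 else set()) for i in range(10)}
        out = go_enrichment(["og0", "og1", "og2", "og3"], annotation).set_index("term_id")
        assert out.loc["T", "p"] == pytest.approx(5 / 210)

        annotation = {"a": {"T"}, "b": {"T"}, "c": set(), "d": set()}
        out = go_enrichment(["a", "c"], annotation).set_index("term_id")
        assert out.loc["T", "p"] == pytest.approx(1 - 1 / 6)

    def test_full_background_draw_gives_p_one(self):
        annotation = {f"og{i}": {"T1", "T2"} if i % 2 else {"T1"} for i in range(6)}
        out = go_enrichment(list(annotation), annotation)
        assert (out["p"] == 1.0).all()

    def test_matches_exhaustive_enumeration(self, rng):
        """Backgrounds of <= 12 orthogroups: p equals draw enumeration."""
        for _ in range(10):
            m = int(rng.integers(6, 13))
            flags = rng.random(m) < 0.4
            if not flags.any():
                continue
            annotation = {f"og{i}": ({"T"} if flags[i] else set()) for i in range(m)}
            n_draw = int(rng.integers(2, m - 1))
            rao = [f"og{i}" for i in rng.choice(m, size=n_draw, replace=False)]
            out = go_enrichment(rao, annotation).set_index("term_id")
            k_obs = sum(flags[int(o[2:])] for o in rao)
            expected = _exhaustive_go_p(list(flags), n_draw, k_obs)
            assert out.loc["T", "p"] == pytest.approx(expected, abs=1e-12)

    def test_missing_rao_orthogroup_raises(self):
        with pytest.raises(ValueError, match="absent"):
            go_enrichment(["missing"], {"og0": {"T"}})

    def test_annotation_collapse_deduplicates(self):
        ogs = {"OG1": {"ath": ["p1", "p2"]}}
        go = pd.DataFrame(
            {"gene_id": ["p1", "p1", "p1", "p2", "p2", "p2"],
             "term_id": ["GO1", "GO2", "GO3", "GO2", "GO3", "GO4"]}
        )
        ann = build_orthogroup_annotation(ogs, go, "ath")
        assert ann["OG1"] == {"GO1", "GO2", "GO3", "GO4"}


def test_implanted_go_term_recovered(null_store):
    """End-to-end: the term implanted in flagged orthogroups is the top
    enrichment hit at FDR < 0.1."""
    from repadapt.synthetic import simulate_gene_properties

    ogs = {f"OG{i}": {"ath": [f"g{i}"]} for i in range(400)}
    flagged = {f"OG{i}" for i in range(40)}
    props = simulate_gene_properties(ogs, n_tissues=6, flagged=flagged,
                                     repeatability_link=1.0, seed=8)
    ann = build_orthogroup_annotation(ogs, props["go"], "ath")
    out = go_enrichment(sorted(flagged), ann)
    assert out.iloc[0]["term_id"] == "GO:9999999"
    assert out.iloc[0]["q"] < 0.1
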