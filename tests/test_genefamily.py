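"""Tissue-specificity tau, network centralities, orthogroup Z, deciles,
duplication metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from repadapt.genefamily import (
    coexpression_centrality,
    decile_means,
    decile_stouffer,
    duplication_metrics,
    gene_tau_table,
    mean_tissue_profiles,
    orthogroup_level_z,
    tissue_tau,
)


class TestTau:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ([5, 5, 5, 5], 0.0),
            ([0, 0, 7, 0], 1.0),
            ([10, 5], 0.5),
        ],
    )
    def test_reference_values(self, profile, expected):
        assert tissue_tau(profile) == pytest.approx(expected)

    def test_scale_invariance_and_monotone_concentration(self, rng):
        x = rng.uniform(0, 10, 8)
        assert tissue_tau(x) == pytest.approx(tissue_tau(13.7 * x))
        # moving expression from a minor tissue onto the max tissue
        y = x.copy()
        j = int(np.argmax(y))
        k = int(np.argmin(y))
        y[j] += y[k]
        y[k] = 0.0
        assert tissue_tau(y) >= tissue_tau(x) - 1e-12

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tissue_tau([0.0, 0.0])

    def test_stage_subtissue_averaging(self):
        expr = pd.DataFrame(
            {
                "gene_id": ["g1"] * 4,
                "tissue": ["leaf", "leaf", "root", "root"],
                "stage": ["a", "b", "a", "b"],
                "subtissue": ["x", "x", "x", "x"],
                "tpm": [10.0, 20.0, 5.0, 5.0],
            }
        )
        profiles = mean_tissue_profiles(expr)
        assert profiles.loc["g1", "leaf"] == 15.0
        taus = gene_tau_table(expr)
        assert taus["tau"].iloc[0] == pytest.approx((1 - 5 / 15) / 1)


def _brute_force_centralities(edges):
    """Shortest-path centralities by exhaustive simple-path enumeration."""
    nodes = sorted({n for e in edges for n in e})
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def all_paths(s, t):
        out = []

        def walk(node, seen):
            if node == t:
                out.append(tuple(seen))
                return
            for nxt in adj[node]:
                if nxt not in seen:
                    walk(nxt, seen + [nxt])

        walk(s, [s])
        return out

    closeness = {}
    betweenness = {n: 0.0 for n in nodes}
    sp_cache = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if paths:
            d = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == d]
            sp_cache[(s, t)] = (d, shortest)
    for n in nodes:
        total = sum(d for (s, t), (d, _) in sp_cache.items() if n in (s, t))
        closeness[n] = 1.0 / total if total > 0 else 0.0
        for (s, t), (_, shortest) in sp_cache.items():
            if n in (s, t):
                continue
            frac = sum(1 for p in shortest if n in p) / len(shortest)
            betweenness[n] += frac
    return closeness, betweenness


class TestCentrality:
    def _edges_df(self, pairs, z=3.0):
        return pd.DataFrame([(a, b, z) for a, b in pairs], columns=["gene_a", "gene_b", "z"])

    def test_path_graph_reference(self):
        out = coexpression_centrality(
            self._edges_df([("A", "B"), ("B", "C"), ("C", "D")])
        ).set_index("gene_id")
        assert out.loc["B", "degree"] == 2
        assert out.loc["B", "strength"] == pytest.approx(6.0)
        assert out.loc["B", "betweenness"] == pytest.approx(2.0)
        assert out.loc["B", "closeness"] == pytest.approx(0.25)

    def test_edge_filter(self):
        edges = pd.DataFrame(
            {"gene_a": ["A", "A", "A"], "gene_b": ["B", "C", "D"], "z": [1.0, -6.0, 2.33]}
        )
        out = coexpression_centrality(edges).set_index("gene_id")
        # z = 1.0 discarded, z = -6 kept (|z| adds to strength), z = 2.33 kept
        assert out.loc["A", "degree"] == 2
        assert out.loc["A", "strength"] == pytest.approx(6.0 + 2.33)
        assert out.loc["B", "degree"] == 0  # isolated after filtering
        assert out.loc["B", "closeness"] == 0.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        """Closeness/betweenness equal exhaustive path enumeration (<= 12 nodes)."""
        for _ in range(8):
            n = int(rng.integers(5, 13))
            pairs = [
                (f"n{i}", f"n{j}")
                for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.35
            ]
            if not pairs:
                continue
            out = coexpression_centrality(self._edges_df(pairs)).set_index("gene_id")
            closeness, betweenness = _brute_force_centralities(pairs)
            for node in closeness:
                assert out.loc[node, "closeness"] == pytest.approx(closeness[node])
                assert out.loc[node, "betweenness"] == pytest.approx(betweenness[node])


class TestOrthogroupZ:
    def _values(self, n, rng):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)], "v": rng.normal(size=n)})

    def test_mean_zero_sd_one_regardless_of_input(self, rng):
        vals = self._values(300, rng)
        vals["v"] = np.exp(vals["v"] * 3)  # heavily skewed input
        ogs = {f"OG{i}": {"ath": [f"g{3 * i}", f"g{3 * i + 1}", f"g{3 * i + 2}"]} for i in range(100)}
        out = orthogroup_level_z(vals, ogs, "ath", "v", high_is_pleiotropic=True)
        assert abs(out["z"].mean()) < 1e-6
        assert abs(out["z"].std(ddof=0) - 1) < 1e-3

    def test_orientation(self, rng):
        vals = self._values(50, rng)
        ogs = {f"OG{i}": {"ath": [f"g{i}"]} for i in range(50)}
        hi = orthogroup_level_z(vals, ogs, "ath", "v", high_is_pleiotropic=True)
        top_gene = vals.loc[vals["v"].idxmax(), "gene_id"]
        top_og = f"OG{top_gene[1:]}"
        assert hi.set_index("orthogroup").loc[top_og, "z"] == hi["z"].max()
        lo = orthogroup_level_z(vals, ogs, "ath", "v", high_is_pleiotropic=False)
        assert lo.set_index("orthogroup").loc[top_og, "z"] == lo["z"].min()

    def test_median_single_copy_maps_to_zero(self, rng):
        vals = pd.DataFrame({"gene_id": [f"g{i}" for i in range(51)], "v": np.arange(51.0)})
        ogs = {f"OG{i}": {"ath": [f"g{i}"]} for i in range(51)}
        out = orthogroup_level_z(vals, ogs, "ath", "v", high_is_pleiotropic=True).set_index("orthogroup")
        assert out.loc["OG25", "z"] == pytest.approx(0.0, abs=1e-10)

    def test_unmeasured_orthogroups_absent(self, rng):
        vals = self._values(4, rng)
        ogs = {"OGa": {"ath": ["g0", "g1"]}, "OGb": {"ath": ["missing"]},
               "OGc": {"ath": ["g2", "g3"]}}
        out = orthogroup_level_z(vals, ogs, "ath", "v", high_is_pleiotropic=True)
        assert set(out["orthogroup"]) == {"OGa", "OGc"}


class TestDecileStouffer:
    def test_reference_values(self):
        z = pd.DataFrame({"orthogroup": list("abcd"), "z": [1.0, 1.0, 1.0, 1.0]})
        rep = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        out = decile_stouffer(z, rep, n_groups=1)
        assert out["stouffer_z"].iloc[0] == pytest.approx(2.0)
        assert out["p"].iloc[0] == pytest.approx(0.0455, abs=1e-3)

    def test_equal_split_and_determinism_under_ties(self, rng):
        n = 100
        z = pd.DataFrame({"orthogroup": [f"og{i:03d}" for i in range(n)], "z": rng.normal(size=n)})
        rep = pd.Series(0.5, index=z["orthogroup"])  # all tied -> id order decides
        out = decile_stouffer(z, rep)
        assert (out["n"] == 10).all()
        out2 = decile_stouffer(z.sample(frac=1, random_state=1), rep)
        pd.testing.assert_frame_equal(out, out2)


class TestDuplication:
    TABLE = pd.DataFrame(
        {
            "orthogroup_id": ["OG1", "OG1", "OG1", "OG2"],
            "support": [0.6, 0.8, 0.9, 0.95],
            "species_under_node": ["spA,spB", "spA,spB", "spA", "spX"],
            "tips_single_genome": [0, 0, 1, 0],
        }
    )

    def test_filters_and_counts(self):
        out = duplication_metrics(
            self.TABLE, gea_species={"spA", "spB"}, known_species={"spA", "spB", "spX"}
        ).set_index("orthogroup_id")
        # OG1: support 0.6 excluded; 0.8 and 0.9 qualify, one species-specific
        assert out.loc["OG1", "n_duplications"] == 2
        assert out.loc["OG1", "n_species_specific"] == 1
        # OG2: no overlap with GEA species -> excluded entirely
        assert "OG2" not in out.index

    def test_unknown_species_raises(self):
        with pytest.raises(ValueError, match="spX"):
            duplication_metrics(self.TABLE, gea_species={"spA"}, known_species={"spA", "spB"})

    def test_decile_means_orders_most_repeatable_first(self, rng):
        rep = pd.Series(rng.random(50), index=[f"og{i}" for i in range(50)])
        counts = pd.DataFrame(
            {"orthogroup_id": rep.index, "n_duplications": (rep < 0.2).astype(int) * 5}
        )
        out = decile_means(counts, rep, ["n_duplications"], n_groups=5)
        assert out["mean_n_duplications"].iloc[0] > out["mean_n_duplications"].iloc[-1]
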