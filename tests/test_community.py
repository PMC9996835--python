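from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from eukbench.community import (
    bp_fractions,
    cluster_samples,
    cooccurrence_edges,
    detect_modules,
    group_labels_from_final,
    presence_calls,
)

from conftest import final_from_labels


def make_cov(rows):
    """rows: (sample, contig, depth, breadth)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "contig_id", "mean_depth", "breadth"]
    )


class TestPresence:
    def test_threshold_inclusive_at_25_percent(self):
        cov = make_cov([("s1", "c1", 1.0, 0.25), ("s1", "c2", 1.0, 0.2499)])
        pres = presence_calls(cov)
        assert bool(pres.loc["c1", "s1"]) is True
        assert bool(pres.loc["c2", "s1"]) is False

    def test_zero_breadth_absent(self):
        cov = make_cov([("s1", "c1", 0.0, 0.0)])
        assert not presence_calls(cov).loc["c1", "s1"]

    def test_random_table_matches_elementwise_threshold(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"s{j}", f"c{i}", 1.0, rng.random())
            for i in range(20)
            for j in range(5)
        ]
        cov = make_cov(rows)
        pres = presence_calls(cov, breadth_min=0.4)
        for s, c, _, b in rows:
            assert bool(pres.loc[c, s]) == (b >= 0.4)


class TestBpFractions:
    def lengths(self, ids, length=1000):
        return pd.DataFrame({"contig_id": ids, "length_bp": length})

    def test_single_present_eukaryote_contig(self):
        cov = make_cov([("s1", "c1", 2.0, 0.9)])
        groups = pd.DataFrame({"contig_id": ["c1"], "group": ["eukaryote"]})
        out = bp_fractions(cov, self.lengths(["c1"]), groups)
        assert out.loc["s1", "eukaryote"] == 1.0
        assert out.loc["s1"].sum() == pytest.approx(1.0)

    def test_equal_weight_split(self):
        cov = make_cov([("s1", "c1", 2.0, 0.9), ("s1", "c2", 2.0, 0.9)])
        groups = pd.DataFrame(
            {"contig_id": ["c1", "c2"], "group": ["eukaryote", "prokaryote"]}
        )
        out = bp_fractions(cov, self.lengths(["c1", "c2"]), groups)
        assert out.loc["s1", "eukaryote"] == pytest.approx(0.5)
        assert out.loc["s1", "prokaryote"] == pytest.approx(0.5)

    def test_random_instance_matches_weighted_tally(self):
        rng = np.random.default_rng(1)
        contigs = [f"c{i}" for i in range(30)]
        lengths = pd.DataFrame(
            {"contig_id": contigs, "length_bp": rng.integers(500, 5000, 30)}
        )
        grp = rng.choice(["eukaryote", "prokaryote", "virus", "NA"], 30)
        groups = pd.DataFrame({"contig_id": contigs, "group": grp})
        rows = [
            (f"s{j}", c, float(rng.uniform(0.1, 5)), float(rng.random()))
            for c in contigs
            for j in range(3)
        ]
        cov = make_cov(rows)
        out = bp_fractions(cov, lengths, groups)
        lb = dict(zip(lengths["contig_id"], lengths["length_bp"]))
        gb = dict(zip(contigs, grp))
        for j in range(3):
            weights: dict[str, float] = {}
            for s, c, d, b in rows:
                if s == f"s{j}" and b >= 0.25:
                    weights[gb[c]] = weights.get(gb[c], 0) + d * lb[c]
            total = sum(weights.values())
            for g, w in weights.items():
                assert out.loc[f"s{j}", g] == pytest.approx(w / total)
        sums = out.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_sample_without_present_contigs_flagged(self):
        cov = make_cov([("s1", "c1", 2.0, 0.9), ("s2", "c1", 0.1, 0.1)])
        groups = pd.DataFrame({"contig_id": ["c1"], "group": ["eukaryote"]})
        with pytest.warns(UserWarning, match="no present contigs"):
            out = bp_fractions(cov, self.lengths(["c1"]), groups)
        assert out.loc["s2"].isna().all()

    def test_group_mapping_from_final_labels(self):
        final = final_from_labels(
            ["a", "b", "c"], ["eukaryote", "noneukaryote", "unclassified"]
        )
        groups = group_labels_from_final(final, viral_ids={"b"})
        assert groups.set_index("contig_id")["group"].to_dict() == {
            "a": "eukaryote",
            "b": "virus",
            "c": "NA",
        }


class TestClusterSamples:
    def planted(self, rng, n=100):
        half = n // 2
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "nonpareil_coverage": np.concatenate(
                    [rng.normal(0.6, 0.04, half), rng.normal(0.9, 0.04, n - half)]
                ),
                "euk_fraction": np.concatenate(
                    [rng.uniform(1e-4, 1e-3, half), rng.uniform(0.05, 0.2, n - half)]
                ),
                "planted": ["deficient"] * half + ["increasing"] * (n - half),
            }
        )

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        df = self.planted(rng, n=20)
        out = cluster_samples(df, seed=1)
        assert (out["cluster"] == df["planted"]).all()

    def test_lower_euk_cluster_named_deficient(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            df = self.planted(rng, n=30)
            out = cluster_samples(df, seed=seed).merge(df, on="sample_id")
            means = out.groupby("cluster")["euk_fraction"].mean()
            assert means["deficient"] < means["increasing"]

    def test_planted_recovery_accuracy(self):
        rng = np.random.default_rng(5)
        df = self.planted(rng, n=100)
        out = cluster_samples(df, seed=0).merge(df, on="sample_id")
        accuracy = (out["cluster"] == out["planted"]).mean()
        assert accuracy >= 0.95

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        df = self.planted(rng, n=40)
        out_a = cluster_samples(df, seed=2).set_index("sample_id")["cluster"]
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        out_b = cluster_samples(shuffled, seed=2).set_index("sample_id")["cluster"]
        assert (out_a.sort_index() == out_b.sort_index()).all()

    def test_zero_fractions_get_pseudocount(self):
        rng = np.random.default_rng(8)
        df = self.planted(rng, n=20)
        df.loc[0, "euk_fraction"] = 0.0
        out = cluster_samples(df, seed=0)
        assert out.loc[out["sample_id"] == "s0", "cluster"].item() == "deficient"

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame(
            {"sample_id": ["s1"], "nonpareil_coverage": [0.5], "euk_fraction": [0.1]}
        )
        with pytest.raises(ValueError, match="at least k"):
            cluster_samples(df, k=2)


def hypergeom_oracle(n_samples, k_a, k_b, x):
    """P(overlap >= x) by exhaustive enumeration of A's sample subsets."""
    universe = range(n_samples)
    b_set = set(range(k_b))
    hits = total = 0
    for a_set in combinations(universe, k_a):
        total += 1
        hits += len(b_set & set(a_set)) >= x
    return hits / total


class TestCooccurrence:
    def presence(self, patterns: dict[str, str]) -> pd.DataFrame:
        mat = {t: [c == "1" for c in row] for t, row in patterns.items()}
        df = pd.DataFrame(mat).T
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        return df

    def test_three_of_five_full_overlap_is_point_one(self):
        pres = self.presence({"A": "11100", "B": "11100"})
        edges = cooccurrence_edges(pres, alpha=0.05)
        row = edges.iloc[0]
        # C(3,3)*C(2,0)/C(5,3) = 1/10
        assert row["p_value"] == pytest.approx(0.1)
        assert not row["significant"]

    def test_no_self_edges(self):
        pres = self.presence({"A": "1100", "B": "0011"})
        edges = cooccurrence_edges(pres)
        assert len(edges) == 1
        assert set(edges[["taxon_a", "taxon_b"]].iloc[0]) == {"A", "B"}

    def test_matches_exhaustive_enumeration_up_to_six_samples(self):
        rng = np.random.default_rng(0)
        for n in range(2, 7):
            for _ in range(10):
                a = rng.integers(0, 2, n)
                b = rng.integers(0, 2, n)
                if a.sum() == 0 or b.sum() == 0:
                    continue
                pres = pd.DataFrame(
                    [a.astype(bool), b.astype(bool)],
                    index=["A", "B"],
                    columns=[f"s{i}" for i in range(n)],
                )
                edges = cooccurrence_edges(pres)
                x = int((a & b).sum())
                expected = hypergeom_oracle(n, int(a.sum()), int(b.sum()), x)
                assert edges.iloc[0]["p_value"] == pytest.approx(expected)

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(1)
        pres = pd.DataFrame(
            rng.integers(0, 2, (12, 8)).astype(bool),
            index=[f"t{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(8)],
        )
        edges = cooccurrence_edges(pres)
        assert ((edges["p_value"] > 0) & (edges["p_value"] <= 1)).all()

    def test_empty_sample_added_sharpens_significance(self):
        # appending a sample where neither taxon occurs cannot make the
        # association less significant (checked by enumeration, N <= 6)
        for n in range(2, 6):
            for k_a in range(1, n + 1):
                for k_b in range(1, n + 1):
                    for x in range(max(0, k_a + k_b - n), min(k_a, k_b) + 1):
                        p_n = hypergeom_oracle(n, k_a, k_b, x)
                        p_n1 = hypergeom_oracle(n + 1, k_a, k_b, x)
                        assert p_n1 <= p_n + 1e-12

    def test_benjamini_hochberg_option_is_more_conservative(self):
        rng = np.random.default_rng(2)
        pres = pd.DataFrame(
            rng.integers(0, 2, (10, 6)).astype(bool),
            index=[f"t{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        raw = cooccurrence_edges(pres, alpha=0.05, fdr=False)
        adj = cooccurrence_edges(pres, alpha=0.05, fdr=True)
        assert adj["significant"].sum() <= raw["significant"].sum()


def clique_edges(nodes):
    rows = [
        {"taxon_a": a, "taxon_b": b, "p_value": 0.0, "significant": True}
        for a, b in combinations(nodes, 2)
    ]
    return pd.DataFrame(rows)


class TestModules:
    def test_two_disjoint_cliques(self):
        edges = pd.concat(
            [
                clique_edges([f"a{i}" for i in range(12)]),
                clique_edges([f"b{i}" for i in range(12)]),
            ],
            ignore_index=True,
        )
        modules, membership = detect_modules(edges, seed=0)
        assert len(modules) == 2
        assert sorted(m.n_nodes for m in modules) == [12, 12]
        assert len(membership) == 24

    def test_module_size_reporting_threshold(self):
        modules_11, _ = detect_modules(clique_edges([f"n{i}" for i in range(11)]), seed=0)
        assert len(modules_11) == 1
        assert modules_11[0].n_edges == comb(11, 2)
        modules_10, membership = detect_modules(
            clique_edges([f"n{i}" for i in range(10)]), seed=0
        )
        assert modules_10 == []
        # the membership still partitions all nodes
        assert len(membership) == 10

    def test_empty_graph(self):
        modules, membership = detect_modules(
            pd.DataFrame(columns=["taxon_a", "taxon_b", "p_value", "significant"])
        )
        assert modules == [] and membership.empty

    def test_planted_three_communities_recovered(self):
        rng = np.random.default_rng(0)
        sizes = [15, 15, 15]
        nodes = [f"g{g}_n{i}" for g, size in enumerate(sizes) for i in range(size)]
        group = {n: int(n[1]) for n in nodes}
        rows = []
        for a, b in combinations(nodes, 2):
            p = 0.8 if group[a] == group[b] else 0.02
            if rng.random() < p:
                rows.append(
                    {"taxon_a": a, "taxon_b": b, "p_value": 0.0, "significant": True}
                )
        modules, membership = detect_modules(pd.DataFrame(rows), seed=1)
        assert len(modules) == 3
        # agreement with the planted partition up to relabeling
        correct = 0
        for m in modules:
            counts = pd.Series([group[n] for n in m.member_ids]).value_counts()
            correct += counts.iloc[0]
        assert correct / len(nodes) >= 0.95
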