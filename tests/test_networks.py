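"""Network construction: collapse, weights, thresholds, consensus, multiplicity."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from foldbridges import networks
from foldbridges.calibration import BridgeCalibration
from foldbridges.synthetic import SyntheticSpec, generate


def annotation_frame(rows):
    return pd.DataFrame(
        rows, columns=["domain_id", "family", "superfamily", "fold", "class"]
    )


@pytest.fixture(scope="module")
def collapsed_default(small_bundle):
    """Calibrated, collapsed fold-level tables for each pseudo-method."""
    out = {}
    ann = small_bundle.annotation
    alpha_of = ann.set_index("domain_id")["class"] == "a"
    for m, table in small_bundle.score_tables.items():
        res = BridgeCalibration.from_score_table(table, ann).fit()
        pairs = table.frame[["domain_i", "domain_j"]].copy()
        pairs["score"] = table.frame[res.score_column]
        alpha = (pairs["domain_i"].map(alpha_of) | pairs["domain_j"].map(alpha_of)).to_numpy()
        pairs["posterior"] = res.posterior(pairs["score"].to_numpy(), alpha)
        conv = "inverse_distance" if table.orientation == "distance" else "score"
        out[m] = networks.collapse(networks.assign_weights(pairs, conv), ann, "fold")
    return out


class TestCollapse:
    def test_highest_posterior_alignment_defines_the_fold_edge(self):
        ann = annotation_frame(
            [
                ("d3etja1", "b.84.1.1", "b.84.1", "b.84", "b"),
                ("dother1", "b.84.1.1", "b.84.1", "b.84", "b"),
                ("d2cvea2", "d.58.1.1", "d.58.1", "d.58", "d"),
            ]
        )
        pairs = pd.DataFrame(
            {
                "domain_i": ["d3etja1", "dother1"],
                "domain_j": ["d2cvea2", "d2cvea2"],
                "posterior": [0.958, 0.41],
                "score": [0.554, 0.30],
            }
        )
        coll = networks.collapse(pairs, ann, "fold")
        assert len(coll) == 1
        row = coll.iloc[0]
        assert (row["group_a"], row["group_b"]) == ("b.84", "d.58")
        assert row["posterior"] == 0.958
        assert {row["provenance_domain_a"], row["provenance_domain_b"]} == {"d3etja1", "d2cvea2"}
        assert row["score"] == 0.554

    def test_one_domain_per_fold_collapse_is_identity(self):
        ann = annotation_frame(
            [(f"d{k}", f"x.{k}.1.1", f"x.{k}.1", f"x.{k}", "x"[:1]) for k in range(4)]
        )
        ann["class"] = "a"
        ann["fold"] = [f"a.{k}" for k in range(4)]
        rng = np.random.default_rng(0)
        i, j = np.triu_indices(4, 1)
        pairs = pd.DataFrame(
            {
                "domain_i": [f"d{a}" for a in i],
                "domain_j": [f"d{b}" for b in j],
                "posterior": rng.random(i.size),
            }
        )
        coll = networks.collapse(pairs, ann, "fold")
        assert len(coll) == len(pairs)
        assert sorted(coll["posterior"]) == sorted(pairs["posterior"])

    def test_two_stage_collapse_equals_direct_collapse(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(6, 20))
            folds = [f"a.{rng.integers(1, 4)}" for _ in range(n)]
            fams = [f"{f}.{rng.integers(1, 3)}.1" for f in folds]
            ann = annotation_frame(
                [
                    (f"d{k}", fams[k], fams[k].rsplit(".", 1)[0], folds[k], "a")
                    for k in range(n)
                ]
            )
            i, j = np.triu_indices(n, 1)
            pairs = pd.DataFrame(
                {
                    "domain_i": [f"d{a}" for a in i],
                    "domain_j": [f"d{b}" for b in j],
                    "posterior": rng.random(i.size),
                }
            )
            direct = networks.collapse(pairs, ann, "fold")
            via_family = networks.collapse(pairs, ann, "family")
            fam_pairs = via_family.rename(
                columns={"group_a": "domain_i", "group_b": "domain_j"}
            )[["domain_i", "domain_j", "posterior"]]
            fam_ann = (
                ann[["family", "superfamily", "fold", "class"]]
                .drop_duplicates()
                .rename(columns={"family": "domain_id"})
            )
            fam_ann["family"] = fam_ann["domain_id"]
            two_stage = networks.collapse(fam_pairs, fam_ann, "fold")
            lhs = direct.set_index(["group_a", "group_b"])["posterior"].sort_index()
            rhs = two_stage.set_index(["group_a", "group_b"])["posterior"].sort_index()
            pd.testing.assert_series_equal(lhs, rhs)

    def test_missing_annotation_lists_offenders(self):
        ann = annotation_frame([("d0", "a.1.1.1", "a.1.1", "a.1", "a")])
        pairs = pd.DataFrame(
            {"domain_i": ["d0"], "domain_j": ["dX"], "posterior": [0.9]}
        )
        with pytest.raises(ValueError, match="dX"):
            networks.collapse(pairs, ann, "fold")


class TestEdgeWeights:
    def test_tm_score_taken_verbatim(self):
        assert networks.assign_edge_weight("tm_score", {"tm_score": 0.554}) == 0.554

    def test_elastic_metric_reciprocal(self):
        assert networks.assign_edge_weight("inverse_distance", {"score": 2.0}) == 0.5
        with pytest.raises(ValueError, match="nonpositive"):
            networks.assign_edge_weight("inverse_distance", {"score": 0.0})

    def test_fatcat_zero_rmsd_full_length_gives_one(self):
        rec = {"opt_rmsd": 0.0, "len_a": 120, "len_b": 80}
        assert networks.assign_edge_weight("fatcat_approx_tm", rec) == pytest.approx(1.0)

    def test_fatcat_tm_decreases_with_rmsd(self):
        tms = [
            networks.fatcat_approx_tm(r, 100, 100) for r in (0.0, 1.0, 3.0, 8.0)
        ]
        assert tms == sorted(tms, reverse=True)
        assert all(0 < t <= 1 for t in tms)

    def test_weights_invariant_to_pair_ordering(self):
        df = pd.DataFrame(
            {"domain_i": ["a", "b"], "domain_j": ["b", "c"], "score": [0.4, 0.8]}
        )
        w1 = networks.assign_weights(df, "score")["weight"]
        w2 = networks.assign_weights(df.iloc[::-1].reset_index(drop=True), "score")["weight"]
        assert sorted(w1) == sorted(w2)


class TestStaticNetworks:
    def test_threshold_above_one_gives_empty_edge_set(self, small_bundle, collapsed_default):
        G = networks.build_static_network(
            collapsed_default["simA"], small_bundle.annotation, 1.0 + 1e-9, "simA"
        )
        assert G.number_of_edges() == 0
        # the node universe is retained even when unconnected
        assert G.number_of_nodes() == small_bundle.annotation["fold"].nunique()

    def test_stricter_network_is_edge_subgraph(self, small_bundle, collapsed_default):
        for m, coll in collapsed_default.items():
            lo = networks.build_static_network(coll, small_bundle.annotation, 0.5, m)
            hi = networks.build_static_network(coll, small_bundle.annotation, 0.9, m)
            assert set(map(frozenset, hi.edges())) <= set(map(frozenset, lo.edges()))

    def test_sweep_emits_twenty_five_networks(self, small_bundle, collapsed_default):
        suite = networks.static_network_sweep(collapsed_default, small_bundle.annotation)
        assert len(suite) == 25
        methods = {m for m, _ in suite}
        assert methods == set(collapsed_default) | {"consensus"}


class TestDynamicSequence:
    def test_birth_threshold_is_highest_grid_value_reached(self):
        ann = annotation_frame(
            [("d0", "a.1.1.1", "a.1.1", "a.1", "a"), ("d1", "a.2.1.1", "a.2.1", "a.2", "a")]
        )
        coll = pd.DataFrame(
            {
                "group_a": ["a.1"],
                "group_b": ["a.2"],
                "posterior": [0.83],
                "provenance_domain_a": ["d0"],
                "provenance_domain_b": ["d1"],
                "weight": [0.83],
            }
        )
        birth, graphs = networks.build_dynamic_sequence(coll, ann, "m")
        assert birth["birth_threshold"].iloc[0] == pytest.approx(0.83)
        assert len(graphs) == 51

    def test_edge_count_nondecreasing_and_final_frame_matches_static(
        self, small_bundle, collapsed_default
    ):
        coll = collapsed_default["simB"]
        grid = np.round(np.arange(1.0, 0.49, -0.05), 10)
        birth, graphs = networks.build_dynamic_sequence(
            coll, small_bundle.annotation, "simB", grid=grid
        )
        counts = [G.number_of_edges() for G in graphs]
        assert counts == sorted(counts)
        static = networks.build_static_network(coll, small_bundle.annotation, grid[-1], "simB")
        assert set(map(frozenset, graphs[-1].edges())) == set(map(frozenset, static.edges()))

    def test_rejects_nondecreasing_grid(self, small_bundle, collapsed_default):
        with pytest.raises(ValueError, match="strictly decreasing"):
            networks.build_dynamic_sequence(
                collapsed_default["simA"], small_bundle.annotation, "simA", grid=[0.5, 0.6]
            )


def two_method_networks(edges_by_method, nodes):
    out = {}
    for m, edges in edges_by_method.items():
        G = nx.Graph(method=m, level="fold", threshold=0.5)
        G.add_nodes_from(nodes)
        for (u, v), w in edges.items():
            G.add_edge(u, v, weight=w, posterior=0.9)
        out[m] = G
    return out


class TestConsensus:
    def test_mean_normalization_worked_example(self):
        nets = two_method_networks(
            {
                "m1": {("f1", "f2"): 0.2, ("f3", "f4"): 0.4},
                "m2": {("f1", "f2"): 2.0, ("f3", "f4"): 4.0},
            },
            ["f1", "f2", "f3", "f4"],
        )
        C = networks.build_consensus(nets)
        assert C["f1"]["f2"]["weight"] == pytest.approx(2 / 3)
        assert C["f3"]["f4"]["weight"] == pytest.approx(4 / 3)

    def test_single_shared_edge_normalizes_to_one(self):
        nets = two_method_networks(
            {"m1": {("f1", "f2"): 0.5}, "m2": {("f1", "f2"): 0.5}}, ["f1", "f2"]
        )
        C = networks.build_consensus(nets)
        assert C["f1"]["f2"]["weight"] == pytest.approx(1.0)

    def test_edge_missing_from_one_method_is_dropped(self):
        nets = two_method_networks(
            {
                "m1": {("f1", "f2"): 1.0, ("f2", "f3"): 1.0},
                "m2": {("f1", "f2"): 1.0, ("f2", "f3"): 1.0},
                "m3": {("f1", "f2"): 1.0, ("f2", "f3"): 1.0},
                "m4": {("f1", "f2"): 1.0},
            },
            ["f1", "f2", "f3"],
        )
        C = networks.build_consensus(nets)
        assert set(map(frozenset, C.edges())) == {frozenset(("f1", "f2"))}
        assert C["f1"]["f2"]["multiplicity"] == 4

    def test_method_with_no_edges_warns_and_empties_consensus(self):
        nets = two_method_networks(
            {"m1": {("f1", "f2"): 1.0}, "m2": {}}, ["f1", "f2"]
        )
        with pytest.warns(UserWarning, match="no edges"):
            C = networks.build_consensus(nets)
        assert C.number_of_edges() == 0

    def test_consensus_matches_naive_intersection(self, small_bundle, collapsed_default):
        nets = {
            m: networks.build_static_network(c, small_bundle.annotation, 0.6, m)
            for m, c in collapsed_default.items()
        }
        C = networks.build_consensus(nets)
        naive = None
        for G in nets.values():
            es = set(map(frozenset, G.edges()))
            naive = es if naive is None else naive & es
        assert set(map(frozenset, C.edges())) == naive


class TestEdgeMultiplicity:
    def test_histogram_partitions_the_union(self, small_bundle, collapsed_default):
        nets = {
            m: networks.build_static_network(c, small_bundle.annotation, 0.6, m)
            for m, c in collapsed_default.items()
        }
        frame, hist = networks.edge_multiplicity(nets)
        union = set()
        for G in nets.values():
            union |= set(map(frozenset, G.edges()))
        assert sum(hist.values()) == len(union)
        n = small_bundle.annotation["fold"].nunique()
        assert len(frame) == n * (n - 1) // 2
        assert (frame["multiplicity"] == 4).sum() == hist[4]

    def test_pair_in_all_methods_counts_four(self):
        nets = two_method_networks(
            {f"m{k}": {("f1", "f2"): 1.0} for k in range(4)}, ["f1", "f2", "f3"]
        )
        frame, _ = networks.edge_multiplicity(nets)
        row = frame.set_index(["group_a", "group_b"]).loc[("f1", "f2")]
        assert row["multiplicity"] == 4

    def test_unique_edge_fraction_rises_as_agreement_falls(self):
        fractions = []
        for agreement in (0.9, 0.3):
            vals = []
            for seed in (0, 1):
                spec = SyntheticSpec(
                    seed=seed, folds_per_class=8, method_agreement=agreement
                )
                b = generate(spec)
                ann = b.annotation
                alpha_of = ann.set_index("domain_id")["class"] == "a"
                nets = {}
                for m, table in b.score_tables.items():
                    res = BridgeCalibration.from_score_table(table, ann).fit()
                    pairs = table.frame[["domain_i", "domain_j"]].copy()
                    pairs["score"] = table.frame[res.score_column]
                    alpha = (
                        pairs["domain_i"].map(alpha_of) | pairs["domain_j"].map(alpha_of)
                    ).to_numpy()
                    pairs["posterior"] = res.posterior(pairs["score"].to_numpy(), alpha)
                    conv = (
                        "inverse_distance" if table.orientation == "distance" else "score"
                    )
                    coll = networks.collapse(networks.assign_weights(pairs, conv), ann, "fold")
                    nets[m] = networks.build_static_network(coll, ann, 0.6, m)
                _, hist = networks.edge_multiplicity(nets)
                vals.append(hist[1] / max(sum(hist.values()), 1))
            fractions.append(np.mean(vals))
        assert fractions[1] > fractions[0]


class TestExport:
    def test_graphml_and_edge_list_round_trip(self, tmp_path, small_bundle, collapsed_default):
        G = networks.build_static_network(
            collapsed_default["simA"], small_bundle.annotation, 0.6, "simA",
            ages=small_bundle.ages,
        )
        networks.write_graphml(G, tmp_path / "net.graphml")
        H = nx.read_graphml(tmp_path / "net.graphml")
        assert H.number_of_edges() == G.number_of_edges()
        networks.write_edge_list(G, tmp_path / "net.tsv")
        df = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(df) == G.number_of_edges()
        assert {"posterior", "weight", "provenance_domain_a"} <= set(df.columns)
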