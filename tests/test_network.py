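import math

import numpy as np
import pandas as pd
import pytest

from pptpseq.data_io import LibraryAnnotation
from pptpseq.diffcall import DifferentialCall
from pptpseq.network import (
    RegulatoryEdge,
    autoregulation,
    build_network,
    condition_overlap,
    regulating_vs_nonregulating,
    relative_binding,
)


def _call(sg, pr, tf, call, fold=2.0, q=1e-4):
    return DifferentialCall(sg, pr, tf, 3.0, 1e-5, q, fold, fold, call)


class TestBuildNetwork:
    def test_sign_convention(self):
        calls = [
            _call("sg1", "P1", "crp", "up"),
            _call("sg2", "P2", "fur", "down"),
            _call("sg3", "P3", "metJ", "ns"),
        ]
        edges = build_network(calls, "glucose")
        assert len(edges) == 2
        by_tf = {e.tf: e for e in edges}
        # knockdown raised activity -> the TF normally represses
        assert by_tf["crp"].sign == "repression"
        assert by_tf["fur"].sign == "activation"
        assert all(e.condition == "glucose" for e in edges)

    def test_all_ns_gives_empty_network(self):
        assert build_network([_call("s", "P", "crp", "ns")]) == []

    def test_edge_count_equals_non_ns_call_count(self):
        rng = np.random.default_rng(0)
        calls = [
            _call(f"sg{i}", f"P{i}", f"TF{i}", rng.choice(["up", "down", "ns", "na"]))
            for i in range(50)
        ]
        edges = build_network(calls)
        assert len(edges) == sum(c.call in {"up", "down"} for c in calls)

    def test_heteromeric_tf_splits_per_gene(self):
        edges = build_network([_call("sg", "P1", "ihfA;ihfB", "up")])
        assert {e.tf for e in edges} == {"ihfA", "ihfB"}


class TestAutoregulation:
    def _library(self):
        sg = pd.DataFrame(
            {"sgrna_id": ["sg1"], "target_tf": ["pgrR"], "is_control": [False]}
        )
        pr = pd.DataFrame(
            {
                "promoter_id": ["PpgrR", "PmetA", "Porphan"],
                "operon": ["pgrR", "metA", "x"],
                "genes": [["pgrR"], ["metA"], ["x"]],
                "tf_gene_of_promoter": ["pgrR", "", ""],
            }
        )
        return LibraryAnnotation(sgrnas=sg, promoters=pr)

    def test_self_edge_retained(self):
        edges = [RegulatoryEdge("pgrR", "PpgrR", "repression", "", 2.0, 1e-4)]
        assert autoregulation(edges, self._library()) == edges

    def test_cross_edge_not_autoregulatory(self):
        edges = [RegulatoryEdge("metJ", "PmetA", "repression", "", 2.0, 1e-4)]
        assert autoregulation(edges, self._library()) == []

    def test_promoter_without_tf_gene_never_autoregulatory(self):
        edges = [RegulatoryEdge("pgrR", "Porphan", "repression", "", 2.0, 1e-4)]
        assert autoregulation(edges, self._library()) == []


class TestConditionOverlap:
    def _edge(self, tf, pr, sign="repression", cond=""):
        return RegulatoryEdge(tf, pr, sign, cond, 2.0, 1e-4)

    def test_identical_sets_all_in_triple_intersection(self):
        edges = [self._edge("a", "P1"), self._edge("b", "P2", "activation")]
        table = condition_overlap({"c1": edges, "c2": edges, "c3": edges})
        triple = table[table["membership_pattern"] == "c1&c2&c3"]
        assert triple["count"].sum() == 2
        assert table.loc[table["membership_pattern"] != "c1&c2&c3", "count"].sum() == 0

    def test_disjoint_sets_have_empty_intersections(self):
        table = condition_overlap(
            {"c1": [self._edge("a", "P1")], "c2": [self._edge("b", "P2")]}
        )
        assert table.loc[table["membership_pattern"] == "c1&c2", "count"].sum() == 0
        assert table["count"].sum() == 2

    def test_hand_built_partition_matches_enumeration(self):
        shared = self._edge("a", "P1")
        e2, e3 = self._edge("b", "P2"), self._edge("c", "P3")
        e4, e5 = self._edge("d", "P4"), self._edge("e", "P5")
        table = condition_overlap(
            {"c1": [shared, e2, e3], "c2": [shared, e4], "c3": [shared, e5]}
        )
        counts = dict(
            zip(table["membership_pattern"] + "/" + table["sign"], table["count"])
        )
        assert counts["c1&c2&c3/repression"] == 1
        assert counts["c1/repression"] == 2
        assert counts["c2/repression"] == 1
        assert counts["c3/repression"] == 1
        assert table["count"].sum() == 5


class TestRelativeBinding:
    def _sites(self, rows):
        return pd.DataFrame(
            rows,
            columns=["tf", "promoter_id", "site_start", "site_end", "fold_enrichment", "tss_position"],
        )

    def test_per_tf_normalization(self):
        out = relative_binding(
            self._sites([("crp", "P1", 0, 10, 10.0, 20), ("crp", "P2", 0, 10, 5.0, 20)])
        )
        got = dict(zip(out["promoter_id"], out["rel_strength_per_tf"]))
        assert got == {"P1": 1.0, "P2": 0.5}

    def test_per_promoter_normalization(self):
        out = relative_binding(
            self._sites([("crp", "P1", 0, 10, 8.0, 20), ("fur", "P1", 0, 10, 2.0, 20)])
        )
        got = dict(zip(out["tf"], out["rel_strength_per_promoter"]))
        assert got == {"crp": 1.0, "fur": 0.25}

    def test_strongest_site_retained_per_pair(self):
        out = relative_binding(
            self._sites([("crp", "P1", 0, 10, 3.0, 20), ("crp", "P1", 50, 60, 7.0, 20)])
        )
        assert len(out) == 1
        assert out["fold_enrichment"].iloc[0] == 7.0
        # TSS-relative center: midpoint 55 minus TSS 20
        assert out["tss_relative_center"].iloc[0] == pytest.approx(35.0)

    def test_idempotent_and_scale_invariant(self):
        sites = self._sites(
            [("crp", "P1", 0, 10, 3.0, 20), ("crp", "P2", 0, 10, 7.0, 20), ("fur", "P1", 0, 4, 2.0, 20)]
        )
        once = relative_binding(sites)
        twice = relative_binding(once[sites.columns])
        pd.testing.assert_frame_equal(once, twice)
        scaled = relative_binding(sites.assign(fold_enrichment=sites["fold_enrichment"] * 13.0))
        np.testing.assert_allclose(
            scaled["rel_strength_per_tf"], once["rel_strength_per_tf"]
        )
        np.testing.assert_allclose(
            scaled["rel_strength_per_promoter"], once["rel_strength_per_promoter"]
        )

    def test_unknown_promoter_skipped_with_warning(self):
        sites = self._sites([("crp", "P1", 0, 10, 3.0, 20), ("crp", "Pxx", 0, 10, 9.0, 20)])
        with pytest.warns(UserWarning, match="unknown promoter"):
            out = relative_binding(sites, known_promoters={"P1"})
        assert out["promoter_id"].tolist() == ["P1"]


class TestRegulatingComparison:
    def _annotated_sites(self, n=50, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(2 * n):
            regulating = i < n
            rows.append(
                (
                    f"TF{i}",
                    f"P{i}",
                    0,
                    10,
                    1.0,
                    0,
                    rng.normal(shift if regulating else 0.0, 1.0),
                )
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "tf", "promoter_id", "site_start", "site_end",
                "fold_enrichment", "tss_position", "rel_strength_per_promoter",
            ],
        )
        edges = [
            RegulatoryEdge(f"TF{i}", f"P{i}", "repression", "", 2.0, 1e-4)
            for i in range(n)
        ]
        return df, edges

    def test_shifted_group_is_significant(self):
        df, edges = self._annotated_sites(n=50, shift=1.5, seed=3)
        out = regulating_vs_nonregulating(
            df, edges, features=["rel_strength_per_promoter"]
        )
        assert out["p_adjusted"].iloc[0] < 0.05

    def test_null_is_rarely_significant(self):
        hits = 0
        for seed in range(20):
            df, edges = self._annotated_sites(n=30, shift=0.0, seed=seed)
            out = regulating_vs_nonregulating(
                df, edges, features=["rel_strength_per_promoter"]
            )
            hits += out["p_adjusted"].iloc[0] < 0.05
        assert hits <= 3

    def test_empty_edges_gives_na(self):
        df, _ = self._annotated_sites(n=10)
        out = regulating_vs_nonregulating(df, [], features=["rel_strength_per_promoter"])
        assert math.isnan(out["p"].iloc[0])

    def test_small_group_gives_na(self):
        df, edges = self._annotated_sites(n=2)
        out = regulating_vs_nonregulating(
            df, edges, features=["rel_strength_per_promoter"]
        )
        assert math.isnan(out["p"].iloc[0])
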