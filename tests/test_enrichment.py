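"""Target-set indexing and shared-miRNA hypergeometric screening."""

import numpy as np
import pandas as pd
import pytest

import cernascreen as cs
from cernascreen.errors import EmptyIndexError, InvalidInputError

from test_stats import hypergeom_tail_oracle


def table_of(rows):
    return pd.DataFrame(
        rows, columns=["rna1", "rna1_category", "rna2", "rna2_category", "score"]
    )


@pytest.fixture
def small_index():
    rows = table_of(
        [
            ("MALAT1", "lncRNA", "miR-1", "miRNA", np.nan),
            ("miR-2", "miRNA", "MALAT1", "lncRNA", np.nan),
            ("GeneA", "mRNA", "miR-1", "miRNA", np.nan),
        ]
    )
    return cs.TargetSetIndex.from_table(rows)


class TestIndexConstruction:
    def test_direction_agnostic_indexing(self, small_index):
        assert small_index.target_set("MALAT1") == {"miR-1", "miR-2"}
        assert small_index.target_set("GeneA") == {"miR-1"}
        assert small_index.universe == {"miR-1", "miR-2"}

    def test_duplicate_rows_counted_once(self):
        rows = table_of(
            [
                ("A", "mRNA", "miR-1", "miRNA", np.nan),
                ("A", "mRNA", "miR-1", "miRNA", np.nan),
            ]
        )
        index = cs.TargetSetIndex.from_table(rows)
        assert index.target_set("A") == {"miR-1"}

    def test_mirna_mirna_rows_join_universe_only(self):
        rows = table_of(
            [
                ("miR-1", "miRNA", "miR-9", "miRNA", np.nan),
                ("A", "mRNA", "miR-1", "miRNA", np.nan),
            ]
        )
        index = cs.TargetSetIndex.from_table(rows)
        assert index.universe == {"miR-1", "miR-9"}
        assert "miR-9" not in index.target_set("A")

    def test_no_mirna_rows_is_empty_index_error(self):
        rows = table_of([("A", "mRNA", "B", "lncRNA", np.nan)])
        with pytest.raises(EmptyIndexError):
            cs.TargetSetIndex.from_table(rows)

    def test_casefold_flag_merges_identifiers(self):
        rows = table_of(
            [
                ("Malat1", "lncRNA", "miR-1", "miRNA", np.nan),
                ("MALAT1", "lncRNA", "miR-2", "miRNA", np.nan),
            ]
        )
        index = cs.TargetSetIndex.from_table(rows, casefold=True)
        assert index.target_set("malat1") == {"mir-1", "mir-2"}


class TestSharedTargetTest:
    def build_index(self, seed_set, gene_sets, universe_size):
        mirnas = [f"m{i}" for i in range(universe_size)]
        rows = [("SEED", "lncRNA", m, "miRNA", np.nan) for m in seed_set]
        for g, s in gene_sets.items():
            rows += [(g, "mRNA", m, "miRNA", np.nan) for m in s]
        seen = set(seed_set) | {m for s in gene_sets.values() for m in s}
        rows += [(m, "miRNA", m, "miRNA", np.nan) for m in mirnas if m not in seen]
        return cs.TargetSetIndex.from_table(table_of(rows))

    def test_full_overlap_example(self):
        mirnas = [f"m{i}" for i in range(10)]
        index = self.build_index(mirnas[:5], {"G": mirnas[1:5]}, 10)
        res = cs.shared_mirna_test(index, "SEED", "G")
        assert (res.k, res.K, res.n, res.N) == (4, 5, 4, 10)
        assert res.p == pytest.approx(5 / 210, rel=1e-12)

    def test_unindexed_gene_is_null_observation(self, small_index):
        res = cs.shared_mirna_test(small_index, "MALAT1", "GhostGene")
        assert (res.k, res.n, res.p, res.indexed) == (0, 0, 1.0, False)

    def test_gene_covering_whole_universe_gives_p_one(self):
        mirnas = [f"m{i}" for i in range(10)]
        index = self.build_index(mirnas[:5], {"G": mirnas}, 10)
        res = cs.shared_mirna_test(index, "SEED", "G")
        assert res.k == res.K == 5 and res.p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_grid(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            N = int(rng.integers(4, 25))
            mirnas = [f"m{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(0, N + 1))
            seed_set = list(rng.choice(mirnas, K, replace=False))
            gene_set = list(rng.choice(mirnas, n, replace=False))
            index = self.build_index(seed_set, {"G": gene_set} if n else {}, N)
            res = cs.shared_mirna_test(index, "SEED", "G")
            assert res.p == pytest.approx(
                hypergeom_tail_oracle(N, K, res.n, res.k), rel=1e-10
            )

    def test_adding_a_shared_mirna_never_increases_p(self):
        mirnas = [f"m{i}" for i in range(20)]
        seed_set = mirnas[:8]
        previous = 1.0
        for extra in range(1, 8):
            gene_set = mirnas[:extra] + mirnas[10 : 10 + (8 - extra)]
            index = self.build_index(seed_set, {"G": gene_set}, 20)
            p = cs.shared_mirna_test(index, "SEED", "G").p
            assert p <= previous + 1e-12
            previous = p

    def test_missing_seed_rejected(self, small_index):
        with pytest.raises(InvalidInputError):
            cs.shared_mirna_test(small_index, "NotASeed", "GeneA")


class TestScreenAll:
    def test_composed_gate(self):
        mirnas = [f"m{i}" for i in range(10)]
        helper = TestSharedTargetTest()
        index = helper.build_index(
            mirnas[:5], {"Hit": mirnas[1:5], "Miss": mirnas[5:9]}, 10
        )
        res = cs.cerna_screen_all(index, "SEED", ["Hit", "Miss"], alpha=0.05)
        assert res.genes() == {"Hit"}
        assert cs.cerna_screen_all(index, "SEED", ["Hit", "Miss"], alpha=0.0).genes() == set()

    def test_gene_order_invariance(self, small_index):
        a = cs.cerna_screen_all(small_index, "MALAT1", ["GeneA", "GeneB"]).table
        b = cs.cerna_screen_all(small_index, "MALAT1", ["GeneB", "GeneA"]).table
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_planted_genes_pass_and_background_rate_controlled(self, scenario):
        # planted ceRNA genes share 24 of the seed's 30 targets in a
        # 500-miRNA universe; background RNAs draw 30 uniformly
        index = cs.TargetSetIndex.from_table(scenario.interactions)
        background = [g for g in index.targets if g.startswith("gene")]
        res = cs.cerna_screen_all(
            index, scenario.truth.seed_id, scenario.truth.planted_cerna + background
        )
        assert set(scenario.truth.planted_cerna) <= res.genes()
        assert (res.table.loc[scenario.truth.planted_cerna, "p"] < 1e-10).all()
        bg_rate = res.table.loc[background, "passes"].mean()
        se = np.sqrt(0.05 * 0.95 / len(background))
        assert bg_rate <= 0.05 + 2 * se


class TestBridging:
    def test_score_ordering_with_lexicographic_ties(self):
        rows = table_of(
            [
                ("SEED", "lncRNA", "miR-a", "miRNA", 0.2),
                ("SEED", "lncRNA", "miR-b", "miRNA", 0.9),
                ("SEED", "lncRNA", "miR-c", "miRNA", 0.9),
                ("G", "mRNA", "miR-a", "miRNA", 0.2),
                ("G", "mRNA", "miR-b", "miRNA", 0.9),
                ("G", "mRNA", "miR-c", "miRNA", 0.9),
            ]
        )
        index = cs.TargetSetIndex.from_table(rows)
        assert cs.bridging_mirnas(index, "SEED", "G") == ["miR-b", "miR-c", "miR-a"]

    def test_single_shared_mirna_intersection(self):
        rows = table_of(
            [
                ("MALAT1", "lncRNA", "miR-194-5p", "miRNA", np.nan),
                ("MALAT1", "lncRNA", "miR-146a", "miRNA", np.nan),
                ("FOXP2", "mRNA", "miR-194-5p", "miRNA", np.nan),
            ]
        )
        index = cs.TargetSetIndex.from_table(rows)
        assert cs.bridging_mirnas(index, "MALAT1", "FOXP2") == ["miR-194-5p"]

    def test_disjoint_sets_give_empty_list(self):
        rows = table_of(
            [
                ("SEED", "lncRNA", "miR-1", "miRNA", np.nan),
                ("G", "mRNA", "miR-2", "miRNA", np.nan),
            ]
        )
        index = cs.TargetSetIndex.from_table(rows)
        assert cs.bridging_mirnas(index, "SEED", "G") == []

    def test_unindexed_identifier_warns_and_returns_empty(self, small_index):
        with pytest.warns(RuntimeWarning):
            assert cs.bridging_mirnas(small_index, "MALAT1", "Ghost") == []
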