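import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from conftest import make_hit, random_probability_motif
from pairmotif.config import RunConfig
from pairmotif.enrichment import (
    GeneSet,
    all_motif_pairs,
    bonferroni_adjust,
    colocalization_test,
    equalize_gene_sets,
    find_overlaps,
    hypergeometric_pair_test,
    load_gene_set,
    pair_matrix,
    pair_positive_genes,
    read_pair_matrix,
    resolve_overlaps,
    write_pair_matrix,
)
from pairmotif.enrichment import test_gene_sets as evaluate_gene_sets
from pairmotif.motifs import Motif
from pairmotif.scan import binomial_promoter_score, index_universe
from pairmotif.synth import generate_background_promoters


def uniform_columns(n):
    return [[0.25, 0.25, 0.25, 0.25]] * n


def deterministic_columns(n, base=0):
    col = [0.0] * 4
    col[base] = 1.0
    return [col] * n


def hypergeom_enumeration(universe, successes, draws, observed):
    """P(X >= observed) by exhaustive enumeration over all draws."""
    total = 0
    hits = 0
    for combo in itertools.combinations(range(universe), draws):
        total += 1
        if sum(1 for x in combo if x < successes) >= observed:
            hits += 1
    return Fraction(hits, total)


class TestFindOverlaps:
    def setup_method(self):
        self.motif_a = Motif("A", np.array(uniform_columns(10)))
        self.motif_b = Motif("B", np.array(uniform_columns(6)))

    def test_basic_interval_arithmetic(self):
        ha = make_hit(0, 0.01, width=10, motif_id="A")
        hb = make_hit(8, 0.01, width=6, motif_id="B")
        (rec,) = find_overlaps([ha], [hb], self.motif_a, self.motif_b)
        assert rec.positions_a == frozenset({8, 9})
        assert rec.positions_b == frozenset({0, 1})

    def test_disjoint_hits_give_no_records(self):
        ha = make_hit(0, 0.01, width=10, motif_id="A")
        hb = make_hit(20, 0.01, width=6, motif_id="B")
        assert find_overlaps([ha], [hb], self.motif_a, self.motif_b) == []

    def test_minus_strand_positions_are_mirrored(self):
        ha = make_hit(0, 0.01, width=10, motif_id="A")
        hb_plus = make_hit(8, 0.01, width=6, strand="+", motif_id="B")
        hb_minus = make_hit(8, 0.01, width=6, strand="-", motif_id="B")
        (rec_p,) = find_overlaps([ha], [hb_plus], self.motif_a, self.motif_b)
        (rec_m,) = find_overlaps([ha], [hb_minus], self.motif_a, self.motif_b)
        # genomic overlap {8, 9}; motif-B-local indices flip 0,1 -> 5,4
        assert rec_p.positions_b == frozenset({0, 1})
        assert rec_m.positions_b == frozenset({5, 4})
        width = 6
        assert rec_m.positions_b == frozenset(
            width - 1 - i for i in rec_p.positions_b
        )


class TestResolveOverlaps:
    def _score(self, hits, motif_id):
        return binomial_promoter_score(
            hits, promoter_length=100, motif_width=hits[0].end - hits[0].start,
            gene_id="g", motif_id=motif_id,
        )

    def test_uniform_overlap_keeps_everything(self):
        motif_a = Motif("A", np.array(uniform_columns(10)))
        motif_b = Motif("B", np.array(uniform_columns(6)))
        ha = make_hit(0, 0.01, width=10, motif_id="A")
        hb = make_hit(8, 0.02, width=6, motif_id="B")
        sa, sb = self._score([ha], "A"), self._score([hb], "B")
        records = find_overlaps([ha], [hb], motif_a, motif_b)
        ra, rb, rescored_a, rescored_b = resolve_overlaps(records, sa, sb)
        assert ra == [ha] and rb == [hb]
        assert rescored_a == sa.binom_score and rescored_b == sb.binom_score

    def test_high_ic_overlap_removes_both_hits(self):
        # overlap covers 3 deterministic columns of A: IC 6 > 4
        motif_a = Motif("A", np.array(deterministic_columns(3) + uniform_columns(7)))
        motif_b = Motif("B", np.array(uniform_columns(6)))
        ha = make_hit(6, 0.01, width=10, motif_id="A")  # A local 0..2 = genomic 6..8
        hb = make_hit(3, 0.02, width=6, motif_id="B")   # genomic 3..8
        sa, sb = self._score([ha], "A"), self._score([hb], "B")
        records = find_overlaps([ha], [hb], motif_a, motif_b)
        assert records[0].ic_a == pytest.approx(6.0)
        ra, rb, rescored_a, rescored_b = resolve_overlaps(records, sa, sb)
        assert ra == [] and rb == []
        assert rescored_a == 1.0 and rescored_b == 1.0

    def test_boundary_ic_exactly_four_is_retained(self):
        motif_a = Motif("A", np.array(deterministic_columns(2) + uniform_columns(8)))
        motif_b = Motif("B", np.array(uniform_columns(6)))
        ha = make_hit(6, 0.01, width=10, motif_id="A")  # overlap = A local {0, 1}
        hb = make_hit(4, 0.02, width=6, motif_id="B")   # genomic 4..8 -> overlap {6, 7}
        sa, sb = self._score([ha], "A"), self._score([hb], "B")
        records = find_overlaps([ha], [hb], motif_a, motif_b)
        assert records[0].ic_a == pytest.approx(4.0)
        ra, rb, *_ = resolve_overlaps(records, sa, sb)
        assert ra == [ha] and rb == [hb]

    def test_equal_ic_different_length_same_decision(self):
        # total IC 5 concentrated in 3 columns vs diluted over 5 columns
        m_sharp = Motif("S", np.array(deterministic_columns(2)
                                      + [[0.5, 0.5, 0, 0]] * 1
                                      + uniform_columns(7)))
        # overlap of length 3 -> IC = 2 + 2 + 1 = 5 > 4
        m_long = Motif("L", np.array([[0.5, 0.5, 0, 0]] * 5 + uniform_columns(5)))
        # overlap of length 5 -> IC = 5 * 1 = 5 > 4
        motif_b = Motif("B", np.array(uniform_columns(6)))
        decisions = []
        for motif_a, ov in ((m_sharp, 3), (m_long, 5)):
            ha = make_hit(6, 0.01, width=10, motif_id=motif_a.motif_id)
            hb = make_hit(6 + ov - 6, 0.02, width=6, motif_id="B")
            sa = self._score([ha], motif_a.motif_id)
            sb = self._score([hb], "B")
            records = find_overlaps([ha], [hb], motif_a, motif_b)
            assert records[0].ic_a == pytest.approx(5.0)
            ra, rb, *_ = resolve_overlaps(records, sa, sb)
            decisions.append((len(ra), len(rb)))
        assert decisions[0] == decisions[1] == (0, 0)


@pytest.fixture(scope="module")
def world():
    rng = np.random.default_rng(99)
    universe = generate_background_promoters(120, 200, seed=11)
    motifs = [random_probability_motif(m, 6, rng) for m in ("A", "B")]
    cfg = RunConfig(n=60)
    indexes = index_universe(motifs, universe, None, cfg)
    return motifs, indexes


class TestColocalization:
    def test_symmetry_under_pair_swap(self, world):
        (ma, mb), idx = world
        common = sorted(idx["A"].member_genes & idx["B"].member_genes)
        assert len(common) >= 5
        for gene in common:
            ab = colocalization_test(gene, idx["A"], idx["B"], ma, mb)
            ba = colocalization_test(gene, idx["B"], idx["A"], mb, ma)
            assert ab.colocalized == ba.colocalized
            assert ab.rescored_a == pytest.approx(ba.rescored_b)
            assert ab.rescored_b == pytest.approx(ba.rescored_a)
        assert pair_positive_genes(idx["A"], idx["B"], ma, mb) == (
            pair_positive_genes(idx["B"], idx["A"], mb, ma)
        )

    def test_gene_missing_from_one_index_raises(self, world):
        (ma, mb), idx = world
        only_a = sorted(idx["A"].member_genes - idx["B"].member_genes)
        if only_a:
            with pytest.raises(KeyError):
                colocalization_test(only_a[0], idx["A"], idx["B"], ma, mb)

    def test_no_overlap_means_colocalized(self, world):
        (ma, mb), idx = world
        for gene in sorted(idx["A"].member_genes & idx["B"].member_genes):
            sa, sb = idx["A"].scores[gene], idx["B"].scores[gene]
            overlapping = any(
                ha.start < hb.end and hb.start < ha.end
                for ha in sa.selected_hits for hb in sb.selected_hits
            )
            if not overlapping:
                rec = colocalization_test(gene, idx["A"], idx["B"], ma, mb)
                assert rec.colocalized
                assert rec.rescored_a == sa.binom_score


class TestHypergeometric:
    def test_forced_full_draw(self):
        p = hypergeometric_pair_test(5, 20, 5, 5)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_observed_is_one(self):
        assert hypergeometric_pair_test(4, 10, 5, 0) == 1.0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_pair_test(4, 10, 5, 5)
        with pytest.raises(ValueError):
            hypergeometric_pair_test(11, 10, 5, 2)

    def test_matches_enumeration_universe_up_to_8(self):
        for universe in range(1, 9):
            for successes in range(universe + 1):
                for draws in range(universe + 1):
                    for observed in range(min(successes, draws) + 1):
                        got = hypergeometric_pair_test(
                            successes, universe, draws, observed
                        )
                        want = hypergeom_enumeration(
                            universe, successes, draws, observed
                        )
                        assert got == pytest.approx(float(want), rel=1e-10)

    def test_monotone_in_observed_count(self):
        previous = 1.1
        for observed in range(0, 9):
            p = hypergeometric_pair_test(10, 40, 12, observed)
            assert p <= previous + 1e-15
            previous = p


class TestBonferroniAndSets:
    def test_adjustment_examples(self):
        assert bonferroni_adjust(0.001, 50) == pytest.approx(0.05)
        assert bonferroni_adjust(0.5, 10) == 1.0
        assert bonferroni_adjust(0.123, 1) == pytest.approx(0.123)

    def test_equalize_truncates_to_smallest(self):
        small = GeneSet("cortex", tuple(f"g{i}" for i in range(12)))
        large = GeneSet("epidermis", tuple(f"h{i}" for i in range(30)))
        out = equalize_gene_sets([small, large])
        assert [s.size for s in out] == [12, 12]
        assert out[1].gene_ids == large.gene_ids[:12]

    def test_equalize_requires_ranking(self):
        small = GeneSet("s", ("a", "b"))
        large = GeneSet("l", ("c", "d", "e"), ranked=False)
        with pytest.raises(ValueError, match="ranked"):
            equalize_gene_sets([small, large])

    def test_equal_sizes_unchanged(self):
        sets = [GeneSet("x", ("a", "b")), GeneSet("y", ("c", "d"))]
        assert equalize_gene_sets(sets) == sets

    def test_load_gene_set_two_column_ranks_by_statistic(self, tmp_path):
        path = tmp_path / "set.tsv"
        path.write_text("gene1\t0.04\ngene2\t0.001\ngene3\t0.01\n")
        gs = load_gene_set(path)
        assert gs.gene_ids == ("gene2", "gene3", "gene1")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("dup", ("a", "a"))


class TestGeneSetTesting:
    def test_counts_and_bonferroni_m(self):
        positives = {
            ("A", "B"): {"g1", "g2", "g3"},
            ("A", "C"): {"g4"},
            ("B", "C"): set(),
        }
        universe = [f"g{i}" for i in range(1, 21)]
        gs = GeneSet("set1", ("g1", "g2", "g5", "missing"))
        df = evaluate_gene_sets(positives, universe, [gs])
        assert len(df) == 3
        row = df.set_index(["motif_a", "motif_b"]).loc[("A", "B")]
        assert row["set_size"] == 3          # 'missing' dropped
        assert row["dropped_genes"] == 1
        assert row["pair_positive_in_set"] == 2
        assert row["m_pairs"] == 3
        expected_raw = hypergeometric_pair_test(3, 20, 3, 2)
        assert row["raw_p"] == pytest.approx(expected_raw)
        assert row["adj_p"] == pytest.approx(min(1.0, expected_raw * 3))

    def test_all_pairs_excludes_self_by_default(self):
        assert all_motif_pairs(["a", "b", "c"]) == [
            ("a", "b"), ("a", "c"), ("b", "c")
        ]
        assert ("a", "a") in all_motif_pairs(["a", "b"], include_self=True)


class TestPairMatrix:
    def test_symmetric_fill_and_missing(self):
        df = pd.DataFrame(
            [{"motif_a": "A", "motif_b": "B", "adj_p": 0.001}]
        )
        mat = pair_matrix(df, ["A", "B", "C"])
        assert mat.loc["A", "B"] == pytest.approx(3.0)
        assert mat.loc["B", "A"] == pytest.approx(3.0)
        assert np.isnan(mat.loc["A", "C"])

    def test_insignificant_pairs_give_zero(self):
        df = pd.DataFrame(
            [{"motif_a": a, "motif_b": b, "adj_p": 1.0}
             for a, b in [("A", "B"), ("A", "C"), ("B", "C")]]
        )
        mat = pair_matrix(df, ["A", "B", "C"])
        off_diag = mat.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off_diag, 0.0)

    def test_unknown_motif_rejected(self):
        df = pd.DataFrame([{"motif_a": "A", "motif_b": "Z", "adj_p": 0.5}])
        with pytest.raises(ValueError, match="Z"):
            pair_matrix(df, ["A", "B"])

    def test_round_trip_preserves_six_decimals(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = [
            {"motif_a": a, "motif_b": b, "adj_p": float(rng.uniform(1e-8, 1.0))}
            for a, b in itertools.combinations("ABCD", 2)
        ]
        mat = pair_matrix(pd.DataFrame(rows), list("ABCD"))
        path = tmp_path / "matrix.tsv"
        write_pair_matrix(mat, path)
        back = read_pair_matrix(path)
        for a, b in itertools.combinations("ABCD", 2):
            assert back.loc[a, b] == pytest.approx(mat.loc[a, b], abs=5e-7)
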