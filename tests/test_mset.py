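import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pymset import mset
from pymset.io import GeneSet, ProbeAnnotation
from pymset.mset import (Background, MsetNull, SignificantList, count_matches,
                         derive_stream_seed, draw_null, hypergeom_oracle,
                         mset_pvalue, null_diagnostics, select_significant)


def _de(pvals: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"p_nominal": pd.Series(pvals)})


def _gene_background(n: int) -> Background:
    return Background(mode="gene",
                      probe_symbols=tuple(f"G{i}" for i in range(n)))


class TestSelectSignificant:
    def test_any_probe_rule_and_unannotated_dropped(self):
        de = _de({"p1": 0.001, "p2": 0.01, "p3": 0.015, "p4": 0.5})
        ann = ProbeAnnotation(symbol_of_probe={
            "p1": "A", "p2": "A", "p3": "", "p4": "B"})
        sig = select_significant(de, ann, threshold=0.02)
        assert sig.symbols == frozenset({"A"})
        assert sig.n == 1

    def test_threshold_one_selects_all_annotated(self, annotation):
        de = _de({p: 0.5 for p in annotation.probe_ids})
        sig = select_significant(de, annotation, threshold=1.0)
        assert sig.symbols == annotation.unique_symbols()

    def test_strict_inequality_at_threshold(self):
        de = _de({"p1": 0.02, "p2": 0.0199})
        ann = ProbeAnnotation(symbol_of_probe={"p1": "A", "p2": "B"})
        assert select_significant(de, ann, 0.02).symbols == frozenset({"B"})

    def test_empty_selection_advises_looser_threshold(self):
        de = _de({"p1": 0.9})
        ann = ProbeAnnotation(symbol_of_probe={"p1": "A"})
        with pytest.raises(ValueError, match="looser"):
            select_significant(de, ann, threshold=0.01)


class TestCountMatches:
    @pytest.mark.parametrize("a, b, expected", [
        ({"A", "B", "C"}, {"B", "C", "D"}, 2),
        ({"A"}, {"B"}, 0),
        ({"A", "B"}, {"A", "B", "C"}, 2)])
    def test_intersection_cardinality(self, a, b, expected):
        assert count_matches(a, b) == expected


class TestDrawNull:
    def test_disjoint_set_puts_all_mass_at_zero(self):
        bg = _gene_background(10)
        null = draw_null(bg, 3, {"X", "Y"}, draws=500, seed=1)
        assert null.match_counts == {0: 500}

    def test_superset_puts_all_mass_at_n(self):
        bg = _gene_background(10)
        null = draw_null(bg, 4, set(bg.probe_symbols), draws=300, seed=1)
        assert null.match_counts == {4: 300}

    def test_identical_seed_identical_histogram(self):
        bg = _gene_background(50)
        kw = dict(n=10, gene_set={f"G{i}" for i in range(15)}, draws=2000)
        a = draw_null(bg, kw["n"], kw["gene_set"], kw["draws"], seed=99)
        b = draw_null(bg, kw["n"], kw["gene_set"], kw["draws"], seed=99)
        assert a.match_counts == b.match_counts

    def test_list_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            draw_null(_gene_background(5), 6, {"G0"}, draws=10, seed=0)

    def test_null_mean_matches_hypergeometric_expectation(self):
        N, K, n = 200, 40, 30
        bg = _gene_background(N)
        null = draw_null(bg, n, {f"G{i}" for i in range(K)},
                         draws=20_000, seed=4)
        expected = n * K / N
        sd_mean = null.sd() / np.sqrt(null.draws)
        assert abs(null.mean() - expected) <= 4 * sd_mean

    def test_probe_mode_collapses_duplicate_probes(self):
        # one gene on 3 probes: a randomized list hitting several of its
        # probes still counts one match
        bg = Background(mode="probe",
                        probe_symbols=("A", "A", "A", "B", "C"))
        null = draw_null(bg, 4, {"A"}, draws=2000, seed=2)
        assert max(null.support()) <= 1

    def test_histogram_counts_sum_to_draws(self):
        bg = _gene_background(30)
        null = draw_null(bg, 7, {f"G{i}" for i in range(9)},
                         draws=1234, seed=8)
        assert sum(null.match_counts.values()) == 1234


class TestMsetPvalue:
    def test_zero_observed_gives_one(self):
        null = MsetNull(draws=100, match_counts={0: 60, 1: 40}, seed=0,
                        background_size=10, list_size=2)
        assert mset_pvalue(0, null) == 1.0

    def test_direct_formula_with_pseudocount(self):
        null = MsetNull(draws=10_000, match_counts={0: 9_990, 1: 10},
                        seed=0, background_size=100, list_size=5)
        assert mset_pvalue(1, null) == pytest.approx(11 / 10_001)

    def test_beyond_support_gives_floor(self):
        null = MsetNull(draws=1000, match_counts={0: 1000}, seed=0,
                        background_size=10, list_size=2)
        assert mset_pvalue(5, null) == pytest.approx(1 / 1001)

    def test_plain_proportion_option(self):
        null = MsetNull(draws=1000, match_counts={0: 990, 1: 10}, seed=0,
                        background_size=100, list_size=5)
        assert mset_pvalue(1, null, pseudocount=False) == pytest.approx(0.01)
        assert mset_pvalue(2, null, pseudocount=False) == 0.0

    @given(st.integers(min_value=0, max_value=12))
    def test_non_increasing_in_observed(self, x):
        null = MsetNull(draws=1023, seed=0, background_size=40, list_size=10,
                        match_counts={k: 2 ** (9 - k) for k in range(10)})
        assert mset_pvalue(x, null) >= mset_pvalue(x + 1, null)


class TestHypergeomOracle:
    def test_worked_micro_example(self):
        # exact enumeration over all C(20,4) draws gives 155/4845
        assert hypergeom_oracle(20, 5, 4, 3) == pytest.approx(
            155 / 4845, rel=1e-12)

    def test_zero_observed_is_certain(self):
        assert hypergeom_oracle(50, 10, 5, 0) == 1.0

    def test_full_overlap_certain_event(self):
        assert hypergeom_oracle(8, 8, 3, 3) == pytest.approx(1.0)

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_oracle(10, 12, 3, 1)
        with pytest.raises(ValueError):
            hypergeom_oracle(10, 4, 3, 4)


class TestNullDiagnostics:
    def test_degenerate_null_trips_all_flags(self):
        null = MsetNull(draws=100, match_counts={0: 100}, seed=0,
                        background_size=10, list_size=2)
        d = null_diagnostics(null)
        assert d.few_support_points and d.narrow_sd and d.mass_concentrated

    def test_three_point_support_flagged_discrete(self):
        null = MsetNull(draws=300, match_counts={0: 100, 1: 100, 2: 100},
                        seed=0, background_size=10, list_size=3)
        assert null_diagnostics(null).few_support_points

    def test_broad_null_carries_no_flags(self):
        # hypergeometric-like null: wide support, sd > 2, diffuse mode
        N, K, n = 400, 100, 40
        bg = _gene_background(N)
        null = draw_null(bg, n, {f"G{i}" for i in range(K)},
                         draws=20_000, seed=6)
        d = null_diagnostics(null)
        assert null.sd() > 2
        assert len(null.support()) >= 12
        assert null.max_mass_fraction() < 0.2
        assert not d.few_support_points
        assert not d.narrow_sd
        assert not d.mass_concentrated


class TestStreams:
    def test_seed_derivation_is_stable_and_label_sensitive(self):
        a = derive_stream_seed(7, "BPD", "SZGene")
        assert a == derive_stream_seed(7, "BPD", "SZGene")
        assert a != derive_stream_seed(7, "BPD", "GAD")
        assert a != derive_stream_seed(8, "BPD", "SZGene")
        assert 0 <= a < 2 ** 31

    def test_adding_a_set_does_not_perturb_others(self, annotation):
        bg = Background.from_annotation(annotation, mode="gene")
        sig = SignificantList(threshold=0.02,
                              symbols=frozenset({"FABP7", "GRM3"}))
        gs = GeneSet("BPD", "SZGene", frozenset({"FABP7"}))
        alone = mset.test_gene_set(sig, bg, gs, draws=500, master_seed=3)
        other = GeneSet("autism", "AGD", frozenset({"NR1D1"}))
        from pymset.io import GeneSetCollection
        both = mset.test_collection(
            sig, bg, GeneSetCollection(entries=(other, gs)),
            draws=500, master_seed=3)
        assert both[1].null.match_counts == alone.null.match_counts
        assert both[1].p_value == alone.p_value


class TestGeneModeOracleAgreement:
    def test_small_grid_tail_matches_hypergeometric(self):
        R = 20_000
        for N, K, n in [(20, 5, 4), (15, 6, 5)]:
            bg = _gene_background(N)
            null = draw_null(bg, n, {f"G{i}" for i in range(K)},
                             draws=R, seed=13)
            for x in range(min(n, K) + 1):
                exact = hypergeom_oracle(N, K, n, x)
                mc = mset_pvalue(x, null, pseudocount=False)
                se = np.sqrt(exact * (1 - exact) / R)
                assert abs(mc - exact) <= 3 * se + 1e-12
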