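"""Isolation-index arithmetic, aggregation paths, and sensitivity analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import reinfiso as rf
from reinfiso.errors import DomainError
from reinfiso.trial_io import Behavior, Context, Target

from conftest import make_counts

# zero or well away from zero: subnormal counts are not meaningful means
means = st.one_of(
    st.just(0.0), st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)
)


class TestIsolationIndex:
    @pytest.mark.parametrize(
        "c,h,expected",
        [
            (44.3, 6.0, 0.76),
            (162.0, 63.0, 0.44),
            (102.3, 7.3, 0.87),
            (58.7, 9.7, 0.72),
            (114.3, 1.0, 0.98),
            (237.0, 0.0, 1.00),
        ],
    )
    def test_published_table_cells(self, c, h, expected):
        assert round(rf.isolation_index(c, h), 2) == pytest.approx(expected)

    def test_symmetry_zero(self):
        assert rf.isolation_index(5.0, 5.0) == 0.0

    def test_both_zero_missing(self):
        assert rf.isolation_index(0.0, 0.0) is None

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            rf.isolation_index(-1.0, 2.0)

    @given(means, means)
    def test_bounded_antisymmetric(self, c, h):
        i = rf.isolation_index(c, h)
        if i is None:
            assert c == h == 0
        else:
            assert -1 <= i <= 1
            assert rf.isolation_index(h, c) == pytest.approx(-i)
            assert (i == 1.0) == (h == 0 < c)

    @given(means, means, st.floats(min_value=0.01, max_value=1e3))
    def test_scale_invariance(self, c, h, k):
        i = rf.isolation_index(c, h)
        if i is not None:
            assert rf.isolation_index(k * c, k * h) == pytest.approx(i)


class TestBehaviorTable:
    def test_replicate_means_feed_index(self, single_group_counts):
        (est,) = rf.behavior_isolation_table(single_group_counts)
        assert est.conspecific_mean == pytest.approx(44.333, abs=1e-3)
        assert est.heterospecific_mean == pytest.approx(6.0)
        assert round(est.i_index, 2) == 0.76
        assert est.conspecific_sd == pytest.approx(np.std([40, 44, 49], ddof=1))

    def test_single_replicate_sd_undefined(self):
        counts = make_counts(
            [("R1", "P", "sympatric", "S", "chase_mf", "conspecific", 10),
             ("R1", "P", "sympatric", "S", "chase_mf", "heterospecific", 10)]
        )
        (est,) = rf.behavior_isolation_table(counts)
        assert est.i_index == 0.0 and est.conspecific_sd is None

    def test_all_zero_behavior_missing(self):
        counts = make_counts(
            [("R1", "P", "sympatric", "S", "spawn", "conspecific", 0),
             ("R1", "P", "sympatric", "S", "spawn", "heterospecific", 0)]
        )
        (est,) = rf.behavior_isolation_table(counts)
        assert est.i_index is None


def five_behavior_replicate(pairs, rep="R1", pop="P", ctx="sympatric", sp="S"):
    rows = []
    for b, (c, h) in zip(Behavior, pairs):
        rows.append((rep, pop, ctx, sp, b.value, "conspecific", c))
        rows.append((rep, pop, ctx, sp, b.value, "heterospecific", h))
    return rows


class TestTotals:
    def test_replicate_total_hand_sum(self):
        counts = make_counts(
            five_behavior_replicate([(2, 0), (5, 1), (10, 2), (20, 4), (30, 5)])
        )
        (est,) = rf.total_isolation_per_replicate(counts)
        assert est.conspecific_mean == 67 and est.heterospecific_mean == 12
        assert est.i_index == pytest.approx(0.6962, abs=1e-4)

    def test_all_het_zero_boundary(self):
        counts = make_counts(
            five_behavior_replicate([(2, 0), (5, 0), (10, 0), (20, 0), (30, 0)])
        )
        (est,) = rf.total_isolation_per_replicate(counts)
        assert est.i_index == 1.0

    def test_single_behavior_subset_equals_behavior_index(self, single_group_counts):
        (tot,) = rf.population_total_isolation(single_group_counts, {Behavior.CHASE_MF})
        (beh,) = rf.behavior_isolation_table(single_group_counts)
        assert tot.i_index == pytest.approx(beh.i_index)

    def test_population_averages_counts_not_indices(self):
        rows = []
        for i, (c, h) in enumerate([(10, 0), (20, 10), (30, 20)], start=1):
            rows += [(f"R{i}", "P", "sympatric", "S", "chase_mm", "conspecific", c),
                     (f"R{i}", "P", "sympatric", "S", "chase_mm", "heterospecific", h)]
        (est,) = rf.population_total_isolation(make_counts(rows), {Behavior.CHASE_MM})
        # means (20, 10) -> 1/3; averaging per-replicate I would give ~0.478
        assert est.i_index == pytest.approx(1 / 3)

    def test_one_replicate_degenerates_to_replicate_total(self):
        counts = make_counts(five_behavior_replicate([(2, 1), (3, 0), (4, 2), (5, 5), (6, 3)]))
        (pop,) = rf.population_total_isolation(counts)
        (rep,) = rf.total_isolation_per_replicate(counts)
        assert pop.i_index == pytest.approx(rep.i_index)

    def test_doubling_counts_invariant(self, single_group_counts):
        doubled = make_counts(
            [(c.replicate_id, c.population, c.context.value, c.species,
              c.behavior.value, c.target.value, 2 * c.count)
             for c in single_group_counts]
        )
        (a,) = rf.population_total_isolation(single_group_counts, {Behavior.CHASE_MF})
        (b,) = rf.population_total_isolation(doubled, {Behavior.CHASE_MF})
        assert a.i_index == pytest.approx(b.i_index)

    def test_empty_subset_rejected(self, single_group_counts):
        with pytest.raises(DomainError):
            rf.total_isolation_per_replicate(single_group_counts, set())


class TestSensitivity:
    def test_drop_none_is_identity(self, paper_like):
        full, reduced = rf.exclude_behaviors_sensitivity(paper_like.stream_counts, [])
        assert full == reduced

    def test_drop_all_rejected(self, paper_like):
        with pytest.raises(DomainError):
            rf.exclude_behaviors_sensitivity(paper_like.stream_counts, list(Behavior))

    def test_reduced_totals_exclude_dropped(self):
        counts = make_counts(
            five_behavior_replicate([(2, 0), (5, 1), (10, 2), (20, 4), (30, 5)])
        )
        full, reduced = rf.exclude_behaviors_sensitivity(
            counts, [Behavior.SOLICIT_SUCCESS, Behavior.SOLICIT_FAIL]
        )
        # complement: spawn (2,0) + chase_mm (20,4) + chase_mf (30,5)
        assert reduced[0].conspecific_mean == 52 and reduced[0].heterospecific_mean == 9
        assert full[0].conspecific_mean == 67

    def test_context_effect_lives_in_solicitation(self, paper_like):
        """The generator puts the sympatry-allopatry contrast in male
        solicitation; dropping it should erase the GLS context effect."""
        full, reduced = rf.exclude_behaviors_sensitivity(
            paper_like.stream_counts, [Behavior.SOLICIT_SUCCESS, Behavior.SOLICIT_FAIL]
        )
        g_full = rf.fit_total_isolation_gls(full, resident_species="E. barrenense")
        g_red = rf.fit_total_isolation_gls(reduced, resident_species="E. barrenense")
        assert g_full.coefficients["context[sympatric]"].p_value < 0.05
        assert g_red.coefficients["context[sympatric]"].p_value > 0.05


class TestResidentCoding:
    def test_resident_species_coded_sympatric(self, paper_like):
        reps = rf.total_isolation_per_replicate(paper_like.stream_counts)
        coded = rf.apply_resident_context(reps, "E. barrenense")
        for e in coded:
            if e.species == "E. barrenense":
                assert e.context is Context.SYMPATRIC
        focal = [e for e in coded if e.species == "E. zonale"]
        assert {e.context for e in focal} == {Context.SYMPATRIC, Context.ALLOPATRIC}
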