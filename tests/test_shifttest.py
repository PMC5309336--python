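"""Permutation shift test: degenerate cases, calibration, BH, summaries."""

import numpy as np
import pytest

from cnflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    bh_adjust,
    build_category_map,
    compare_hit_sets,
    make_planted_samples,
    shift_statistic,
    summarize_groups,
    test_all as run_shift_tests,
)
from cnflux.sampling import FluxSampleSet
from cnflux.shifttest import ShiftTestResult
from cnflux.synth import PlantedShiftSpec


class TestShiftStatistic:
    def test_full_separation_gives_zero(self):
        rng = np.random.default_rng(0)
        v_low = rng.uniform(0, 1, 200)
        v_high = rng.uniform(5, 6, 200)
        stat, p = shift_statistic(v_low, v_high, seed=1)
        assert stat == 0.0 and p == 0.0

    def test_identical_constant_vectors_give_one(self):
        v = np.full(50, 3.14)
        stat, p = shift_statistic(v, v.copy(), seed=1)
        assert p == 1.0

    def test_null_is_conservative(self):
        # identical sampling distributions: p concentrates near 1
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(50):
            stat, p = shift_statistic(
                rng.normal(0, 1, 500), rng.normal(0, 1, 500),
                seed=int(rng.integers(2**31)),
            )
            ps.append(p)
        ps = np.asarray(ps)
        assert np.mean(ps < 0.05) <= 0.07
        assert np.median(ps) > 0.9

    def test_two_sd_shift_is_below_the_detection_floor(self):
        # the minority-sign fraction at a 2 sd shift of unit normals
        # concentrates at Phi(-sqrt(2)) ~ 0.079, so p ~ 0.157: the test
        # responds to near-disjoint supports, not moderate shifts
        rng = np.random.default_rng(6)
        ps = [
            shift_statistic(
                rng.normal(0, 1, 500), rng.normal(2, 1, 500),
                seed=int(rng.integers(2**31)),
            )[1]
            for _ in range(20)
        ]
        assert 0.10 < np.mean(ps) < 0.25

    def test_large_separation_is_detected(self):
        rng = np.random.default_rng(7)
        ps = [
            shift_statistic(
                rng.normal(0, 1, 500), rng.normal(6, 1, 500),
                seed=int(rng.integers(2**31)),
            )[1]
            for _ in range(20)
        ]
        assert max(ps) < 0.01

    def test_p_lies_on_the_statistic_grid(self):
        rng = np.random.default_rng(8)
        n, reps = 40, 10
        v_low, v_high = rng.normal(0, 1, n), rng.normal(1, 1, n)
        stat, p = shift_statistic(v_low, v_high, n_repeats=reps, seed=3)
        # stat is a mean of integers over reps, scaled by n
        grid_val = stat * n * reps
        assert grid_val == pytest.approx(round(grid_val), abs=1e-9)
        assert p == min(1.0, 2.0 * stat)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            shift_statistic(np.zeros(5), np.zeros(6))
        with pytest.raises(ValueError):
            shift_statistic(np.zeros(5), np.zeros(5), n_repeats=0)


class TestBhAdjust:
    def test_closed_form_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_value(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_monotone_and_dominating(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTestAll:
    def test_identical_sets_nothing_significant(self):
        low, _, _ = make_planted_samples(PlantedShiftSpec(10, 0, 200, 0.0, seed=3))
        results, skipped = run_shift_tests(low, low, seed=4)
        assert skipped == []
        assert not any(r.significant for r in results)

    def test_alpha_zero_nothing_significant(self):
        low, high, _ = make_planted_samples(PlantedShiftSpec(5, 5, 200, 6.0, seed=3))
        results, _ = run_shift_tests(low, high, alpha=0.0, seed=4)
        assert not any(r.significant for r in results)

    def test_widely_separated_columns_are_flagged_up(self):
        low, high, truth = make_planted_samples(
            PlantedShiftSpec(20, 5, 400, 6.0, seed=5)
        )
        results, _ = run_shift_tests(low, high, seed=6)
        sig = {r.reaction_id for r in results if r.significant}
        assert sig == truth
        assert all(r.direction == "up" for r in results if r.significant)

    def test_non_shared_reactions_are_skipped(self):
        low, high, _ = make_planted_samples(PlantedShiftSpec(4, 0, 100, 0.0, seed=7))
        high2 = FluxSampleSet(
            [f"other_{i}" for i in range(3)] + high.reaction_ids[3:],
            high.samples,
        )
        results, skipped = run_shift_tests(low, high2, seed=8)
        assert len(results) == 1
        assert len(skipped) == 6

    def test_no_shared_reactions_is_an_error(self):
        low, _, _ = make_planted_samples(PlantedShiftSpec(4, 0, 100, 0.0, seed=7))
        other = FluxSampleSet(["x1", "x2", "x3", "x4"], low.samples)
        with pytest.raises(ValueError, match="share"):
            run_shift_tests(low, other)

    def test_seeded_determinism(self):
        low, high, _ = make_planted_samples(PlantedShiftSpec(10, 5, 300, 3.0, seed=9))
        r1, _ = run_shift_tests(low, high, seed=11)
        r2, _ = run_shift_tests(low, high, seed=11)
        assert [(r.reaction_id, r.p_value, r.q_value) for r in r1] == [
            (r.reaction_id, r.p_value, r.q_value) for r in r2
        ]


@pytest.fixture()
def pigment_model():
    """Small model with 7 pigment reactions and a few others."""
    mets = [Metabolite("m_c", "", "c")]
    rxns = []
    for i in range(7):
        rxns.append(Reaction(f"PIG{i}", {"m_c": 1 if i % 2 else -1}, 0, 10,
                             gpr=f"gP{i}", subsystem="pigment metabolism"))
    rxns.append(Reaction("TRA", {"m_c": -1}, 0, 10, gpr="gT", subsystem="transport"))
    rxns.append(Reaction("NOGENE", {"m_c": -1}, 0, 10, gpr="",
                         subsystem="pigment metabolism"))
    return MetabolicModel("pig", mets, rxns, objective_id="TRA")


class TestSummarizeGroups:
    def _results(self, ids, sig_up=(), sig_down=()):
        out = []
        for rid in ids:
            r = ShiftTestResult(rid, 0.0, 1.0, q_value=1.0)
            if rid in sig_up:
                r.significant, r.direction, r.q_value = True, "up", 0.01
            elif rid in sig_down:
                r.significant, r.direction, r.q_value = True, "down", 0.01
            out.append(r)
        return out

    def test_percentages_over_group_size(self, pigment_model):
        results = self._results(
            [r.id for r in pigment_model.reactions],
            sig_up={"PIG0", "PIG1", "PIG2"},
        )
        cmap = build_category_map()
        summaries = {s.group: s for s in summarize_groups(results, pigment_model, cmap)}
        pig = summaries["pigments"]
        assert pig.n_reactions_in_group == 8  # incl. the GPR-less reaction
        assert pig.n_up == 3
        assert pig.pct_up == pytest.approx(100 * 3 / 8)

    def test_gene_associated_filter(self, pigment_model):
        results = self._results(
            [r.id for r in pigment_model.reactions], sig_up={"NOGENE"}
        )
        cmap = build_category_map()
        summaries = {s.group: s for s in summarize_groups(results, pigment_model, cmap)}
        assert summaries["pigments"].n_up == 0
        summaries2 = {
            s.group: s
            for s in summarize_groups(results, pigment_model, cmap,
                                      gene_associated_only=False)
        }
        assert summaries2["pigments"].n_up == 1

    def test_nothing_significant_means_zero_percent(self, pigment_model):
        results = self._results([r.id for r in pigment_model.reactions])
        for s in summarize_groups(results, pigment_model, build_category_map()):
            assert s.pct_up == 0.0 and s.pct_down == 0.0


class TestCompareHitSets:
    def test_disjoint_sets_share_nothing(self, pigment_model):
        table = compare_hit_sets({"PIG0"}, {"gT"}, pigment_model)
        assert (table["shared"] == 0).all()

    def test_identical_sets_have_no_unique(self, pigment_model):
        table = compare_hit_sets({"PIG0", "PIG1"}, {"gP0", "gP1"}, pigment_model)
        assert (table["sampling_only"] == 0).all()
        assert (table["de_only"] == 0).all()
        assert table["shared"].sum() == 2
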