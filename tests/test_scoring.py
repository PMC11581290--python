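"""Preservation and combined degradation scores."""

import numpy as np
import pytest

from gelflq.background import background_from_lanes
from gelflq.model import LanePartition, LaneProfile, ZoneWindow
from gelflq.scoring import (
    ScoringOptions,
    combined_score,
    normalize_to_control,
    preservation_score_single,
    preservation_score_total_rna,
    score_run,
)
from gelflq.synthetic import ExperimentSpec, TimePoint, synth_experiment


def make_partition(pairs, label="lane"):
    """Partition with given (peak_auc, degradation_auc) pairs; windows synthetic."""
    n = len(pairs)
    pw, dw = [], []
    for k in range(n):
        start = 100 * k + 50
        pw.append(ZoneWindow(start, start + 20, "peak"))
        dw.append(ZoneWindow(start - 40, start, "degradation"))
    return LanePartition(
        label=label,
        peak_windows=tuple(pw),
        degradation_windows=tuple(dw),
        peak_aucs=tuple(p for p, _ in pairs),
        degradation_aucs=tuple(d for _, d in pairs),
    )


class TestNormalization:
    def test_fold_change(self):
        assert normalize_to_control(50.0, 100.0) == 0.5

    def test_control_against_itself_is_one(self):
        assert normalize_to_control(123.4, 123.4) == 1.0

    def test_zero_signal_gives_zero(self):
        assert normalize_to_control(0.0, 100.0) == 0.0

    def test_dead_control_rejected(self):
        with pytest.raises(ValueError, match="control lane has no measurable signal"):
            normalize_to_control(10.0, 0.0)


class TestPreservationSingle:
    def test_pure_product_scores_one(self):
        assert preservation_score_single(100.0, 0.0) == 1.0

    def test_stated_arithmetic(self):
        assert preservation_score_single(60.0, 40.0) == pytest.approx(0.6)

    def test_empty_lane_rejected(self):
        with pytest.raises(ValueError, match="empty lane"):
            preservation_score_single(0.0, 0.0)

    def test_strictly_decreasing_in_smear_fraction(self, law_cal):
        spec = ExperimentSpec(
            timepoints=tuple(
                TimePoint(f"f{int(f*100)}", (2000.0,), f) for f in (0.0, 0.2, 0.4, 0.6, 0.8)
            ),
            replicates=1,
            base_seed=21,
        )
        runs, _ = synth_experiment(spec)
        run = runs[0]
        bg = background_from_lanes(run.background_lanes)
        records = score_run(run, options=ScoringOptions(background=bg))
        scores = [r.preservation_raw for r in records]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestPreservationTotalRna:
    def test_control_is_one(self):
        assert preservation_score_total_rna(1.0, 1.0) == 1.0

    def test_stated_product(self):
        assert preservation_score_total_rna(0.8, 0.5) == pytest.approx(0.4)

    def test_symmetric(self):
        assert preservation_score_total_rna(0.3, 0.7) == preservation_score_total_rna(0.7, 0.3)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            preservation_score_total_rna(0.0, 0.5)


class TestCombinedScore:
    def test_control_against_itself_is_one(self):
        part = make_partition([(100.0, 20.0), (80.0, 10.0)])
        assert combined_score(part, part) == 1.0

    def test_single_peak_reduces_to_normalized_preservation(self):
        sample = make_partition([(60.0, 40.0)])
        control = make_partition([(90.0, 10.0)])
        expected = preservation_score_single(60.0, 40.0) / preservation_score_single(90.0, 10.0)
        assert combined_score(sample, control) == pytest.approx(expected)

    def test_peak_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="peak count"):
            combined_score(make_partition([(1.0, 0.0)]), make_partition([(1.0, 0.0), (1.0, 0.0)]))

    def test_faster_degrading_arm_scores_lower_at_every_time(self):
        def arm(fracs, seed):
            tps = tuple(
                TimePoint(lbl, (1869.0, 5070.0), f, 1.0 - 0.4 * f)
                for lbl, f in fracs
            )
            return ExperimentSpec(timepoints=tps, replicates=1, base_seed=seed)

        labels = ["t0", "t1", "t2", "t3"]
        slow = arm(zip(labels, (0.02, 0.10, 0.20, 0.30)), 31)
        fast = arm(zip(labels, (0.02, 0.30, 0.50, 0.70)), 31)
        results = {}
        for name, spec in (("slow", slow), ("fast", fast)):
            run = synth_experiment(spec)[0][0]
            bg = background_from_lanes(run.background_lanes)
            recs = score_run(
                run, options=ScoringOptions(mode="two-peak", background=bg, min_separation=30)
            )
            results[name] = {r.condition: r.combined_norm for r in recs}
        for label in ["t1", "t2", "t3"]:
            assert results["fast"][label] < results["slow"][label]


class TestScoreRun:
    def test_one_record_per_lane_control_first(self, ivt_experiment, law_cal):
        _, runs, _ = ivt_experiment
        run = runs[0]
        bg = background_from_lanes(run.background_lanes)
        records = score_run(run, cal=law_cal, options=ScoringOptions(background=bg))
        assert [r.condition for r in records] == ["control", "day2", "day4", "day7", "day10"]

    def test_control_identities_exact(self, ivt_experiment):
        _, runs, _ = ivt_experiment
        run = runs[0]
        bg = background_from_lanes(run.background_lanes)
        control = score_run(run, options=ScoringOptions(background=bg))[0]
        assert control.preservation_norm == 1.0
        assert control.combined_norm == 1.0
        assert control.peak_aucs_norm == (1.0,)

    def test_peak_auc_monotone_under_monotone_degradation(self, ivt_experiment):
        _, runs, _ = ivt_experiment
        for run in runs:
            bg = background_from_lanes(run.background_lanes)
            records = score_run(run, options=ScoringOptions(background=bg))
            # generator degrades monotonically: amplitude_scale and (1 - smear) both fall
            peaks = [r.peak_aucs[0] for r in records]
            assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_missing_control_rejected(self, ivt_experiment):
        _, runs, _ = ivt_experiment
        run = runs[0]
        import dataclasses

        broken = dataclasses.replace(run, control=None)
        with pytest.raises(ValueError, match="control"):
            score_run(broken)

    def test_short_lanes_rejected(self):
        from gelflq.model import GelRun

        short = lambda label: LaneProfile(label, np.full(20, 5.0))
        run = GelRun("g", "", None, [], short("c"), {"s": short("s")})
        with pytest.raises(ValueError, match="too short"):
            score_run(run)

    def test_scale_invariance_of_normalized_scores(self, ivt_experiment):
        _, runs, _ = ivt_experiment
        run = runs[0]
        import dataclasses

        gain = 3.7
        scaled = dataclasses.replace(
            run,
            ladder=run.ladder.with_values(run.ladder.values * gain),
            background_lanes=[b.with_values(b.values * gain) for b in run.background_lanes],
            control=run.control.with_values(run.control.values * gain),
            samples={k: v.with_values(v.values * gain) for k, v in run.samples.items()},
        )
        for r_orig, r_scaled in zip(
            score_run(run, options=ScoringOptions(background=background_from_lanes(run.background_lanes))),
            score_run(scaled, options=ScoringOptions(background=background_from_lanes(scaled.background_lanes))),
        ):
            assert r_scaled.preservation_norm == pytest.approx(r_orig.preservation_norm, rel=1e-9)
            assert r_scaled.combined_norm == pytest.approx(r_orig.combined_norm, rel=1e-9)
            for a, b in zip(r_scaled.peak_aucs_norm, r_orig.peak_aucs_norm):
                assert a == pytest.approx(b, rel=1e-9)

    def test_strategy_injection(self, ivt_experiment):
        _, runs, _ = ivt_experiment
        run = runs[0]
        bg = background_from_lanes(run.background_lanes)
        harsh = lambda p, d: p / (p + 2.0 * d)  # double weight on the smear
        default = score_run(run, options=ScoringOptions(background=bg))
        custom = score_run(run, options=ScoringOptions(background=bg, strategy=harsh))
        assert custom[1].preservation_raw < default[1].preservation_raw

    def test_normalization_reduces_replicate_variability(self, law_cal):
        # lane-level gain jitter: CV of normalized scores <= CV of raw scores
        import dataclasses

        spec = ExperimentSpec(base_seed=77, replicates=6)
        runs, _ = synth_experiment(spec)
        rng = np.random.default_rng(5)
        raw, norm = {}, {}
        for run in runs:
            gain = float(rng.uniform(0.6, 1.6))
            jittered = dataclasses.replace(
                run,
                ladder=run.ladder,
                background_lanes=[b.with_values(b.values * gain) for b in run.background_lanes],
                control=run.control.with_values(run.control.values * gain),
                samples={k: v.with_values(v.values * gain) for k, v in run.samples.items()},
            )
            bg = background_from_lanes(jittered.background_lanes)
            for rec in score_run(jittered, options=ScoringOptions(background=bg)):
                raw.setdefault(rec.condition, []).append(rec.peak_aucs[0])
                norm.setdefault(rec.condition, []).append(rec.peak_aucs_norm[0])
        for condition in ("day2", "day4", "day7", "day10"):
            cv = lambda xs: np.std(xs) / np.mean(xs)
            assert cv(norm[condition]) <= cv(raw[condition]) + 1e-9
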