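import dataclasses
import json

import pytest

from dbsteer.lead import DIRECTIONAL, RING, DomainError, ExplorationPoint
from dbsteer.optimizer import (
    AlgorithmConfig,
    SpaceExhaustedError,
    burden_report,
    check_convergence,
    directional_stage_required,
    init_stage,
    run_hemisphere,
    run_stage,
    suggest_next,
)
from dbsteer.patient_sim import make_patient, make_responder
from dbsteer.score_map import ScoreMap
from dbsteer.scoring import select_symptoms
from dbsteer.session_io import session_to_dict


def constant_responder(spec, value=2.0, side_effect=False):
    scores = {sid: value for sid in spec.symptom_ids}

    def responder(setting):
        return dict(scores), side_effect

    return responder


class TestInitStage:
    def test_three_ring_points(self, config):
        points = init_stage(RING, config)
        assert [(p.coord1, p.amplitude) for p in points] == [
            (0.5, 3.0), (1.5, 4.0), (2.5, 3.0),
        ]

    def test_four_directional_points(self, config):
        points = init_stage(DIRECTIONAL, config)
        assert [p.coord1 for p in points] == [0.0, 90.0, 180.0, 270.0]
        assert all(p.amplitude == 3.5 for p in points)

    def test_wrong_stage_label(self, config):
        with pytest.raises(DomainError):
            init_stage("axial", config)

    def test_point_counts_enforced(self):
        with pytest.raises(ValueError):
            AlgorithmConfig(predefined_ring_points=((0.5, 1.0), (1.5, 1.0)))


class TestSuggestNext:
    def test_uniform_scores_maximize_distance(self, config):
        m = ScoreMap(RING, a_max=config.a_max, n_coord1=7, n_amp=6)
        explored = [ExplorationPoint(RING, 0.0, 1.0)]
        m.update(explored[0], 2.0)
        suggestion = suggest_next(m, explored, 0, config)
        # Brute-force oracle: farthest admissible node from the single
        # explored point (constant predicted term cancels).
        cc, aa = m.grid_nodes()
        best = max(
            (
                ((c / 3 - 0.0 / 3) ** 2 + ((a - 1.0) / config.a_max) ** 2, c, a)
                for c, a in zip(cc, aa)
                if a > 0
            ),
        )
        assert (suggestion.coord1, suggestion.amplitude) == (best[1], best[2])

    def test_pure_exploitation_limit(self):
        config = AlgorithmConfig(beta0=0.0, beta0_directional=0.0)
        m = ScoreMap(RING, n_coord1=7, n_amp=6)
        low = ExplorationPoint(RING, 1.5, 2.0)
        m.update(low, 0.5)
        m.update(ExplorationPoint(RING, 0.0, 1.0), 3.5)
        suggestion = suggest_next(m, [p for p, _, _ in m.observations], 5, config)
        assert (suggestion.coord1, suggestion.amplitude) == (1.5, 2.0)

    def test_capped_minimum_skipped(self):
        config = AlgorithmConfig(beta0=0.0, beta0_directional=0.0)
        m = ScoreMap(RING, n_coord1=7, n_amp=6)
        m.update(ExplorationPoint(RING, 1.5, 2.0), 0.5, side_effect=True)
        m.update(ExplorationPoint(RING, 3.0, 3.0), 1.5)
        suggestion = suggest_next(m, [p for p, _, _ in m.observations], 5, config)
        # The capped neighborhood around coord 1.5 excludes the map minimum.
        assert m.is_admissible(suggestion)

    def test_space_exhausted(self, config, two_symptom_spec):
        m = ScoreMap(RING, n_coord1=7, n_amp=6, cap_step=5.0)
        for c in (0.0, 1.0, 2.0, 3.0):
            m.update(ExplorationPoint(RING, c, 1.0), 2.0, side_effect=True)
        with pytest.raises(SpaceExhaustedError):
            suggest_next(m, [p for p, _, _ in m.observations], 0, config)


class TestConvergence:
    def test_close_suggestion_converges(self, config):
        explored = [ExplorationPoint(RING, 1.5, 2.5)]
        near = ExplorationPoint(RING, 1.55, 2.6)
        assert check_convergence(near, explored, config)

    def test_far_suggestion_does_not(self, config):
        explored = [ExplorationPoint(RING, 1.5, 2.5)]
        far = ExplorationPoint(RING, 0.0, 5.0)
        assert not check_convergence(far, explored, config)

    def test_identical_point_converges(self, config):
        explored = [ExplorationPoint(RING, 1.5, 2.5)]
        assert check_convergence(explored[0], explored, config)


class TestRunStage:
    def test_max_steps_three_returns_best_predefined(self, two_symptom_spec):
        config = AlgorithmConfig(max_steps_ring=3)
        steps, _, converged = run_stage(
            constant_responder(two_symptom_spec), RING, config, two_symptom_spec
        )
        assert len(steps) == 3
        assert not converged
        assert [s.point.coord1 for s in steps] == [0.5, 1.5, 2.5]

    def test_all_side_effects_exhaust_space(self, two_symptom_spec):
        config = AlgorithmConfig(
            predefined_ring_points=((0.5, 0.2), (1.5, 0.2), (2.5, 0.2)),
            amp_step=0.2,
        )
        with pytest.raises(SpaceExhaustedError):
            run_stage(
                constant_responder(two_symptom_spec, side_effect=True),
                RING,
                config,
                two_symptom_spec,
            )

    def test_responder_failure_has_step_context(self, two_symptom_spec):
        def broken(setting):
            raise RuntimeError("sensor offline")

        with pytest.raises(RuntimeError, match="step 1"):
            run_stage(broken, RING, AlgorithmConfig(), two_symptom_spec)


class TestDirectionalTrigger:
    def test_pure_bottom_ring_skips_stage_two(self):
        from dbsteer.lead import ring_point_to_setting

        setting = ring_point_to_setting(ExplorationPoint(RING, 0.0, 3.0))
        assert not directional_stage_required(setting)

    def test_fractional_position_triggers(self):
        from dbsteer.lead import ring_point_to_setting

        setting = ring_point_to_setting(ExplorationPoint(RING, 1.4, 3.0))
        assert directional_stage_required(setting)


class TestRunHemisphere:
    def test_determinism(self, config):
        def one_record():
            patient = make_patient(17, "clinical")
            spec = select_symptoms(patient.assessments())
            return run_hemisphere(make_responder(patient), config, spec)

        a, b = one_record(), one_record()
        assert json.dumps(session_to_dict(a), sort_keys=True) == json.dumps(
            session_to_dict(b), sort_keys=True
        )

    def test_never_exceeds_step_budget_or_bounds(self, config):
        for seed in range(6):
            patient = make_patient(seed, "clinical")
            spec = select_symptoms(patient.assessments())
            record = run_hemisphere(make_responder(patient), config, spec)
            assert record.n_steps <= config.max_steps_ring + config.max_steps_directional
            assert [s.index for s in record.steps] == list(
                range(1, record.n_steps + 1)
            )
            for s in record.steps:
                assert 0.0 < s.point.amplitude <= config.a_max
                if s.stage == RING:
                    assert 0.0 <= s.point.coord1 <= 3.0

    def test_anytime_best_non_increasing(self, config):
        patient = make_patient(23, "clinical")
        spec = select_symptoms(patient.assessments())
        record = run_hemisphere(make_responder(patient), config, spec)
        best = float("inf")
        for s in record.steps:
            if not s.side_effect:
                best = min(best, s.total)
            assert best <= min(
                (x.total for x in record.steps[: s.index] if not x.side_effect),
                default=float("inf"),
            ) + 1e-12

    def test_directional_worsening_keeps_ring_setting(self, two_symptom_spec):
        # Ring scores improve with amplitude; directional scores are awful.
        def responder(setting):
            value = 3.0 if setting.mode == DIRECTIONAL else max(
                0.0, 2.0 - 0.3 * setting.amplitude
            )
            return {sid: round(value, 1) for sid in two_symptom_spec.symptom_ids}, False

        record = run_hemisphere(responder, AlgorithmConfig(), two_symptom_spec)
        if len(record.stage_transitions) == 2:
            assert record.best_step.stage == RING


class TestBurdenReport:
    def test_counts(self, config):
        patient = make_patient(31, "clinical")
        spec = select_symptoms(patient.assessments())
        record = run_hemisphere(make_responder(patient), config, spec)
        total, to_best = burden_report(record)
        assert total == record.n_steps
        assert 1 <= to_best <= total
        assert record.steps[to_best - 1].total == record.best_step.total

    def test_empty_record_errors(self, config, two_symptom_spec):
        from dbsteer.optimizer import SessionRecord

        with pytest.raises(ValueError):
            burden_report(SessionRecord(spec=two_symptom_spec, config=config))
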