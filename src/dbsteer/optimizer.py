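"""Two-stage iterative optimization loop over the stimulation space.

Stage 1 (ring mode) explores vertical position x amplitude; if the best
ring setting puts cathodic current on any segmented electrode (E2-E7),
stage 2 (directional mode) explores rotation angle x amplitude at that
vertical position.  Each stage seeds a fixed set of predefined points
(three for ring, four for directional), then repeatedly suggests the
admissible lattice node minimizing

    acquisition(x) = predicted_score(x) - beta(t) * dist_to_nearest_explored(x)

with ``beta(t) = beta0 * decay**t`` decaying over the suggestion index
``t``, i.e. wide exploration first, exploitation of low-score regions
later.  The stage stops once the suggested point falls within the
normalized convergence distance of an already explored point (checked
after ``min_steps`` evaluations) or when ``max_steps`` is reached.

The acquisition rule is an explicit stand-in for the clinical method,
which is proprietary; only its explore-then-exploit behavior is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from dbsteer.lead import (
    DEFAULT_GEOMETRY,
    DIRECTIONAL,
    RING,
    DomainError,
    ExplorationPoint,
    LeadGeometry,
    StimSetting,
    directional_point_to_setting,
    ring_point_to_setting,
)
from dbsteer.score_map import ScoreMap, _coord1_distance
from dbsteer.scoring import WeightedScoreSpec, total_weighted_score


class SpaceExhaustedError(RuntimeError):
    """No admissible lattice node remains to explore."""


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable parameters of the two-stage loop.

    Frequency, pulse width and wash-in are session metadata: they are
    stamped on every generated setting and logged, never optimized.
    """

    predefined_ring_points: tuple[tuple[float, float], ...] = (
        (0.5, 3.0),
        (1.5, 4.0),
        (2.5, 3.0),
    )
    predefined_directional_points: tuple[tuple[float, float], ...] = (
        (0.0, 3.5),
        (90.0, 3.5),
        (180.0, 3.5),
        (270.0, 3.5),
    )
    a_max: float = 5.0
    amp_step: float = 0.1
    convergence_distance: float = 0.08
    convergence_distance_directional: float = 0.05
    beta0: float = 5.0
    beta_decay: float = 0.85
    beta0_directional: float = 3.0
    beta_decay_directional: float = 0.7
    min_steps_ring: int = 8
    min_steps_directional: int = 5
    max_steps_ring: int = 14
    max_steps_directional: int = 11
    n_coord1: int = 31
    n_amp: int = 26
    frequency: float = 130.0
    pulse_width: float = 60.0
    wash_in_s: float = 30.0
    step_duration_s: float = 165.0  # wash-in plus assessment time, logged only

    def __post_init__(self) -> None:
        if len(self.predefined_ring_points) != 3:
            raise ValueError("exactly 3 predefined ring points required")
        if len(self.predefined_directional_points) != 4:
            raise ValueError("exactly 4 predefined directional points required")
        if self.amp_step <= 0:
            raise ValueError("amp_step must be positive")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        for decay in (self.beta_decay, self.beta_decay_directional):
            if not 0 < decay <= 1:
                raise ValueError("beta decay factors must lie in (0, 1]")

    def min_steps(self, stage: str) -> int:
        return self.min_steps_ring if stage == RING else self.min_steps_directional

    def max_steps(self, stage: str) -> int:
        return self.max_steps_ring if stage == RING else self.max_steps_directional

    def beta(self, stage: str, step_index: int) -> float:
        """Exploration weight after ``step_index`` post-seed suggestions."""
        if stage == RING:
            return self.beta0 * self.beta_decay**step_index
        return self.beta0_directional * self.beta_decay_directional**step_index

    def convergence_threshold(self, stage: str) -> float:
        return (
            self.convergence_distance
            if stage == RING
            else self.convergence_distance_directional
        )


@dataclass(frozen=True)
class SessionStep:
    """One evaluated stimulation setting within a session."""

    index: int
    stage: str
    point: ExplorationPoint
    setting: StimSetting
    scores: dict[str, float]
    total: float
    side_effect: bool
    timestamp_s: float


@dataclass
class SessionRecord:
    """Full log of one hemisphere's optimization session."""

    spec: WeightedScoreSpec
    config: AlgorithmConfig
    steps: list[SessionStep] = field(default_factory=list)
    stage_transitions: list[tuple[str, int]] = field(default_factory=list)
    converged: dict[str, bool] = field(default_factory=dict)
    best_per_stage: dict[str, SessionStep] = field(default_factory=dict)

    @property
    def best_step(self) -> SessionStep:
        """Admissible step with the lowest total weighted score.

        Ties go to the lower amplitude, then the earlier step.
        """
        admissible = [s for s in self.steps if not s.side_effect]
        if not admissible:
            raise ValueError("no admissible steps recorded")
        return min(admissible, key=lambda s: (s.total, s.setting.amplitude, s.index))

    @property
    def final_setting(self) -> StimSetting:
        return self.best_step.setting

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def init_stage(stage: str, config: AlgorithmConfig) -> list[ExplorationPoint]:
    """The fixed predefined points opening an exploration stage."""
    if stage == RING:
        coords = config.predefined_ring_points
    elif stage == DIRECTIONAL:
        coords = config.predefined_directional_points
    else:
        raise DomainError(f"unknown stage {stage!r}")
    return [ExplorationPoint(stage, c, a) for c, a in coords]


def _normalized_distance(
    stage: str, a: ExplorationPoint, b: ExplorationPoint, a_max: float
) -> float:
    span = 3.0 if stage == RING else 360.0
    dc = _coord1_distance(stage, a.coord1, b.coord1) / span
    da = (a.amplitude - b.amplitude) / a_max
    return float(np.hypot(dc, da))


def _distance_to_explored(
    stage: str,
    coord1: np.ndarray,
    amplitude: np.ndarray,
    explored: list[ExplorationPoint],
    a_max: float,
) -> np.ndarray:
    span = 3.0 if stage == RING else 360.0
    ec = np.array([p.coord1 for p in explored])
    ea = np.array([p.amplitude for p in explored])
    dc = np.abs(coord1[:, None] - ec[None, :])
    if stage == DIRECTIONAL:
        dc = dc % 360.0
        dc = np.minimum(dc, 360.0 - dc)
    dc /= span
    da = (amplitude[:, None] - ea[None, :]) / a_max
    return np.sqrt(dc**2 + da**2).min(axis=1)


def suggest_next(
    score_map: ScoreMap,
    explored: list[ExplorationPoint],
    step_index: int,
    config: AlgorithmConfig,
) -> ExplorationPoint:
    """Pick the admissible lattice node minimizing the acquisition value.

    ``step_index`` counts suggestions made after the predefined points and
    drives the exploration weight decay.  Ties are broken by lower
    amplitude, then lower coordinate.
    """
    if not explored:
        raise ValueError("predefined points must be explored first")
    cc, aa = score_map.grid_nodes()
    mask = score_map.admissible_mask()
    mask &= aa > 0.0  # zero amplitude is no stimulation, never suggested
    if not mask.any():
        raise SpaceExhaustedError("stimulation space exhausted")
    predicted = score_map.grid_predictions()
    beta = config.beta(score_map.stage, step_index)
    dist = _distance_to_explored(score_map.stage, cc, aa, explored, config.a_max)
    acquisition = predicted - beta * dist
    acquisition[~mask] = np.inf
    # Lexicographic argmin: acquisition, then amplitude, then coord1.
    order = np.lexsort((cc, aa, acquisition))
    best = order[0]
    return ExplorationPoint(score_map.stage, float(cc[best]), float(aa[best]))


def check_convergence(
    suggested: ExplorationPoint,
    explored: list[ExplorationPoint],
    config: AlgorithmConfig,
) -> bool:
    """True when the suggestion lies within threshold of an explored point."""
    if not explored:
        raise ValueError("convergence is undefined without explored points")
    nearest = min(
        _normalized_distance(suggested.stage, suggested, p, config.a_max)
        for p in explored
    )
    return nearest < config.convergence_threshold(suggested.stage)


def _point_to_setting(
    point: ExplorationPoint,
    config: AlgorithmConfig,
    geometry: LeadGeometry,
    base_vertical: float | None,
) -> StimSetting:
    kwargs = dict(
        a_max=config.a_max,
        frequency=config.frequency,
        pulse_width=config.pulse_width,
    )
    if point.stage == RING:
        return ring_point_to_setting(point, geometry, **kwargs)
    if base_vertical is None:
        raise ValueError("directional stage requires a base vertical position")
    return directional_point_to_setting(point, base_vertical, geometry, **kwargs)


def run_stage(
    responder,
    stage: str,
    config: AlgorithmConfig,
    spec: WeightedScoreSpec,
    base_vertical: float | None = None,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
    start_index: int = 1,
) -> tuple[list[SessionStep], ScoreMap, bool]:
    """Run one exploration stage to convergence or the step limit.

    ``responder`` maps a :class:`StimSetting` to ``(per-symptom scores,
    side-effect flag)``.  Returns the recorded steps, the final score map
    and the converged flag.
    """
    score_map = ScoreMap(
        stage,
        a_max=config.a_max,
        n_coord1=config.n_coord1,
        n_amp=config.n_amp,
        cap_step=config.amp_step,
    )
    steps: list[SessionStep] = []
    explored: list[ExplorationPoint] = []

    def evaluate(point: ExplorationPoint) -> None:
        setting = _point_to_setting(point, config, geometry, base_vertical)
        try:
            scores, side_effect = responder(setting)
        except Exception as exc:
            raise RuntimeError(
                f"responder failed at step {start_index + len(steps)} "
                f"({stage}, coord1={point.coord1}, A={point.amplitude})"
            ) from exc
        total, side_effect = total_weighted_score(spec, scores, side_effect)
        index = start_index + len(steps)
        steps.append(
            SessionStep(
                index=index,
                stage=stage,
                point=point,
                setting=setting,
                scores=dict(scores),
                total=total,
                side_effect=side_effect,
                timestamp_s=index * config.step_duration_s,
            )
        )
        explored.append(point)
        score_map.update(point, total, side_effect)

    for point in init_stage(stage, config):
        evaluate(point)

    converged = False
    suggestion_index = 0
    while len(steps) < config.max_steps(stage):
        suggested = suggest_next(score_map, explored, suggestion_index, config)
        suggestion_index += 1
        if len(steps) >= config.min_steps(stage) and check_convergence(
            suggested, explored, config
        ):
            converged = True
            break
        # Below min_steps a near-duplicate suggestion is re-tested anyway
        # (it still costs a step and, with noise, refines the map).
        evaluate(suggested)
    return steps, score_map, converged


def _stage_best(steps: list[SessionStep]) -> SessionStep:
    admissible = [s for s in steps if not s.side_effect]
    if not admissible:
        raise SpaceExhaustedError("every explored setting triggered a side effect")
    return min(admissible, key=lambda s: (s.total, s.setting.amplitude, s.index))


def directional_stage_required(setting: StimSetting) -> bool:
    """Stage 2 triggers when any segmented electrode (E2-E7) is cathodic."""
    return any(f < 0.0 for f in setting.fractions[1:7])


def run_hemisphere(
    responder,
    config: AlgorithmConfig,
    spec: WeightedScoreSpec,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
) -> SessionRecord:
    """Run the full two-stage loop for one hemisphere."""
    record = SessionRecord(spec=spec, config=config)
    record.stage_transitions.append((RING, 1))
    ring_steps, _, ring_converged = run_stage(
        responder, RING, config, spec, geometry=geometry
    )
    record.steps.extend(ring_steps)
    record.converged[RING] = ring_converged
    ring_best = _stage_best(ring_steps)
    record.best_per_stage[RING] = ring_best

    if directional_stage_required(ring_best.setting):
        start = len(record.steps) + 1
        record.stage_transitions.append((DIRECTIONAL, start))
        dir_steps, _, dir_converged = run_stage(
            responder,
            DIRECTIONAL,
            config,
            spec,
            base_vertical=ring_best.point.coord1,
            geometry=geometry,
            start_index=start,
        )
        record.steps.extend(dir_steps)
        record.converged[DIRECTIONAL] = dir_converged
        record.best_per_stage[DIRECTIONAL] = _stage_best(dir_steps)
    return record


def burden_report(record: SessionRecord) -> tuple[int, int]:
    """(steps until convergence stop, steps until the final best setting)."""
    if not record.steps:
        raise ValueError("empty session record")
    best = record.best_step
    first_best = min(
        s.index
        for s in record.steps
        if not s.side_effect and s.total == best.total
    )
    return record.n_steps, first_best
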