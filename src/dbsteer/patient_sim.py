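"""Synthetic patients with ground-truth response fields.

Each symptom responds to stimulation through a separable field: a Gaussian
spatial kernel over the vertical position (and, for steered settings, the
rotation angle) multiplied by an amplitude sigmoid anchored so that zero
amplitude leaves the symptom at its untreated baseline::

    score = clip(baseline_off - max_improvement * V(p) * Theta(theta) * S(A)
                 + noise, 0, 4)        quantized to 0.1

The effective coordinate of a setting is its cathodic-share-weighted
vertical centroid and circular-mean angle.  Ring-symmetric settings see
the angular kernel averaged over the full circle; partially steered
settings blend the directed and averaged kernels by the circular resultant
length, so steering toward the sweet angle helps in proportion to how
directional the setting actually is.

A side-effect field defines a threshold amplitude surface ``T(p, theta)``
that dips near a configurable sector (emulating, e.g., capsular effects);
a tested setting reports a side effect whenever its amplitude reaches the
local threshold.

Three difficulty presets are provided: ``easy`` (noise free, one shared
sweet spot, no side effects), ``clinical`` (noise plus a side-effect
sector) and ``adversarial`` (conflicting sweet spots at least one level
unit apart).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from dbsteer.lead import (
    DEFAULT_GEOMETRY,
    DIRECTIONAL,
    RING,
    ExplorationPoint,
    LeadGeometry,
    StimSetting,
    directional_point_to_setting,
    directional_resultant,
    ring_point_to_setting,
    vertical_centroid,
)
from dbsteer.scoring import SymptomAssessment, WeightedScoreSpec, total_weighted_score

SCORE_QUANTUM = 0.1

PRESETS = ("easy", "clinical", "adversarial")


def _quantize(score: float) -> float:
    return round(round(score / SCORE_QUANTUM) * SCORE_QUANTUM, 1)


def _circdiff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class SymptomField:
    """Ground-truth response field of one symptom."""

    name: str
    source: str  # clinician | sensor
    baseline_off: float
    max_improvement: float
    sweet_p: float
    sweet_theta: float
    sigma_p: float
    sigma_theta: float
    a50: float
    slope: float
    noise_sd: float = 0.0

    @property
    def baseline_on(self) -> float:
        """Baseline under effective therapy, used for weighting."""
        return _quantize(max(self.baseline_off - self.max_improvement, 0.0))

    def _ring_theta_factor(self) -> float:
        # Average of the angular kernel over the full circle; independent
        # of the sweet angle, so computed on a fixed grid once per call.
        phis = np.arange(0.0, 360.0, 5.0)
        d = np.abs(phis - 0.0)
        d = np.minimum(d % 360.0, 360.0 - (d % 360.0))
        return float(np.mean(np.exp(-(d**2) / (2.0 * self.sigma_theta**2))))

    def _amplitude_factor(self, amplitude: float) -> float:
        raw0 = 1.0 / (1.0 + math.exp(self.a50 / self.slope))
        raw = 1.0 / (1.0 + math.exp(-(amplitude - self.a50) / self.slope))
        return max((raw - raw0) / (1.0 - raw0), 0.0)

    def evaluate(
        self, p_eff: float, theta_eff: float, rho: float, amplitude: float
    ) -> float:
        """Noise-free, unquantized score at an effective coordinate."""
        v = math.exp(-((p_eff - self.sweet_p) ** 2) / (2.0 * self.sigma_p**2))
        directed = math.exp(
            -(_circdiff(theta_eff, self.sweet_theta) ** 2)
            / (2.0 * self.sigma_theta**2)
        )
        theta_factor = rho * directed + (1.0 - rho) * self._ring_theta_factor()
        effect = (
            self.max_improvement * v * theta_factor * self._amplitude_factor(amplitude)
        )
        return self.baseline_off - effect


@dataclass(frozen=True)
class SideEffectField:
    """Amplitude threshold surface; side effect when A >= T(p, theta)."""

    center_p: float = 1.5
    center_theta: float = 180.0
    sigma_p: float = 0.8
    sigma_theta: float = 70.0
    t_near: float = math.inf  # threshold at the sector center
    t_far: float = math.inf  # threshold far away
    floor: float = 0.5
    ceiling: float = 10.0

    def threshold(self, p_eff: float, theta_eff: float, rho: float) -> float:
        if math.isinf(self.t_far):
            return math.inf
        dp = (p_eff - self.center_p) ** 2 / (2.0 * self.sigma_p**2)
        directed = math.exp(
            -dp
            - _circdiff(theta_eff, self.center_theta) ** 2
            / (2.0 * self.sigma_theta**2)
        )
        ring_avg = math.exp(-dp) * float(
            np.mean(
                np.exp(
                    -np.minimum(
                        np.abs(np.arange(0.0, 360.0, 5.0) - self.center_theta) % 360.0,
                        360.0
                        - np.abs(np.arange(0.0, 360.0, 5.0) - self.center_theta)
                        % 360.0,
                    )
                    ** 2
                    / (2.0 * self.sigma_theta**2)
                )
            )
        )
        proximity = rho * directed + (1.0 - rho) * ring_avg
        t = self.t_far - (self.t_far - self.t_near) * proximity
        return min(max(t, self.floor), self.ceiling)


@dataclass
class SyntheticPatient:
    """One hemisphere's ground truth: symptom fields plus side effects."""

    seed: int
    preset: str
    symptoms: tuple[SymptomField, ...]
    side_effects: SideEffectField
    geometry: LeadGeometry = field(default_factory=LeadGeometry)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)

    def reset_noise(self) -> None:
        """Rewind the noise stream so a session can be replayed exactly."""
        self._rng = np.random.default_rng(self.seed)

    def assessments(self) -> tuple[SymptomAssessment, ...]:
        return tuple(
            SymptomAssessment(
                name=s.name,
                source=s.source,
                baseline_off=s.baseline_off,
                baseline_on=s.baseline_on,
            )
            for s in self.symptoms
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "preset": self.preset,
            "symptoms": [asdict(s) for s in self.symptoms],
            "side_effects": asdict(self.side_effects),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticPatient":
        return cls(
            seed=payload["seed"],
            preset=payload["preset"],
            symptoms=tuple(SymptomField(**s) for s in payload["symptoms"]),
            side_effects=SideEffectField(**payload["side_effects"]),
        )

    @classmethod
    def from_json(cls, path) -> "SyntheticPatient":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _effective_coordinate(
    setting: StimSetting, geometry: LeadGeometry
) -> tuple[float, float, float]:
    p_eff = vertical_centroid(setting, geometry)
    rho, theta_eff = directional_resultant(setting, geometry)
    return p_eff, theta_eff, rho


def respond(
    patient: SyntheticPatient,
    setting: StimSetting,
    noise: bool = True,
) -> tuple[dict[str, float], bool]:
    """Simulate the patient's scored response to one stimulation setting.

    Returns per-symptom quantized scores keyed by symptom id and the
    side-effect flag.  At zero amplitude every symptom sits at its
    untreated baseline (noise-free).
    """
    if setting.amplitude <= 0.0:
        return (
            {a.symptom_id: a.baseline_off for a in patient.assessments()},
            False,
        )
    p_eff, theta_eff, rho = _effective_coordinate(setting, patient.geometry)
    scores: dict[str, float] = {}
    for s, assessment in zip(patient.symptoms, patient.assessments()):
        value = s.evaluate(p_eff, theta_eff, rho, setting.amplitude)
        if noise and s.noise_sd > 0.0:
            value += patient._rng.normal(0.0, s.noise_sd)
        scores[assessment.symptom_id] = _quantize(min(max(value, 0.0), 4.0))
    threshold = patient.side_effects.threshold(p_eff, theta_eff, rho)
    return scores, bool(setting.amplitude >= threshold)


def make_responder(patient: SyntheticPatient, noise: bool = True):
    """Adapter: callable ``StimSetting -> (scores, side_effect)``."""

    def responder(setting: StimSetting) -> tuple[dict[str, float], bool]:
        return respond(patient, setting, noise=noise)

    return responder


# ---------------------------------------------------------------------------
# Patient generation
# ---------------------------------------------------------------------------

_SYMPTOM_POOL = (
    ("rigidity_upper_limb", "clinician"),
    ("bradykinesia_hand", "clinician"),
    ("tremor_rest", "clinician"),
    ("finger_tapping_speed", "sensor"),
    ("hand_grasp_amplitude", "sensor"),
    ("tremor_postural", "sensor"),
)


def _draw_field(
    rng: np.random.Generator,
    name: str,
    source: str,
    sweet_p: float,
    sweet_theta: float,
    noisy: bool,
) -> SymptomField:
    baseline_off = _quantize(rng.uniform(2.0, 4.0))
    max_improvement = _quantize(rng.uniform(0.5, 1.0) * baseline_off)
    # Sensors resolve finer than clinicians, hence the lower noise floor.
    noise_sd = 0.0
    if noisy:
        noise_sd = 0.05 if source == "sensor" else 0.15
    return SymptomField(
        name=name,
        source=source,
        baseline_off=baseline_off,
        max_improvement=max(max_improvement, 0.5),
        sweet_p=sweet_p,
        sweet_theta=sweet_theta,
        sigma_p=float(rng.uniform(0.6, 1.0)),
        sigma_theta=float(rng.uniform(60.0, 110.0)),
        a50=float(rng.uniform(1.0, 2.5)),
        slope=float(rng.uniform(0.3, 0.6)),
        noise_sd=noise_sd,
    )


def make_patient(
    seed: int, preset: str = "easy", n_symptoms: int | None = None
) -> SyntheticPatient:
    """Generate a reproducible synthetic patient for one hemisphere."""
    if preset not in PRESETS:
        raise ValueError(f"preset must be one of {PRESETS}, got {preset!r}")
    rng = np.random.default_rng(seed)
    if n_symptoms is None:
        n_symptoms = int(rng.integers(2, 5))
    pool = list(_SYMPTOM_POOL)
    rng.shuffle(pool)
    chosen = pool[:n_symptoms]
    noisy = preset != "easy"

    base_p = float(rng.uniform(0.2, 2.8))
    base_theta = float(rng.uniform(0.0, 360.0))
    fields: list[SymptomField] = []
    for i, (name, source) in enumerate(chosen):
        if preset == "adversarial" and i == 1:
            # Force a conflicting sweet spot >= 1 level unit away.
            offset = float(rng.uniform(1.0, 1.8))
            sweet_p = base_p + offset if base_p < 1.2 else base_p - offset
            sweet_p = min(max(sweet_p, 0.0), 3.0)
            sweet_theta = (base_theta + 180.0) % 360.0
        else:
            jitter = 0.0 if preset == "easy" else float(rng.uniform(-0.3, 0.3))
            sweet_p = min(max(base_p + jitter, 0.0), 3.0)
            theta_jitter = 0.0 if preset == "easy" else float(rng.uniform(-30, 30))
            sweet_theta = (base_theta + theta_jitter) % 360.0
        fields.append(_draw_field(rng, name, source, sweet_p, sweet_theta, noisy))

    if preset == "easy":
        side = SideEffectField()  # infinite thresholds: never triggers
    else:
        side = SideEffectField(
            center_p=float(rng.uniform(0.0, 3.0)),
            center_theta=float(rng.uniform(0.0, 360.0)),
            sigma_p=float(rng.uniform(0.5, 0.9)),
            sigma_theta=float(rng.uniform(50.0, 90.0)),
            t_near=float(rng.uniform(3.0, 4.5)),
            t_far=float(rng.uniform(5.5, 7.0)),
        )
    return SyntheticPatient(
        seed=seed, preset=preset, symptoms=tuple(fields), side_effects=side
    )


def brute_force_optimum(
    patient: SyntheticPatient,
    spec: WeightedScoreSpec,
    n_coord1: int = 31,
    n_amp: int = 26,
    a_max: float = 5.0,
) -> tuple[ExplorationPoint, float]:
    """Exhaustive noise-free optimum over the two-stage reachable lattice.

    Evaluates every admissible ring-stage node, then every directional
    node at the ring-optimal vertical position, and returns the overall
    best (lowest total weighted score; ties to lower amplitude, then lower
    coordinate).  Raises when side effects block the entire space.
    """

    def evaluate(point: ExplorationPoint, base_p: float | None):
        if point.stage == RING:
            setting = ring_point_to_setting(point, patient.geometry, a_max=a_max)
        else:
            setting = directional_point_to_setting(
                point, base_p, patient.geometry, a_max=a_max
            )
        scores, side_effect = respond(patient, setting, noise=False)
        if side_effect:
            return None
        total, _ = total_weighted_score(spec, scores)
        return total

    def scan(stage: str, coord1_grid: np.ndarray, base_p: float | None):
        best = None
        for c in coord1_grid:
            for a in np.linspace(0.0, a_max, n_amp):
                if a <= 0.0:
                    continue
                point = ExplorationPoint(stage, float(c), float(a))
                total = evaluate(point, base_p)
                if total is None:
                    continue
                key = (total, point.amplitude, point.coord1)
                if best is None or key < best[0]:
                    best = (key, point, total)
        return best

    ring_best = scan(RING, np.linspace(0.0, 3.0, n_coord1), None)
    if ring_best is None:
        raise ValueError("stimulation space exhausted: side effects everywhere")
    best = ring_best
    dir_best = scan(
        DIRECTIONAL,
        np.linspace(0.0, 360.0, n_coord1, endpoint=False),
        ring_best[1].coord1,
    )
    if dir_best is not None and dir_best[0] < best[0]:
        best = dir_best
    return best[1], best[2]
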