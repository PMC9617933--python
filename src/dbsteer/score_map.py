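"""Interpolated score maps over a 2D stimulation space.

A :class:`ScoreMap` accumulates sparse observations ``(point, score,
side-effect flag)`` and estimates the score everywhere on a regular
lattice by inverse-distance weighting (power 2) in normalized coordinates:
the vertical position is scaled by its 3-level span, rotation angles are
treated circularly and scaled by 360 deg, and the amplitude is scaled by
its configured maximum.  The interpolant passes exactly through the data.

Side-effect observations carve amplitude caps into the map: within a
neighborhood of the offending coordinate (0.5 level units for the ring
stage, 60 deg for the directional stage by default) every lattice node at
or above ``observed amplitude - one amplitude step`` becomes inadmissible.
Adding observations can only shrink the admissible region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dbsteer.lead import DIRECTIONAL, RING, DomainError, ExplorationPoint

IDW_POWER = 2.0
_EXACT_EPS = 1e-9

DEFAULT_N_COORD1 = 31
DEFAULT_N_AMP = 26
DEFAULT_CAP_STEP = 0.1
DEFAULT_RING_RADIUS = 0.5
DEFAULT_DIRECTIONAL_RADIUS = 60.0


class EmptyMapError(ValueError):
    """Prediction was requested from a map without observations."""


@dataclass(frozen=True)
class SideEffectBoundary:
    """Amplitude cap around a coordinate where a side effect occurred."""

    coord1: float
    cap: float  # mA; nodes with amplitude >= cap are inadmissible
    radius: float  # coord1 units (level units or degrees)


def _coord1_distance(stage: str, a: float, b: float) -> float:
    d = abs(a - b)
    if stage == DIRECTIONAL:
        d = d % 360.0
        d = min(d, 360.0 - d)
    return d


class ScoreMap:
    """Surrogate score estimate over one exploration stage's 2D space."""

    def __init__(
        self,
        stage: str,
        a_max: float = 5.0,
        n_coord1: int = DEFAULT_N_COORD1,
        n_amp: int = DEFAULT_N_AMP,
        cap_step: float = DEFAULT_CAP_STEP,
        boundary_radius: float | None = None,
    ) -> None:
        if stage not in (RING, DIRECTIONAL):
            raise DomainError(f"unknown stage {stage!r}")
        if a_max <= 0:
            raise ValueError("a_max must be positive")
        self.stage = stage
        self.a_max = float(a_max)
        if stage == RING:
            self.coord1_grid = np.linspace(0.0, 3.0, n_coord1)
            self._coord1_span = 3.0
            default_radius = DEFAULT_RING_RADIUS
        else:
            self.coord1_grid = np.linspace(0.0, 360.0, n_coord1, endpoint=False)
            self._coord1_span = 360.0
            default_radius = DEFAULT_DIRECTIONAL_RADIUS
        self.amp_grid = np.linspace(0.0, self.a_max, n_amp)
        self.cap_step = float(cap_step)
        self.boundary_radius = (
            float(boundary_radius) if boundary_radius is not None else default_radius
        )
        self.observations: list[tuple[ExplorationPoint, float, bool]] = []
        self.boundaries: list[SideEffectBoundary] = []

    # -- bookkeeping --------------------------------------------------------

    @property
    def coord1_step(self) -> float:
        return float(self.coord1_grid[1] - self.coord1_grid[0])

    @property
    def amp_step(self) -> float:
        return float(self.amp_grid[1] - self.amp_grid[0])

    def _check_bounds(self, point: ExplorationPoint) -> None:
        if point.stage != self.stage:
            raise DomainError(
                f"point stage {point.stage!r} does not match map stage {self.stage!r}"
            )
        if self.stage == RING and not 0.0 <= point.coord1 <= 3.0:
            raise DomainError(f"coord1 {point.coord1} outside [0, 3]")
        if not 0.0 <= point.amplitude <= self.a_max + 1e-9:
            raise DomainError(
                f"amplitude {point.amplitude} outside [0, {self.a_max}]"
            )

    def update(
        self, point: ExplorationPoint, score: float, side_effect: bool = False
    ) -> "ScoreMap":
        """Record an observation; duplicates within grid resolution replace.

        A side-effect observation additionally installs an amplitude cap of
        ``point.amplitude - cap_step`` within ``boundary_radius`` of the
        coordinate.  Returns ``self`` for chaining.
        """
        self._check_bounds(point)
        for i, (existing, _, _) in enumerate(self.observations):
            if (
                _coord1_distance(self.stage, existing.coord1, point.coord1)
                < self.coord1_step / 2.0
                and abs(existing.amplitude - point.amplitude) < self.amp_step / 2.0
            ):
                self.observations[i] = (point, float(score), bool(side_effect))
                break
        else:
            self.observations.append((point, float(score), bool(side_effect)))
        if side_effect:
            self.boundaries.append(
                SideEffectBoundary(
                    coord1=point.coord1,
                    cap=max(point.amplitude - self.cap_step, 0.0),
                    radius=self.boundary_radius,
                )
            )
        return self

    # -- interpolation ------------------------------------------------------

    def _normalized_distances(
        self, coord1: np.ndarray, amplitude: np.ndarray
    ) -> np.ndarray:
        """Distances from query nodes to every observation, shape (q, n_obs)."""
        obs_c = np.array([p.coord1 for p, _, _ in self.observations])
        obs_a = np.array([p.amplitude for p, _, _ in self.observations])
        dc = np.abs(coord1[:, None] - obs_c[None, :])
        if self.stage == DIRECTIONAL:
            dc = dc % 360.0
            dc = np.minimum(dc, 360.0 - dc)
        dc /= self._coord1_span
        da = (amplitude[:, None] - obs_a[None, :]) / self.a_max
        return np.sqrt(dc**2 + da**2)

    def _predict_arrays(
        self, coord1: np.ndarray, amplitude: np.ndarray
    ) -> np.ndarray:
        if not self.observations:
            raise EmptyMapError("score map has no observations")
        scores = np.array([s for _, s, _ in self.observations])
        dist = self._normalized_distances(coord1, amplitude)
        with np.errstate(divide="ignore"):
            weights = dist ** (-IDW_POWER)
        exact = dist < _EXACT_EPS
        predicted = np.empty(len(coord1))
        any_exact = exact.any(axis=1)
        if any_exact.any():
            idx = exact.argmax(axis=1)
            predicted[any_exact] = scores[idx[any_exact]]
        rest = ~any_exact
        if rest.any():
            w = weights[rest]
            predicted[rest] = (w * scores[None, :]).sum(axis=1) / w.sum(axis=1)
        return np.clip(predicted, 0.0, 4.0)

    def predict(self, point: ExplorationPoint) -> float:
        """Inverse-distance-weighted score estimate at ``point``."""
        self._check_bounds(point)
        return float(
            self._predict_arrays(
                np.array([point.coord1]), np.array([point.amplitude])
            )[0]
        )

    def grid_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened ``(coord1, amplitude)`` arrays of all lattice nodes."""
        cc, aa = np.meshgrid(self.coord1_grid, self.amp_grid, indexing="ij")
        return cc.ravel(), aa.ravel()

    def grid_predictions(self) -> np.ndarray:
        """Predicted score at every lattice node (flattened, coord1-major)."""
        cc, aa = self.grid_nodes()
        return self._predict_arrays(cc, aa)

    # -- admissibility ------------------------------------------------------

    def admissible_amplitude_cap(self, coord1: float) -> float:
        """Lowest active amplitude cap at ``coord1`` (inf when uncapped)."""
        cap = np.inf
        for b in self.boundaries:
            if _coord1_distance(self.stage, coord1, b.coord1) <= b.radius + 1e-9:
                cap = min(cap, b.cap)
        return cap

    def is_admissible(self, point: ExplorationPoint) -> bool:
        self._check_bounds(point)
        return point.amplitude < self.admissible_amplitude_cap(point.coord1) - 1e-9

    def admissible_mask(self) -> np.ndarray:
        """Boolean admissibility of every lattice node (flattened)."""
        cc, aa = self.grid_nodes()
        caps = np.array([self.admissible_amplitude_cap(c) for c in self.coord1_grid])
        cap_per_node = np.repeat(caps, len(self.amp_grid))
        return aa < cap_per_node - 1e-9

    # -- export / serialization --------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Gridded table of (coord1, amplitude, predicted, admissible)."""
        cc, aa = self.grid_nodes()
        return pd.DataFrame(
            {
                "coord1": cc,
                "amplitude": aa,
                "predicted": self.grid_predictions(),
                "admissible": self.admissible_mask(),
            }
        )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "a_max": self.a_max,
            "n_coord1": len(self.coord1_grid),
            "n_amp": len(self.amp_grid),
            "cap_step": self.cap_step,
            "boundary_radius": self.boundary_radius,
            "observations": [
                {
                    "coord1": p.coord1,
                    "amplitude": p.amplitude,
                    "score": s,
                    "side_effect": f,
                }
                for p, s, f in self.observations
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScoreMap":
        m = cls(
            stage=payload["stage"],
            a_max=payload["a_max"],
            n_coord1=payload["n_coord1"],
            n_amp=payload["n_amp"],
            cap_step=payload["cap_step"],
            boundary_radius=payload["boundary_radius"],
        )
        for obs in payload["observations"]:
            m.update(
                ExplorationPoint(m.stage, obs["coord1"], obs["amplitude"]),
                obs["score"],
                obs["side_effect"],
            )
        return m


def update_map(
    score_map: ScoreMap, point: ExplorationPoint, score: float, side_effect: bool = False
) -> ScoreMap:
    """Functional alias for :meth:`ScoreMap.update`."""
    return score_map.update(point, score, side_effect)


def predict_score(score_map: ScoreMap, point: ExplorationPoint) -> float:
    """Functional alias for :meth:`ScoreMap.predict`."""
    return score_map.predict(point)


def export_map(score_map: ScoreMap, path=None) -> pd.DataFrame:
    """Export the gridded map; writes CSV when ``path`` is given."""
    frame = score_map.to_frame()
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
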