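"""Geometry and current-fractionalization model of a 1-3-3-1 directional lead.

The lead has a bottom ring contact (E1), two directional levels of three
segments each (E2-E4 lower, E5-E7 upper) and a top ring contact (E8); the
implanted pulse-generator case acts as the return (anode) in monopolar mode.

Stimulation-space coordinates are continuous:

* vertical position ``p`` in level units, ``0.0`` at the E1 center up to
  ``3.0`` at the E8 center (ring-mode axis);
* rotation angle ``theta`` in degrees, with the segment columns E2/E5 at
  0 deg, E3/E6 at 120 deg and E4/E7 at 240 deg (directional-mode axis).

Conversions to concrete electrode percentages interpolate linearly between
the two adjacent levels (and, for directional settings, between the two
segment directions adjacent to ``theta``) and round to integer percents by
the largest-remainder rule with ties awarded to the lowest electrode index,
which reproduces the familiar 34/33/33 equal-thirds pattern.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

RING = "ring"
DIRECTIONAL = "directional"

#: Index of the IPG case entry in a length-9 fractionalization vector.
CASE_INDEX = 8

_SEGMENT_SPAN_DEG = 120.0


class DomainError(ValueError):
    """A coordinate lies outside the declared stimulation-space bounds."""


class SafetyError(ValueError):
    """A requested amplitude exceeds the configured safety limit."""


@dataclass(frozen=True)
class LeadGeometry:
    """Physical and logical layout of the 1-3-3-1 directional lead."""

    n_levels: int = 4
    segments_per_level: tuple[int, ...] = (1, 3, 3, 1)
    electrode_labels: tuple[str, ...] = (
        "E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8",
    )
    segment_angles: tuple[float, ...] = (0.0, 120.0, 240.0)
    level_spacing_mm: float = 2.0
    lead_radius_mm: float = 0.65

    def __post_init__(self) -> None:
        if self.n_levels != len(self.segments_per_level):
            raise ValueError("segments_per_level must list one count per level")
        if sum(self.segments_per_level) != len(self.electrode_labels):
            raise ValueError("electrode count must match segment layout")
        if len(set(self.electrode_labels)) != len(self.electrode_labels):
            raise ValueError("electrode labels must be unique")
        if len(self.segment_angles) != 3:
            raise ValueError("directional levels carry exactly 3 segments")
        gaps = np.diff(sorted(self.segment_angles))
        if not np.allclose(gaps, 120.0):
            raise ValueError("segments must sit at mutually 120 deg spacing")

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_labels)

    @property
    def electrode_levels(self) -> tuple[int, ...]:
        """Level index (0-based, bottom up) of each electrode, E1..E8."""
        levels: list[int] = []
        for level, n_seg in enumerate(self.segments_per_level):
            levels.extend([level] * n_seg)
        return tuple(levels)

    def level_electrodes(self, level: int) -> tuple[int, ...]:
        """Electrode indices (0-based) belonging to ``level``."""
        return tuple(
            i for i, lv in enumerate(self.electrode_levels) if lv == level
        )

    def is_directional(self, electrode: int) -> bool:
        return self.segments_per_level[self.electrode_levels[electrode]] > 1

    def electrode_angle(self, electrode: int) -> float | None:
        """Segment direction of a directional electrode, ``None`` for rings."""
        level = self.electrode_levels[electrode]
        if self.segments_per_level[level] == 1:
            return None
        position = self.level_electrodes(level).index(electrode)
        return self.segment_angles[position]


DEFAULT_GEOMETRY = LeadGeometry()


@dataclass(frozen=True)
class ExplorationPoint:
    """A coordinate in one of the two 2D stimulation spaces.

    ``coord1`` is a vertical position in ``[0, 3]`` level units for the
    ring stage, or a rotation angle in ``[0, 360)`` degrees (normalized
    modulo 360) for the directional stage.
    """

    stage: str
    coord1: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.stage not in (RING, DIRECTIONAL):
            raise DomainError(f"unknown stage {self.stage!r}")
        if self.stage == RING:
            if not 0.0 <= self.coord1 <= 3.0:
                raise DomainError(
                    f"vertical position {self.coord1} outside [0, 3]"
                )
        else:
            object.__setattr__(self, "coord1", float(self.coord1) % 360.0)
        if self.amplitude < 0.0:
            raise DomainError(f"amplitude {self.amplitude} must be >= 0")


@dataclass(frozen=True)
class StimSetting:
    """A concrete stimulation setting on the 8-electrode lead.

    ``fractions`` holds the signed current fraction of E1..E8 followed by
    the IPG case: cathodes negative, anodes positive.  For any setting
    with non-zero amplitude the cathodic fractions sum to -1 and the
    anodic fractions to +1 (monopolar settings carry the case at +1).
    """

    amplitude: float
    fractions: tuple[float, ...]
    frequency: float = 130.0
    pulse_width: float = 60.0
    mode: str = RING

    def __post_init__(self) -> None:
        if len(self.fractions) != 9:
            raise ValueError("fractions must have 9 entries (E1..E8 + case)")
        if self.amplitude < 0.0:
            raise ValueError("amplitude must be >= 0")
        fr = np.asarray(self.fractions, dtype=float)
        if np.any(np.abs(fr) > 1.0 + 1e-9):
            raise ValueError("electrode fraction magnitudes must lie in [0, 1]")
        if self.amplitude > 0.0:
            cath = fr[fr < 0].sum()
            anod = fr[fr > 0].sum()
            if not math.isclose(cath, -1.0, abs_tol=1e-9):
                raise ValueError(f"cathodic fractions sum to {cath}, not -1")
            if not math.isclose(anod, 1.0, abs_tol=1e-9):
                raise ValueError(f"anodic fractions sum to {anod}, not +1")

    @property
    def percents(self) -> tuple[int, ...]:
        """Signed integer-percent representation of ``fractions``."""
        return tuple(int(round(f * 100)) for f in self.fractions)

    def cathodic_shares(self) -> np.ndarray:
        """Unsigned cathodic share of each lead electrode (case excluded)."""
        fr = np.asarray(self.fractions[:8], dtype=float)
        return np.where(fr < 0, -fr, 0.0)


def largest_remainder(shares: np.ndarray, total: int = 100) -> np.ndarray:
    """Round non-negative ``shares`` (summing to 1) to integers summing to ``total``.

    Leftover units after flooring go to the largest fractional remainders,
    ties resolved in favor of the lowest index.
    """
    raw = np.asarray(shares, dtype=float) * total
    base = np.floor(raw + 1e-9).astype(int)
    remainder = raw - base
    missing = total - int(base.sum())
    if missing < 0:  # pragma: no cover - defensive, shares must sum to 1
        raise ValueError("shares must sum to 1")
    order = sorted(range(len(base)), key=lambda i: (-remainder[i], i))
    for i in order[:missing]:
        base[i] += 1
    return base


def _vertical_level_shares(p: float, geometry: LeadGeometry) -> dict[int, float]:
    """Split unit cathodic current between the two levels adjacent to ``p``."""
    floor_level = int(math.floor(p))
    frac = p - floor_level
    if floor_level >= geometry.n_levels - 1:
        return {geometry.n_levels - 1: 1.0}
    if frac <= 1e-12:
        return {floor_level: 1.0}
    return {floor_level: 1.0 - frac, floor_level + 1: frac}


def _angular_segment_weights(
    theta: float, geometry: LeadGeometry
) -> dict[int, float]:
    """Split unit current between the two segment directions adjacent to theta.

    Returns a mapping of within-level segment position (0, 1, 2) to weight.
    """
    theta = float(theta) % 360.0
    sector = int(theta // _SEGMENT_SPAN_DEG) % 3
    t = (theta - sector * _SEGMENT_SPAN_DEG) / _SEGMENT_SPAN_DEG
    if t <= 1e-12:
        return {sector: 1.0}
    return {sector: 1.0 - t, (sector + 1) % 3: t}


def _shares_to_setting(
    shares: np.ndarray,
    amplitude: float,
    mode: str,
    frequency: float,
    pulse_width: float,
) -> StimSetting:
    if amplitude <= 0.0:
        fractions = (0.0,) * 9
    else:
        percents = largest_remainder(shares)
        fractions = tuple(-pct / 100.0 for pct in percents) + (1.0,)
    return StimSetting(
        amplitude=amplitude,
        fractions=fractions,
        frequency=frequency,
        pulse_width=pulse_width,
        mode=mode,
    )


def ring_point_to_setting(
    point: ExplorationPoint,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
    a_max: float = 5.0,
    frequency: float = 130.0,
    pulse_width: float = 60.0,
) -> StimSetting:
    """Convert a ring-stage point into a monopolar ring-mode setting.

    The cathodic current is interpolated linearly between the two levels
    adjacent to the vertical position; a directional level's share is split
    equally among its three segments.  The case carries the +100% anode.
    """
    if point.stage != RING:
        raise DomainError("ring_point_to_setting requires a ring-stage point")
    if not 0.0 <= point.coord1 <= 3.0:
        raise DomainError(f"vertical position {point.coord1} outside [0, 3]")
    if point.amplitude > a_max:
        raise SafetyError(
            f"amplitude {point.amplitude} mA exceeds limit {a_max} mA"
        )
    shares = np.zeros(geometry.n_electrodes)
    for level, level_share in _vertical_level_shares(point.coord1, geometry).items():
        electrodes = geometry.level_electrodes(level)
        for e in electrodes:
            shares[e] = level_share / len(electrodes)
    return _shares_to_setting(shares, point.amplitude, RING, frequency, pulse_width)


def directional_point_to_setting(
    point: ExplorationPoint,
    base_vertical: float,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
    a_max: float = 5.0,
    frequency: float = 130.0,
    pulse_width: float = 60.0,
) -> StimSetting:
    """Convert a directional-stage point into a steered monopolar setting.

    The vertical split between adjacent levels is fixed by ``base_vertical``
    (carried over from the best ring-stage setting).  Within each
    directional level the current is interpolated between the two segment
    directions adjacent to the rotation angle; ring levels (E1/E8) receive
    their vertical share undirected.
    """
    if point.stage != DIRECTIONAL:
        raise DomainError(
            "directional_point_to_setting requires a directional-stage point"
        )
    if not 0.0 <= base_vertical <= 3.0:
        raise DomainError(f"base vertical {base_vertical} outside [0, 3]")
    if point.amplitude > a_max:
        raise SafetyError(
            f"amplitude {point.amplitude} mA exceeds limit {a_max} mA"
        )
    theta = float(point.coord1) % 360.0
    seg_weights = _angular_segment_weights(theta, geometry)
    shares = np.zeros(geometry.n_electrodes)
    for level, level_share in _vertical_level_shares(base_vertical, geometry).items():
        electrodes = geometry.level_electrodes(level)
        if len(electrodes) == 1:
            shares[electrodes[0]] = level_share
        else:
            for pos, w in seg_weights.items():
                shares[electrodes[pos]] += level_share * w
    return _shares_to_setting(
        shares, point.amplitude, DIRECTIONAL, frequency, pulse_width
    )


def setting_to_vector(
    setting: StimSetting, geometry: LeadGeometry = DEFAULT_GEOMETRY
) -> np.ndarray:
    """Signed fraction vector in fixed order E1..E8 with the case last."""
    return np.asarray(setting.fractions, dtype=float)


def vertical_centroid(
    setting: StimSetting, geometry: LeadGeometry = DEFAULT_GEOMETRY
) -> float:
    """Cathodic-share-weighted vertical position of a setting, in level units."""
    shares = setting.cathodic_shares()
    total = shares.sum()
    if total <= 0.0:
        raise ValueError("setting carries no cathodic current")
    levels = np.asarray(geometry.electrode_levels, dtype=float)
    return float((shares * levels).sum() / total)


def directional_resultant(
    setting: StimSetting, geometry: LeadGeometry = DEFAULT_GEOMETRY
) -> tuple[float, float]:
    """Circular mean of the cathodic steering, as ``(rho, theta_deg)``.

    ``rho`` is the resultant length relative to the total cathodic share:
    0 for a purely ring-symmetric setting, 1 for a fully steered one.
    """
    shares = setting.cathodic_shares()
    total = shares.sum()
    if total <= 0.0:
        raise ValueError("setting carries no cathodic current")
    x = y = 0.0
    for e, share in enumerate(shares):
        if share <= 0.0:
            continue
        angle = geometry.electrode_angle(e)
        if angle is None:
            continue
        x += share * math.cos(math.radians(angle))
        y += share * math.sin(math.radians(angle))
    rho = math.hypot(x, y) / total
    theta = math.degrees(math.atan2(y, x)) % 360.0 if rho > 1e-12 else 0.0
    return rho, theta


# ---------------------------------------------------------------------------
# Electrode-configuration string dialect ("E1: -70%, E2, E3, E4: -10%")
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^(E[1-8])$")
_LABEL_PCT_RE = re.compile(r"^(E[1-8])\s*:\s*([+-]?\d+)\s*%$")


def parse_configuration(text: str) -> dict[str, int]:
    """Parse an electrode-configuration string into ``{label: signed percent}``.

    Grouped labels share the trailing percent, e.g. ``"E2, E3, E4: -10%"``
    assigns -10 to all three electrodes.  Unicode minus signs are accepted.
    """
    normalized = (
        text.replace("−", "-").replace("–", "-").replace("—", "-")
    )
    result: dict[str, int] = {}
    pending: list[str] = []
    for token in normalized.split(","):
        token = token.strip()
        if not token:
            continue
        m = _LABEL_RE.match(token)
        if m:
            pending.append(m.group(1))
            continue
        m = _LABEL_PCT_RE.match(token)
        if not m:
            raise ValueError(f"unparseable configuration token {token!r}")
        pct = int(m.group(2))
        for label in pending + [m.group(1)]:
            if label in result:
                raise ValueError(f"electrode {label} listed twice")
            result[label] = pct
        pending = []
    if pending:
        raise ValueError(f"dangling electrode labels without percent: {pending}")
    if not result:
        raise ValueError("empty electrode configuration")
    return result


def format_configuration(
    setting: StimSetting, geometry: LeadGeometry = DEFAULT_GEOMETRY
) -> str:
    """Canonical configuration string: one ``label: pct%`` pair per electrode."""
    parts = []
    for label, pct in zip(geometry.electrode_labels, setting.percents[:8]):
        if pct != 0:
            parts.append(f"{label}: {pct}%")
    return ", ".join(parts)


def setting_from_percents(
    percents: dict[str, int],
    amplitude: float,
    frequency: float = 130.0,
    pulse_width: float = 60.0,
    mode: str = RING,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
) -> StimSetting:
    """Build a setting from a ``{label: signed percent}`` mapping.

    The IPG case balances whatever the lead electrodes do not: a purely
    cathodic (monopolar) configuration gets the case at +100%.
    """
    fractions = [0.0] * 9
    for label, pct in percents.items():
        try:
            idx = geometry.electrode_labels.index(label)
        except ValueError as exc:
            raise ValueError(f"unknown electrode label {label!r}") from exc
        fractions[idx] = pct / 100.0
    fractions[CASE_INDEX] = -sum(fractions[:8])
    return StimSetting(
        amplitude=amplitude,
        fractions=tuple(fractions),
        frequency=frequency,
        pulse_width=pulse_width,
        mode=mode,
    )


def steering_angle_linear(
    setting: StimSetting, geometry: LeadGeometry = DEFAULT_GEOMETRY
) -> float:
    """Invert the angular interpolation of a steered setting, in degrees.

    Sums cathodic shares per segment position across directional levels and
    inverts the two-adjacent-segment linear split (the exact inverse of the
    forward mapping, unlike a plain circular mean which bows toward the
    chord between segment directions).
    """
    shares = setting.cathodic_shares()
    weights = [0.0, 0.0, 0.0]
    for e, share in enumerate(shares):
        if share <= 0.0:
            continue
        level = geometry.electrode_levels[e]
        if geometry.segments_per_level[level] == 1:
            continue
        weights[geometry.level_electrodes(level).index(e)] += share
    total = sum(weights)
    if total <= 0.0:
        raise ValueError("setting has no directional cathodic current")
    active = [i for i, w in enumerate(weights) if w > 0.0]
    if len(active) == 1:
        return geometry.segment_angles[active[0]]
    if len(active) != 2:
        raise ValueError("steering spans more than two segment directions")
    a, b = active
    if (a, b) == (0, 2):  # adjacency wraps: sector from 240 deg back to 0 deg
        a, b = 2, 0
    t = weights[b] / total
    return (geometry.segment_angles[a] + t * _SEGMENT_SPAN_DEG) % 360.0


def fit_exploration_point(
    setting: StimSetting,
    stage: str,
    geometry: LeadGeometry = DEFAULT_GEOMETRY,
    theta_step: float = 0.5,
) -> tuple[ExplorationPoint, int]:
    """Invert the fractionalization mapping for a cathodic setting.

    Returns the exploration point whose regenerated integer percents best
    match ``setting`` plus the residual (max absolute percent difference).
    The vertical position is the cathodic centroid; for directional
    settings the rotation angle is found by grid search at ``theta_step``
    resolution.
    """
    p = vertical_centroid(setting, geometry)
    target = np.asarray(setting.percents[:8])

    def residual(candidate: StimSetting) -> int:
        return int(np.max(np.abs(np.asarray(candidate.percents[:8]) - target)))

    if stage == RING:
        point = ExplorationPoint(RING, round(p, 4), setting.amplitude)
        regenerated = ring_point_to_setting(
            point, geometry, a_max=max(setting.amplitude, 5.0)
        )
        return point, residual(regenerated)
    best: tuple[int, float] | None = None
    for theta in np.arange(0.0, 360.0, theta_step):
        point = ExplorationPoint(DIRECTIONAL, float(theta), setting.amplitude)
        regenerated = directional_point_to_setting(
            point, p, geometry, a_max=max(setting.amplitude, 5.0)
        )
        res = residual(regenerated)
        if best is None or res < best[0]:
            best = (res, float(theta))
    assert best is not None
    return ExplorationPoint(DIRECTIONAL, best[1], setting.amplitude), best[0]
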