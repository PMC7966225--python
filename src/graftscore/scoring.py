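"""Ordinal scoring of the grafted alveolus.

Each assessment level (3, 5, 7 and 9 mm below the cementoenamel junction)
receives a horizontal score 0-3 comparing the narrowest labiolingual bone
bridge thickness with the labiolingual width of the central incisor's root
at the same depth.  The top score requires the bridge to be at least as
thick as the root.  The four scores sum to a 0-12 total classified as
failure (0), poor (1-4), moderate (5-8) or good (9-12); a total of 0 is
reserved for sides without any bone bridge.

Two modification rules cover edge cases: a narrow bridge lying above or
between the measurement levels is scored at its own depth and assigned to
the nearest level, and severe incisor root resorption replaces the 9 mm
root-width denominator with the root diameter 0.5 mm beneath the apex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ASSESSMENT_LEVELS_MM,
    GeometryError,
    LabeledVolume,
    ToothLandmarks,
)

#: score-ratio cuts: ratio in [0, CUT1) -> 1, [CUT1, CUT2) -> 2, >= CUT2 -> 3
#: (zero bone width always scores 0).  A ratio exactly at a cut belongs to
#: the higher score, consistent with the "at least the root width" anchor
#: for the top score.
DEFAULT_SCORE_BOUNDARIES: tuple[float, float] = (0.5, 1.0)

CATEGORY_BINS = {
    "failure": (0, 0),
    "poor": (1, 4),
    "moderate": (5, 8),
    "good": (9, 12),
}


class ScoringContractError(ValueError):
    """A scoring rule was invoked outside its stated preconditions."""


def score_level(
    bone_width_mm: float,
    root_width_mm: float,
    boundaries: tuple[float, float] = DEFAULT_SCORE_BOUNDARIES,
) -> int:
    """Horizontal 0-3 score for one level.

    ``bone_width_mm`` is the narrowest labiolingual bridge thickness at the
    level; ``root_width_mm`` the incisor root's labiolingual width used as
    denominator (possibly the near-apex diameter under the resorption rule).
    """
    if not root_width_mm > 0:
        raise ValueError(
            "root_width_mm must be positive (apply the resorption rule first)"
        )
    if bone_width_mm < 0:
        raise ValueError("bone_width_mm must be non-negative")
    if bone_width_mm == 0:
        return 0
    rho = bone_width_mm / root_width_mm
    lo, hi = boundaries
    if rho < lo:
        return 1
    if rho < hi:
        return 2
    return 3


def categorize(total: int) -> str:
    """Map a 0-12 total to failure/poor/moderate/good."""
    if not 0 <= total <= 12:
        raise ValueError("total must be in 0..12")
    for name, (lo, hi) in CATEGORY_BINS.items():
        if lo <= total <= hi:
            return name
    raise AssertionError("unreachable")


def nearest_level(depth_mm: float) -> float:
    """Nearest assessment level to a depth; ties go to the more coronal level."""
    levels = np.asarray(ASSESSMENT_LEVELS_MM)
    dist = np.abs(levels - depth_mm)
    # stable argmin returns the first (most coronal) level on ties
    return float(levels[int(np.argmin(dist))])


@dataclass
class LevelMeasurement:
    """One level's widths, score and rule flags."""

    level_mm: float
    bone_width_mm: float
    root_width_mm: float
    score: int
    flags: frozenset[str] = field(default_factory=frozenset)
    modified_source_depth_mm: float | None = None

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3):
            raise ValueError("score must be in 0..3")
        if "modified_level" not in self.flags and (
            (self.score == 0) != (self.bone_width_mm == 0)
        ):
            raise ValueError("score 0 iff zero bone width (without modification)")
        unknown = set(self.flags) - {"modified_level", "resorption_rule"}
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")


@dataclass
class SideAssessment:
    """Four level measurements plus bridge presence, total and category."""

    side: str
    levels: tuple[LevelMeasurement, LevelMeasurement, LevelMeasurement, LevelMeasurement]
    bridge_present: bool
    total: int
    category: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in ("cleft", "noncleft"):
            raise ValueError("side must be 'cleft' or 'noncleft'")
        if tuple(m.level_mm for m in self.levels) != ASSESSMENT_LEVELS_MM:
            raise ValueError("levels must be the four depths 3/5/7/9 mm in order")
        if self.total != sum(m.score for m in self.levels):
            raise ValueError("total must equal the sum of level scores")
        if (self.total == 0) != (not self.bridge_present):
            raise ValueError("total 0 is reserved for sides without a bone bridge")
        if self.category != categorize(self.total):
            raise ValueError("category inconsistent with total")


def apply_between_level_modification(
    levels: tuple[LevelMeasurement, ...],
    bridge: tuple[bool, float | None],
    width_at_bridge_depth_mm: float,
    root_width_at_bridge_depth_mm: float,
    boundaries: tuple[float, float] = DEFAULT_SCORE_BOUNDARIES,
) -> tuple[LevelMeasurement, ...]:
    """Score a bridge that evaded every measurement level.

    Precondition: a bridge is present but all four level scores are 0.  The
    bridge is scored at its own depth and the score is assigned to the
    nearest level, flagged ``modified_level``.
    """
    present, bridge_depth_mm = bridge
    if not present or bridge_depth_mm is None:
        raise ScoringContractError("modification requires a detected bridge")
    if any(m.score != 0 for m in levels):
        raise ScoringContractError(
            "modification applies only when no level detected the bridge"
        )
    target = nearest_level(bridge_depth_mm)
    score = score_level(
        width_at_bridge_depth_mm, root_width_at_bridge_depth_mm, boundaries
    )
    if score == 0:
        # detected spanning bone with no measurable slice width: bridge is
        # present but below level resolution; minimal nonzero score
        score = 1
    out = []
    for m in levels:
        if m.level_mm == target:
            out.append(
                replace(
                    m,
                    score=score,
                    flags=m.flags | {"modified_level"},
                    modified_source_depth_mm=float(bridge_depth_mm),
                )
            )
        else:
            out.append(m)
    return tuple(out)


def apply_resorption_rule(
    level9: LevelMeasurement,
    root_width_near_apex_mm: float,
    boundaries: tuple[float, float] = DEFAULT_SCORE_BOUNDARIES,
) -> LevelMeasurement:
    """Re-score the 9 mm level against the root diameter 0.5 mm beneath the apex.

    Applies only when the (resorbed) incisor root no longer reaches the 9 mm
    plane, signalled upstream by an absent root width at that depth.
    """
    if level9.root_width_mm > 0:
        raise ScoringContractError(
            "resorption rule applies only when the root is absent at 9 mm"
        )
    if not root_width_near_apex_mm > 0:
        raise ValueError("root_width_near_apex_mm must be positive")
    score = score_level(level9.bone_width_mm, root_width_near_apex_mm, boundaries)
    return replace(
        level9,
        root_width_mm=float(root_width_near_apex_mm),
        score=score,
        flags=level9.flags | {"resorption_rule"},
    )


def assess_side(
    levels: tuple[LevelMeasurement, ...],
    bridge_present: bool,
    side: str = "cleft",
    provenance: dict | None = None,
) -> SideAssessment:
    """Total the four level scores and classify the side."""
    total = int(sum(m.score for m in levels))
    if bridge_present and total == 0:
        raise ScoringContractError(
            "bridge present but total 0: between-level modification was skipped"
        )
    if not bridge_present and total > 0:
        raise ScoringContractError("nonzero scores without a detected bridge")
    return SideAssessment(
        side=side,
        levels=tuple(levels),  # type: ignore[arg-type]
        bridge_present=bridge_present,
        total=total,
        category=categorize(total),
        provenance=provenance or {},
    )


def assess_volume(
    volume: LabeledVolume,
    landmarks: dict[str, ToothLandmarks],
    side: str = "cleft",
    boundaries: tuple[float, float] = DEFAULT_SCORE_BOUNDARIES,
) -> SideAssessment:
    """Full pipeline: reorient, detect the bridge, measure, score, classify.

    ``landmarks`` must contain the reference central incisor under key
    ``"incisor"``; a ``"canine"`` entry is optional (root labels suffice for
    the mesiodistal sweep).
    """
    from . import geometry  # local import to keep module load order simple

    inc = landmarks["incisor"]
    extra = {k: v for k, v in landmarks.items() if k != "incisor"}
    vol = geometry.reorient_to_tooth_axis(volume, inc, extra_landmarks=extra)
    lm: ToothLandmarks = vol.meta["landmarks"]["incisor"]

    present, bridge_depth = geometry.detect_bridge(vol, lm)
    apex_depth = lm.root_length_mm
    prov: dict = {
        "side": side,
        "bridge_present": present,
        "bridge_depth_mm": bridge_depth,
        "score_boundaries": list(boundaries),
        "levels": [],
    }

    measurements: list[LevelMeasurement] = []
    for depth in ASSESSMENT_LEVELS_MM:
        section = geometry.extract_level_section(vol, lm, depth)
        try:
            bone_w = geometry.measure_min_bridge_width(section)
        except GeometryError:
            bone_w = 0.0 if not present else geometry.measure_min_bridge_width(
                section, centroids=geometry.projected_root_centroids(vol)
            )
        root_w = geometry.measure_root_width(vol, lm, depth)
        if root_w is None:
            if depth != ASSESSMENT_LEVELS_MM[-1]:
                raise GeometryError(
                    f"incisor root absent at {depth:g} mm; only the 9 mm level "
                    "supports the resorption rule"
                )
            near_apex = geometry.measure_root_width(vol, lm, apex_depth - 0.5)
            if near_apex is None:
                raise GeometryError("incisor root absent 0.5 mm above its apex")
            lvl = apply_resorption_rule(
                _raw_level(depth, bone_w, 0.0), near_apex, boundaries
            )
            measurements.append(lvl)
        else:
            score = score_level(bone_w, root_w, boundaries)
            measurements.append(
                LevelMeasurement(depth, bone_w, root_w, score, frozenset())
            )
        m = measurements[-1]
        prov["levels"].append(
            {"level_mm": m.level_mm, "bone_width_mm": m.bone_width_mm,
             "root_width_mm": m.root_width_mm, "score": m.score,
             "flags": sorted(m.flags)}
        )

    levels = tuple(measurements)
    if present and all(m.score == 0 for m in levels):
        assert bridge_depth is not None
        section = geometry.extract_level_section(vol, lm, bridge_depth)
        bone_w = geometry.measure_min_bridge_width(
            section, centroids=geometry.projected_root_centroids(vol)
        )
        root_w = geometry.measure_root_width(vol, lm, bridge_depth)
        if root_w is None:
            root_w = geometry.measure_root_width(vol, lm, apex_depth - 0.5)
        if root_w is None:
            raise GeometryError("no incisor root width available at bridge depth")
        levels = apply_between_level_modification(
            levels, (present, bridge_depth), bone_w, root_w, boundaries
        )
        prov["modification"] = {
            "bridge_depth_mm": bridge_depth, "bone_width_mm": bone_w,
            "root_width_mm": root_w,
        }
        for entry, m in zip(prov["levels"], levels):
            entry["score"] = m.score
            entry["flags"] = sorted(m.flags)

    return assess_side(levels, present, side=side, provenance=prov)


def _raw_level(depth: float, bone_w: float, root_w: float) -> LevelMeasurement:
    """Pre-resorption placeholder with a zero root width (not yet scored)."""
    lm = LevelMeasurement.__new__(LevelMeasurement)
    lm.level_mm = depth
    lm.bone_width_mm = bone_w
    lm.root_width_mm = root_w
    lm.score = 0
    lm.flags = frozenset()
    lm.modified_source_depth_mm = None
    return lm
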