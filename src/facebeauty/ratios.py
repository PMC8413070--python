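"""The 19-value facial ratio feature set (FS) and its normalization.

Fourteen *golden ratios* compare facial distance pairs against the classical
ideal phi ~ 1.618 (e.g. the under-eye span over the interocular span); five
*symmetry ratios* compare a left-side distance with its right-side
counterpart, so a perfectly bilaterally symmetric face scores 1.0 on all
five.  All 19 values are ratios of Euclidean landmark distances and are
therefore invariant under translation, rotation and uniform scaling of the
landmark set.

Ratios are defined declaratively by an *index map*: each entry names a
numerator and a denominator distance expression over 1-based landmark
indices.  A distance endpoint may be a single landmark or the midpoint of
two landmarks (written ``[i, j]``), and the denominator may carry a scale
factor (the "half upper-lip height" row).  Alternate schemas therefore load
without code changes.

Two maps ship:

``"printed"`` (default)
    The ratio table as published for the 86-point schema, including its
    internally inconsistent nose-width denominator d(65,59) in rows 2 and 5
    (rows 7, 8, 13 use d(65,69)).  One forced repair: the published mouth
    width references landmark 87, which does not exist in an 86-point
    schema; the mouth-corner pair (74, 80) — the pair the symmetry rows
    identify as the mouth corners — is used instead.
``"nose-width-corrected"``
    Identical except d(65,69) is used for the nose width everywhere.

Normalization follows a two-step scheme: z-score each value against the
fitting set, then linearly rescale so the fitting set's minimum and maximum
land exactly on configurable bounds (defaults lb=0, ub=1.618, the golden
ratio).  Applied to new data the map extrapolates rather than clips, so it
stays strictly monotone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landmarks import LandmarkSet, Point2D, euclidean_distance, midpoint

__all__ = [
    "RatioDef",
    "RatioFeatureVector",
    "NormalizationParams",
    "DegenerateLandmarkError",
    "GOLDEN_RATIO",
    "INDEX_MAPS",
    "GOLDEN_NAMES",
    "SYMMETRY_NAMES",
    "FEATURE_NAMES",
    "golden_ratios",
    "symmetry_ratios",
    "feature_set",
    "fit_normalization",
    "apply_normalization",
]

#: phi, the classical golden ratio and the default normalization upper bound.
GOLDEN_RATIO = 1.618


class DegenerateLandmarkError(ValueError):
    """A ratio's denominator distance is zero (coincident landmarks)."""


# A point reference is an int (landmark index) or a 2-list/tuple [i, j]
# meaning the midpoint of landmarks i and j.
PointRef = int | Sequence[int]


@dataclass(frozen=True)
class RatioDef:
    """One ratio: (distance num_a..num_b) / (scale * distance den_a..den_b)."""

    name: str
    description: str
    num: tuple[PointRef, PointRef]
    den: tuple[PointRef, PointRef]
    den_scale: float = 1.0


def _resolve(landmarks: LandmarkSet, ref: PointRef) -> Point2D:
    if isinstance(ref, int):
        return landmarks[ref]
    i, j = ref
    return midpoint(landmarks[i], landmarks[j])


def _ratio_value(landmarks: LandmarkSet, rd: RatioDef) -> float:
    num = euclidean_distance(_resolve(landmarks, rd.num[0]),
                             _resolve(landmarks, rd.num[1]))
    den = euclidean_distance(_resolve(landmarks, rd.den[0]),
                             _resolve(landmarks, rd.den[1])) * rd.den_scale
    if den == 0.0:
        raise DegenerateLandmarkError(
            f"ratio {rd.name!r} ({rd.description}): zero denominator "
            f"distance between {rd.den[0]} and {rd.den[1]}"
        )
    return num / den


_BROW_MID = (23, 37)  # midpoint between the brow heads: the inter-brow point

_GOLDEN_PRINTED: tuple[RatioDef, ...] = (
    RatioDef("g01", "Under eyes/Interocular", (49, 57), (43, 55)),
    RatioDef("g02", "Under eyes/Nose width", (49, 57), (65, 59)),
    RatioDef("g03", "Mouth width/Interocular", (74, 80), (43, 55)),
    RatioDef("g04", "Upper lip-jaw/Interocular", (77, 12), (43, 55)),
    RatioDef("g05", "Upper lip-jaw/Nose width", (77, 12), (65, 59)),
    RatioDef("g06", "Interocular/Lip height", (43, 55), (77, 83)),
    RatioDef("g07", "Nose width/Interocular", (65, 69), (43, 55)),
    RatioDef("g08", "Nose width/Upper lip height (half)",
             (65, 69), (77, 84), den_scale=0.5),
    RatioDef("g09", "Interocular/Nose mouth height", (43, 55), (67, 77)),
    RatioDef("g10", "Face top-eyebrows/Eyebrows-Nose",
             (1, _BROW_MID), (_BROW_MID, 67)),
    RatioDef("g11", "Eyebrows-nose/Nose-jaw", (_BROW_MID, 67), (67, 12)),
    RatioDef("g12", "Face top-eyebrows/Nose-Jaw", (1, _BROW_MID), (67, 12)),
    RatioDef("g13", "Interocular/Nose width", (43, 55), (65, 69)),
    RatioDef("g14", "Face height/Face width", (1, 12), (7, 17)),
)

_SYMMETRY: tuple[RatioDef, ...] = (
    RatioDef("s01", "Lower eyebrow length", (27, 32), (38, 42)),
    RatioDef("s02", "Lower lip length", (80, 84), (74, 84)),
    RatioDef("s03", "Upper eyebrow", (23, _BROW_MID), (35, _BROW_MID)),
    RatioDef("s04", "Upper lip", (80, 77), (74, 77)),
    RatioDef("s05", "Nose", (65, 67), (69, 67)),
)


def _with_nose_corrected(defs: tuple[RatioDef, ...]) -> tuple[RatioDef, ...]:
    out = []
    for rd in defs:
        den = tuple(65 if r == 65 else (69 if r == 59 else r) for r in rd.den) \
            if rd.den == (65, 59) else rd.den
        out.append(RatioDef(rd.name, rd.description, rd.num, den, rd.den_scale))
    return tuple(out)


#: Shipped index maps: name -> (golden defs, symmetry defs).
INDEX_MAPS: dict[str, tuple[tuple[RatioDef, ...], tuple[RatioDef, ...]]] = {
    "printed": (_GOLDEN_PRINTED, _SYMMETRY),
    "nose-width-corrected": (_with_nose_corrected(_GOLDEN_PRINTED), _SYMMETRY),
}

GOLDEN_NAMES: tuple[str, ...] = tuple(rd.name for rd in _GOLDEN_PRINTED)
SYMMETRY_NAMES: tuple[str, ...] = tuple(rd.name for rd in _SYMMETRY)
#: Canonical FS ordering: the 14 golden ratios then the 5 symmetry ratios.
FEATURE_NAMES: tuple[str, ...] = GOLDEN_NAMES + SYMMETRY_NAMES


def load_index_map(config: Mapping) -> tuple[tuple[RatioDef, ...], tuple[RatioDef, ...]]:
    """Build an index map from a structured config.

    ``config`` maps ``"golden"`` / ``"symmetry"`` to lists of entries
    ``{name, description?, num: [ref, ref], den: [ref, ref], den_scale?}``
    where each ref is an int landmark index or a 2-list ``[i, j]`` meaning
    the midpoint of i and j.
    """
    def parse_ref(r) -> PointRef:
        if isinstance(r, int):
            return r
        return (int(r[0]), int(r[1]))

    def parse_block(entries) -> tuple[RatioDef, ...]:
        return tuple(
            RatioDef(
                e["name"], e.get("description", e["name"]),
                (parse_ref(e["num"][0]), parse_ref(e["num"][1])),
                (parse_ref(e["den"][0]), parse_ref(e["den"][1])),
                float(e.get("den_scale", 1.0)),
            )
            for e in entries
        )

    return parse_block(config["golden"]), parse_block(config["symmetry"])


def _resolve_map(index_map) -> tuple[tuple[RatioDef, ...], tuple[RatioDef, ...]]:
    if isinstance(index_map, str):
        try:
            return INDEX_MAPS[index_map]
        except KeyError:
            raise ValueError(f"unknown index map {index_map!r}; "
                             f"available: {sorted(INDEX_MAPS)}") from None
    if isinstance(index_map, Mapping):
        return load_index_map(index_map)
    return index_map  # already a (golden, symmetry) tuple of RatioDefs


def golden_ratios(landmarks: LandmarkSet,
                  index_map="printed") -> dict[str, float]:
    """The 14 golden ratios, in table order, as an ordered name->value dict."""
    golden, _ = _resolve_map(index_map)
    return {rd.name: _ratio_value(landmarks, rd) for rd in golden}


def symmetry_ratios(landmarks: LandmarkSet,
                    index_map="printed") -> dict[str, float]:
    """The 5 symmetry ratios; 1.0 indicates perfect bilateral symmetry."""
    _, symmetry = _resolve_map(index_map)
    return {rd.name: _ratio_value(landmarks, rd) for rd in symmetry}


@dataclass(frozen=True)
class RatioFeatureVector:
    """The 19-value FS for one face: 14 golden ratios then 5 symmetry ratios."""

    golden: dict[str, float]
    symmetry: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.golden) != 14 or len(self.symmetry) != 5:
            raise ValueError("FS must have 14 golden + 5 symmetry ratios")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.golden) + tuple(self.symmetry)

    def as_vector(self) -> np.ndarray:
        """Length-19 array, golden ratios first, stable order."""
        return np.array(list(self.golden.values())
                        + list(self.symmetry.values()), dtype=float)

    def __len__(self) -> int:
        return 19


def feature_set(landmarks: LandmarkSet,
                index_map="printed") -> RatioFeatureVector:
    """Compute the full 19-value FS for one landmark set.

    Raises :class:`DegenerateLandmarkError` if any denominator distance is
    zero, and ``ValueError`` (from landmark validation) on non-finite input.
    """
    return RatioFeatureVector(
        golden=golden_ratios(landmarks, index_map),
        symmetry=symmetry_ratios(landmarks, index_map),
    )


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted parameters of the two-step z-score + linear-scaling map."""

    mean_s: float
    std_s: float
    min_z: float
    max_z: float
    lb: float = 0.0
    ub: float = GOLDEN_RATIO

    def __post_init__(self) -> None:
        if not self.std_s > 0:
            raise ValueError("std_s must be > 0")
        if not self.max_z > self.min_z:
            raise ValueError("max_z must exceed min_z")
        if not self.ub > self.lb:
            raise ValueError("ub must exceed lb")


def fit_normalization(scores: Sequence[float], lb: float = 0.0,
                      ub: float = GOLDEN_RATIO, ddof: int = 0) -> NormalizationParams:
    """Fit the two-step normalization on a set of values.

    z_i = (s_i - mean(S)) / std(S), then a linear map sending
    [min(Z), max(Z)] onto [lb, ub].  ``ddof=0`` (population standard
    deviation) is the default z-score convention; pass ``ddof=1`` for the
    sample form.

    Raises on fewer than 2 values or a constant input (std = 0).
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 values to fit normalization")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite value in normalization input")
    std = float(s.std(ddof=ddof))
    if std == 0.0:
        raise ValueError("degenerate distribution: all values equal (std = 0)")
    mean = float(s.mean())
    z = (s - mean) / std
    return NormalizationParams(mean_s=mean, std_s=std,
                               min_z=float(z.min()), max_z=float(z.max()),
                               lb=float(lb), ub=float(ub))


def apply_normalization(scores: Sequence[float], params: NormalizationParams,
                        clip: bool = False) -> np.ndarray:
    """Apply a fitted normalization; strictly monotone, affine.

    On the fitting set itself the minimum maps exactly to ``lb`` and the
    maximum exactly to ``ub``.  Out-of-range inputs extrapolate beyond the
    bounds unless ``clip=True``.
    """
    s = np.asarray(list(scores), dtype=float)
    z = (s - params.mean_s) / params.std_s
    out = params.lb + (z - params.min_z) / (params.max_z - params.min_z) \
        * (params.ub - params.lb)
    if clip:
        out = np.clip(out, params.lb, params.ub)
    return out
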