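"""Synthetic faces: landmark sets, toy renders, and planted-signal scores.

Real face datasets of this kind ship three artifacts per face — an 86-point
landmark file, a 350x350 frontal image, and a mean attractiveness score on
a 1-5 scale.  This module emulates all three so the entire pipeline is
exercisable without any external download.

The canonical template is a fixed, bilaterally mirror-symmetric 86-point
layout in a 350x350 frame whose indices play the anatomical roles the
ratio tables assume (face outline 1-22, brows 23-42, eyes 43-62, nose
63-70, mouth 71-86).  By construction all five symmetry ratios equal 1.0
exactly on the template and all 19 ratios are finite and positive.

``sample_face`` perturbs the template: named ratios can be *warped* to
target values (the landmark pair in the ratio's numerator is scaled about
its midpoint), and mirror-breaking Gaussian jitter of a chosen standard
deviation is applied anti-symmetrically, so the symmetric component of the
face is preserved while the symmetry ratios drift from 1.

Rendering is deliberately schematic — a skin-colored face polygon with
landmark-anchored dark features on a gray background, plus Gaussian pixel
speckle — but it carries controllable hue, texture and shape signal into
the descriptor blocks, which is all the pipeline needs.

``make_dataset`` plants a named score function (``"ratio-linear"``,
``"hue-only"`` or ``"fusion"``) on the sampled faces, maps the raw values
affinely onto the batch's [1, 5] range, adds Gaussian rater noise and
clips to [1, 5].  Everything is seeded and regenerates bit-exactly.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .landmarks import LandmarkSet, N_LANDMARKS, write_landmarks
from .ratios import INDEX_MAPS, RatioDef

__all__ = [
    "FaceSpec",
    "SyntheticRecord",
    "SyntheticDataset",
    "IMAGE_SIZE",
    "SCORE_FUNCTIONS",
    "make_landmark_template",
    "sample_face",
    "render_face",
    "make_dataset",
    "write_dataset",
]

#: Frame size (width = height, pixels) of rendered faces.
IMAGE_SIZE = 350

# The 86-point template: index -> (x, y), y downward, midline at x = 175.
# Mirror pairs are exact integer reflections about the midline, so every
# symmetry ratio is exactly 1.0 on the template.
_TEMPLATE: dict[int, tuple[float, float]] = {
    # face outline: 1 = forehead top, 2..11 down the left side, 12 = chin,
    # 13..22 back up the right side
    1: (175, 38),
    2: (120, 55), 3: (85, 85), 4: (65, 120), 5: (57, 150), 6: (55, 168),
    7: (55, 185), 8: (60, 225), 9: (75, 265), 10: (100, 298), 11: (140, 322),
    12: (175, 332),
    13: (210, 322), 14: (250, 298), 15: (275, 265), 16: (290, 225),
    17: (295, 185), 18: (295, 168), 19: (293, 150), 20: (285, 120),
    21: (265, 85), 22: (230, 55),
    # brows: left 23..32, right 33..42
    23: (95, 95), 24: (120, 90), 25: (111, 143), 26: (130, 88), 27: (110, 100),
    28: (105, 105), 29: (125, 95), 30: (135, 92), 31: (145, 96), 32: (150, 98),
    33: (245, 105), 34: (220, 88), 35: (239, 143), 36: (230, 90), 37: (255, 95),
    38: (200, 98), 39: (225, 95), 40: (215, 92), 41: (205, 96), 42: (240, 100),
    # eyes: left 43..52, right 53..62
    43: (145, 160), 44: (105, 152), 45: (95, 160), 46: (115, 150),
    47: (130, 150), 48: (110, 172), 49: (127, 175), 50: (135, 170),
    51: (120, 148), 52: (120, 162),
    53: (255, 160), 54: (235, 150), 55: (205, 160), 56: (245, 152),
    57: (223, 175), 58: (220, 150), 59: (240, 172), 60: (215, 170),
    61: (230, 148), 62: (230, 162),
    # nose 63..70
    63: (175, 155), 64: (160, 200), 65: (150, 220), 66: (162, 228),
    67: (175, 225), 68: (188, 228), 69: (200, 220), 70: (190, 200),
    # mouth 71..86
    71: (150, 264), 72: (160, 258), 73: (168, 256), 74: (140, 270),
    75: (152, 278), 76: (182, 256), 77: (175, 260), 78: (158, 270),
    79: (192, 270), 80: (210, 270), 81: (198, 278), 82: (175, 272),
    83: (175, 280), 84: (175, 285), 85: (190, 258), 86: (200, 264),
}

#: (left index, right index) exact mirror pairs of the template.
MIRROR_PAIRS: tuple[tuple[int, int], ...] = (
    (2, 22), (3, 21), (4, 20), (5, 19), (6, 18), (7, 17), (8, 16), (9, 15),
    (10, 14), (11, 13),
    (23, 37), (24, 36), (25, 35), (26, 34), (27, 42), (28, 33), (29, 39),
    (30, 40), (31, 41), (32, 38),
    (43, 55), (44, 56), (45, 53), (46, 54), (47, 58), (48, 59), (49, 57),
    (50, 60), (51, 61), (52, 62),
    (64, 70), (65, 69), (66, 68),
    (71, 86), (72, 85), (73, 76), (74, 80), (75, 81), (78, 79),
)

#: Landmarks lying on the vertical midline.
MIDLINE: tuple[int, ...] = (1, 12, 63, 67, 77, 82, 83, 84)


def make_landmark_template(image_id: str = "template") -> LandmarkSet:
    """The canonical mirror-symmetric 86-point landmark layout."""
    pts = [_TEMPLATE[i] for i in range(1, N_LANDMARKS + 1)]
    return LandmarkSet(pts, image_id=image_id,
                       image_size=(IMAGE_SIZE, IMAGE_SIZE))


@dataclass(frozen=True)
class FaceSpec:
    """Controls for one sampled face.

    asymmetry
        Standard deviation (px) of the mirror-breaking landmark jitter.
    ratio_targets
        Map of golden-ratio name (e.g. ``"g01"``) to a target value; the
        numerator landmark pair is rescaled about its midpoint to hit it.
    hue, saturation
        Skin color of the rendered face, HSV convention on [0, 1).
    texture_noise_sd
        Standard deviation of the Gaussian pixel speckle, 8-bit units.
    """

    asymmetry: float = 0.0
    ratio_targets: dict[str, float] = field(default_factory=dict)
    hue: float = 0.08
    saturation: float = 0.5
    texture_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.asymmetry < 0 or self.texture_noise_sd < 0:
            raise ValueError("asymmetry and texture_noise_sd must be >= 0")
        if not (0 <= self.hue < 1 and 0 <= self.saturation <= 1):
            raise ValueError("hue must be in [0,1) and saturation in [0,1]")


class RatioTargetError(ValueError):
    """A requested ratio target is unsupported or geometrically infeasible."""


def _find_ratio_def(name: str) -> RatioDef:
    golden, symmetry = INDEX_MAPS["printed"]
    for rd in golden + symmetry:
        if rd.name == name:
            return rd
    raise RatioTargetError(f"unknown ratio name {name!r}")


def _warp_to_targets(pts: np.ndarray, targets: dict[str, float]) -> np.ndarray:
    """Scale each target ratio's numerator landmark pair to hit its target.

    Only ratios whose numerator endpoints are plain landmarks (not
    midpoints) and disjoint from the denominator are warpable; a shared
    landmark would make the target self-referential, hence infeasible.
    """
    pts = pts.copy()
    for name, target in targets.items():
        rd = _find_ratio_def(name)
        if target <= 0:
            raise RatioTargetError(f"{name}: target must be > 0, got {target}")
        a, b = rd.num
        if not (isinstance(a, int) and isinstance(b, int)):
            raise RatioTargetError(
                f"{name}: numerator involves a midpoint; not warpable"
            )
        den_pts = {r for ref in rd.den for r in
                   ((ref,) if isinstance(ref, int) else tuple(ref))}
        if {a, b} & den_pts:
            raise RatioTargetError(
                f"{name}: numerator and denominator share a landmark; "
                "the target is geometrically self-referential"
            )

        def coord(ref):
            if isinstance(ref, int):
                return pts[ref - 1]
            i, j = ref
            return (pts[i - 1] + pts[j - 1]) / 2.0

        den = float(np.linalg.norm(coord(rd.den[0]) - coord(rd.den[1])))
        num = float(np.linalg.norm(pts[a - 1] - pts[b - 1]))
        if den == 0.0 or num == 0.0:
            raise RatioTargetError(f"{name}: degenerate geometry")
        factor = target * den * rd.den_scale / num
        mid = (pts[a - 1] + pts[b - 1]) / 2.0
        pts[a - 1] = mid + (pts[a - 1] - mid) * factor
        pts[b - 1] = mid + (pts[b - 1] - mid) * factor
    return pts


def _apply_asymmetry(pts: np.ndarray, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Anti-symmetric Gaussian jitter: left point gets +d, its mirror gets
    the sign-flipped reflection, so the pair's symmetric average is kept."""
    pts = pts.copy()
    if sd == 0:
        return pts
    for left, right in MIRROR_PAIRS:
        d = rng.normal(0.0, sd, size=2)
        pts[left - 1] += d
        pts[right - 1] += np.array([d[0], -d[1]])
    for idx in MIDLINE:
        pts[idx - 1][0] += rng.normal(0.0, sd)
    return pts


def render_face(landmarks: LandmarkSet, hue: float, saturation: float,
                texture_noise_sd: float, seed: int = 0) -> np.ndarray:
    """Render a schematic 350x350 RGB face for a landmark set.

    The face outline polygon is filled with the requested HSV skin color
    (value fixed at 0.8), landmark-anchored dark features (brows, eyes,
    nose, mouth) are drawn on top, and seeded Gaussian speckle of the given
    standard deviation is added.  Deterministic for a fixed seed.
    """
    skin = tuple(int(round(255 * c))
                 for c in colorsys.hsv_to_rgb(hue, saturation, 0.8))
    # background: a darker tint of the same tone (ambient/hair), so the
    # hue histogram reflects the face color rather than the frame
    bg = tuple(int(round(255 * c))
               for c in colorsys.hsv_to_rgb(hue, saturation, 0.45))
    dark = (50, 35, 30)
    img = Image.new("RGB", (IMAGE_SIZE, IMAGE_SIZE), bg)
    draw = ImageDraw.Draw(img)

    def xy(i):
        p = landmarks[i]
        return (p.x, p.y)

    outline = [xy(i) for i in range(1, 23)]
    draw.polygon(outline, fill=skin)
    # brows
    draw.line([xy(23), xy(32)], fill=dark, width=4)
    draw.line([xy(38), xy(37)], fill=dark, width=4)
    # eyes: ellipses centred between the inner and outer corners
    for inner, outer in ((43, 45), (55, 53)):
        (x1, y1), (x2, y2) = xy(inner), xy(outer)
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        rx = abs(x2 - x1) / 2 + 4
        draw.ellipse([cx - rx, cy - 8, cx + rx, cy + 8], fill=dark)
    # under-eye shading anchored at landmarks 49 / 57
    for i in (49, 57):
        x, y = xy(i)
        draw.line([(x - 10, y), (x + 10, y)], fill=dark, width=2)
    # nose: bridge line plus nostril base
    draw.line([xy(63), xy(67)], fill=dark, width=3)
    draw.line([xy(65), xy(69)], fill=dark, width=3)
    # mouth: corner-to-corner band through the lip midpoints
    draw.line([xy(74), xy(77), xy(80)], fill=dark, width=4)
    draw.line([xy(74), xy(83), xy(80)], fill=dark, width=4)

    arr = np.asarray(img, dtype=float)
    if texture_noise_sd > 0:
        noise = np.random.default_rng(seed).normal(
            0.0, texture_noise_sd, size=arr.shape)
        arr = arr + noise
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def sample_face(spec: FaceSpec,
                image_id: str = "synthetic") -> tuple[LandmarkSet, np.ndarray]:
    """Sample one (landmark set, rendered image) pair from a FaceSpec."""
    rng = np.random.default_rng(spec.seed)
    pts = make_landmark_template().as_array()
    if spec.ratio_targets:
        pts = _warp_to_targets(pts, spec.ratio_targets)
    pts = _apply_asymmetry(pts, spec.asymmetry, rng)
    landmarks = LandmarkSet.from_array(pts, image_id=image_id,
                                       image_size=(IMAGE_SIZE, IMAGE_SIZE))
    image = render_face(landmarks, spec.hue, spec.saturation,
                        spec.texture_noise_sd, seed=spec.seed)
    return landmarks, image


@dataclass(frozen=True)
class SyntheticRecord:
    """One generated face: landmarks, rendered image, score, face spec."""

    image_id: str
    landmarks: LandmarkSet
    image: np.ndarray
    score: float
    spec: FaceSpec


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated cohort plus the metadata needed to regenerate it."""

    records: tuple[SyntheticRecord, ...]
    metadata: dict

    def __len__(self) -> int:
        return len(self.records)

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records], dtype=float)


# Each planted score function draws per-face controls and returns
# (FaceSpec kwargs, raw latent score).  The latent components are
# standardized against their known uniform ranges so the stated weights
# are in standard-deviation units.
def _std_uniform(x: float, lo: float, hi: float) -> float:
    return (x - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))


def _ratio_linear(rng: np.random.Generator) -> tuple[dict, float]:
    g01 = rng.uniform(1.2, 2.0)
    g14 = rng.uniform(1.0, 1.4)
    raw = 1.0 * g01 + 1.5 * g14
    # asymmetry jitter stays off so the realized ratios equal the planted
    # targets and the score is exactly linear in the extracted features
    return dict(ratio_targets={"g01": g01, "g14": g14},
                asymmetry=0.0, hue=0.08, saturation=0.5,
                texture_noise_sd=8.0), raw


def _hue_only(rng: np.random.Generator) -> tuple[dict, float]:
    hue = rng.uniform(0.0, 1.0)
    return dict(hue=hue, saturation=0.8, asymmetry=1.0,
                texture_noise_sd=8.0), float(hue)


def _fusion(rng: np.random.Generator) -> tuple[dict, float]:
    # Skin color is modelled as a 1-D tone axis: hue and saturation co-vary,
    # so the color effect is carried by both the H and S histograms.  Hue
    # stays clear of the 0/1 wrap so speckle cannot alias the two ends.
    # Non-planted factors (asymmetry jitter) are held fixed so the planted
    # effects are identifiable; weights are in sd units of the latent score.
    g01 = rng.uniform(1.2, 2.0)
    g14 = rng.uniform(1.0, 1.4)
    hue = rng.uniform(0.05, 0.95)
    tex = rng.uniform(9.0, 15.0)
    raw = (0.35 * _std_uniform(g01, 1.2, 2.0)
           + 0.35 * _std_uniform(g14, 1.0, 1.4)
           + 0.9 * _std_uniform(hue, 0.05, 0.95)
           + 0.2 * _std_uniform(tex, 9.0, 15.0))
    return dict(ratio_targets={"g01": g01, "g14": g14}, hue=hue,
                saturation=0.3 + 0.65 * hue, asymmetry=0.0,
                texture_noise_sd=tex), float(raw)


SCORE_FUNCTIONS: dict[str, Callable] = {
    "ratio-linear": _ratio_linear,
    "hue-only": _hue_only,
    "fusion": _fusion,
}


def make_dataset(n: int, score_fn: str = "fusion", noise_sd: float = 0.2,
                 seed: int = 0) -> SyntheticDataset:
    """Generate n scored synthetic faces with a planted score function.

    The raw planted values are mapped affinely so the batch spans [1, 5],
    Gaussian noise of ``noise_sd`` is added on the latent scale, and the
    result is clipped to [1, 5] (rater means live on a bounded scale).
    With ``noise_sd=0`` the scores are an exact affine function of the
    planted features.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        fn = SCORE_FUNCTIONS[score_fn]
    except KeyError:
        raise ValueError(f"unknown score function {score_fn!r}; "
                         f"available: {sorted(SCORE_FUNCTIONS)}") from None
    root = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    noise_rng = np.random.default_rng(root.spawn(1)[0])
    face_seeds = np.random.default_rng(root.spawn(1)[0]).integers(
        0, 2 ** 31 - 1, size=n)

    specs, raws = [], []
    for i in range(n):
        kwargs, raw = fn(draw_rng)
        specs.append(FaceSpec(seed=int(face_seeds[i]), **kwargs))
        raws.append(raw)
    raws = np.asarray(raws, dtype=float)
    lo, hi = raws.min(), raws.max()
    scale = (hi - lo) if hi > lo else 1.0
    latent = 1.0 + 4.0 * (raws - lo) / scale
    scores = latent + noise_rng.normal(0.0, noise_sd, size=n) \
        if noise_sd > 0 else latent
    scores = np.clip(scores, 1.0, 5.0)

    records = []
    for i, spec in enumerate(specs):
        image_id = f"syn{i:05d}"
        lm, img = sample_face(spec, image_id=image_id)
        records.append(SyntheticRecord(image_id=image_id, landmarks=lm,
                                       image=img, score=float(scores[i]),
                                       spec=spec))
    metadata = {"n": n, "score_fn": score_fn, "noise_sd": noise_sd,
                "seed": seed,
                "score_map": "affine batch-range map onto [1,5], then clip"}
    return SyntheticDataset(records=tuple(records), metadata=metadata)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Write a dataset as manifest CSV + landmark files + PNG images.

    The layout matches what the real-data loader consumes:
    ``manifest.csv`` with header ``image_id,image_path,landmark_path,score``
    plus ``images/*.png`` and ``landmarks/*.txt``.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "landmarks").mkdir(parents=True, exist_ok=True)
    lines = ["image_id,image_path,landmark_path,score"]
    for rec in dataset.records:
        img_rel = f"images/{rec.image_id}.png"
        lm_rel = f"landmarks/{rec.image_id}.txt"
        Image.fromarray(rec.image).save(outdir / img_rel)
        write_landmarks(rec.landmarks, outdir / lm_rel)
        lines.append(f"{rec.image_id},{img_rel},{lm_rel},{rec.score!r}")
    manifest = outdir / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
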