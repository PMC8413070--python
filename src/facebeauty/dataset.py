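"""Dataset loading and batch feature extraction.

A dataset is declared by a manifest CSV with header
``image_id,image_path,landmark_path,score`` (paths relative to the
manifest's directory; score is the mean rating on the 1-5 scale).
Extraction turns it into :class:`FeatureTables`: one row per image of the
19 ratio features and of each descriptor block, with bit-stable column
order.  Per-image failures are logged and skipped rather than aborting the
batch; a summary count is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import descriptors as desc
from .landmarks import read_landmarks
from .ratios import FEATURE_NAMES, feature_set
from .synthetic import SyntheticDataset

logger = logging.getLogger("facebeauty")

__all__ = ["FeatureTables", "load_manifest", "extract_features",
           "extract_from_manifest", "BLOCK_COLUMNS"]

BLOCK_COLUMNS = {
    "T": list(desc.TextureFeatures.names),
    "S": list(desc.HuVector.names),
}


@dataclass
class FeatureTables:
    """Per-image feature tables: FS plus the T/C/S descriptor blocks.

    All frames share the same image_id index; ``scores`` is the label
    series on the raw 1-5 scale.
    """

    fs: pd.DataFrame
    texture: pd.DataFrame
    color: pd.DataFrame
    shape: pd.DataFrame
    scores: pd.Series

    def matrix(self, fs_columns: Sequence[str] | None = None,
               blocks: Iterable[str] = ()) -> pd.DataFrame:
        """Design matrix: selected FS columns ++ blocks in fixed T, C, S order."""
        parts = [self.fs[list(fs_columns)] if fs_columns is not None else self.fs]
        for label in ("T", "C", "S"):
            if label in tuple(blocks):
                parts.append({"T": self.texture, "C": self.color,
                              "S": self.shape}[label])
        return pd.concat(parts, axis=1)

    def __len__(self) -> int:
        return len(self.fs)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV; validates the expected header."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["image_id", "image_path", "landmark_path", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    if df.empty:
        raise ValueError(f"manifest {path} has no rows")
    return df


def _extract_one(image_id, landmarks, image, index_map, bins_per_channel,
                 glcm_levels, glcm_offsets):
    fs = feature_set(landmarks, index_map=index_map)
    gray = desc.to_grayscale(image)
    tex = desc.texture_features(
        desc.glcm(gray, levels=glcm_levels, offsets=glcm_offsets))
    col = desc.hsv_histogram(image, bins_per_channel=bins_per_channel)
    shp = desc.hu_moments(gray)
    tex_vals = np.nan_to_num(tex.as_vector(), nan=0.0)
    return fs.as_vector(), tex_vals, col.as_vector(), shp.as_vector(), col.names


def _assemble(rows, index_map) -> FeatureTables:
    ids = [r[0] for r in rows]
    color_names = rows[0][4] if rows else ()
    return FeatureTables(
        fs=pd.DataFrame([r[1] for r in rows], index=ids,
                        columns=list(FEATURE_NAMES)),
        texture=pd.DataFrame([r[2] for r in rows], index=ids,
                             columns=BLOCK_COLUMNS["T"]),
        color=pd.DataFrame([r[3] for r in rows], index=ids,
                           columns=list(color_names)),
        shape=pd.DataFrame([r[5] for r in rows], index=ids,
                           columns=BLOCK_COLUMNS["S"]),
        scores=pd.Series([r[6] for r in rows], index=ids, name="score"),
    )


def extract_features(dataset: SyntheticDataset, index_map: str = "printed",
                     bins_per_channel: int = 16, glcm_levels: int = 8,
                     glcm_offsets=desc.DEFAULT_OFFSETS) -> FeatureTables:
    """Extract FS + T/C/S tables from an in-memory synthetic dataset."""
    rows = []
    for rec in dataset.records:
        fs, tex, col, shp, cnames = _extract_one(
            rec.image_id, rec.landmarks, rec.image, index_map,
            bins_per_channel, glcm_levels, glcm_offsets)
        rows.append((rec.image_id, fs, tex, col, cnames, shp, rec.score))
    return _assemble(rows, index_map)


def extract_from_manifest(manifest_path: str | Path,
                          index_map: str = "printed",
                          bins_per_channel: int = 16, glcm_levels: int = 8,
                          glcm_offsets=desc.DEFAULT_OFFSETS) -> FeatureTables:
    """Extract feature tables for every manifest row, skipping failures.

    A row whose landmark file or image cannot be read/validated is logged
    at WARNING and skipped; the function raises only if no row succeeds.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = load_manifest(manifest_path)
    rows, failures = [], 0
    for rec in df.itertuples(index=False):
        try:
            landmarks = read_landmarks(base / rec.landmark_path,
                                       image_id=str(rec.image_id))
            image = np.asarray(Image.open(base / rec.image_path).convert("RGB"))
            fs, tex, col, shp, cnames = _extract_one(
                rec.image_id, landmarks, image, index_map,
                bins_per_channel, glcm_levels, glcm_offsets)
            rows.append((str(rec.image_id), fs, tex, col, cnames, shp,
                         float(rec.score)))
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            failures += 1
            logger.warning("skipping %s: %s", rec.image_id, exc)
    logger.info("extracted %d images, skipped %d", len(rows), failures)
    if not rows:
        raise ValueError("feature extraction failed for every manifest row")
    return _assemble(rows, index_map)
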