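"""86-point facial landmark sets: reading, validation, geometric primitives.

A landmark file in the canonical dialect is 86 lines of ``x y`` (floats,
whitespace-separated), one landmark per line, addressed 1-based in file
order.  The coordinate convention is the usual image-annotation one:
x grows rightward, y grows downward, origin at the top-left pixel,
units are pixels.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

__all__ = [
    "N_LANDMARKS",
    "Point2D",
    "LandmarkSet",
    "LandmarkSchemaError",
    "LandmarkParseError",
    "read_landmarks",
    "write_landmarks",
    "euclidean_distance",
    "midpoint",
]

#: Number of landmarks per face in this schema.
N_LANDMARKS = 86


class LandmarkSchemaError(ValueError):
    """Raised when a landmark file has the wrong number of points."""


class LandmarkParseError(ValueError):
    """Raised when a landmark file contains a malformed line."""


@dataclass(frozen=True)
class Point2D:
    """A 2-D point in pixel coordinates (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinate: ({self.x}, {self.y})")

    def __iter__(self):
        yield self.x
        yield self.y


def euclidean_distance(p: Point2D, q: Point2D) -> float:
    """Euclidean distance d(p, q) in pixels; symmetric, non-negative."""
    return math.hypot(p.x - q.x, p.y - q.y)


def midpoint(p: Point2D, q: Point2D) -> Point2D:
    """Midpoint of the segment pq."""
    return Point2D((p.x + q.x) / 2.0, (p.y + q.y) / 2.0)


class LandmarkSet:
    """An ordered set of exactly 86 landmarks for one face image.

    Landmarks are addressed by 1-based index (``lm[1]`` is the first file
    line), matching the indexing used by the ratio tables.

    Parameters
    ----------
    points
        Sequence of 86 (x, y) pairs or :class:`Point2D`.
    image_id
        Opaque identifier carried through feature tables.
    image_size
        Optional (width, height) of the source image in pixels.
    """

    def __init__(
        self,
        points: Sequence,
        image_id: str = "",
        image_size: tuple[int, int] | None = None,
    ) -> None:
        pts = [p if isinstance(p, Point2D) else Point2D(float(p[0]), float(p[1]))
               for p in points]
        if len(pts) != N_LANDMARKS:
            raise LandmarkSchemaError(
                f"expected {N_LANDMARKS} landmarks, found {len(pts)}"
            )
        self._points: tuple[Point2D, ...] = tuple(pts)
        self.image_id = image_id
        self.image_size = image_size

    def __getitem__(self, index: int) -> Point2D:
        if not 1 <= index <= N_LANDMARKS:
            raise IndexError(
                f"landmark index {index} out of range 1..{N_LANDMARKS}"
            )
        return self._points[index - 1]

    def __len__(self) -> int:
        return N_LANDMARKS

    def __iter__(self):
        return iter(self._points)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return self._points == other._points

    def __repr__(self) -> str:
        return f"LandmarkSet(image_id={self.image_id!r}, n={N_LANDMARKS})"

    def distance(self, m: int, n: int) -> float:
        """d(m, n): Euclidean distance between landmarks m and n (1-based)."""
        return euclidean_distance(self[m], self[n])

    def transformed(self, fn) -> "LandmarkSet":
        """Return a copy with ``fn(Point2D) -> Point2D`` applied to each point."""
        return LandmarkSet([fn(p) for p in self._points],
                           image_id=self.image_id, image_size=self.image_size)

    def as_array(self):
        import numpy as np

        return np.array([[p.x, p.y] for p in self._points], dtype=float)

    @classmethod
    def from_array(cls, arr, image_id: str = "",
                   image_size: tuple[int, int] | None = None) -> "LandmarkSet":
        return cls([(float(x), float(y)) for x, y in arr],
                   image_id=image_id, image_size=image_size)


def _open_text(source: Union[str, Path, TextIO]):
    if isinstance(source, (str, Path)):
        return open(source, "r"), True
    return source, False


def read_landmarks(
    source: Union[str, Path, TextIO],
    dialect: str = "canonical",
    image_id: str | None = None,
) -> LandmarkSet:
    """Read a landmark file.

    Parameters
    ----------
    source
        Path or open text stream.
    dialect
        ``"canonical"`` — exactly 86 ``x y`` lines; ``"tolerant"`` — same,
        but a single leading count/header line is skipped if the file
        would otherwise have 87 lines or the first line is not two floats.
    image_id
        Defaults to the file stem when reading from a path.

    Raises
    ------
    LandmarkSchemaError
        If the point count differs from 86.
    LandmarkParseError
        If a line does not parse as two floats (message cites the line).
    """
    if dialect not in ("canonical", "tolerant"):
        raise ValueError(f"unknown landmark dialect: {dialect!r}")
    stream, should_close = _open_text(source)
    try:
        lines = [ln for ln in (raw.strip() for raw in stream) if ln]
    finally:
        if should_close:
            stream.close()

    if dialect == "tolerant" and lines:
        toks = lines[0].split()
        header_like = len(toks) != 2
        if not header_like:
            try:
                float(toks[0]), float(toks[1])
            except ValueError:
                header_like = True
        if header_like or len(lines) == N_LANDMARKS + 1:
            lines = lines[1:]

    points = []
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if len(toks) != 2:
            raise LandmarkParseError(
                f"line {lineno}: expected two tokens, got {len(toks)}: {line!r}"
            )
        try:
            x, y = float(toks[0]), float(toks[1])
        except ValueError:
            raise LandmarkParseError(
                f"line {lineno}: non-numeric token in {line!r}"
            ) from None
        points.append((x, y))

    if len(points) != N_LANDMARKS:
        raise LandmarkSchemaError(
            f"expected {N_LANDMARKS} landmarks, found {len(points)}"
        )
    if image_id is None:
        image_id = Path(source).stem if isinstance(source, (str, Path)) else ""
    return LandmarkSet(points, image_id=image_id)


def write_landmarks(landmarks: LandmarkSet,
                    target: Union[str, Path, TextIO]) -> None:
    """Write a LandmarkSet in the canonical dialect (86 ``x y`` lines).

    Uses ``repr`` floats so that a read/write round trip is exact.
    """
    body = "".join(f"{p.x!r} {p.y!r}\n" for p in landmarks)
    if isinstance(target, (str, Path)):
        Path(target).write_text(body)
    else:
        target.write(body)
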