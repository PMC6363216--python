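"""Landmark I/O and scheme handling for dorsal-outline configurations.

The unit of data is one photograph's digitized dorsal outline: 30 ordered
2D points running from the first coccygeal vertebra (point 1, croup) over
the withers (point 15) to the medial canthus of the eye (point 30).
Point indices are 1-based in every public interface, matching the
anatomical numbering used in the field; internal arrays are 0-based numpy.

Files are read and written in the TPS landmark format (tpsDig dialect):
records start with ``LM=k``, followed by ``k`` whitespace-separated
coordinate lines and optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

N_OUTLINE_POINTS = 30
#: 1-based index of the withers landmark (tenth thoracic vertebra).
WITHERS_INDEX = 15

REGIONS = ("full", "back_croup", "neck_head")

#: Default fixed-landmark indices for the mixed scheme: the anatomical
#: points 1 (first coccygeal vertebra), 15 (withers) and 30 (eye) are
#: certain; the remaining five clay marks (lumbo-sacral and thoraco-lumbar
#: junctions, atlas, temporo-mandibular joint, facial crest) have no
#: published outline indices, so their placement along the curve is a
#: documented, configurable default.
DEFAULT_MIXED_FIXED = (1, 6, 11, 15, 24, 27, 29, 30)


class TPSParseError(ValueError):
    """Raised when a TPS file violates the record format."""


class SchemeError(ValueError):
    """Raised for inconsistent method-scheme definitions or region misuse."""


@dataclass
class LandmarkConfiguration:
    """One photograph's ordered outline points plus identity metadata.

    ``points`` is a ``(k, 2)`` float array in image units (already
    multiplied by ``scale`` when one was present in the source file).
    """

    points: np.ndarray
    horse_id: str = ""
    condition: str = "standing"
    photo_id: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinate in photo {self.photo_id!r}")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def _region_indices(region: str) -> tuple[int, ...]:
    """1-based point indices belonging to a region window."""
    if region == "full":
        return tuple(range(1, N_OUTLINE_POINTS + 1))
    if region == "back_croup":
        return tuple(range(1, WITHERS_INDEX + 1))        # 1..15, 15 points
    if region == "neck_head":
        return tuple(range(WITHERS_INDEX, N_OUTLINE_POINTS + 1))  # 15..30, 16 points
    raise SchemeError(f"unknown region {region!r}; expected one of {REGIONS}")


@dataclass(frozen=True)
class MethodScheme:
    """Which outline indices are fixed landmarks vs sliding semilandmarks.

    ``fixed_indices`` uses the 1-based anatomical numbering; the sliding
    set is the complement within the region window.
    """

    name: str
    fixed_indices: frozenset[int]
    region: str = "full"
    stabilize_neck_angle: bool = False

    def __post_init__(self) -> None:
        window = set(_region_indices(self.region))
        bad = set(self.fixed_indices) - window
        if bad:
            raise SchemeError(
                f"fixed indices {sorted(bad)} fall outside region {self.region!r}"
            )

    @property
    def window(self) -> tuple[int, ...]:
        return _region_indices(self.region)

    @property
    def sliding_indices(self) -> frozenset[int]:
        return frozenset(self.window) - self.fixed_indices

    def positions_of(self, indices: Iterable[int]) -> np.ndarray:
        """0-based array positions (within the region window) of 1-based indices."""
        window = self.window
        lookup = {idx: pos for pos, idx in enumerate(window)}
        return np.array(sorted(lookup[i] for i in indices), dtype=int)


def mixed_scheme(
    fixed: Sequence[int] = DEFAULT_MIXED_FIXED, stabilize_neck_angle: bool = False
) -> MethodScheme:
    """Mixed method: the clay-marked anatomical points plus the eye are fixed
    landmarks, every other outline point slides."""
    return MethodScheme("mixed", frozenset(fixed), "full", stabilize_neck_angle)


def ssl_scheme(stabilize_neck_angle: bool = False) -> MethodScheme:
    """Pure sliding-semilandmark method: only the medial canthus of the eye
    (point 30) is a fixed landmark; the 29 other points slide."""
    return MethodScheme("ssl", frozenset({N_OUTLINE_POINTS}), "full", stabilize_neck_angle)


@dataclass
class ShapeSample:
    """A homogeneous collection of configurations analysed under one scheme."""

    configurations: list[LandmarkConfiguration]
    scheme: MethodScheme = field(default_factory=ssl_scheme)

    def __post_init__(self) -> None:
        counts = {c.n_points for c in self.configurations}
        if len(counts) > 1:
            raise ValueError(f"mixed point counts in sample: {sorted(counts)}")

    def __len__(self) -> int:
        return len(self.configurations)

    def coords(self) -> np.ndarray:
        """Stack all configurations into an ``(n, k, 2)`` array."""
        return np.stack([c.points for c in self.configurations])

    def with_coords(self, coords: np.ndarray) -> "ShapeSample":
        """Copy of the sample with coordinates replaced, metadata preserved."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape[0] != len(self.configurations):
            raise ValueError("coordinate stack does not match sample size")
        new = [
            replace(c, points=coords[i]) for i, c in enumerate(self.configurations)
        ]
        return ShapeSample(new, self.scheme)


# ---------------------------------------------------------------------------
# TPS format


def read_tps(
    path: str | os.PathLike,
    scheme: MethodScheme | None = None,
    invert_y: bool = False,
    condition: str = "standing",
) -> ShapeSample:
    """Read a TPS landmark file into a :class:`ShapeSample`.

    ``SCALE=`` factors are applied (coordinates multiplied). ``invert_y``
    flips the y axis for files digitized with an image-style origin
    (y growing downward), so downstream shapes render anatomically upright.
    """
    configs: list[LandmarkConfiguration] = []
    with open(path) as fh:
        lines = fh.read().splitlines()

    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"line {i + 1}: expected LM=, got {line!r}")
        record_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"line {i + 1}: bad LM= count {line!r}") from exc
        i += 1
        pts = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines) or "=" in lines[i]:
                raise TPSParseError(
                    f"record {record_no}: LM={k} but only {j} coordinate lines"
                )
            fields = lines[i].split()
            if len(fields) != 2:
                raise TPSParseError(
                    f"line {i + 1}: expected two coordinates, got {lines[i]!r}"
                )
            try:
                pts[j] = [float(fields[0]), float(fields[1])]
            except ValueError as exc:
                raise TPSParseError(
                    f"line {i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        image, ident, scale = "", "", None
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, _, value = lines[i].partition("=")
            key = key.strip().upper()
            if key == "IMAGE":
                image = value.strip()
            elif key == "ID":
                ident = value.strip()
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TPSParseError(f"line {i + 1}: bad SCALE= value") from exc
            i += 1
        if scale is not None:
            pts = pts * scale
        if invert_y:
            pts[:, 1] = -pts[:, 1]
        configs.append(
            LandmarkConfiguration(
                pts,
                horse_id=ident or image or str(record_no),
                condition=condition,
                photo_id=image or str(record_no),
                scale=scale,
            )
        )
    return ShapeSample(configs, scheme if scheme is not None else ssl_scheme())


def write_tps(sample: ShapeSample, path: str | os.PathLike) -> None:
    """Write a sample as a TPS file re-readable by :func:`read_tps`.

    When a configuration carries a scale factor, raw (pixel) coordinates
    are stored and the ``SCALE=`` line re-applies it on read.
    """
    out: list[str] = []
    for c in sample.configurations:
        pts = c.points if c.scale is None else c.points / c.scale
        out.append(f"LM={c.n_points}")
        out.extend(f"{x:.12g} {y:.12g}" for x, y in pts)
        if c.photo_id:
            out.append(f"IMAGE={c.photo_id}")
        if c.horse_id:
            out.append(f"ID={c.horse_id}")
        if c.scale is not None:
            out.append(f"SCALE={c.scale:.12g}")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Geometry-preserving preprocessing


def flip_horizontal(
    config: LandmarkConfiguration, axis_x: float = 0.0
) -> LandmarkConfiguration:
    """Mirror a configuration about the vertical line ``x = axis_x``.

    Point order is untouched: indices are anatomical, not spatial, so a
    head-left profile simply becomes a head-right one.
    """
    pts = config.points.copy()
    pts[:, 0] = 2.0 * axis_x - pts[:, 0]
    return replace(config, points=pts)


def select_region(sample: ShapeSample, region: str) -> ShapeSample:
    """Restrict a full 30-point sample to one outline window.

    ``back_croup`` keeps points 1..15 and ``neck_head`` keeps 15..30 (the
    withers point belongs to both windows). The scheme's fixed/sliding
    sets are intersected with the window; point order is preserved.
    """
    if sample.scheme.region != "full":
        raise SchemeError(
            f"sample is already restricted to {sample.scheme.region!r}"
        )
    if region == "full":
        return sample
    window = _region_indices(region)
    sl = slice(window[0] - 1, window[-1])
    scheme = MethodScheme(
        sample.scheme.name,
        frozenset(sample.scheme.fixed_indices) & set(window),
        region,
        stabilize_neck_angle=False,
    )
    configs = [replace(c, points=c.points[sl]) for c in sample.configurations]
    return ShapeSample(configs, scheme)
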