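"""Tooth outlines, dentitions, and their on-disk formats.

An outline is an *open* ordered 2D point sequence tracing the upper
(functional) crown of a tooth from its mesial to its distal baseline
terminus.  The coordinate convention is x increasing mesial->distal and
y increasing basal->apical.  Dentitions hold one jaw hemisphere only
(tooth rows are bilaterally symmetric), as ordered tooth lists per jaw.

Two on-disk dialects are supported:

* ``csv`` -- one file per dentition with columns
  ``species, jaw, position, point_index, x, y`` (header mandatory);
  ``#``-prefixed ``key: value`` lines before the header carry metadata,
  e.g. ``# orientation: distal_to_mesial`` to request point reversal.
* ``tps`` -- the standard morphometrics TPS format, one specimen per
  tooth with ``ID=species_jaw_position``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import Polygon

__all__ = [
    "Outline",
    "Tooth",
    "Dentition",
    "OutlineFormatError",
    "SegmentationError",
    "resample",
    "center_and_scale",
    "segment_crown",
    "read_dentition",
    "write_dentition",
]

JAWS = ("upper", "lower")

STANDARD_N_POINTS = 1000


class OutlineFormatError(ValueError):
    """Raised when a dentition file violates the format contract."""


class SegmentationError(ValueError):
    """Raised when no crown/base segmentation can be found automatically."""


@dataclass(frozen=True)
class Outline:
    """Open ordered point sequence; first and last points are the baseline termini."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("outline points must be an (n, 2) array")
        if len(pts) < 3:
            raise ValueError("an outline needs at least 3 points")
        if np.any(np.all(pts[1:] == pts[:-1], axis=1)):
            raise ValueError("outline contains identical consecutive points")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Total polyline arc length."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        """Arithmetic mean of the outline points (point-based centroid)."""
        return self.points.mean(axis=0)

    def closed_polygon(self) -> Polygon:
        """Shapely polygon closed by the straight baseline segment."""
        poly = Polygon(self.points)
        if not poly.is_valid:
            raise ValueError("baseline closure self-intersects; cannot form area")
        return poly

    def reversed(self) -> "Outline":
        return Outline(self.points[::-1].copy())


@dataclass(frozen=True)
class Tooth:
    species: str
    jaw: str
    position: int
    outline: Outline

    def __post_init__(self):
        if self.jaw not in JAWS:
            raise ValueError(f"jaw must be one of {JAWS}, got {self.jaw!r}")
        if self.position < 1:
            raise ValueError("tooth positions are 1-based")

    @property
    def tooth_id(self) -> tuple:
        return (self.species, self.jaw, self.position)


@dataclass
class Dentition:
    """Species-keyed pair of tooth rows (one jaw hemisphere)."""

    species: str
    rows: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for jaw, teeth in self.rows.items():
            if jaw not in JAWS:
                raise ValueError(f"unknown jaw {jaw!r}")
            positions = [t.position for t in teeth]
            expected = list(range(1, len(teeth) + 1))
            if positions != expected:
                missing = sorted(set(expected) - set(positions))
                raise OutlineFormatError(
                    f"{self.species}/{jaw}: positions must be consecutive from 1; "
                    f"got {positions} (gap at {missing})"
                )

    def teeth(self):
        for jaw in JAWS:
            yield from self.rows.get(jaw, [])

    def n_teeth(self) -> int:
        return sum(len(v) for v in self.rows.values())


# ---------------------------------------------------------------------------
# geometry


def resample(outline: Outline, n: int) -> Outline:
    """Resample to ``n`` points at equal arc-length spacing.

    Endpoints are preserved exactly; interior points are linearly
    interpolated along the polyline.  An input that already carries
    ``n`` points within 0.1% of uniform spacing is returned unchanged:
    re-interpolating such an outline would move points by no more than
    that same spacing error while accumulating corner-cutting drift, so
    the operation is made exactly idempotent instead.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    pts = outline.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate zero-length outline")
    target = np.linspace(0.0, total, n)
    if len(pts) == n and np.abs(s - target).max() < 1e-3 * total:
        return outline
    x = np.interp(target, s, pts[:, 0])
    y = np.interp(target, s, pts[:, 1])
    x[0], y[0] = pts[0]
    x[-1], y[-1] = pts[-1]
    return Outline(np.column_stack([x, y]))


def center_and_scale(outline: Outline, mode: str = "length") -> Outline:
    """Center on the point centroid and normalize size.

    mode ``"length"`` scales to unit polyline length; mode ``"area"``
    scales so the baseline-closed polygon has unit area.
    """
    pts = outline.points
    if mode == "length":
        size = outline.length
    elif mode == "area":
        size = np.sqrt(outline.closed_polygon().area)
        if size <= 0:
            raise ValueError("degenerate zero-area outline")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scaled = pts / size
    return Outline(scaled - scaled.mean(axis=0))


def _moving_average(pts: np.ndarray, window: int, closed: bool) -> np.ndarray:
    if closed:
        pad = window // 2
        ext = np.vstack([pts[-pad:], pts, pts[:pad]])
        kernel = np.ones(window) / window
        sm = np.column_stack(
            [np.convolve(ext[:, k], kernel, mode="valid") for k in (0, 1)]
        )
        return sm
    # open curve: shrink the window near the ends
    out = pts.copy()
    half = window // 2
    for i in range(len(pts)):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def segment_crown(full_outline: Outline, termini: tuple | None = None) -> Outline:
    """Cut the upper-crown outline from a full tooth outline.

    Segmentation rules, in order of precedence:

    1. explicit ``termini`` (two point indices) supplied as metadata --
       honored verbatim;
    2. the lowest concave lateral point on each side of the apex, when a
       concavity is detectable on both sides (detected on a window-5
       moving-average smoothing of the outline);
    3. otherwise, the most distant pair of points in the lower half of
       the bounding box.

    Closed input (first point approximately equal to the last) is
    treated as a ring; open input without termini is assumed to be an
    already-segmented crown and returned unchanged.
    """
    pts = full_outline.points
    closed = np.allclose(pts[0], pts[-1], atol=1e-9 * max(1.0, np.abs(pts).max()))
    if closed:
        pts = pts[:-1]
    if termini is None and not closed:
        return full_outline

    if termini is not None:
        i, j = sorted(int(k) for k in termini)
        if not (0 <= i < j < len(pts)):
            raise ValueError("termini indices out of range")
    else:
        i, j = _detect_base(pts, closed)

    return _cut_arc(pts, i, j, closed)


def _detect_base(pts: np.ndarray, closed: bool) -> tuple:
    scale = np.ptp(pts, axis=0).max()
    sm = _moving_average(pts, 5, closed)
    n = len(sm)
    idx = np.arange(n)
    prev = (idx - 1) % n if closed else np.clip(idx - 1, 0, n - 1)
    nxt = (idx + 1) % n if closed else np.clip(idx + 1, 0, n - 1)
    e1 = sm[idx] - sm[prev]
    e2 = sm[nxt] - sm[idx]
    cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    # orientation sign from the shoelace sum of the (smoothed) ring
    area2 = np.sum(sm[:, 0] * sm[(idx + 1) % n, 1] - sm[(idx + 1) % n, 0] * sm[:, 1])
    sign = 1.0 if area2 >= 0 else -1.0
    concave = (cross * sign) < -1e-9 * scale * scale

    apex = int(np.argmax(pts[:, 1]))
    ymid = pts[:, 1].min() + 0.5 * np.ptp(pts[:, 1])
    lower = pts[:, 1] <= ymid

    left = concave & lower & (pts[:, 0] < pts[apex, 0])
    right = concave & lower & (pts[:, 0] > pts[apex, 0])
    if left.any() and right.any():
        i = int(np.flatnonzero(left)[np.argmin(pts[left, 1])])
        j = int(np.flatnonzero(right)[np.argmin(pts[right, 1])])
        return tuple(sorted((i, j)))

    # rule 3: most distant pair among lower-half points
    cand = np.flatnonzero(lower)
    if len(cand) < 2:
        raise SegmentationError(
            "no detectable base region; annotate the baseline termini manually"
        )
    sub = pts[cand]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    a, b = np.unravel_index(np.argmax(d2), d2.shape)
    return tuple(sorted((int(cand[a]), int(cand[b]))))


def _cut_arc(pts: np.ndarray, i: int, j: int, closed: bool) -> Outline:
    """Return the arc between indices i<j that carries the apex."""
    apex = int(np.argmax(pts[:, 1]))
    inner = pts[i : j + 1]
    if closed:
        outer = np.vstack([pts[j:], pts[: i + 1]])
        arc = inner if i <= apex <= j else outer
    else:
        arc = inner
    if arc[0, 0] > arc[-1, 0]:
        arc = arc[::-1]
    return Outline(arc.copy())


# ---------------------------------------------------------------------------
# i/o


def write_dentition(dentition: Dentition, path, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        _write_csv(dentition, path)
    elif dialect == "tps":
        _write_tps(dentition, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_dentition(path, dialect: str = "csv") -> Dentition:
    path = Path(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "tps":
        return _read_tps(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_csv(dentition: Dentition, path: Path) -> None:
    rows = []
    for tooth in dentition.teeth():
        for k, (x, y) in enumerate(tooth.outline.points):
            rows.append((tooth.species, tooth.jaw, tooth.position, k, x, y))
    frame = pd.DataFrame(
        rows, columns=["species", "jaw", "position", "point_index", "x", "y"]
    )
    with open(path, "w") as fh:
        fh.write("# orientation: mesial_to_distal\n")
        for key, value in dentition.metadata.items():
            if key != "orientation":
                fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def _read_csv(path: Path) -> Dentition:
    metadata = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            body.write(line)
    body.seek(0)
    try:
        frame = pd.read_csv(body)
    except Exception as exc:  # noqa: BLE001 - rewrap parser errors
        raise OutlineFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"species", "jaw", "position", "point_index", "x", "y"}
    if not required.issubset(frame.columns):
        raise OutlineFormatError(
            f"{path}: missing columns {sorted(required - set(frame.columns))}"
        )
    reverse = metadata.get("orientation", "mesial_to_distal") == "distal_to_mesial"
    species = str(frame["species"].iloc[0])
    rows: dict = {}
    seen = set()
    for (jaw, position), group in frame.groupby(["jaw", "position"], sort=True):
        key = (jaw, int(position))
        if key in seen:  # pragma: no cover - groupby already merges
            raise OutlineFormatError(f"duplicate tooth {key}")
        seen.add(key)
        group = group.sort_values("point_index")
        pts = group[["x", "y"]].to_numpy(dtype=float)
        if len(pts) < 3:
            raise OutlineFormatError(
                f"{species}/{jaw}/{int(position)}: fewer than 3 outline points"
            )
        if reverse:
            pts = pts[::-1]
        rows.setdefault(str(jaw), []).append(
            Tooth(species, str(jaw), int(position), Outline(pts))
        )
    for jaw in rows:
        rows[jaw].sort(key=lambda t: t.position)
    return Dentition(species, rows, metadata)


def _write_tps(dentition: Dentition, path: Path) -> None:
    with open(path, "w") as fh:
        for tooth in dentition.teeth():
            pts = tooth.outline.points
            fh.write(f"LM={len(pts)}\n")
            for x, y in pts:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={tooth.species}_{tooth.jaw}_{tooth.position}\n")


def _read_tps(path: Path) -> Dentition:
    teeth = []
    species = None
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise OutlineFormatError(f"{path}: expected LM= record at line {i + 1}")
        n = int(lines[i].split("=", 1)[1])
        coords = []
        for k in range(n):
            parts = lines[i + 1 + k].split()
            coords.append((float(parts[0]), float(parts[1])))
        i += 1 + n
        if i >= len(lines) or not lines[i].upper().startswith("ID="):
            raise OutlineFormatError(f"{path}: missing ID= record")
        ident = lines[i].split("=", 1)[1]
        sp, jaw, pos = ident.rsplit("_", 2)
        species = species or sp
        if len(coords) < 3:
            raise OutlineFormatError(f"{ident}: fewer than 3 outline points")
        teeth.append(Tooth(sp, jaw, int(pos), Outline(np.array(coords))))
        i += 1
    if not teeth:
        raise OutlineFormatError(f"{path}: empty TPS file")
    rows: dict = {}
    seen = set()
    for tooth in teeth:
        if tooth.tooth_id in seen:
            raise OutlineFormatError(f"duplicate tooth {tooth.tooth_id}")
        seen.add(tooth.tooth_id)
        rows.setdefault(tooth.jaw, []).append(tooth)
    for jaw in rows:
        rows[jaw].sort(key=lambda t: t.position)
    return Dentition(species, rows)
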