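"""Single-tooth complexity measures and their species-level pooling.

Ten measures per crown outline:

* CUSP1 / CUSP2 -- counts of major and minor cusps.  Apex candidates are
  local maxima of distance from the baseline; a cusp is *major* iff its
  topographic prominence (drop to the higher of its two cols) reaches 2%
  of the total outline length, with the largest cusp always major.
* OAR -- outline length / baseline-closed area.
* OCR -- outline length / centroid size, with centroid size taken as the
  square root of the *sum of distances* to the point centroid (so the
  value depends on the standard n = 1000 resampling).
* OIR -- escribed/inscribed circle *area* ratio, capped at 25.  (The
  reciprocal reading would be bounded by 1 and could never reach the
  cap, so the ratio is taken escribed over inscribed.)
* DFS -- total |coefficient| mass of the cosine-Fourier expansion.
* ANS / ASC / AND -- surface-angle sum, its signed cadence across the
  resolution ladder, and mean pairwise angle disparity.
* OPC -- orientation patch count: mean number of maximal runs of
  constant discretized direction over partitions (2, 4, 8), rotation
  offsets, and the resolution ladder.

The resolution ladder is n_R = n / (5 * 2^(R-1)) for R = 1..6, rounded
to the nearest integer: 200, 100, 50, 25, 13, 6 at n = 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import find_peaks
from shapely import maximum_inscribed_circle, minimum_bounding_radius

from .distances import N_HARMONICS, dfs
from .outlines import Dentition, Outline, center_and_scale, resample
from .distances import interior_angles

__all__ = [
    "ComplexityRecord",
    "resolution_ladder",
    "count_cusps",
    "oar",
    "ocr",
    "oir",
    "angle_measures",
    "opc",
    "streak_count",
    "tooth_complexity",
    "species_complexity",
    "complexity_table",
]

OIR_CAP = 25.0
COL_THRESHOLD = 0.02  # prominence threshold as a fraction of outline length
PARTITIONS = (2, 4, 8)

RAW_MEASURES = ("CUSP1", "CUSP2", "OAR", "OCR", "OIR", "DFS", "ANS", "ASC", "AND", "OPC")


@dataclass(frozen=True)
class ComplexityRecord:
    """Raw complexity values for one tooth (or one species' mean)."""

    CUSP1: float
    CUSP2: float
    OAR: float
    OCR: float
    OIR: float
    DFS: float
    ANS: float
    ASC: float
    AND: float
    OPC: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def cusp_ratio(self) -> float:
        """CUSP2/CUSP1, with the convention 0 when CUSP1 = 0."""
        return self.CUSP2 / self.CUSP1 if self.CUSP1 > 0 else 0.0


def resolution_ladder(n: int = 1000, levels: int = 6) -> list:
    """Strictly decreasing point counts n_R = n / (5 * 2^(R-1))."""
    ladder = []
    for r in range(1, levels + 1):
        # round half up (banker's rounding would give 12 instead of 13)
        n_r = int(np.floor(n / (5.0 * 2 ** (r - 1)) + 0.5))
        if ladder and n_r >= ladder[-1]:
            break
        ladder.append(n_r)
    return ladder


# ---------------------------------------------------------------------------
# cusp counting


def _baseline_distance(outline: Outline) -> np.ndarray:
    """Perpendicular distance of each point from the line through the
    baseline termini (first and last points)."""
    pts = outline.points
    p0, p1 = pts[0], pts[-1]
    axis = p1 - p0
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("coincident baseline termini")
    normal = np.array([-axis[1], axis[0]]) / norm
    return np.abs((pts - p0) @ normal)


def count_cusps(outline: Outline, level: str | None = None):
    """Count (major, minor) cusps; with ``level`` given, return one count.

    A flat crown (no local maxima of baseline distance) counts (0, 0);
    any non-flat crown has at least one major cusp.
    """
    height = _baseline_distance(outline)
    threshold = COL_THRESHOLD * outline.length
    peaks, props = find_peaks(height, prominence=0.0)
    if len(peaks) == 0:
        major, minor = 0, 0
    else:
        prom = props["prominences"]
        is_major = prom >= threshold
        is_major[np.argmax(height[peaks])] = True  # the largest cusp is always major
        major = int(is_major.sum())
        minor = int(len(peaks) - major)
    if level is None:
        return major, minor
    if level == "major":
        return major
    if level == "minor":
        return minor
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# excentricity measures


def oar(outline: Outline) -> float:
    """Outline length divided by the baseline-closed area."""
    area = outline.closed_polygon().area
    if area <= 0:
        raise ValueError("zero-area crown")
    return outline.length / area


def ocr(outline: Outline) -> float:
    """Outline length divided by centroid size (Sum-of-distances root).

    Resolution-dependent by definition; computed on the standard
    resampling in the pipeline.
    """
    pts = outline.points
    centroid = pts.mean(axis=0)
    dist_sum = np.linalg.norm(pts - centroid, axis=1).sum()
    if dist_sum <= 0:
        raise ValueError("degenerate outline")
    return outline.length / np.sqrt(dist_sum)


def oir(outline: Outline, cap: float = OIR_CAP) -> float:
    """Escribed/inscribed circle area ratio, capped."""
    poly = outline.closed_polygon()
    if poly.area <= 0:
        raise ValueError("zero-area crown")
    r_out = minimum_bounding_radius(poly)
    scale = max(np.ptp(outline.points, axis=0))
    radius_line = maximum_inscribed_circle(poly, tolerance=1e-7 * scale)
    r_in = radius_line.length
    if r_in <= 0:
        return cap
    return float(min((r_out / r_in) ** 2, cap))


# ---------------------------------------------------------------------------
# angle measures


def _angles_at(outline: Outline, n_r: int) -> np.ndarray:
    pts = resample(outline, n_r).points
    return interior_angles(pts)


def angle_measures(outline: Outline, ladder=None, absolute_asc: bool = False):
    """(ANS, ASC, AND) averaged over the resolution ladder.

    ANS averages the per-resolution sums of |angle - pi|; ASC averages
    the successive (signed) differences of those sums; AND averages the
    mean absolute pairwise angle difference over interior points,
    normalized by (n_R - 2)^2 ordered pairs.
    """
    ladder = list(ladder) if ladder is not None else resolution_ladder(len(outline))
    usable = [n_r for n_r in ladder if n_r >= 3]
    if len(usable) < len(ladder):
        warnings.warn("dropping ladder resolutions with fewer than 3 points", stacklevel=2)
    if not usable:
        raise ValueError("no usable resolution in ladder")

    sums = []
    disparities = []
    for n_r in usable:
        ang = _angles_at(outline, n_r)
        sums.append(np.abs(ang - np.pi).sum())
        diff = np.abs(ang[:, None] - ang[None, :])
        disparities.append(diff.sum() / (len(ang)) ** 2)
    ans = float(np.mean(sums))
    asc_terms = np.diff(sums)
    if absolute_asc:
        asc_terms = np.abs(asc_terms)
    asc = float(asc_terms.mean()) if len(asc_terms) else 0.0
    and_ = float(np.mean(disparities))
    return ans, asc, and_


# ---------------------------------------------------------------------------
# orientation patch count


def streak_count(vectors: np.ndarray, partitions: int, offset: float = 0.0) -> int:
    """Number of maximal runs of constant direction sector.

    Directions are the angles of successive-point vectors, discretized
    into ``partitions`` equal circular sectors rotated by ``offset``.
    """
    theta = np.arctan2(vectors[:, 1], vectors[:, 0])
    sector = np.floor(((theta - offset) % (2 * np.pi)) / (2 * np.pi / partitions)).astype(int)
    sector %= partitions
    return int(1 + np.count_nonzero(sector[1:] != sector[:-1]))


def _rotation_offsets(partitions: int, lowest: int) -> list:
    sector = 2 * np.pi / partitions
    offsets = [0.0, sector / 2.0]
    if partitions == lowest:
        offsets.append(sector / 4.0)
    return offsets


def opc(outline: Outline, partitions=PARTITIONS, ladder=None) -> float:
    """Mean streak count over partitions, rotation offsets, and resolutions."""
    ladder = list(ladder) if ladder is not None else resolution_ladder(len(outline))
    usable = [n_r for n_r in ladder if n_r >= 3]
    counts = []
    lowest = min(partitions)
    for n_r in usable:
        pts = resample(outline, n_r).points
        vectors = np.diff(pts, axis=0)
        for p in partitions:
            for offset in _rotation_offsets(p, lowest):
                counts.append(streak_count(vectors, p, offset))
    return float(np.mean(counts))


# ---------------------------------------------------------------------------
# per-tooth and per-species records


def tooth_complexity(
    outline: Outline,
    n_points: int = 1000,
    harmonics: int = N_HARMONICS,
    ladder=None,
) -> ComplexityRecord:
    """All ten complexity measures for one crown outline.

    The outline is resampled to ``n_points`` and the scale-sensitive
    measures are computed on the length-normalized outline so teeth of
    different sizes are comparable (tooth size is outside the scope of
    the shape descriptors).
    """
    out = resample(outline, n_points)
    norm = center_and_scale(out, "length")
    # DFS is computed at unit centroid size (the conventional shape-space
    # scale): unit outline length would shrink strongly undulating crowns
    # and mask the extra coefficient mass their cusps carry
    centered = out.points - out.points.mean(axis=0)
    cs_norm = Outline(centered / np.sqrt((centered**2).sum(axis=1).mean()))
    if ladder is None:
        # default ladder: silently usable resolutions only
        ladder = [n_r for n_r in resolution_ladder(n_points) if n_r >= 3]
    else:
        ladder = list(ladder)
    major, minor = count_cusps(norm)
    ans, asc, and_ = angle_measures(norm, ladder)
    return ComplexityRecord(
        CUSP1=float(major),
        CUSP2=float(minor),
        OAR=oar(norm),
        OCR=ocr(norm),
        OIR=oir(norm),
        DFS=dfs(cs_norm, harmonics),
        ANS=ans,
        ASC=asc,
        AND=and_,
        OPC=opc(norm, ladder=ladder),
    )


def species_complexity(dentition: Dentition, n_points: int = 1000, **kwargs) -> ComplexityRecord:
    """Species record: mean over all teeth of both jaws, per measure."""
    records = [tooth_complexity(t.outline, n_points, **kwargs) for t in dentition.teeth()]
    if not records:
        raise ValueError(f"empty dentition for {dentition.species}")
    mean = {
        name: float(np.mean([getattr(r, name) for r in records])) for name in RAW_MEASURES
    }
    return ComplexityRecord(**mean)


def complexity_table(dentitions, n_points: int = 1000, **kwargs):
    """Per-species complexity table with min-max normalization and pooling.

    Raw columns are the per-species means; ``*_norm`` columns are their
    global min-max normalizations; pooled columns sum normalized values:
    Cx_exc = OCR + OAR + OIR, Cx_ang = ANS + ASC + AND + OPC,
    Cx_four = DFS, and Cx_combined sums all ten.  ``cusp_ratio`` is
    CUSP2/CUSP1 on the raw species means.
    """
    import pandas as pd

    dentitions = list(dentitions)
    rows = {}
    for dentition in dentitions:
        rec = species_complexity(dentition, n_points, **kwargs)
        rows[dentition.species] = {**rec.as_dict(), "cusp_ratio": rec.cusp_ratio}
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "species"

    for name in RAW_MEASURES:
        col = frame[name]
        span = col.max() - col.min()
        frame[f"{name}_norm"] = 0.0 if span == 0 else (col - col.min()) / span
    frame["Cx_exc"] = frame[["OCR_norm", "OAR_norm", "OIR_norm"]].sum(axis=1)
    frame["Cx_ang"] = frame[["ANS_norm", "ASC_norm", "AND_norm", "OPC_norm"]].sum(axis=1)
    frame["Cx_four"] = frame["DFS_norm"]
    frame["Cx_combined"] = frame[[f"{m}_norm" for m in RAW_MEASURES]].sum(axis=1)
    return frame
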