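"""Partial-Procrustes superimposition by bounded grid search.

The search minimizes a supplied distance measure over rotation within
+-pi/8, shift along x and y within +-10% of the normalized outline's
bounding-box diagonal, and scale within +-25%, evaluated under both
size-normalization modes (outline length and baseline-closed area); the
lower of the two minima is kept.  The default grid (17 rotation x 9x9
shift x 11 scale steps) is followed by one local refinement pass at a
quarter of the original step around the best grid point.  Everything is
deterministic for a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .outlines import Outline, center_and_scale

__all__ = ["GridSpec", "AlignmentResult", "align_pair", "symmetry_tolerance"]

ROT_MAX = np.pi / 8
SHIFT_MAX = 0.10
SCALE_MAX = 0.25


@dataclass(frozen=True)
class GridSpec:
    """Search grid: step counts per axis plus the bound constants."""

    rot_steps: int = 17
    shift_steps: int = 9
    scale_steps: int = 11
    rot_max: float = ROT_MAX
    shift_max: float = SHIFT_MAX
    scale_max: float = SCALE_MAX
    refine: bool = True
    refine_steps: int = 9

    def validate(self) -> None:
        if min(self.rot_steps, self.shift_steps, self.scale_steps) < 1:
            raise ValueError("grid spec must have at least one step per axis")


@dataclass(frozen=True)
class AlignmentResult:
    rotation: float
    shift: tuple
    scale: float
    size_mode: str
    distance: float


def symmetry_tolerance(grid: "GridSpec", mean_distance: float, absolute: float = 0.02) -> float:
    """Documented bound on |d(a,b) - d(b,a)| for the aligned measures.

    Two grid effects make the searched minima order-dependent even with
    the size change split evenly between the shapes: (1) the scale grid
    is linear, so the reciprocal of a grid value is up to one step away
    from the nearest grid value; (2) the scale range [1-s_max, 1+s_max]
    is not closed under inversion -- the reciprocal of its lower edge,
    1/(1-s_max), exceeds the upper edge by 1/(1-s_max) - (1+s_max)
    (about 0.083 for the standard +-25% range), so boundary optima carry
    that much irreducible relative asymmetry.  The absolute term covers
    rasterization noise of the pixel-count measure.
    """
    if grid.scale_steps > 1:
        step = 2 * grid.scale_max / (grid.scale_steps - 1)
    else:
        step = 2 * grid.scale_max
    deficit = 1.0 / (1.0 - grid.scale_max) - (1.0 + grid.scale_max)
    return (step + deficit) * mean_distance + absolute


def _axis(center: float, halfwidth: float, steps: int, bound: float) -> np.ndarray:
    if steps == 1:
        return np.array([center])
    vals = np.linspace(center - halfwidth, center + halfwidth, steps)
    return vals[np.abs(vals) <= bound + 1e-12]


def _transform(pts: np.ndarray, rot: float, scale: float, shift: np.ndarray) -> np.ndarray:
    c, s = np.cos(rot), np.sin(rot)
    rotated = pts @ np.array([[c, s], [-s, c]])
    return scale * rotated + shift


def _search(a_pts, b_pts, measure, grid, rots, scales, shifts_x, shifts_y, diag):
    # The size change s is split evenly between the shapes (a/sqrt(s) vs
    # sqrt(s)*b), keeping the search near-symmetric in the pair order.
    # For absolutely homogeneous measures (EMD, HED) the split folds back
    # onto fixed reference points: d(a/r, r*R*b + t) = d(a, s*R*b + r*t)/r
    # with r = sqrt(s).  Scale-aware measures (SAO) expose set_scale(r)
    # and swap in a reference mask scaled by 1/r instead.
    homogeneous = getattr(measure, "homogeneous", True)
    scale_aware = hasattr(measure, "set_scale")
    best = (np.inf, 0.0, 1.0, (0.0, 0.0))
    for rot in rots:
        for scale in scales:
            r = np.sqrt(scale)
            if scale_aware:
                # explicit split: reference at 1/r, candidate at r
                measure.set_scale(r)
                base = _transform(b_pts, rot, r, np.zeros(2))
                r_shift, r_div = 1.0, 1.0
            elif homogeneous:
                base = _transform(b_pts, rot, scale, np.zeros(2))
                r_shift, r_div = r, r
            else:
                base = _transform(b_pts, rot, scale, np.zeros(2))
                r_shift, r_div = 1.0, 1.0
            for sx in shifts_x:
                for sy in shifts_y:
                    shifted = base + np.array([sx * diag * r_shift, sy * diag * r_shift])
                    d = measure(a_pts, shifted) / r_div
                    if d < best[0]:
                        best = (d, rot, scale, (sx, sy))
    return best


def align_pair(a: Outline, b: Outline, measure, grid: GridSpec | None = None) -> AlignmentResult:
    """Find the transform of ``b`` (``a`` fixed) minimizing ``measure``.

    ``measure`` is called as ``measure(a_points, b_points)`` on plain
    arrays.  Both outlines must carry equal point counts.
    """
    grid = grid or GridSpec()
    grid.validate()
    if len(a) != len(b):
        raise ValueError("align_pair requires equal point counts")

    overall = None
    for mode in ("length", "area"):
        try:
            a0 = center_and_scale(a, mode).points
            b0 = center_and_scale(b, mode).points
        except ValueError:
            continue  # e.g. self-intersecting closure in area mode
        # symmetric shift unit: mean of the two bounding-box diagonals
        diag = 0.5 * (
            float(np.linalg.norm(np.ptp(a0, axis=0)))
            + float(np.linalg.norm(np.ptp(b0, axis=0)))
        )
        fn = measure.prepare_pair(a0, b0) if hasattr(measure, "prepare_pair") else measure

        rots = _axis(0.0, grid.rot_max, grid.rot_steps, grid.rot_max)
        scales = 1.0 + _axis(0.0, grid.scale_max, grid.scale_steps, grid.scale_max)
        sx = _axis(0.0, grid.shift_max, grid.shift_steps, grid.shift_max)
        sy = _axis(0.0, grid.shift_max, grid.shift_steps, grid.shift_max)
        d, rot, scale, shift = _search(a0, b0, fn, grid, rots, scales, sx, sy, diag)

        if grid.refine and min(grid.rot_steps, grid.shift_steps, grid.scale_steps) > 1:
            steps = {
                "rot": 2 * grid.rot_max / max(grid.rot_steps - 1, 1),
                "shift": 2 * grid.shift_max / max(grid.shift_steps - 1, 1),
                "scale": 2 * grid.scale_max / max(grid.scale_steps - 1, 1),
            }
            k = grid.refine_steps
            rots_r = _axis(rot, steps["rot"], k, grid.rot_max)
            scales_r = _axis(scale - 1.0, steps["scale"], k, grid.scale_max) + 1.0
            sx_r = _axis(shift[0], steps["shift"], k, grid.shift_max)
            sy_r = _axis(shift[1], steps["shift"], k, grid.shift_max)
            d2, rot2, scale2, shift2 = _search(
                a0, b0, fn, grid, rots_r, scales_r, sx_r, sy_r, diag
            )
            if d2 < d:
                d, rot, scale, shift = d2, rot2, scale2, shift2

        if overall is None or d < overall.distance:
            overall = AlignmentResult(
                rotation=float(rot),
                shift=(float(shift[0]), float(shift[1])),
                scale=float(scale),
                size_mode=mode,
                distance=float(d),
            )
    if overall is None:
        raise ValueError("no valid size-normalization mode for this pair")
    return overall
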