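"""The six pairwise tooth-shape distance measures.

EMD, HED, and SAO compare superimposed outlines and are routed through
the partial-Procrustes grid search (:mod:`heterodont.align`); DFD, OAD,
and ADD act on centered, length-normalized outlines directly.  SAO is a
similarity (1 = identical) in its raw form; the pipeline stores the
distance ``1 - SAO`` so that all six measures average coherently.

Fourier machinery: open coordinate series x(t), y(t) are expanded with
the orthonormal type-II discrete cosine transform.  "24 harmonics"
means the first 24 non-DC coefficients per stream; DC terms encode the
(already removed) translation and are excluded from DFD and DFS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct as _dct
from scipy.fft import idct as _idct
from scipy.spatial import cKDTree
from shapely import Polygon, contains_xy, prepare

from .outlines import Outline, center_and_scale, resample

__all__ = [
    "DctCoefficients",
    "AngleFunction",
    "DistanceTensor",
    "MEASURES",
    "ALIGNED_MEASURES",
    "emd",
    "hed",
    "sao",
    "dct",
    "inverse_dct",
    "dfd",
    "angle_function",
    "oad",
    "add",
    "dfs",
    "mean_shape",
    "pairwise_distances",
]

N_HARMONICS = 24
N_ANGLE_POINTS = 100
SAO_GRID = 100

ALIGNED_MEASURES = ("EMD", "HED", "SAO")
FOURIER_MEASURES = ("DFD", "OAD", "ADD")
ALL_MEASURES = ALIGNED_MEASURES + FOURIER_MEASURES


def _pts(outline) -> np.ndarray:
    return outline.points if isinstance(outline, Outline) else np.asarray(outline, float)


# ---------------------------------------------------------------------------
# point-set measures


def emd(a, b) -> float:
    """Euclidean mean distance: sum of the two directed mean nearest-point
    distances between the outlines (computed both ways)."""
    pa, pb = _pts(a), _pts(b)
    if len(pa) != len(pb):
        raise ValueError("EMD requires equal point counts")
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab = tb.query(pa)[0].mean()
    d_ba = ta.query(pb)[0].mean()
    return float(d_ab + d_ba)


def hed(a, b) -> float:
    """Homologous Euclidean outline distance.

    With equal point counts this is twice the mean positionwise distance
    (the simplified formula); with unequal counts each point is matched
    to the point at the nearest relative position on the other outline
    and the two directed means are summed.
    """
    pa, pb = _pts(a), _pts(b)
    na, nb = len(pa), len(pb)
    if na == nb:
        return float(2.0 * np.linalg.norm(pa - pb, axis=1).mean())
    ia = np.arange(1, na + 1)
    ib = np.arange(1, nb + 1)
    k = np.argmin(np.abs(ia[:, None] / na - ib[None, :] / nb), axis=1)
    l = np.argmin(np.abs(ib[:, None] / nb - ia[None, :] / na), axis=1)
    term_a = np.linalg.norm(pa - pb[k], axis=1).mean()
    term_b = np.linalg.norm(pb - pa[l], axis=1).mean()
    return float(term_a + term_b)


@dataclass(frozen=True)
class _Raster:
    """Fixed pixel grid shared by both shapes of an SAO comparison."""

    centers_x: np.ndarray
    centers_y: np.ndarray


def sao_grid(a, b, n_units: int = SAO_GRID) -> _Raster:
    """Build the shared rasterization grid *before* alignment: the maximum
    x and y extents over both shapes are discretized into ``n_units``."""
    pa, pb = _pts(a), _pts(b)
    allp = np.vstack([pa, pb])
    lo = allp.min(axis=0)
    hi = allp.max(axis=0)
    # half-unit margin so aligned shapes shifted to the rim stay on-grid
    span = np.maximum(hi - lo, 1e-12)
    lo = lo - 0.25 * span
    hi = hi + 0.25 * span
    xs = lo[0] + (np.arange(n_units) + 0.5) * (hi[0] - lo[0]) / n_units
    ys = lo[1] + (np.arange(n_units) + 0.5) * (hi[1] - lo[1]) / n_units
    gx, gy = np.meshgrid(xs, ys)
    return _Raster(gx.ravel(), gy.ravel())


def _mask(outline, raster: _Raster) -> np.ndarray:
    poly = Polygon(_pts(outline))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate or self-intersecting shape in SAO")
    prepare(poly)
    minx, miny, maxx, maxy = poly.bounds
    x, y = raster.centers_x, raster.centers_y
    box = (x >= minx) & (x <= maxx) & (y >= miny) & (y <= maxy)
    mask = np.zeros(len(x), dtype=bool)
    mask[box] = contains_xy(poly, x[box], y[box])
    return mask


def sao(a, b, raster: _Raster | None = None) -> float:
    """Superimposed area overlap similarity in [0, 1] over rasterized pixel
    sets: 2|A&B| / (|A|+|B|).  A pixel belongs to a shape iff its center
    lies inside the baseline-closed polygon."""
    if raster is None:
        raster = sao_grid(a, b)
    ma, mb = _mask(a, raster), _mask(b, raster)
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        raise ValueError("degenerate zero-area shapes in SAO")
    return float(2.0 * np.logical_and(ma, mb).sum() / denom)


def sao_distance(a, b, raster: _Raster | None = None) -> float:
    return 1.0 - sao(a, b, raster)


class _PreparedEmd:
    """EMD bound to a fixed reference outline (KD-tree built once)."""

    homogeneous = True

    def __init__(self, a_pts: np.ndarray):
        self._a = a_pts
        self._tree_a = cKDTree(a_pts)

    def __call__(self, a_pts, b_pts) -> float:
        d_ab = cKDTree(b_pts).query(self._a)[0].mean()
        d_ba = self._tree_a.query(b_pts)[0].mean()
        return float(d_ab + d_ba)


class EmdMeasure:
    """EMD with a per-pair fast path for the alignment search."""

    homogeneous = True

    def __call__(self, a, b) -> float:
        return emd(a, b)

    @staticmethod
    def prepare_pair(a_pts: np.ndarray, b_pts: np.ndarray):
        return _PreparedEmd(a_pts)


class _PreparedSao:
    """SAO distance on a raster frozen from the pre-alignment pair.

    Supports the symmetric size split of the search: ``set_scale(r)``
    switches the cached reference mask to the shape scaled by 1/r, to be
    compared against the candidate scaled by r.
    """

    homogeneous = False

    def __init__(self, a_pts: np.ndarray, b_pts: np.ndarray):
        self._a_pts = a_pts
        self._raster = sao_grid(a_pts, b_pts)
        self._mask_cache: dict = {}
        self._mask_a, self._count_a = self._ref_mask(1.0)

    def _ref_mask(self, r: float):
        key = round(float(r), 12)
        if key not in self._mask_cache:
            mask = _mask(self._a_pts / r, self._raster)
            self._mask_cache[key] = (mask, int(mask.sum()))
        return self._mask_cache[key]

    def set_scale(self, r: float) -> None:
        self._mask_a, self._count_a = self._ref_mask(r)

    def __call__(self, a_pts, b_pts) -> float:
        mask_b = _mask(b_pts, self._raster)
        denom = self._count_a + int(mask_b.sum())
        if denom == 0:
            raise ValueError("degenerate zero-area shapes in SAO")
        return 1.0 - float(2.0 * np.logical_and(self._mask_a, mask_b).sum() / denom)


class SaoMeasure:
    """1 - SAO with the rasterization grid fixed before the search."""

    homogeneous = False

    def __call__(self, a, b) -> float:
        return sao_distance(a, b)

    @staticmethod
    def prepare_pair(a_pts: np.ndarray, b_pts: np.ndarray):
        return _PreparedSao(a_pts, b_pts)


# ---------------------------------------------------------------------------
# cosine-Fourier machinery


@dataclass(frozen=True)
class DctCoefficients:
    """Orthonormal DCT-II expansion of the x(t) and y(t) coordinate series.

    ``dc`` holds the two DC terms, ``coef`` the per-axis harmonic
    coefficients with shape (2, harmonics).
    """

    dc: np.ndarray
    coef: np.ndarray
    n_points: int

    @property
    def harmonics(self) -> int:
        return self.coef.shape[1]


def dct(outline, harmonics: int = N_HARMONICS) -> DctCoefficients:
    if harmonics < 1:
        raise ValueError("need at least one harmonic")
    pts = _pts(outline)
    n = len(pts)
    harmonics = min(harmonics, n - 1)
    c = _dct(pts.T, norm="ortho")  # shape (2, n)
    return DctCoefficients(dc=c[:, 0].copy(), coef=c[:, 1 : harmonics + 1].copy(), n_points=n)


def inverse_dct(coefficients: DctCoefficients, n: int | None = None) -> Outline:
    """Reconstruct an outline from (possibly truncated) DCT coefficients."""
    n = n or coefficients.n_points
    full = np.zeros((2, n))
    full[:, 0] = coefficients.dc
    h = min(coefficients.harmonics, n - 1)
    full[:, 1 : h + 1] = coefficients.coef[:, :h]
    if n != coefficients.n_points:
        # orthonormal DCT scales with sqrt(length); compensate so the
        # reconstruction keeps the original amplitude
        full *= np.sqrt(n / coefficients.n_points)
    pts = _idct(full, norm="ortho")
    return Outline(pts.T)


def dfd(a, b, harmonics: int = N_HARMONICS) -> float:
    """Discrete cosine Fourier distance: Euclidean norm over all non-DC
    coefficient differences of the two outlines."""
    ca, cb = dct(a, harmonics), dct(b, harmonics)
    if ca.harmonics != cb.harmonics:
        raise ValueError("mismatched harmonic counts")
    return float(np.linalg.norm(ca.coef - cb.coef))


def dfs(outline, harmonics: int = N_HARMONICS) -> float:
    """Fourier coefficient sum: total |coefficient| mass over both axes and
    all non-DC harmonics; a proxy for the information needed to describe
    the shape."""
    return float(np.abs(dct(outline, harmonics).coef).sum())


def mean_shape(outlines, harmonics: int | None = None) -> Outline:
    """Average outlines by averaging their cosine-Fourier coefficients and
    reconstructing; full-rank by default."""
    outlines = list(outlines)
    if not outlines:
        raise ValueError("cannot average an empty set of outlines")
    n = len(_pts(outlines[0]))
    if any(len(_pts(o)) != n for o in outlines):
        raise ValueError("outlines must share the same point count")
    h = harmonics or (n - 1)
    cs = [dct(o, h) for o in outlines]
    mean_dc = np.mean([c.dc for c in cs], axis=0)
    mean_coef = np.mean([c.coef for c in cs], axis=0)
    return inverse_dct(DctCoefficients(mean_dc, mean_coef, n), n)


# ---------------------------------------------------------------------------
# angle functions


@dataclass(frozen=True)
class AngleFunction:
    """Cumulative surface-angle sum over the interior points of an outline
    resampled to ``N_ANGLE_POINTS``; anchored to start at 0."""

    values: np.ndarray
    angles: np.ndarray


def interior_angles(pts: np.ndarray) -> np.ndarray:
    """Interior angle in [0, pi] at each point 2..n-1 of the polyline."""
    v1 = pts[:-2] - pts[1:-1]
    v2 = pts[2:] - pts[1:-1]
    dot = (v1 * v2).sum(axis=1)
    norm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    cosang = np.clip(dot / np.maximum(norm, 1e-300), -1.0, 1.0)
    return np.arccos(cosang)


def angle_function(outline, n: int = N_ANGLE_POINTS) -> AngleFunction:
    pts = resample(Outline(_pts(outline)), n).points
    ang = interior_angles(pts)
    cum = np.cumsum(ang)
    return AngleFunction(values=cum - cum[0], angles=ang)


def oad(a, b, n: int = N_ANGLE_POINTS) -> float:
    """Outline angle sum distance: discrete integral of the absolute gap
    between the two anchored cumulative angle functions."""
    fa = a if isinstance(a, AngleFunction) else angle_function(a, n)
    fb = b if isinstance(b, AngleFunction) else angle_function(b, n)
    return float(np.abs(fa.values - fb.values).sum())


def add(a, b, n: int = N_ANGLE_POINTS, harmonics: int = N_HARMONICS) -> float:
    """Angle-function cosine Fourier distance: Euclidean norm over the
    non-DC DCT coefficients of the two anchored angle functions."""
    fa = a if isinstance(a, AngleFunction) else angle_function(a, n)
    fb = b if isinstance(b, AngleFunction) else angle_function(b, n)
    h = min(harmonics, len(fa.values) - 1)
    ca = _dct(fa.values, norm="ortho")[1 : h + 1]
    cb = _dct(fb.values, norm="ortho")[1 : h + 1]
    return float(np.linalg.norm(ca - cb))


# ---------------------------------------------------------------------------
# orchestration


class DistanceTensor:
    """Pairwise tooth distances indexed by (tooth A, tooth B, measure).

    Symmetric storage under a canonical key order; ``d(t, t) = 0`` by
    construction for any registered tooth.
    """

    def __init__(self, measures=ALL_MEASURES):
        self.measures = tuple(measures)
        self._data: dict = {}

    @staticmethod
    def _key(a, b):
        return (a, b) if a <= b else (b, a)

    def set(self, a, b, measure: str, value: float) -> None:
        self._data.setdefault(self._key(a, b), {})[measure] = float(value)

    def get(self, a, b, measure: str) -> float:
        if a == b:
            return 0.0
        return self._data[self._key(a, b)][measure]

    def pairs(self):
        return self._data.keys()

    def minmax(self, measure: str) -> tuple:
        vals = [v[measure] for v in self._data.values() if measure in v]
        return (min(vals), max(vals)) if vals else (np.nan, np.nan)

    def to_frame(self):
        import pandas as pd

        rows = [
            ("|".join(map(str, a)), "|".join(map(str, b)), m, v)
            for (a, b), mv in sorted(self._data.items())
            for m, v in sorted(mv.items())
        ]
        return pd.DataFrame(rows, columns=["tooth_a", "tooth_b", "measure", "value"])


def pairwise_distances(
    teeth,
    measures=ALL_MEASURES,
    grid=None,
    pairs=None,
    n_points: int = None,
) -> DistanceTensor:
    """Compute the distance tensor over a set of teeth.

    EMD/HED/SAO run through the superimposition search; DFD/OAD/ADD act
    on centered, length-normalized outlines.  SAO is stored as the
    distance ``1 - SAO``.  ``pairs`` restricts computation to the given
    tooth-id pairs (default: all unordered pairs).
    """
    from .align import GridSpec, align_pair

    grid = grid or GridSpec()
    teeth = list(teeth)
    by_id = {t.tooth_id: t for t in teeth}
    if pairs is None:
        ids = sorted(by_id)
        pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]

    n = n_points or len(teeth[0].outline)
    prepped = {}
    for tid, tooth in by_id.items():
        out = resample(tooth.outline, n)
        prepped[tid] = {
            "raw": out,
            "norm": center_and_scale(out, "length"),
        }
        if "OAD" in measures or "ADD" in measures:
            prepped[tid]["af"] = angle_function(prepped[tid]["norm"])

    tensor = DistanceTensor(measures)
    measure_fns = {"EMD": EmdMeasure(), "HED": hed, "SAO": SaoMeasure()}
    for ida, idb in pairs:
        if ida == idb:
            continue
        a, b = prepped[ida], prepped[idb]
        for m in measures:
            if m in ALIGNED_MEASURES:
                try:
                    result = align_pair(a["raw"], b["raw"], measure_fns[m], grid)
                except ValueError as exc:
                    raise ValueError(f"measure {m} failed for pair {ida} vs {idb}: {exc}") from exc
                value = result.distance
            elif m == "DFD":
                value = dfd(a["norm"], b["norm"])
            elif m == "OAD":
                value = oad(a["af"], b["af"])
            elif m == "ADD":
                value = add(a["af"], b["af"])
            else:
                raise ValueError(f"unknown measure {m!r}")
            tensor.set(ida, idb, m, value)
    return tensor


MEASURES = {
    "EMD": emd,
    "HED": hed,
    "SAO": sao,
    "DFD": dfd,
    "OAD": oad,
    "ADD": add,
}
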