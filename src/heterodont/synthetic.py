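"""Synthetic dentitions, sequence alignments, trees, and trait tables.

The tooth generator produces open crown outlines on a unit-width
baseline from a small parametric family: a sinusoidal crown dome carries
``n_major_cusps`` raised-cosine cusps that tile the crown (adjacent cusp
supports touch, so clefts between cusps reach the baseline dome), plus
optional narrow cusplets riding on the cusp flanks whose prominence
stays below the 2%-of-outline-length "col" threshold that separates
minor from major cusps.  Asymmetry is applied as a horizontal shear of
the profile, which leaves baseline-distance extrema untouched.

All randomness flows from a single integer seed per call; noise is
applied to shape *parameters* rather than to individual points, so
resampling invariants hold for every generated tooth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skbio import TreeNode

from .outlines import Dentition, Outline, Tooth, resample

__all__ = [
    "ToothParams",
    "DentitionParams",
    "make_tooth",
    "make_dentition",
    "random_tree",
    "simulate_k2p_sequences",
    "make_trait_table",
]


@dataclass(frozen=True)
class ToothParams:
    """Parameters of a single synthetic crown outline."""

    n_major_cusps: int = 1
    n_minor_cusps: int = 0
    cusp_height: float = 0.5
    minor_cusp_height: float = 0.01
    asymmetry: float = 0.0
    elongation: float = 1.0
    smoothness: float = 0.0

    def validate(self) -> None:
        if self.n_major_cusps < 1:
            raise ValueError("need at least one major cusp")
        if self.n_minor_cusps < 0:
            raise ValueError("n_minor_cusps must be non-negative")
        if not (0 < self.cusp_height <= 1):
            raise ValueError("cusp_height must lie in (0, 1]")
        if not (0 <= self.minor_cusp_height < 1):
            raise ValueError("minor_cusp_height must lie in [0, 1)")
        if not (-1 <= self.asymmetry <= 1):
            raise ValueError("asymmetry must lie in [-1, 1]")
        if self.elongation <= 0:
            raise ValueError("elongation must be positive")
        if self.smoothness < 0:
            raise ValueError("smoothness must be non-negative")

    def perturbed(self, deltas: dict) -> "ToothParams":
        """Return a copy with numeric fields shifted by ``deltas`` and clipped
        back into their valid ranges."""
        values = dataclasses.asdict(self)
        for key, delta in deltas.items():
            if key not in values:
                raise KeyError(f"unknown tooth parameter {key!r}")
            values[key] = values[key] + delta
        values["n_major_cusps"] = max(1, int(round(values["n_major_cusps"])))
        values["n_minor_cusps"] = max(0, int(round(values["n_minor_cusps"])))
        values["cusp_height"] = float(np.clip(values["cusp_height"], 1e-3, 1.0))
        values["minor_cusp_height"] = float(
            np.clip(values["minor_cusp_height"], 0.0, 0.999)
        )
        values["asymmetry"] = float(np.clip(values["asymmetry"], -1.0, 1.0))
        values["elongation"] = max(1e-3, float(values["elongation"]))
        values["smoothness"] = max(0.0, float(values["smoothness"]))
        return ToothParams(**values)


@dataclass(frozen=True)
class DentitionParams:
    """Parameters of a synthetic two-row dentition.

    ``monognathic_gradient`` maps tooth-parameter names to the total
    change accumulated from the mesial (position fraction 0) to the
    distal (fraction 1) end of each row; ``dignathic_offset`` is a
    parameter delta applied to every lower-jaw tooth.  Zero gradient and
    zero offset therefore yield a perfectly homodont dentition.
    """

    n_teeth_upper: int = 10
    n_teeth_lower: int = 10
    base: ToothParams = field(default_factory=ToothParams)
    monognathic_gradient: dict = field(default_factory=dict)
    dignathic_offset: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_teeth_upper < 1 or self.n_teeth_lower < 1:
            raise ValueError("each jaw needs at least one tooth")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.base.validate()


def _raised_cosine(x: np.ndarray, center: float, width: float) -> np.ndarray:
    u = (x - center) / width
    out = np.zeros_like(x)
    mask = np.abs(u) <= 0.5
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[mask]))
    return out


def make_tooth(params: ToothParams, n_points: int = 1000) -> Outline:
    """Generate one crown outline with ``n_points`` equally spaced points.

    Deterministic for fixed parameters.  The baseline runs from (0, 0)
    to (1, 0); crown height is ``elongation`` in units of tooth width.
    """
    params.validate()
    if n_points < 32:
        raise ValueError("need n_points >= 32")

    m = max(4 * n_points, 2048)
    x = np.linspace(0.0, 1.0, m)
    ch = params.cusp_height
    dome = np.sin(np.pi * x)

    k = params.n_major_cusps
    width = 1.0 / k
    centers = (np.arange(k) + 0.5) * width
    cusps = np.zeros_like(x)
    for c in centers:
        cusps += _raised_cosine(x, c, width)
    y = (1.0 - ch) * dome + ch * cusps

    if params.n_minor_cusps > 0 and params.minor_cusp_height > 0:
        # cusplets must be steep enough to puncture the local slope,
        # otherwise they leave no local maximum to count
        slope = np.abs(np.gradient(y, x)).max()
        w_minor = min(
            0.8 / params.n_minor_cusps,
            0.5 * np.pi * params.minor_cusp_height / max(slope, 1e-9),
        )
        span = (0.15, 0.85)
        mcenters = span[0] + (span[1] - span[0]) * (
            (np.arange(params.n_minor_cusps) + 0.5) / params.n_minor_cusps
        )
        for c in mcenters:
            y += params.minor_cusp_height * _raised_cosine(x, c, w_minor)

    y *= params.elongation
    if params.smoothness > 0:
        sigma = params.smoothness * m / 100.0
        y = gaussian_filter1d(y, sigma, mode="nearest")
        y -= np.linspace(y[0], y[-1], m)  # re-pin the baseline termini

    xs = x + 0.3 * params.asymmetry * (y / params.elongation)
    return resample(Outline(np.column_stack([xs, y])), n_points)


def make_dentition(
    params: DentitionParams, n_points: int = 1000, species: str = "synthetic"
) -> Dentition:
    """Generate a two-row dentition with positions 1..n per jaw."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    noisy_fields = ("cusp_height", "elongation", "asymmetry")
    rows: dict = {}
    for jaw, n_teeth in (("upper", params.n_teeth_upper), ("lower", params.n_teeth_lower)):
        teeth = []
        for pos in range(1, n_teeth + 1):
            frac = 0.5 if n_teeth == 1 else (pos - 1) / (n_teeth - 1)
            deltas = {k: v * frac for k, v in params.monognathic_gradient.items()}
            if jaw == "lower":
                for k, v in params.dignathic_offset.items():
                    deltas[k] = deltas.get(k, 0.0) + v
            if params.noise_sd > 0:
                for fname in noisy_fields:
                    deltas[fname] = deltas.get(fname, 0.0) + params.noise_sd * rng.normal()
            else:
                rng.normal(size=len(noisy_fields))  # keep the stream position fixed
            tooth_params = params.base.perturbed(deltas)
            teeth.append(Tooth(species, jaw, pos, make_tooth(tooth_params, n_points)))
        rows[jaw] = teeth
    return Dentition(species, rows, {"seed": params.seed})


# ---------------------------------------------------------------------------
# trees and sequences


def random_tree(
    n_leaves: int,
    seed: int = 0,
    branch_range: tuple = (0.02, 0.3),
    prefix: str = "sp",
) -> TreeNode:
    """Random binary tree by iterative pairwise joining, with uniform
    branch lengths drawn from ``branch_range`` (expected substitutions/site)."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    width = len(str(n_leaves))
    nodes = [TreeNode(name=f"{prefix}{i + 1:0{width}d}") for i in range(n_leaves)]
    lo, hi = branch_range
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        n.length = float(rng.uniform(lo, hi))
    return TreeNode(children=nodes)


_ALPHABET = np.array(list("ACGT"))
# transition partners under the A<->G / C<->T pairing
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _k2p_probs(distance: float, kappa: float) -> tuple:
    """(P, Q): expected transition/transversion proportions after evolving a
    site for ``distance`` expected substitutions under K2P.

    ``kappa`` is the transition/transversion *ratio* R = alpha/(2*beta),
    i.e. the expected ratio of transition to transversion events, so the
    empirical ts/tv count ratio converges to kappa on short branches.
    """
    beta = distance / (2.0 * (kappa + 1.0))
    alpha = 2.0 * kappa * beta
    p = 0.25 + 0.25 * np.exp(-4.0 * beta) - 0.5 * np.exp(-2.0 * (alpha + beta))
    q = 0.5 - 0.5 * np.exp(-4.0 * beta)
    return float(p), float(q)


def simulate_k2p_sequences(
    tree: TreeNode, seq_length: int, kappa: float = 2.0, seed: int = 0
) -> dict:
    """Simulate one sequence per leaf under the Kimura two-parameter model.

    Branch lengths are read as expected substitutions per site.  Returns
    a mapping leaf name -> sequence string.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be positive")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    result = {}

    def descend(node, seq):
        for child in node.children:
            b = float(child.length or 0.0)
            if b > 0:
                p, q = _k2p_probs(b, kappa)
                r = rng.random(seq_length)
                child_seq = seq.copy()
                ts = r < p
                tv1 = (r >= p) & (r < p + q / 2)
                tv2 = (r >= p + q / 2) & (r < p + q)
                child_seq[ts] = _TRANSITION[seq[ts]]
                child_seq[tv1] = _TRANSVERSIONS[seq[tv1], 0]
                child_seq[tv2] = _TRANSVERSIONS[seq[tv2], 1]
            else:
                rng.random(seq_length)  # keep the stream aligned across trees
                child_seq = seq.copy()
            if child.is_tip():
                result[child.name] = "".join(_ALPHABET[child_seq])
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    return result


# ---------------------------------------------------------------------------
# trait tables


def make_trait_table(pairs_dg, relation: str = "independent",
                     noise_sd: float = 0.0, seed: int = 0):
    """Ground-truth trait-difference table for the divergence scan.

    ``pairs_dg`` is a DataFrame with columns ``species_a, species_b, dG``.
    ``relation="independent"`` draws |N(0,1)| differences i.i.d.;
    ``"increasing"`` sets the expected difference equal to dG plus
    Gaussian noise, so with zero noise differences are perfectly
    rank-correlated with dG.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "species_a": pairs_dg["species_a"].to_numpy(),
            "species_b": pairs_dg["species_b"].to_numpy(),
            "dG": pairs_dg["dG"].to_numpy(dtype=float),
        }
    )
    n = len(table)
    if relation == "independent":
        diff = np.abs(rng.normal(size=n))
    elif relation == "increasing":
        diff = table["dG"].to_numpy() + noise_sd * rng.normal(size=n)
    else:
        raise ValueError(f"unknown relation {relation!r}")
    table["diff"] = diff
    return table
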