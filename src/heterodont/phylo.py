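"""K2P distances, neighbor-joining trees, and normalized genetic distances.

The Kimura two-parameter distance separates transition (P) and
transversion (Q) proportions over pairwise-complete sites:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites with a gap or ambiguity in either sequence of a pair are excluded
(pairwise deletion).  Tree building goes through scikit-bio's
Saitou-Nei neighbor joining (negative branch lengths set to zero);
patristic distances from the resulting tree, min-max normalized over
all species pairs, give the genetic distance dG in [0, 1].  An
externally built Newick tree can be supplied instead of the alignment.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "SaturatedDistanceError",
    "read_fasta",
    "write_fasta",
    "k2p_pair",
    "k2p_standard_error",
    "k2p_matrix",
    "nj_tree",
    "patristic_matrix",
    "dg_table",
    "robinson_foulds",
]

# A,G (purines) get even codes and C,T (pyrimidines) odd ones, so a
# substitution is a transition iff the two codes share parity
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class SaturatedDistanceError(ValueError):
    """K2P distance undefined (log argument non-positive)."""


def read_fasta(path) -> dict:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if len(records) < 2:
        raise ValueError("alignment needs at least two sequences")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must share one length")
    return records


def write_fasta(alignment: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(alignment):
            fh.write(f">{name}\n{alignment[name]}\n")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == base.encode()] = code
    return out


def k2p_pair(a: np.ndarray, b: np.ndarray) -> tuple:
    """(distance, P, Q, n_sites) for two encoded sequences."""
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no pairwise-complete ungapped sites")
    av, bv = a[valid], b[valid]
    diff = av != bv
    same_class = (av % 2) == (bv % 2)  # A,G are even; C,T are odd
    p = float(np.count_nonzero(diff & same_class)) / n
    q = float(np.count_nonzero(diff & ~same_class)) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(f"saturated pair (P={p:.4f}, Q={q:.4f})")
    d = -0.5 * np.log(w1 * np.sqrt(w2))
    return float(d), p, q, n


def k2p_distance(p: float, q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistanceError(f"saturated (P={p}, Q={q})")
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def k2p_standard_error(p: float, q: float, n: int) -> float:
    """Large-sample standard error of the K2P estimator (delta method)."""
    c1 = 1.0 / (1.0 - 2.0 * p - q)
    c2 = 1.0 / (1.0 - 2.0 * q)
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * p + c3 * c3 * q - (c1 * p + c3 * q) ** 2) / n
    return float(np.sqrt(var))


def k2p_matrix(alignment: dict) -> pd.DataFrame:
    """Symmetric K2P distance matrix over all sequence pairs."""
    names = sorted(alignment)
    encoded = {name: _encode(alignment[name]) for name in names}
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        d = k2p_pair(encoded[a], encoded[b])[0]
        mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def nj_tree(distances: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive input."""
    arr = distances.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be square and symmetric")
    if arr.shape[0] < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    dm = DistanceMatrix(arr, [str(i) for i in distances.index])
    return nj(dm, neg_as_zero=True)


def patristic_matrix(tree: TreeNode) -> pd.DataFrame:
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def dg_table(tree: TreeNode) -> pd.DataFrame:
    """All species pairs with patristic distance min-max normalized to dG.

    Columns ``species_a < species_b`` lexicographically; rows sorted by
    dG with name ties broken deterministically.
    """
    pat = patristic_matrix(tree)
    names = sorted(pat.index)
    rows = [
        (a, b, float(pat.loc[a, b])) for a, b in itertools.combinations(names, 2)
    ]
    frame = pd.DataFrame(rows, columns=["species_a", "species_b", "patristic"])
    lo, hi = frame["patristic"].min(), frame["patristic"].max()
    if hi <= lo:
        raise ValueError("all pairs equidistant; dG normalization undefined")
    frame["dG"] = (frame["patristic"] - lo) / (hi - lo)
    frame = frame.sort_values(
        ["dG", "species_a", "species_b"], kind="mergesort"
    ).reset_index(drop=True)
    return frame


def robinson_foulds(a: TreeNode, b: TreeNode) -> float:
    """Unrooted Robinson-Foulds distance between two trees."""
    return float(a.compare_rfd(b, rooted=False))
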