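"""Jaw- and dentition-level heterodonty statistics.

Four statistics per distance measure:

* HMS -- sequential monognathic heterodonty: each tooth contributes the
  distances to its mesial and distal neighbors; the sum is divided by
  2n as printed, with missing-neighbor terms at the row ends skipped
  (so a homogeneous row of sequential distance d gives d * (n-1)/n).
* HMT -- total monognathic heterodonty: the full double sum over tooth
  pairs within a jaw, divided by n^2 (diagonal zeros included).
* HDG -- dignathic heterodonty: teeth matched across jaws at the
  nearest relative position (k = argmin_j |i/n_i - j/n_j|); the two
  directed mean distances are summed.
* HMX -- the within-jaw maximum pair distance.

The cross-species phenotypic distance DP applies the same relative-
position matching within like jaws (upper vs upper, lower vs lower) and
averages the two per-jaw values.

Aggregation normalizes each (statistic, measure) column to [0, 1] over
the species set and then averages across the six distance measures;
within-measure ratios (graduality HMX/HMS, HDG/HMT) are formed on the
raw per-measure values and averaged afterwards, because a scale-free
ratio needs no normalization.
"""

from __future__ import annotations

import numpy as np

from .distances import ALL_MEASURES, ALIGNED_MEASURES, DistanceTensor
from .outlines import JAWS, Dentition

__all__ = [
    "hms",
    "hmt",
    "hdg",
    "hmx",
    "relative_position_matching",
    "phenotypic_distance",
    "heterodonty_record",
    "aggregate_and_normalize",
    "needed_pairs",
]

STATISTICS = ("HMS", "HMT", "HDG", "HMX")
OUTLINE_BASED = ("EMD", "HED", "SAO")
ANGLE_BASED = ("OAD", "ADD")


def _row_ids(row):
    return [t.tooth_id if hasattr(t, "tooth_id") else t for t in row]


def hms(row, d: DistanceTensor, measure: str) -> float:
    """Sequential monognathic heterodonty (neighbor distances / 2n)."""
    ids = _row_ids(row)
    n = len(ids)
    if n < 2:
        raise ValueError("HMS needs at least two teeth in the row")
    total = 0.0
    for i in range(n):
        if i > 0:
            total += d.get(ids[i], ids[i - 1], measure)
        if i < n - 1:
            total += d.get(ids[i], ids[i + 1], measure)
    return total / (2.0 * n)


def hmt(row, d: DistanceTensor, measure: str) -> float:
    """Total monognathic heterodonty (all-pair double sum / n^2)."""
    ids = _row_ids(row)
    n = len(ids)
    if n < 2:
        raise ValueError("HMT needs at least two teeth in the row")
    total = sum(
        d.get(ids[i], ids[j], measure) for i in range(n) for j in range(n) if i != j
    )
    return total / (n * n)


def hmx(row, d: DistanceTensor, measure: str) -> float:
    """Maximum distance between any two teeth of the row."""
    ids = _row_ids(row)
    n = len(ids)
    if n < 2:
        raise ValueError("HMX needs at least two teeth in the row")
    return max(d.get(ids[i], ids[j], measure) for i in range(n) for j in range(i + 1, n))


def relative_position_matching(n_from: int, n_to: int) -> np.ndarray:
    """For each 1-based position i in a row of ``n_from`` teeth, the 0-based
    index of the tooth at the nearest relative position in a row of
    ``n_to`` teeth (k = argmin_j |i/n_i - j/n_j|; first minimum on ties)."""
    i = np.arange(1, n_from + 1)[:, None] / n_from
    j = np.arange(1, n_to + 1)[None, :] / n_to
    return np.argmin(np.abs(i - j), axis=1)


def _directed_matched_mean(ids_a, ids_b, d: DistanceTensor, measure: str) -> float:
    match = relative_position_matching(len(ids_a), len(ids_b))
    return float(
        np.mean([d.get(ids_a[i], ids_b[k], measure) for i, k in enumerate(match)])
    )


def hdg(dentition: Dentition, d: DistanceTensor, measure: str) -> float:
    """Dignathic heterodonty: sum of the two directed relative-position-
    matched mean distances between the jaws."""
    upper = _row_ids(dentition.rows.get("upper", []))
    lower = _row_ids(dentition.rows.get("lower", []))
    if not upper or not lower:
        raise ValueError(f"{dentition.species}: both jaws required for HDG")
    return _directed_matched_mean(upper, lower, d, measure) + _directed_matched_mean(
        lower, upper, d, measure
    )


def phenotypic_distance(a: Dentition, b: Dentition, d: DistanceTensor, measure: str) -> float:
    """Cross-species phenotypic distance DP: relative-position matching
    within like jaws, averaged over the two jaws."""
    for jaw in JAWS:
        if not a.rows.get(jaw) or not b.rows.get(jaw):
            raise ValueError(f"jaw {jaw!r} missing in {a.species} or {b.species}")
    per_jaw = []
    for jaw in JAWS:
        ids_a = _row_ids(a.rows[jaw])
        ids_b = _row_ids(b.rows[jaw])
        per_jaw.append(
            _directed_matched_mean(ids_a, ids_b, d, measure)
            + _directed_matched_mean(ids_b, ids_a, d, measure)
        )
    return float(np.mean(per_jaw))


def needed_pairs(dentition: Dentition, statistics=STATISTICS):
    """Unordered tooth-id pairs a given statistics set actually reads.

    HMT/HMX need all within-jaw pairs, HMS only neighbors, HDG the
    cross-jaw matched pairs.  Lets callers fill the tensor lazily.
    """
    pairs = set()
    want_all = "HMT" in statistics or "HMX" in statistics
    for jaw, row in dentition.rows.items():
        ids = _row_ids(row)
        if want_all:
            pairs.update(
                (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
            )
        elif "HMS" in statistics:
            pairs.update((ids[i], ids[i + 1]) for i in range(len(ids) - 1))
    if "HDG" in statistics and all(dentition.rows.get(j) for j in JAWS):
        upper = _row_ids(dentition.rows["upper"])
        lower = _row_ids(dentition.rows["lower"])
        for i, k in enumerate(relative_position_matching(len(upper), len(lower))):
            pairs.add(tuple(sorted((upper[i], lower[k]))))
        for j, l in enumerate(relative_position_matching(len(lower), len(upper))):
            pairs.add(tuple(sorted((lower[j], upper[l]))))
    return sorted(pairs)


def heterodonty_record(
    dentition: Dentition, d: DistanceTensor, measures=ALL_MEASURES
) -> dict:
    """Per-measure HMS/HMT/HDG/HMX for one dentition.

    Row-level statistics are averaged over the jaws present.
    """
    record = {}
    rows = [row for row in dentition.rows.values() if len(row) >= 2]
    if not rows:
        raise ValueError(f"{dentition.species}: no row with >= 2 teeth")
    for m in measures:
        record[("HMS", m)] = float(np.mean([hms(r, d, m) for r in rows]))
        record[("HMT", m)] = float(np.mean([hmt(r, d, m) for r in rows]))
        record[("HMX", m)] = float(np.mean([hmx(r, d, m) for r in rows]))
        record[("HDG", m)] = hdg(dentition, d, m)
    return record


def aggregate_and_normalize(records: dict, measures=ALL_MEASURES):
    """Build the species-level measure table from per-species records.

    ``records`` maps species -> {(statistic, measure): value}.  Columns:
    per-measure raw values (``HMS_EMD`` ...), measure-averaged
    normalized statistics (``HMS_norm`` ...), and derived ratios
    (``graduality`` = HMX/HMS, ``hdg_hmt_ratio``, and the outline- vs
    angle-measure ratio per statistic).
    """
    import pandas as pd

    if len(records) < 2:
        raise ValueError("normalization needs at least two species")
    species = sorted(records)
    frame = pd.DataFrame(
        {f"{stat}_{m}": [records[sp][(stat, m)] for sp in species]
         for stat in STATISTICS for m in measures},
        index=pd.Index(species, name="species"),
    )

    for stat in STATISTICS:
        normed = []
        for m in measures:
            col = frame[f"{stat}_{m}"]
            span = col.max() - col.min()
            normed.append((col - col.min()) / span if span > 0 else col * 0.0)
        frame[f"{stat}_norm"] = pd.concat(normed, axis=1).mean(axis=1)

    def _ratio(num_stat, den_stat):
        vals = []
        for m in measures:
            num = frame[f"{num_stat}_{m}"]
            den = frame[f"{den_stat}_{m}"]
            vals.append(num.where(den > 0) / den.where(den > 0))
        return pd.concat(vals, axis=1).mean(axis=1)

    frame["graduality"] = _ratio("HMX", "HMS")
    frame["hdg_hmt_ratio"] = _ratio("HDG", "HMT")

    outline_ms = [m for m in measures if m in OUTLINE_BASED]
    angle_ms = [m for m in measures if m in ANGLE_BASED]
    if outline_ms and angle_ms:
        for stat in STATISTICS:
            outl = frame[[f"{stat}_{m}" for m in outline_ms]]
            ang = frame[[f"{stat}_{m}" for m in angle_ms]]
            outl_n = (outl - outl.min()) / (outl.max() - outl.min()).replace(0, np.nan)
            ang_n = (ang - ang.min()) / (ang.max() - ang.min()).replace(0, np.nan)
            frame[f"{stat}_outl"] = outl_n.mean(axis=1)
            frame[f"{stat}_ang"] = ang_n.mean(axis=1)
            frame[f"{stat}_outl_ang_ratio"] = frame[f"{stat}_outl"] / frame[
                f"{stat}_ang"
            ].where(frame[f"{stat}_ang"] > 0)
    return frame
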