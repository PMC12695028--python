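"""Sliding-window divergence-vs-relatedness scan.

Species pairs are ordered by normalized genetic distance dG.  For each
window start n, a *lower* set of ``window`` consecutive pairs (ranks
[n, n+window)) is compared against an *upper* set the same size placed
``offset`` ranks further up ([n+window+offset, n+2*window+offset)); a
one-sided Wilcoxon/Mann-Whitney rank-sum test (normal approximation
with tie correction) asks whether trait differences in the upper set
are stochastically greater.  No multiple-testing correction is applied
across windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "build_pair_table",
    "sliding_scan",
    "composition_annotation",
    "taxonomic_relation",
]

RELATION_LEVELS = (
    "same_family",
    "same_order",
    "same_superorder",
    "different_superorders",
)


def taxonomic_relation(tax_a: dict, tax_b: dict) -> str:
    """Finest shared taxonomic level between two species.

    Taxonomy entries carry ``family``, ``order``, ``superorder`` keys.
    """
    if tax_a.get("family") and tax_a.get("family") == tax_b.get("family"):
        return "same_family"
    if tax_a.get("order") and tax_a.get("order") == tax_b.get("order"):
        return "same_order"
    if tax_a.get("superorder") and tax_a.get("superorder") == tax_b.get("superorder"):
        return "same_superorder"
    return "different_superorders"


def build_pair_table(
    measures: pd.DataFrame, dg: pd.DataFrame, taxonomy: dict | None = None
) -> pd.DataFrame:
    """All unordered species pairs with per-trait absolute differences.

    ``measures`` is a species-indexed table of numeric traits; ``dg``
    the pair table from :func:`heterodont.phylo.dg_table`.  Rows come
    out sorted ascending by dG, ties broken by species names, so the
    ordering is deterministic across runs.
    """
    measure_species = set(measures.index)
    pair_species = set(dg["species_a"]) | set(dg["species_b"])
    missing = sorted(pair_species - measure_species)
    if missing:
        raise ValueError(f"species missing from measure table: {missing}")

    table = dg[["species_a", "species_b", "dG"]].copy()
    numeric = measures.select_dtypes(include=[np.number])
    a_vals = numeric.loc[table["species_a"]].to_numpy()
    b_vals = numeric.loc[table["species_b"]].to_numpy()
    diffs = pd.DataFrame(
        np.abs(a_vals - b_vals), columns=numeric.columns, index=table.index
    )
    table = pd.concat([table, diffs], axis=1)
    if taxonomy is not None:
        unlabeled = sorted(pair_species - set(taxonomy))
        if unlabeled:
            raise ValueError(f"species without taxonomy labels: {unlabeled}")
        table["relation"] = [
            taxonomic_relation(taxonomy[a], taxonomy[b])
            for a, b in zip(table["species_a"], table["species_b"])
        ]
    table = table.sort_values(
        ["dG", "species_a", "species_b"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def sliding_scan(
    table: pd.DataFrame, trait: str, window: int = 100, offset: int = 0
) -> pd.DataFrame:
    """Windowed one-sided rank-sum scan of a trait difference against dG rank.

    Returns one row per window start n with the p-value and both window
    anchors: the dG of the highest-ranked pair of the lower set
    (``dG_anchor``) and of the lowest-ranked pair of the upper set.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in pair table")
    total = len(table)
    span = 2 * window + offset
    if total < span:
        raise ValueError(
            f"need at least {span} pairs for window={window}, offset={offset}; got {total}"
        )
    values = table[trait].to_numpy(dtype=float)
    dg = table["dG"].to_numpy(dtype=float)
    rows = []
    for n in range(total - span + 1):
        lower = values[n : n + window]
        upper = values[n + window + offset : n + span]
        p = mannwhitneyu(upper, lower, alternative="greater", method="asymptotic")[1]
        rows.append(
            (n, dg[n + window - 1], dg[n + window + offset], trait, float(p))
        )
    return pd.DataFrame(
        rows, columns=["n", "dG_anchor", "dG_upper_start", "trait", "p"]
    )


def composition_annotation(table: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """Per-window fractions of pairs at each taxonomic relation level."""
    if "relation" not in table.columns:
        raise ValueError("pair table carries no taxonomy relation labels")
    total = len(table)
    if total < window:
        raise ValueError("fewer pairs than the window size")
    codes = table["relation"].to_numpy()
    rows = []
    for n in range(total - window + 1):
        chunk = codes[n : n + window]
        fractions = [np.count_nonzero(chunk == lvl) / window for lvl in RELATION_LEVELS]
        rows.append((n, *fractions))
    return pd.DataFrame(rows, columns=["n", *RELATION_LEVELS])
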