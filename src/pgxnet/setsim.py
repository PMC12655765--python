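"""Set-similarity coefficients on per-drug target sets.

The central coefficient is the B-index,

    B(x, y) = 1/2 * |x ∩ y| * (1/|x| + 1/|y|),

a size-aware similarity for two non-empty finite sets. Each shared element
is weighted by the probability of drawing it from each set, so an overlap
with a small target set counts for more than the same overlap with a large
one. B ranges from 0 (disjoint) to 1 (identical sets) and dominates the
classical coefficients: Russell-Rao <= Jaccard <= Dice <= B, the last step
being the AM-HM inequality on the two set sizes.

Conventions
-----------
Any comparison involving an empty set returns 0.0 (the index is defined for
non-empty sets; zero is the natural limit and keeps matrices total). Drugs
with empty target sets are dropped from similarity matrices with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Iterable, Mapping
from typing import AbstractSet

import numpy as np
import pandas as pd

VALID_INDEX_NAMES = ("b_index", "jaccard", "dice", "russell_rao")

PAIR_REPORT_COLUMNS = [
    "drug_a", "drug_b", "size_a", "size_b", "shared",
    "b_index", "jaccard", "dice",
]


def b_index(x: AbstractSet, y: AbstractSet) -> float:
    """B-index of two finite sets: ``0.5 * |x & y| * (1/|x| + 1/|y|)``.

    Equals 1 iff ``x == y`` (non-empty) and 0 iff the sets are disjoint.
    Comparisons involving an empty set return 0.0 by convention.
    """
    if not x or not y:
        return 0.0
    inter = len(x & y)
    return 0.5 * inter * (1.0 / len(x) + 1.0 / len(y))


def jaccard(x: AbstractSet, y: AbstractSet) -> float:
    """Jaccard index ``|x & y| / |x | y|``; 0.0 if both sets are empty."""
    if not x and not y:
        return 0.0
    return len(x & y) / len(x | y)


def dice(x: AbstractSet, y: AbstractSet) -> float:
    """Sorensen-Dice coefficient ``2|x & y| / (|x| + |y|)``; 0.0 for two empties."""
    if not x and not y:
        return 0.0
    return 2.0 * len(x & y) / (len(x) + len(y))


def russell_rao(x: AbstractSet, y: AbstractSet, universe: AbstractSet) -> float:
    """Russell-Rao coefficient ``|x & y| / |universe|``.

    Both sets must be subsets of the (non-empty) attribute universe.
    """
    if not universe:
        raise ValueError("russell_rao requires a non-empty universe")
    if not (x <= universe) or not (y <= universe):
        raise ValueError("sets must be subsets of the universe")
    return len(x & y) / len(universe)


def _coefficient(index_name: str, universe: AbstractSet | None):
    if index_name == "b_index":
        return b_index
    if index_name == "jaccard":
        return jaccard
    if index_name == "dice":
        return dice
    if index_name == "russell_rao":
        if universe is None:
            raise ValueError("russell_rao needs an explicit universe")
        return lambda x, y: russell_rao(x, y, universe)
    raise ValueError(f"unknown index {index_name!r}; expected one of {VALID_INDEX_NAMES}")


def pairwise_similarity(
    target_sets: Mapping[str, AbstractSet],
    index_name: str = "b_index",
    universe: AbstractSet | None = None,
) -> pd.DataFrame:
    """Symmetric drug x drug similarity matrix for the chosen coefficient.

    Drugs with empty target sets are excluded with a warning. The diagonal
    is the coefficient's self-similarity (1.0 except for Russell-Rao, where
    it is |x|/|universe|). ``DataFrame.attrs['index_name']`` records the
    coefficient used.
    """
    if not target_sets:
        raise ValueError("target_sets is empty")
    empty = sorted(d for d, s in target_sets.items() if not s)
    if empty:
        warnings.warn(
            f"dropping {len(empty)} drug(s) with empty target sets: {empty[:5]}...",
            stacklevel=2,
        )
    ids = sorted(d for d, s in target_sets.items() if s)
    if universe is None and index_name == "russell_rao":
        universe = set().union(*(target_sets[d] for d in ids))
    coef = _coefficient(index_name, universe)
    n = len(ids)
    values = np.empty((n, n))
    sets = [target_sets[d] for d in ids]
    for i in range(n):
        values[i, i] = coef(sets[i], sets[i])
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = coef(sets[i], sets[j])
    out = pd.DataFrame(values, index=ids, columns=ids)
    out.attrs["index_name"] = index_name
    return out


def pair_report(
    target_sets: Mapping[str, AbstractSet],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per unordered drug pair with sizes, overlap, and coefficients.

    Returns the table plus a summary dict with ``n_pairs``,
    ``pairs_shared_ge1`` and ``pairs_shared_0`` (the two counts always sum
    to C(n, 2)). Empty-set drugs participate (their coefficients are 0).
    """
    ids = sorted(target_sets)
    rows = []
    for a, b in itertools.combinations(ids, 2):
        x, y = target_sets[a], target_sets[b]
        shared = len(x & y)
        rows.append((a, b, len(x), len(y), shared,
                     b_index(x, y), jaccard(x, y), dice(x, y)))
    table = pd.DataFrame(rows, columns=PAIR_REPORT_COLUMNS)
    summary = {
        "n_drugs": len(ids),
        "n_pairs": len(table),
        "pairs_shared_ge1": int((table["shared"] >= 1).sum()) if len(table) else 0,
        "pairs_shared_0": int((table["shared"] == 0).sum()) if len(table) else 0,
    }
    return table, summary


def write_similarity_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="drug_id", float_format="%.10g")


def read_similarity_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_target_sets(path) -> dict[str, set]:
    """Read a two-column TSV (drug_id, gene_id; one membership per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("target-set TSV needs columns drug_id, gene_id")
    drug_col, gene_col = df.columns[:2]
    return {d: set(g) for d, g in df.groupby(drug_col)[gene_col]}


def write_target_sets(target_sets: Mapping[str, Iterable], path) -> None:
    rows = [(d, g) for d in sorted(target_sets) for g in sorted(target_sets[d])]
    pd.DataFrame(rows, columns=["drug_id", "gene_id"]).to_csv(path, sep="\t", index=False)
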