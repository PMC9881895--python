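"""Cross-platform meta-analysis of synthetic-lethality screens.

Different multiplex-perturbation platforms screen different cell lines and
different pair sets, and most hits do not replicate across platforms. The
platform weight quantifies within-platform replicability: for each pair of
cell lines screened by a platform, take the Jaccard coefficient of their
hit sets; the weight is the median over all cell-line pairs. The paralog
score of a gene pair is then the weighted sum of its hits minus the
weighted sum of its misses (assayed but not hit), each cell line carrying
its platform's weight. Pairs with a high score that are hits on more than
one platform are candidate background-independent (gold standard)
synthetic lethals.

The hit matrix is a long-format DataFrame with columns ``platform``,
``cell_line``, ``pair``, ``tested`` (bool) and ``hit`` (bool).
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

HIT_MATRIX_COLUMNS = ("platform", "cell_line", "pair", "tested", "hit")


class MetaAnalysisError(ValueError):
    pass


def validate_hit_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    missing = set(HIT_MATRIX_COLUMNS) - set(matrix.columns)
    if missing:
        raise MetaAnalysisError(f"hit matrix missing columns: {sorted(missing)}")
    bad = matrix["hit"] & ~matrix["tested"]
    if bad.any():
        raise MetaAnalysisError("hit flagged on untested (platform, cell line, pair) rows")
    return matrix


def jaccard(hits_a: Iterable, hits_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B| of two hit sets; 0 if both are empty (with warning)."""
    a, b = set(hits_a), set(hits_b)
    union = a | b
    if not union:
        warnings.warn(
            "Jaccard of two empty hit sets is 0 by convention", stacklevel=2
        )
        return 0.0
    return len(a & b) / len(union)


def platform_weight(platform_slice: pd.DataFrame) -> float:
    """Median Jaccard coefficient over all unordered cell-line pairs.

    ``platform_slice`` holds one platform's rows of the hit matrix. With
    exactly two cell lines the weight is their single coefficient; a
    single cell line leaves replicability undefined and raises.
    """
    lines = sorted(platform_slice["cell_line"].unique())
    if len(lines) < 2:
        raise MetaAnalysisError(
            f"platform weight undefined with {len(lines)} cell line(s)"
        )
    hit_sets = {
        line: set(platform_slice.loc[
            (platform_slice["cell_line"] == line) & platform_slice["hit"], "pair"
        ])
        for line in lines
    }
    coeffs = [
        jaccard(hit_sets[a], hit_sets[b]) for a, b in itertools.combinations(lines, 2)
    ]
    return float(np.median(coeffs))


def platform_weights(matrix: pd.DataFrame) -> pd.Series:
    """Per-platform replicability weights over the whole hit matrix."""
    validate_hit_matrix(matrix)
    weights = {
        platform: platform_weight(sub)
        for platform, sub in matrix.groupby("platform", sort=True)
    }
    return pd.Series(weights, name="weight")


def paralog_score(
    pair: str, matrix: pd.DataFrame, weights: Mapping[str, float]
) -> float:
    """Weighted hits minus weighted misses for one pair.

    Every (platform, cell line) in which the pair was tested contributes
    its platform's weight, positively for a hit and negatively for a miss;
    untested cell lines contribute nothing.
    """
    rows = matrix[(matrix["pair"] == pair) & matrix["tested"]]
    if rows.empty:
        raise MetaAnalysisError(f"pair {pair!r} was tested nowhere")
    w = rows["platform"].map(weights)
    if w.isna().any():
        missing = rows.loc[w.isna(), "platform"].unique().tolist()
        raise MetaAnalysisError(f"no weight for platform(s) {missing}")
    sign = np.where(rows["hit"], 1.0, -1.0)
    return float((sign * w.to_numpy()).sum())


def paralog_scores(
    matrix: pd.DataFrame, weights: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Score every tested pair; count platforms on which it was a hit.

    Returns a DataFrame with ``pair``, ``score``, ``n_platforms_hit`` and
    ``n_platforms_tested``.
    """
    validate_hit_matrix(matrix)
    if weights is None:
        weights = platform_weights(matrix)
    tested = matrix[matrix["tested"]]
    records = []
    for pair, sub in tested.groupby("pair", sort=True):
        w = sub["platform"].map(weights).to_numpy()
        sign = np.where(sub["hit"], 1.0, -1.0)
        records.append(
            {
                "pair": pair,
                "score": float((sign * w).sum()),
                "n_platforms_hit": int(sub.loc[sub["hit"], "platform"].nunique()),
                "n_platforms_tested": int(sub["platform"].nunique()),
            }
        )
    return pd.DataFrame(records)


def select_gold_standards(
    records: pd.DataFrame,
    min_score: float = 0.25,
    min_studies: int = 2,
) -> pd.DataFrame:
    """Flag candidate gold-standard synthetic lethals.

    Gold iff paralog score strictly exceeds ``min_score`` and the pair was
    a hit on at least ``min_studies`` platforms.
    """
    out = records.copy()
    out["gold_standard"] = (out["score"] > min_score) & (
        out["n_platforms_hit"] >= min_studies
    )
    return out
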