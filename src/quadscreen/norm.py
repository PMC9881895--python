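"""Count normalization, log2 fold changes and mode-centering.

The preprocessing chain for a pooled knockout screen is: add a pseudocount,
scale each sample to a fixed mean depth per construct, take log2 fold
change against a reference sample (plasmid or T0), shift each construct
group so its modal fold change is zero, then average replicates. Mode
centering uses a Gaussian kernel density estimate (Silverman bandwidth,
512-point grid) so the heavy left tail contributed by essential-gene
constructs does not drag the centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .screens import CountMatrix, LibraryAnnotation, ScreenDataError


class NormalizationError(ValueError):
    pass


def normalize_counts(
    cm: CountMatrix,
    pseudocount: float = 5,
    target_per_construct: float = 500,
) -> CountMatrix:
    """Pseudocount + depth normalization.

    Adds ``pseudocount`` to every cell, then scales each sample so its
    total equals ``target_per_construct`` times the number of constructs
    (i.e. the per-construct mean equals the target). Relative abundances
    within a sample are preserved.
    """
    if pseudocount < 0:
        raise NormalizationError("pseudocount must be >= 0")
    x = cm.counts.astype(float) + pseudocount
    totals = x.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise NormalizationError(
            f"sample(s) {bad} have zero total after pseudocount; scaling undefined"
        )
    target_total = target_per_construct * len(cm.counts)
    normed = x * (target_total / totals)
    return CountMatrix(counts=normed, sample_meta=cm.sample_meta)


def compute_lfc(
    norm: CountMatrix,
    reference: str | Sequence[str] = "T0",
) -> pd.DataFrame:
    """Log2 fold change of every non-reference sample against the reference.

    ``reference`` is either a sample role (``plasmid`` or ``T0``; all
    samples with that role form the reference set) or an explicit list of
    sample ids. With a reference set, the per-construct reference value is
    the mean of the normalized counts across the set.

    Returns a long-format table with columns ``construct_id``, ``sample``,
    ``replicate`` and ``lfc``.
    """
    if isinstance(reference, str):
        ref_samples = norm.samples_with_role(reference)
        if not ref_samples:
            raise NormalizationError(f"no samples with reference role {reference!r}")
    else:
        ref_samples = list(reference)
        missing = set(ref_samples) - set(norm.sample_ids)
        if missing:
            raise NormalizationError(f"reference samples not in matrix: {sorted(missing)}")
    ref = norm.counts[ref_samples].mean(axis=1)
    if (ref <= 0).any():
        raise NormalizationError(
            "zero normalized reference value; use a positive pseudocount upstream"
        )
    rows = []
    meta = norm.sample_meta
    for sample in norm.sample_ids:
        if sample in ref_samples:
            continue
        lfc = np.log2(norm.counts[sample] / ref)
        rep = meta.loc[sample].get("replicate", sample)
        rows.append(
            pd.DataFrame(
                {
                    "construct_id": norm.counts.index,
                    "sample": sample,
                    "replicate": rep,
                    "lfc": lfc.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def estimate_mode(values: np.ndarray, grid_size: int = 512) -> float:
    """Location of the highest peak of a Gaussian KDE (Silverman bandwidth).

    The density is evaluated on a fixed 512-point grid spanning the data
    range; the argmax is the mode. Degenerate (zero-variance) input returns
    the common value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise NormalizationError("cannot estimate the mode of an empty set")
    if np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_size)
    density = kde(grid)
    return float(grid[np.argmax(density)])


def mode_center(
    lfc: pd.DataFrame,
    grouping: str = "per_group",
    group_col: str = "group",
    control_group: str | None = None,
    min_group: int = 10,
    value_col: str = "lfc",
) -> pd.DataFrame:
    """Shift fold changes so the modal value of each group is zero.

    ``grouping='per_group'`` shifts every group (e.g. gene_N, N_gene, A_B)
    by its own estimated mode. ``grouping='controls'`` estimates the mode
    on the ``control_group`` rows only and shifts the whole table by that
    single value (used when a study has a designated negative-control
    class). Centering is a subtraction, so within-group differences are
    preserved and the operation is invariant to adding a constant.

    Groups smaller than ``min_group`` raise an error: KDE mode estimates
    on a handful of points are unstable.
    """
    out = lfc.copy()
    if grouping == "per_group":
        for name, sub in out.groupby(group_col, sort=False):
            if len(sub) < min_group:
                raise NormalizationError(
                    f"group {name!r} has {len(sub)} < {min_group} values; "
                    "mode estimate unstable"
                )
            shift = estimate_mode(sub[value_col].to_numpy())
            out.loc[sub.index, value_col] = sub[value_col] - shift
    elif grouping == "controls":
        if control_group is None:
            raise NormalizationError("controls grouping needs control_group")
        ctrl = out[out[group_col] == control_group]
        if len(ctrl) < min_group:
            raise NormalizationError(
                f"control group {control_group!r} has {len(ctrl)} < {min_group} values"
            )
        shift = estimate_mode(ctrl[value_col].to_numpy())
        out[value_col] = out[value_col] - shift
    else:
        raise NormalizationError(f"unknown grouping scheme {grouping!r}")
    return out


def average_replicates(
    lfc: pd.DataFrame,
    strict: bool = True,
    value_col: str = "lfc",
) -> pd.Series:
    """Per-construct mean fold change across replicates.

    With ``strict=True``, a construct missing from any replicate is an
    error; with ``strict=False`` the mean is taken over the replicates
    where the construct was observed (a warning is emitted).
    """
    pivot = lfc.pivot_table(
        index="construct_id", columns="replicate", values=value_col, aggfunc="mean"
    )
    if pivot.isna().any().any():
        missing = pivot.index[pivot.isna().any(axis=1)].tolist()
        if strict:
            raise NormalizationError(
                f"constructs missing from some replicate(s): {missing[:5]}"
            )
        warnings.warn(
            f"{len(missing)} construct(s) missing from some replicates; "
            "averaging over available replicates",
            stacklevel=2,
        )
    means = pivot.mean(axis=1, skipna=not strict)
    means.name = "lfc"
    return means


@dataclass
class StudyPreprocessConfig:
    """Declarative per-study preprocessing variant.

    Source studies differ in which sample is the reference, how fold
    changes are anchored, and which constructs are excluded. Those
    differences are data, not code branches: e.g. one study is anchored on
    its nonessential_AAVS1 negative controls with a gene family removed to
    avoid false pair discovery; another has a single singleton orientation
    and anchors on nonessential_Fluc controls.
    """

    reference: str = "plasmid"
    grouping: str = "per_group"
    control_group: str | None = None
    exclude_gene_prefixes: tuple[str, ...] = ()
    pseudocount: float = 5
    target_per_construct: float = 500

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "grouping": self.grouping,
            "control_group": self.control_group,
            "exclude_gene_prefixes": list(self.exclude_gene_prefixes),
            "pseudocount": self.pseudocount,
            "target_per_construct": self.target_per_construct,
        }


def preprocess_screen(
    cm: CountMatrix,
    groups: pd.Series,
    config: StudyPreprocessConfig | None = None,
) -> pd.Series:
    """Full chain: normalize -> LFC -> mode-center -> replicate mean.

    ``groups`` maps construct id to its group label (gene_N / N_gene /
    A_B / control). Returns the per-construct mean centered fold change.
    """
    config = config or StudyPreprocessConfig()
    normed = normalize_counts(
        cm, pseudocount=config.pseudocount,
        target_per_construct=config.target_per_construct,
    )
    lfc = compute_lfc(normed, reference=config.reference)
    lfc["group"] = lfc["construct_id"].map(groups)
    if config.exclude_gene_prefixes:
        keep = ~lfc["construct_id"].str.startswith(tuple(config.exclude_gene_prefixes))
        lfc = lfc[keep].reset_index(drop=True)
    lfc = mode_center(
        lfc, grouping=config.grouping, control_group=config.control_group
    )
    return average_replicates(lfc)
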