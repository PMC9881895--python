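"""Seven-guide array designs and the multiplicative-null regression.

A 7-position Cas12a array in which each position carries either an
essential- or a nonessential-targeting guide probes whether independent
knockouts combine additively in log2 fold-change space. Enumerating every
essential/nonessential assignment gives 2^7 = 128 arrays per guide pool;
three pools with independent guide picks give 384 arrays. Under the
multiplicative (additive-in-log) null, fold change is modelled as

    y ~ A @ beta        (no intercept)

where A is the arrays x positions binary matrix and beta the per-position
single-knockout effects. Because higher-order arrays saturate the fitness
phenotype, the fit is restricted to arrays encoding at most two essential
guides before estimating beta; predicted array fitness is then simply the
sum of the fitted coefficients over occupied positions. Position-effect
diagnostics (mean fold change of single-essential arrays per position, and
forward-vs-reverse array deviations) localize where guide expression
efficiency drops off along the array.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd


class DesignError(ValueError):
    pass


def position_columns(n_positions: int) -> list[str]:
    return [f"pos{j}" for j in range(1, n_positions + 1)]


def enumerate_7mer_designs(n_positions: int = 7, n_pools: int = 3) -> pd.DataFrame:
    """All essential/nonessential assignments for every pool.

    Returns one row per (pool, binary assignment): columns ``pool``,
    ``array_id``, ``pos1..posN`` (0 = nonessential guide, 1 = essential
    guide) and ``guides`` (pool-specific guide identifiers, since each
    pool uses its own guide picks for the same genes).
    """
    if n_positions < 1:
        raise DesignError("need at least one array position")
    cols = position_columns(n_positions)
    rows = []
    for pool in range(1, n_pools + 1):
        for bits in itertools.product((0, 1), repeat=n_positions):
            word = "".join(map(str, bits))
            guides = ";".join(
                f"p{pool}.pos{j}.{'ess' if b else 'non'}"
                for j, b in enumerate(bits, start=1)
            )
            row = {"pool": pool, "array_id": f"pool{pool}_{word}", "guides": guides}
            row.update(dict(zip(cols, bits)))
            rows.append(row)
    return pd.DataFrame(rows)


def filter_low_order(designs: pd.DataFrame, max_essentials: int = 2) -> pd.DataFrame:
    """Keep arrays encoding at most ``max_essentials`` essential guides."""
    cols = [c for c in designs.columns if c.startswith("pos")]
    keep = designs[cols].sum(axis=1) <= max_essentials
    return designs[keep].reset_index(drop=True)


@dataclass
class MultiplicativeFit:
    """Least-squares fit of the no-intercept multiplicative null model."""

    beta: pd.DataFrame  # positions x pools (one shared column if shared fit)
    r2_by_pool: pd.Series
    predictions: pd.Series
    residuals: pd.Series
    shared: bool

    def beta_for_pool(self, pool) -> pd.Series:
        col = "shared" if self.shared else pool
        return self.beta[col]


def fit_multiplicative_model(
    designs: pd.DataFrame,
    value_col: str = "fc",
    per_pool: bool = False,
) -> MultiplicativeFit:
    """Fit ``y ~ A beta`` without intercept; report per-pool R².

    The no-intercept form is justified by the normalization convention:
    fold changes are centered so arrays with zero essential guides sit at
    zero, making the baseline structurally zero. By default a single beta
    is shared across pools (positions, not guides, are the coefficients);
    ``per_pool=True`` fits each pool separately. R² = 1 - SSE/SST over
    array-level observations within each pool.

    A rank-deficient design matrix raises, naming the dependent columns.
    """
    cols = [c for c in designs.columns if c.startswith("pos")]
    n_pos = len(cols)
    if value_col not in designs.columns:
        raise DesignError(f"designs table has no {value_col!r} column")
    if len(designs) < n_pos + 1:
        raise DesignError(
            f"need at least {n_pos + 1} arrays to fit {n_pos} coefficients"
        )

    def _check_rank(A: np.ndarray) -> None:
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            # identify columns not adding rank, scanning left to right
            dependent, base = [], np.empty((A.shape[0], 0))
            for j in range(A.shape[1]):
                trial = np.column_stack([base, A[:, j]])
                if np.linalg.matrix_rank(trial) == base.shape[1]:
                    dependent.append(cols[j])
                else:
                    base = trial
            raise DesignError(f"design matrix rank-deficient; dependent columns: {dependent}")

    def _fit(A: np.ndarray, y: np.ndarray) -> np.ndarray:
        _check_rank(A)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return beta

    preds = pd.Series(np.nan, index=designs.index, dtype=float)
    if per_pool:
        beta_cols = {}
        for pool, sub in designs.groupby("pool", sort=True):
            A = sub[cols].to_numpy(dtype=float)
            y = sub[value_col].to_numpy(dtype=float)
            b = _fit(A, y)
            beta_cols[pool] = b
            preds.loc[sub.index] = A @ b
        beta = pd.DataFrame(beta_cols, index=cols)
    else:
        A = designs[cols].to_numpy(dtype=float)
        y = designs[value_col].to_numpy(dtype=float)
        b = _fit(A, y)
        beta = pd.DataFrame({"shared": b}, index=cols)
        preds.loc[designs.index] = A @ b

    resid = designs[value_col] - preds
    r2 = {}
    for pool, sub in designs.groupby("pool", sort=True):
        y = sub[value_col].to_numpy(dtype=float)
        sse = float(((y - preds.loc[sub.index].to_numpy()) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        r2[pool] = 1.0 - sse / sst if sst > 0 else np.nan
    return MultiplicativeFit(
        beta=beta, r2_by_pool=pd.Series(r2, name="r2"),
        predictions=preds, residuals=resid, shared=not per_pool,
    )


def predict_array_fitness(bits, beta) -> float:
    """Expected fold change of an array: sum of beta over occupied positions."""
    bits = np.asarray(bits, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if bits.shape != beta.shape:
        raise DesignError("design row and beta have different lengths")
    return float(bits @ beta)


def position_effect_profile(
    designs: pd.DataFrame, value_col: str = "fc"
) -> pd.DataFrame:
    """Per-position fold change of single-essential arrays, per pool.

    Returns one row per (pool, position) with mean, standard deviation and
    array count; a position with no single-essential array in a pool is
    kept with ``missing=True`` so gaps are visible rather than silent.
    """
    cols = [c for c in designs.columns if c.startswith("pos")]
    singles = designs[designs[cols].sum(axis=1) == 1]
    records = []
    for pool in sorted(designs["pool"].unique()):
        pool_rows = singles[singles["pool"] == pool]
        for j, col in enumerate(cols, start=1):
            at_j = pool_rows[pool_rows[col] == 1]
            if at_j.empty:
                records.append(
                    {"pool": pool, "position": j, "mean_fc": np.nan,
                     "std_fc": np.nan, "n": 0, "missing": True}
                )
            else:
                vals = at_j[value_col]
                records.append(
                    {"pool": pool, "position": j, "mean_fc": float(vals.mean()),
                     "std_fc": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     "n": int(len(vals)), "missing": False}
                )
    return pd.DataFrame(records)


def forward_reverse_deviation(
    forward: pd.Series, reverse: pd.Series, n_positions: int | None = None,
    forward_positions: pd.Series | None = None,
) -> pd.DataFrame:
    """Deviation of reverse-orientation from forward-orientation fold change.

    ``forward`` and ``reverse`` are per-gene fold changes from arrays
    carrying one essential guide, with the gene order reversed between the
    two array sets. Values on the diagonal (deviation 0) indicate gene- and
    guide-level effects independent of position; non-zero deviations
    indicate position-specific effects. If ``forward_positions`` (gene ->
    position in the forward array) is given, each gene is annotated with
    its position in both orientations (reverse position = n + 1 - forward).
    """
    unmatched = set(forward.index) ^ set(reverse.index)
    if unmatched:
        raise DesignError(f"genes present in only one orientation: {sorted(unmatched)}")
    genes = list(forward.index)
    out = pd.DataFrame(
        {
            "gene": genes,
            "forward_fc": forward.loc[genes].to_numpy(),
            "reverse_fc": reverse.loc[genes].to_numpy(),
        }
    )
    out["deviation"] = out["reverse_fc"] - out["forward_fc"]
    if forward_positions is not None:
        if n_positions is None:
            n_positions = int(forward_positions.max())
        out["forward_position"] = out["gene"].map(forward_positions).astype(int)
        out["reverse_position"] = n_positions + 1 - out["forward_position"]
    return out
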