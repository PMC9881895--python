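"""Synthetic screens with known ground truth.

Generators emulate the three data shapes the pipeline consumes: pooled
screen count matrices (negative-binomial counts around expected fold
changes composed from single-gene fitness, guide efficiency and declared
genetic-interaction effects), multi-platform hit matrices with tunable
per-platform replicability, and seven-position array fold changes for the
multiplicative-null regression. Everything is bit-reproducible under its
seed.

Guide efficiency enters as a multiplicative attenuation of each gene's
fitness effect; the probability that an array achieves a joint knockout of
all its targets is modelled as the product of member efficiencies (so e.g.
80% single-gene efficiency implies ~50% triple-knockout efficiency), and
declared interaction effects are attenuated by that product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screens import (
    GROUP_A_B,
    GROUP_GENE_N,
    GROUP_N_GENE,
    CountMatrix,
    LibraryAnnotation,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Ground truth behind a simulated screen.

    ``smf`` maps gene -> true single-knockout log2 fold change; ``gi``
    maps a frozenset of genes -> interaction effect (extra log2 fold
    change applied when a construct targets every member of the set);
    ``efficiency`` maps gene -> editing efficiency in [0, 1] (default 1).
    ``lfc_sigma`` is the per-construct-per-replicate fold-change noise;
    ``dispersion`` the negative-binomial overdispersion of counts.
    """

    smf: dict[str, float] = field(default_factory=dict)
    gi: dict[frozenset, float] = field(default_factory=dict)
    efficiency: dict[str, float] = field(default_factory=dict)
    lfc_sigma: float = 0.3
    dispersion: float = 0.1
    seed: int = 0

    def gene_efficiency(self, gene: str) -> float:
        eff = self.efficiency.get(gene, 1.0)
        if not 0 <= eff <= 1:
            raise SimulationError(f"efficiency of {gene!r} outside [0, 1]")
        return eff

    def expected_lfc(self, targets: Sequence[str]) -> float:
        """Efficiency-weighted additive fitness plus applicable GI effects."""
        targets = [t for t in targets if t]
        for t in targets:
            if t not in self.smf:
                raise SimulationError(f"no true SMF declared for target {t!r}")
        total = sum(self.gene_efficiency(t) * self.smf[t] for t in targets)
        tset = set(targets)
        for members, effect in self.gi.items():
            if members <= tset:
                total += effect * joint_knockout_probability(
                    [self.gene_efficiency(g) for g in members]
                )
        return total


def joint_knockout_probability(efficiencies: Sequence[float]) -> float:
    """Probability all members of a set are edited: product of efficiencies."""
    p = 1.0
    for eff in efficiencies:
        if not 0 <= eff <= 1:
            raise SimulationError(f"efficiency {eff} outside [0, 1]")
        p *= eff
    return p


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial with Var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen_counts(
    truth: SimTruth,
    library: LibraryAnnotation,
    depth: float = 500,
    replicates: int = 2,
    timepoint: str = "T14",
) -> CountMatrix:
    """Pooled-screen count matrix for a guide-array library.

    The reference sample ("T0") draws negative-binomial counts around a
    uniform abundance of ``depth`` reads per construct. Each endpoint
    replicate draws counts around depth * 2^(expected LFC + noise), where
    the expected LFC follows :meth:`SimTruth.expected_lfc` and the noise
    is N(0, lfc_sigma^2) per construct and replicate.
    """
    if depth <= 0:
        raise SimulationError("depth must be positive")
    rng = np.random.default_rng(truth.seed)
    constructs = list(library.table["construct_id"])
    targets = list(library.table["targets"])
    expected = np.array([truth.expected_lfc(t) for t in targets])

    data = {"T0": _nb_draw(rng, np.full(len(constructs), depth), truth.dispersion)}
    meta = {"T0": {"role": "T0", "timepoint": "T0", "replicate": "T0"}}
    for rep in range(1, replicates + 1):
        noise = rng.normal(0.0, truth.lfc_sigma, size=len(constructs))
        mean = depth * np.power(2.0, expected + noise)
        name = f"{timepoint}_rep{rep}"
        data[name] = _nb_draw(rng, mean, truth.dispersion)
        meta[name] = {"role": "endpoint", "timepoint": timepoint, "replicate": f"rep{rep}"}
    counts = pd.DataFrame(data, index=pd.Index(constructs, name="construct_id"))
    return CountMatrix(counts=counts, sample_meta=pd.DataFrame.from_dict(meta, orient="index"))


def make_pair_library(
    gene1: str = "GENE1",
    gene2: str = "GENE2",
    n_per_group: int = 3,
    n_controls: int = 0,
    spacer_rng: np.random.Generator | None = None,
) -> LibraryAnnotation:
    """Minimal two-slot paralog library: both singleton orientations for
    each gene plus A_B pair constructs, ``n_per_group`` constructs each,
    optionally plus ``n_controls`` control-control constructs (no targets;
    they serve as the neutral anchor for centering)."""
    from .design import random_spacer

    rng = spacer_rng or np.random.default_rng(7)
    records = []

    def _add(cid, targets, cls, orientation):
        records.append(
            {
                "construct_id": cid,
                "spacers": (random_spacer(rng), random_spacer(rng)),
                "drs": ("TAATTTCTACTATTGTAGAT",),
                "targets": targets,
                "construct_class": cls,
                "control_type": "none" if cls != "control" else "nonessential",
                "orientation": orientation,
            }
        )

    for i in range(n_per_group):
        _add(f"{gene1}_N_{i}", (gene1,), "single", GROUP_GENE_N)
        _add(f"N_{gene1}_{i}", (gene1,), "single", GROUP_N_GENE)
        _add(f"{gene2}_N_{i}", (gene2,), "single", GROUP_GENE_N)
        _add(f"N_{gene2}_{i}", (gene2,), "single", GROUP_N_GENE)
        _add(f"{gene1}_{gene2}_{i}", (gene1, gene2), "pair", GROUP_A_B)
    for i in range(n_controls):
        _add(f"control_{i}", (), "control", "control")
    return LibraryAnnotation.from_records(records)


def simulate_pair_lfc(
    smf1: float,
    smf2: float,
    gi_effect: float = 0.0,
    n_per_group: int = 3,
    replicates: int = 2,
    sigma: float = 0.3,
    seed: int = 0,
    gene1: str = "GENE1",
    gene2: str = "GENE2",
) -> pd.DataFrame:
    """Construct-level fold changes for one pair, directly in LFC space.

    Each of the five groups (gene_N and N_gene for both genes, plus A_B)
    carries ``n_per_group`` constructs; every construct's fold change is
    its true value plus N(0, sigma^2) noise per replicate, averaged over
    replicates. Returns the tidy construct table consumed by the GI
    scoring functions (columns ``construct_id``, ``gene1``, ``gene2``,
    ``group``, ``lfc``).
    """
    rng = np.random.default_rng(seed)
    truth_pair = smf1 + smf2 + gi_effect
    rows = []

    def _emit(prefix, g1, g2, group, true_value):
        for i in range(n_per_group):
            noise = rng.normal(0.0, sigma, size=replicates).mean()
            rows.append(
                {
                    "construct_id": f"{prefix}_{i}",
                    "gene1": g1,
                    "gene2": g2,
                    "group": group,
                    "lfc": true_value + noise,
                }
            )

    _emit(f"{gene1}_N", gene1, "control", GROUP_GENE_N, smf1)
    _emit(f"N_{gene1}", "control", gene1, GROUP_N_GENE, smf1)
    _emit(f"{gene2}_N", gene2, "control", GROUP_GENE_N, smf2)
    _emit(f"N_{gene2}", "control", gene2, GROUP_N_GENE, smf2)
    _emit(f"{gene1}_{gene2}", gene1, gene2, GROUP_A_B, truth_pair)
    return pd.DataFrame(rows)


def simulate_multiplatform_hits(
    n_platforms: int = 5,
    cell_lines_per: int = 3,
    n_pairs: int = 500,
    n_true_sl: int = 50,
    recall_per_platform: Sequence[float] = (0.9, 0.7, 0.5, 0.3, 0.1),
    fpr: float = 0.01,
    seed: int = 0,
    tested_fraction: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Long-format hit matrix with per-platform replicability.

    Each platform screens ``cell_lines_per`` cell lines over a (possibly
    partial, via ``tested_fraction``) subset of ``n_pairs`` pairs, of
    which the first ``n_true_sl`` are true synthetic lethals. A true SL is
    called a hit in each cell line independently with the platform's
    recall; any other tested pair is called at ``fpr``.
    """
    if len(recall_per_platform) != n_platforms:
        raise SimulationError("need one recall per platform")
    for p in list(recall_per_platform) + [fpr]:
        if not 0 <= p <= 1:
            raise SimulationError(f"probability {p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = np.array([f"pair{i:04d}" for i in range(n_pairs)])
    is_true_sl = np.arange(n_pairs) < n_true_sl
    frames = []
    for k in range(n_platforms):
        platform = f"platform{k + 1}"
        recall = recall_per_platform[k]
        if tested_fraction is not None:
            mask = rng.random(n_pairs) < tested_fraction[k]
        else:
            mask = np.ones(n_pairs, dtype=bool)
        tested_pairs = pairs[mask]
        p_hit = np.where(is_true_sl[mask], recall, fpr)
        for line_idx in range(cell_lines_per):
            hits = rng.random(len(tested_pairs)) < p_hit
            frames.append(
                pd.DataFrame(
                    {
                        "platform": platform,
                        "cell_line": f"{platform}_line{line_idx + 1}",
                        "pair": tested_pairs,
                        "tested": True,
                        "hit": hits,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_7mer_lfc(
    beta: Sequence[float],
    designs: pd.DataFrame,
    position_attenuation: Sequence[float] | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    value_col: str = "fc",
) -> pd.DataFrame:
    """Array fold changes under the additive model with position attenuation.

    fc_i = sum_j A_ij * beta_j * attenuation_j + N(0, sigma^2). Attenuation
    multipliers in [0, 1] emulate the loss of guide expression efficiency
    at late array positions.
    """
    cols = [c for c in designs.columns if c.startswith("pos")]
    beta = np.asarray(beta, dtype=float)
    if len(beta) != len(cols):
        raise SimulationError("beta length must match the number of positions")
    if position_attenuation is None:
        atten = np.ones(len(cols))
    else:
        atten = np.asarray(position_attenuation, dtype=float)
        if len(atten) != len(cols) or (atten < 0).any() or (atten > 1).any():
            raise SimulationError("attenuation must be per-position values in [0, 1]")
    rng = np.random.default_rng(seed)
    A = designs[cols].to_numpy(dtype=float)
    y = A @ (beta * atten) + rng.normal(0.0, sigma, size=len(designs))
    out = designs.copy()
    out[value_col] = y
    return out
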