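"""Genetic-interaction scoring under the multiplicative null model.

Single mutant fitness (SMF) for a gene is the mean log2 fold change of its
gene-control constructs. The expected fitness of a joint knockout is the
sum of the member SMFs (multiplicative model in log space); the observed
fitness is the mean fold change of all constructs targeting the full set.
Their difference, dLFC = observed - expected, measures the genetic
interaction: negative values are synthetic/synergistic, positive values
masking/suppressing. For pairs, a modified Cohen's D standardizes the
separation between the observed fold-change distribution and the expected
distribution implied by the two single-knockout groups:

    expected_mean = mu1 + mu2
    expected_std  = sqrt(std1^2 + std2^2)
    Spooled       = sqrt((expected_std^2 + observed_std^2) / 2)
    D             = (expected_mean - observed_mean) / Spooled

so D > 0 when the pair is more depleted than expected. Default hit calling
uses dLFC < -1 with D > 0.8 (pair mode) or the dLFC thresholds alone
(threshold mode, used for gene sets of any size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .screens import GROUP_A_B, GROUP_GENE_N, GROUP_N_GENE, ReferenceGeneSets

SINGLETON_GROUPS = (GROUP_GENE_N, GROUP_N_GENE)


class GIError(ValueError):
    pass


@dataclass(frozen=True)
class GroupStats:
    """Mean, sample standard deviation (ddof=1) and size of a construct group."""

    mean: float
    std: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise GIError(f"GroupStats needs n >= 2, got n={self.n}")
        if self.std < 0:
            raise GIError("standard deviation must be >= 0")

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "GroupStats":
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise GIError(f"need >= 2 values to form GroupStats, got {arr.size}")
        return cls(mean=float(arr.mean()), std=float(arr.std(ddof=1)), n=int(arr.size))


def single_mutant_fitness(constructs: pd.DataFrame, gene: str) -> float:
    """Mean fold change of the gene-control constructs of ``gene``.

    ``constructs`` is a tidy table with columns ``gene1``, ``gene2``,
    ``group`` and ``lfc`` (construct-level, replicate-averaged). Both
    singleton orientations (gene_N and N_gene) are pooled.
    """
    sub = _singleton_rows(constructs, gene)
    if sub.empty:
        raise GIError(f"no singleton (gene-control) constructs for gene {gene!r}")
    return float(sub["lfc"].mean())


def _singleton_rows(constructs: pd.DataFrame, gene: str) -> pd.DataFrame:
    is_single = constructs["group"].isin(SINGLETON_GROUPS)
    hits = is_single & (
        ((constructs["group"] == GROUP_GENE_N) & (constructs["gene1"] == gene))
        | ((constructs["group"] == GROUP_N_GENE) & (constructs["gene2"] == gene))
    )
    return constructs[hits]


def _pair_rows(constructs: pd.DataFrame, gene1: str, gene2: str) -> pd.DataFrame:
    is_pair = constructs["group"] == GROUP_A_B
    fwd = (constructs["gene1"] == gene1) & (constructs["gene2"] == gene2)
    rev = (constructs["gene1"] == gene2) & (constructs["gene2"] == gene1)
    return constructs[is_pair & (fwd | rev)]


def expected_double_mutant_fitness(smf1: float, smf2: float) -> float:
    """Expected joint fitness: the sum of single mutant fitnesses (log space)."""
    if not (math.isfinite(smf1) and math.isfinite(smf2)):
        raise GIError("SMF values must be finite")
    return smf1 + smf2


def delta_lfc(observed_dmf: float, expected_dmf: float) -> float:
    """dLFC = observed - expected; negative = synthetic, positive = masking."""
    return observed_dmf - expected_dmf


def cohens_d(g1: GroupStats, g2: GroupStats, observed: GroupStats) -> float:
    """Modified Cohen's D between the expected and observed distributions.

    Composed exactly from the four-formula chain in the module docstring;
    D > 0 when the observed mean is more negative than expected.
    """
    expected_mean = g1.mean + g2.mean
    expected_std = math.sqrt(g1.std**2 + g2.std**2)
    spooled = math.sqrt((expected_std**2 + observed.std**2) / 2)
    if spooled == 0:
        raise GIError("Spooled is zero: degenerate (zero-spread) distributions")
    return (expected_mean - observed.mean) / spooled


@dataclass
class GIResult:
    """Interaction score for one gene set."""

    genes: tuple[str, ...]
    smf: dict[str, float]
    expected_dmf: float
    observed_dmf: float
    dlfc: float
    cohens_d: float | None  # pairs only
    classification: str = "none"  # synthetic_lethal | masking | none
    hit: bool = False

    def as_record(self) -> dict:
        rec = {
            "genes": "|".join(self.genes),
            "expected_dmf": self.expected_dmf,
            "observed_dmf": self.observed_dmf,
            "dlfc": self.dlfc,
            "cohens_d": self.cohens_d,
            "classification": self.classification,
            "hit": self.hit,
        }
        for i, g in enumerate(self.genes, start=1):
            rec[f"gene{i}"] = g
            rec[f"smf{i}"] = self.smf[g]
        return rec


def score_pair(constructs: pd.DataFrame, gene1: str, gene2: str) -> GIResult:
    """SMF, dLFC and Cohen's D for one gene pair.

    Observed statistics use all constructs annotated A_B for the pair in
    either orientation; singleton statistics pool both orientations.
    """
    singles1 = _singleton_rows(constructs, gene1)["lfc"]
    singles2 = _singleton_rows(constructs, gene2)["lfc"]
    pairs = _pair_rows(constructs, gene1, gene2)["lfc"]
    if pairs.empty:
        raise GIError(f"no double-targeting constructs for pair ({gene1}, {gene2})")
    if singles1.empty or singles2.empty:
        missing = gene1 if singles1.empty else gene2
        raise GIError(f"no singleton constructs for gene {missing!r}")
    smf1 = float(singles1.mean())
    smf2 = float(singles2.mean())
    expected = expected_double_mutant_fitness(smf1, smf2)
    observed = float(pairs.mean())
    d = None
    if len(singles1) >= 2 and len(singles2) >= 2 and len(pairs) >= 2:
        try:
            d = cohens_d(
                GroupStats.from_values(singles1),
                GroupStats.from_values(singles2),
                GroupStats.from_values(pairs),
            )
        except GIError:
            d = None  # zero-spread groups: effect size undefined
    return GIResult(
        genes=(gene1, gene2),
        smf={gene1: smf1, gene2: smf2},
        expected_dmf=expected,
        observed_dmf=observed,
        dlfc=delta_lfc(observed, expected),
        cohens_d=d,
    )


def score_set(constructs: pd.DataFrame, genes: Sequence[str],
              set_col: str = "target_set") -> GIResult:
    """dLFC for a triple or quad (threshold-mode only, no Cohen's D).

    Expected fitness is the sum of member SMFs; observed is the mean fold
    change of rows whose ``target_set`` equals the full gene set.
    """
    genes = tuple(genes)
    key = "|".join(sorted(genes))
    obs_rows = constructs[
        constructs.get(set_col, pd.Series(index=constructs.index, dtype=object))
        .map(lambda s: "|".join(sorted(s.split("|"))) if isinstance(s, str) else None)
        == key
    ]
    if obs_rows.empty:
        raise GIError(f"no constructs targeting the full set {genes}")
    smf = {g: single_mutant_fitness(constructs, g) for g in genes}
    expected = float(sum(smf.values()))
    observed = float(obs_rows["lfc"].mean())
    return GIResult(
        genes=genes, smf=smf, expected_dmf=expected, observed_dmf=observed,
        dlfc=delta_lfc(observed, expected), cohens_d=None,
    )


def call_interactions(
    results: Iterable[GIResult],
    dlfc_sl: float = -1.0,
    d_min: float = 0.8,
    dlfc_mask: float = 1.0,
    mode: str = "pair",
) -> list[GIResult]:
    """Classify interactions with strict-inequality thresholds.

    ``pair`` mode: hit iff dLFC < dlfc_sl AND Cohen's D > d_min (both
    strict). ``threshold`` mode (any set size): synthetic_lethal iff
    dLFC < dlfc_sl, masking iff dLFC > dlfc_mask; no D requirement.
    """
    out = []
    for res in results:
        classification, hit = "none", False
        if mode == "pair":
            if res.cohens_d is None:
                raise GIError(f"pair-mode calling needs Cohen's D for {res.genes}")
            if res.dlfc < dlfc_sl and res.cohens_d > d_min:
                classification, hit = "synthetic_lethal", True
        elif mode == "threshold":
            if res.dlfc < dlfc_sl:
                classification, hit = "synthetic_lethal", True
            elif res.dlfc > dlfc_mask:
                classification, hit = "masking", True
        else:
            raise GIError(f"unknown calling mode {mode!r}")
        res.classification = classification
        res.hit = hit
        out.append(res)
    return out


def results_to_frame(results: Iterable[GIResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_record() for r in results])


# ---------------------------------------------------------------------------
# Gene-level essentiality and precision-recall
# ---------------------------------------------------------------------------


def gene_level_essentiality(
    array_lfc: pd.DataFrame,
    threshold: float = -1.0,
    target_col: str = "target",
    value_col: str = "lfc",
) -> pd.DataFrame:
    """Mean fold change per target (gene or gene set) with essential flag.

    The target mean pools all arrays and replicates; a target is essential
    iff its mean fold change is strictly below ``threshold``.
    """
    means = array_lfc.groupby(target_col)[value_col].mean()
    out = means.to_frame("mean_fc")
    out["essential"] = out["mean_fc"] < threshold
    return out.reset_index()


def precision_recall(scores: pd.Series, refs: ReferenceGeneSets) -> pd.DataFrame:
    """Precision-recall points over reference genes ranked by depletion.

    Targets are ranked ascending by fold change (most depleted first);
    precision and recall are evaluated at each rank over reference-set
    members only — targets in neither reference set are ignored.
    """
    in_ref = scores.index.isin(refs.essential) | scores.index.isin(refs.nonessential)
    ranked = scores[in_ref].sort_values(kind="mergesort")
    n_ess = int(ranked.index.isin(refs.essential).sum())
    n_non = len(ranked) - n_ess
    if n_ess == 0 or n_non == 0:
        raise GIError("need at least one essential and one nonessential reference "
                      "gene among the scored targets")
    is_ess = ranked.index.isin(refs.essential).astype(int)
    tp = np.cumsum(is_ess)
    rank = np.arange(1, len(ranked) + 1)
    return pd.DataFrame(
        {
            "target": ranked.index,
            "score": ranked.to_numpy(),
            "rank": rank,
            "recall": tp / n_ess,
            "precision": tp / rank,
        }
    )
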