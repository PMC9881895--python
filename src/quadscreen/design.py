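"""Paralog family nomination and four-guide array / oligo construction.

Candidate paralog pairs come from a BioMart-style identity table (percent
identity is reported in both directions, AB and BA, which differ when the
proteins differ in length) and a CCLE-style expression summary. The
prototype selection profile keeps pairs with mean identity in [30, 99]%,
delta identity < 10%, and both genes constitutively expressed (mean
log-expression > 2, stdev < 1.5); the relaxed profile drops the delta and
variance filters, retaining only the identity interval and the mean-
expression floor. Families of size three and four are grown with a
"difference from top paralog" rule: gene C joins A's family when the
identity drop from A's best paralog, AB - AC, is below a threshold (10%
strict, 20% relaxed), capped at four members.

Each target (single gene, pair, triple or quad) is covered by two
four-spacer arrays. Pairs reuse the same four guides in a different
order; triples and quads use disjoint guide sets across the two arrays,
with triples padded to four spacers by a filler guide (random nonessential
guide in the prototype dialect, nontargeting in the relaxed dialect).
Arrays are synthesized as a single oligo pool; :func:`assemble_oligo`
emits the bit-exact sequence for either template dialect and
:func:`parse_oligo` inverts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The three internal direct repeats, in array order (proven variants
#: chosen to minimize recombination between repeats).
INTERNAL_DRS = (
    "TAATTTCTACTATTGTAGAT",
    "AAATTTCTACTCTAGTAGAT",
    "TAATTTCTACTGTCGTAGAT",
)

#: BsmBI linker segments flanking the array body in the oligo.
FIVE_PRIME_LINKER = "cgtctcgAGAT"
THREE_PRIME_LINKER = "GAATggagacg"
POLIII_TERMINATOR = "TTTTTT"

#: (5' primer, 3' primer) per template dialect.
DIALECT_PRIMERS = {
    "prototype": ("AATGATACGGCGACCACCGA", "ATCTCGTATGCCGTCTTCTGCTTG"),
    "inzolia": ("AGGCACTTGCTCGTACGACG", "TTAAGGTGCCGGGCCCACAT"),
}

BSMBI_SITES = ("CGTCTC", "GAGACG")
SPACER_LENGTH = 20


class LibraryDesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Paralog candidate selection
# ---------------------------------------------------------------------------


def compute_identity_stats(ab: float, ba: float) -> tuple[float, float]:
    """Mean percent identity (AB+BA)/2 and delta percent identity |AB-BA|."""
    for value in (ab, ba):
        if not 0 <= value <= 100:
            raise LibraryDesignError(f"percent identity {value} outside [0, 100]")
    return (ab + ba) / 2, abs(ab - ba)


@dataclass(frozen=True)
class SelectionProfile:
    """Thresholds for one library-design generation."""

    identity_min: float = 30.0   # inclusive
    identity_max: float = 99.0   # inclusive
    delta_max: float | None = 10.0       # None disables the filter
    expression_mean_min: float = 2.0
    expression_std_max: float | None = 1.5  # None disables the filter
    family_drop_threshold: float = 10.0
    pad_pool: str = "nonessential"


PROFILES = {
    "prototype": SelectionProfile(),
    "inzolia": SelectionProfile(
        delta_max=None,
        expression_std_max=None,
        family_drop_threshold=20.0,
        pad_pool="nontargeting",
    ),
}


def select_paralog_pairs(
    candidates: pd.DataFrame,
    expression: pd.DataFrame,
    profile: str | SelectionProfile = "prototype",
) -> pd.DataFrame:
    """Apply identity and expression filters to candidate paralog pairs.

    ``candidates`` needs columns ``gene_a``, ``gene_b``, ``pct_ab``,
    ``pct_ba``; ``expression`` is indexed by gene with ``mean`` and
    ``stdev`` columns. Returns the candidates with ``mean_identity``,
    ``delta_identity``, ``accepted`` and a ``reason`` code for rejections
    (a gene missing from the expression table rejects the pair).
    """
    prof = PROFILES[profile] if isinstance(profile, str) else profile
    out = candidates.copy()
    stats = [
        compute_identity_stats(ab, ba)
        for ab, ba in zip(out["pct_ab"], out["pct_ba"])
    ]
    out["mean_identity"] = [s[0] for s in stats]
    out["delta_identity"] = [s[1] for s in stats]
    reasons = []
    for _, row in out.iterrows():
        reason = ""
        if not prof.identity_min <= row["mean_identity"] <= prof.identity_max:
            reason = "identity_out_of_range"
        elif prof.delta_max is not None and row["delta_identity"] >= prof.delta_max:
            reason = "delta_identity"
        else:
            for gene in (row["gene_a"], row["gene_b"]):
                if gene not in expression.index:
                    reason = "missing_expression"
                    break
                expr = expression.loc[gene]
                if expr["mean"] <= prof.expression_mean_min:
                    reason = "low_expression"
                    break
                if (
                    prof.expression_std_max is not None
                    and expr["stdev"] >= prof.expression_std_max
                ):
                    reason = "variable_expression"
                    break
        reasons.append(reason)
    out["reason"] = reasons
    out["accepted"] = out["reason"] == ""
    return out


def pair_identity_lookup(identity: pd.DataFrame) -> dict[frozenset, float]:
    """Symmetric gene-pair -> mean percent identity map."""
    lookup: dict[frozenset, float] = {}
    for _, row in identity.iterrows():
        mean_id, _ = compute_identity_stats(row["pct_ab"], row["pct_ba"])
        lookup[frozenset((row["gene_a"], row["gene_b"]))] = mean_id
    return lookup


def expand_families(
    genes: Sequence[str],
    identity: pd.DataFrame,
    drop_threshold: float = 10.0,
    max_family: int = 4,
) -> list[tuple[str, ...]]:
    """Grow paralog families around each anchor gene.

    For anchor A, the top paralog B maximizes sequence identity (mean
    percent identity of the pair); any other candidate C with identity
    drop AB - AC strictly below ``drop_threshold`` joins the family.
    Families are truncated to ``max_family`` members keeping the
    highest-identity companions (ties broken alphabetically so output is
    independent of input ordering), deduplicated across anchors, and
    genes with no paralog in the table are excluded.
    """
    lookup = pair_identity_lookup(identity)
    pool = set(genes)
    families: set[frozenset] = set()
    for anchor in sorted(pool):
        partners = [
            (other, ident)
            for key, ident in lookup.items()
            if anchor in key
            for other in key - {anchor}
            if other in pool
        ]
        if not partners:
            continue  # singleton: no paralog in table
        partners.sort(key=lambda t: (-t[1], t[0]))
        top_gene, top_identity = partners[0]
        members = [anchor, top_gene]
        for other, ident in partners[1:]:
            if top_identity - ident < drop_threshold:
                members.append(other)
            if len(members) == max_family:
                break
        families.add(frozenset(members))
    return sorted(tuple(sorted(f)) for f in families)


# ---------------------------------------------------------------------------
# Array construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class In4merArray:
    """One four-spacer guide array (half of a two-array target design)."""

    targets: tuple[str, ...]
    spacers: tuple[str, str, str, str]
    array_index: int  # 1 or 2
    drs: tuple[str, str, str] = INTERNAL_DRS
    pad: str = "none"  # nonessential-guide | nontargeting | none

    def __post_init__(self) -> None:
        if len(self.spacers) != 4:
            raise LibraryDesignError("an array carries exactly 4 spacers")
        n_targets = len(self.targets)
        if n_targets == 3 and self.pad == "none":
            raise LibraryDesignError("triple-target arrays need one padding slot")
        if n_targets in (1, 2, 4) and self.pad != "none":
            raise LibraryDesignError("only triple-target arrays carry padding")


def build_in4mer_arrays(
    targets: Sequence[str],
    guides: Mapping[str, Sequence[str]],
    pad_source: Sequence[str] = (),
    profile: str | SelectionProfile = "prototype",
    seed: int = 0,
) -> tuple[In4merArray, In4merArray]:
    """Two four-guide arrays for a single gene, pair, triple or quad.

    ``guides`` maps each target gene to its ranked spacer list. Layouts
    (fixed, deterministic permutations):

    * single:  [g1, g2, g3, g4] and its reverse [g4, g3, g2, g1]
    * pair:    [A1, B1, A2, B2] and [B2, A2, B1, A1] (same guides,
      different order)
    * triple:  [A1, B1, C1, pad1] and [A2, B2, C2, pad2]; pads drawn from
      ``pad_source`` (nonessential guides in the prototype profile,
      nontargeting in the relaxed profile) reproducibly under ``seed``
    * quad:    [A1, B1, C1, D1] and [A2, B2, C2, D2] (disjoint spacers)
    """
    prof = PROFILES[profile] if isinstance(profile, str) else profile
    targets = tuple(targets)
    n = len(targets)
    if not 1 <= n <= 4:
        raise LibraryDesignError(f"a target set has 1-4 genes, got {n}")
    need = {1: 4, 2: 2, 3: 2, 4: 2}[n]
    for gene in targets:
        if len(guides.get(gene, ())) < need:
            raise LibraryDesignError(
                f"gene {gene!r} needs >= {need} ranked guides for a "
                f"{n}-gene target"
            )
    pad = "none"
    if n == 1:
        g = list(guides[targets[0]][:4])
        s1, s2 = tuple(g), tuple(reversed(g))
    elif n == 2:
        a, b = targets
        s1 = (guides[a][0], guides[b][0], guides[a][1], guides[b][1])
        s2 = (guides[b][1], guides[a][1], guides[b][0], guides[a][0])
    elif n == 3:
        if len(pad_source) < 2:
            raise LibraryDesignError("triple-target arrays need >= 2 padding guides")
        rng = np.random.default_rng(seed)
        pads = rng.choice(len(pad_source), size=2, replace=False)
        pad = (
            "nontargeting" if prof.pad_pool == "nontargeting" else "nonessential-guide"
        )
        s1 = tuple(guides[g][0] for g in targets) + (pad_source[pads[0]],)
        s2 = tuple(guides[g][1] for g in targets) + (pad_source[pads[1]],)
    else:
        s1 = tuple(guides[g][0] for g in targets)
        s2 = tuple(guides[g][1] for g in targets)
    return (
        In4merArray(targets=targets, spacers=s1, array_index=1, pad=pad),
        In4merArray(targets=targets, spacers=s2, array_index=2, pad=pad),
    )


# ---------------------------------------------------------------------------
# Oligo assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OligoRecord:
    sequence: str
    dialect: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def validate_spacer(spacer: str) -> None:
    """Reject spacers that cannot be synthesized/cloned/expressed.

    A spacer must be 20 nt of ACGT, free of internal BsmBI recognition
    sites (which would be cut during golden-gate assembly) and free of
    runs of four or more T (a Pol III terminator would truncate the
    transcript before the end of the array).
    """
    if len(spacer) != SPACER_LENGTH:
        raise LibraryDesignError(
            f"spacer length {len(spacer)} != {SPACER_LENGTH}: {spacer!r}"
        )
    upper = spacer.upper()
    if set(upper) - set("ACGT"):
        raise LibraryDesignError(f"spacer has non-ACGT characters: {spacer!r}")
    for site in BSMBI_SITES:
        if site in upper:
            raise LibraryDesignError(f"spacer contains BsmBI site {site}: {spacer!r}")
    if "TTTT" in upper:
        raise LibraryDesignError(
            f"spacer contains a >= 4 nt T run (Pol III terminator): {spacer!r}"
        )


def assemble_oligo(array: In4merArray, dialect: str = "inzolia") -> OligoRecord:
    """Bit-exact synthesis oligo for an array in the given template dialect.

    Layout: 5' primer + BsmBI linker + spacer1 + DR + spacer2 + DR +
    spacer3 + DR + spacer4 + TTTTTT terminator + BsmBI linker + 3' primer.
    The relaxed-template ("inzolia") primers give a 208 nt oligo; the
    prototype's longer 3' primer gives 212 nt.
    """
    if dialect not in DIALECT_PRIMERS:
        raise LibraryDesignError(f"unknown dialect {dialect!r}")
    for spacer in array.spacers:
        validate_spacer(spacer)
    p5, p3 = DIALECT_PRIMERS[dialect]
    body = "".join(
        spacer + dr for spacer, dr in zip(array.spacers[:3], array.drs)
    ) + array.spacers[3]
    seq = p5 + FIVE_PRIME_LINKER + body + POLIII_TERMINATOR + THREE_PRIME_LINKER + p3
    return OligoRecord(sequence=seq, dialect=dialect)


def parse_oligo(sequence: str, dialect: str = "inzolia") -> tuple[str, str, str, str]:
    """Recover the four spacers from an assembled oligo (inverse of assembly)."""
    if dialect not in DIALECT_PRIMERS:
        raise LibraryDesignError(f"unknown dialect {dialect!r}")
    p5, p3 = DIALECT_PRIMERS[dialect]
    prefix = p5 + FIVE_PRIME_LINKER
    suffix = POLIII_TERMINATOR + THREE_PRIME_LINKER + p3
    if not sequence.startswith(prefix) or not sequence.endswith(suffix):
        raise LibraryDesignError("sequence does not match the dialect template flanks")
    body = sequence[len(prefix) : len(sequence) - len(suffix)]
    spacers, pos = [], 0
    for dr in INTERNAL_DRS:
        spacers.append(body[pos : pos + SPACER_LENGTH])
        pos += SPACER_LENGTH
        if body[pos : pos + len(dr)] != dr:
            raise LibraryDesignError(f"expected DR {dr} at body offset {pos}")
        pos += len(dr)
    spacers.append(body[pos:])
    if len(spacers[-1]) != SPACER_LENGTH:
        raise LibraryDesignError("trailing spacer has wrong length")
    return tuple(spacers)


def random_spacer(rng: np.random.Generator, length: int = SPACER_LENGTH) -> str:
    """A random valid spacer (rejection sampling against validate_spacer)."""
    bases = np.array(list("ACGT"))
    while True:
        spacer = "".join(rng.choice(bases, size=length))
        try:
            validate_spacer(spacer)
        except LibraryDesignError:
            continue
        return spacer


# ---------------------------------------------------------------------------
# Library composition accounting
# ---------------------------------------------------------------------------

#: Printed composition of the two library generations (target counts).
PROTOTYPE_COMPOSITION = {
    "single_genes": 19687,
    "pairs": 2082,
    "triples": 167,
    "quads": 48,
    "egfp_arrays": 4,
    "intergenic_arrays": 0,
    "nontargeting_arrays": 0,
}

INZOLIA_COMPOSITION = {
    "single_genes": 19687,
    "pairs": 4435,
    "triples": 376,
    "quads": 100,
    "egfp_arrays": 20,
    "intergenic_arrays": 500,
    "nontargeting_arrays": 50,
}


def library_size(
    composition: Mapping[str, int], arrays_per_target: int = 2
) -> int:
    """Total array count: two arrays per target plus control arrays."""
    targets = sum(
        composition.get(key, 0)
        for key in ("single_genes", "pairs", "triples", "quads")
    )
    controls = sum(
        composition.get(key, 0)
        for key in ("egfp_arrays", "intergenic_arrays", "nontargeting_arrays")
    )
    return arrays_per_target * targets + controls
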