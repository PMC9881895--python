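"""Screen data containers, readers and exact-match read counting.

The central objects are :class:`CountMatrix` (integer read counts for
constructs x samples, with per-sample metadata), :class:`LibraryAnnotation`
(which guide array targets what) and :class:`ReferenceGeneSets` (essential /
nonessential gene symbols used for screen QC).

Read counting for Cas12a guide-array amplicon sequencing is strictly
exact-match: a read is assigned to a construct only if the expected array
sequence occurs verbatim at the expected offset, anchored on a constant
vector-derived sequence so that primer stagger regions of 0-8 nt do not
break the match.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sample roles recognised in sample metadata.
SAMPLE_ROLES = ("plasmid", "T0", "endpoint")

#: Roles that may serve as the fold-change reference.
REFERENCE_ROLES = ("plasmid", "T0")

#: Construct group labels for two-slot constructs.
GROUP_GENE_N = "gene_N"
GROUP_N_GENE = "N_gene"
GROUP_A_B = "A_B"
GROUP_CONTROL = "control"

#: Leading direct repeat expressed from the vector backbone, immediately 5'
#: of the first spacer of an array (read off the custom sequencing primer).
LEADING_DR = "TAATTTCTACTCTTGTAGAT"

#: Constant vector sequence immediately 5' of the leading DR, used as the
#: anchor when matching the full array (leading DR included).
VECTOR_ANCHOR = "GACGAAACACCGG"


class ScreenDataError(ValueError):
    """Raised for malformed count tables, annotations or read libraries."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Read counts for constructs x samples plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by construct id with one column per sample id.
        Values must be finite and non-negative (integers for raw counts;
        floats after normalization).
    sample_meta
        DataFrame indexed by sample id with at least a ``role`` column
        (one of ``plasmid``, ``T0``, ``endpoint``); optional ``timepoint``,
        ``replicate`` and ``cell_line`` columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ScreenDataError(f"duplicate construct ids: {dups}")
        if "role" not in self.sample_meta.columns:
            raise ScreenDataError("sample_meta must have a 'role' column")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ScreenDataError(f"samples without metadata: {sorted(missing)}")
        bad_roles = set(self.sample_meta["role"]) - set(SAMPLE_ROLES)
        if bad_roles:
            raise ScreenDataError(
                f"unknown sample roles {sorted(bad_roles)}; expected one of {SAMPLE_ROLES}"
            )
        roles = set(self.sample_meta.loc[list(self.counts.columns), "role"])
        if not roles & set(REFERENCE_ROLES):
            raise ScreenDataError(
                "no reference-role sample (plasmid or T0) present in the screen"
            )
        values = self.counts.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ScreenDataError("counts contain non-finite values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ScreenDataError(
                f"negative count at construct {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )

    @property
    def construct_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_with_role(self, role: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["role"] == role])

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "construct_id"
        out.to_csv(path, sep="\t")


def read_count_table(path: str | Path, sample_meta: Mapping | pd.DataFrame) -> CountMatrix:
    """Read a constructs x samples TSV of integer read counts.

    The first column holds construct ids, the header row sample ids. Any
    cell that is not a non-negative integer raises :class:`ScreenDataError`
    naming the offending row and column; duplicated construct ids are
    rejected.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ScreenDataError(f"duplicate construct id {dup!r} in {path}")
    parsed = {}
    for col in raw.columns:
        vals = np.empty(len(raw), dtype=np.int64)
        for i, (construct, cell) in enumerate(raw[col].items()):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ScreenDataError(
                    f"missing count at construct {construct!r}, sample {col!r}"
                )
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ScreenDataError(
                    f"non-integer count {cell!r} at construct {construct!r}, sample {col!r}"
                ) from None
            if value < 0:
                raise ScreenDataError(
                    f"negative count {cell!r} at construct {construct!r}, sample {col!r}"
                )
            vals[i] = value
        parsed[col] = vals
    counts = pd.DataFrame(parsed, index=raw.index)
    counts.index.name = "construct_id"
    if not isinstance(sample_meta, pd.DataFrame):
        sample_meta = pd.DataFrame.from_dict(dict(sample_meta), orient="index")
    return CountMatrix(counts=counts, sample_meta=sample_meta)


# ---------------------------------------------------------------------------
# LibraryAnnotation
# ---------------------------------------------------------------------------

CONSTRUCT_CLASSES = ("single", "pair", "triple", "quad", "control")
CONTROL_TYPES = ("nonessential", "nontargeting", "intergenic", "EGFP", "none")

_CLASS_N_TARGETS = {"single": 1, "pair": 2, "triple": 3, "quad": 4, "control": 0}


@dataclass
class LibraryAnnotation:
    """Per-construct annotation: spacers, DRs, targets, class and controls.

    Backed by a DataFrame with columns ``construct_id``, ``spacers`` (tuple
    of nucleotide strings), ``drs`` (tuple of internal direct repeats, one
    fewer than spacers), ``targets`` (tuple of gene symbols; empty for pure
    controls), ``construct_class``, ``control_type`` and ``orientation``
    (``gene_N``/``N_gene``/``A_B`` for two-slot constructs, else None).
    """

    table: pd.DataFrame

    REQUIRED = (
        "construct_id",
        "spacers",
        "drs",
        "targets",
        "construct_class",
        "control_type",
        "orientation",
    )

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ScreenDataError(f"annotation missing columns: {sorted(missing)}")
        if self.table["construct_id"].duplicated().any():
            raise ScreenDataError("duplicate construct ids in annotation")
        for _, row in self.table.iterrows():
            n_sp = len(row["spacers"])
            if not 1 <= n_sp <= 7:
                raise ScreenDataError(
                    f"{row['construct_id']}: spacer count {n_sp} outside 1..7"
                )
            if len(row["drs"]) != n_sp - 1:
                raise ScreenDataError(
                    f"{row['construct_id']}: need {n_sp - 1} internal DRs, "
                    f"got {len(row['drs'])}"
                )
            cls = row["construct_class"]
            if cls not in CONSTRUCT_CLASSES:
                raise ScreenDataError(f"{row['construct_id']}: unknown class {cls!r}")
            if len(row["targets"]) != _CLASS_N_TARGETS[cls]:
                raise ScreenDataError(
                    f"{row['construct_id']}: class {cls!r} inconsistent with "
                    f"{len(row['targets'])} targets"
                )

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "LibraryAnnotation":
        rows = []
        for rec in records:
            row = dict(rec)
            row.setdefault("control_type", "none")
            row.setdefault("orientation", None)
            row["spacers"] = tuple(row["spacers"])
            row["drs"] = tuple(row.get("drs", ()))
            row["targets"] = tuple(row.get("targets", ()))
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        for col in ("spacers", "drs", "targets"):
            out[col] = out[col].map(lambda t: ";".join(t))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LibraryAnnotation":
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("spacers", "drs", "targets"):
            raw[col] = raw[col].map(lambda s: tuple(x for x in s.split(";") if x))
        raw["orientation"] = raw["orientation"].map(lambda s: s or None)
        return cls(raw)

    def array_body(self, construct_id: str) -> str:
        """Spacers interleaved with internal DRs (leading DR excluded)."""
        row = self.table.set_index("construct_id").loc[construct_id]
        return interleave(row["spacers"], row["drs"])


def interleave(spacers: Sequence[str], drs: Sequence[str]) -> str:
    """Concatenate spacer1 + DR1 + spacer2 + ... + spacerN."""
    if len(drs) != len(spacers) - 1:
        raise ScreenDataError("need exactly one internal DR between adjacent spacers")
    parts = []
    for i, sp in enumerate(spacers):
        parts.append(sp)
        if i < len(drs):
            parts.append(drs[i])
    return "".join(parts)


def classify_construct(
    slot1_gene: str | None,
    slot2_gene: str | None,
    slot1_is_control: bool,
    slot2_is_control: bool,
) -> str:
    """Group label for a two-slot construct.

    A targeting gene paired with a control guide in the second slot is
    ``gene_N``; control first is ``N_gene``; two targeting genes is ``A_B``;
    two controls is ``control``. A slot flagged control must not carry a
    target gene and vice versa (ambiguous annotation).
    """
    for slot, gene, is_ctrl in (("1", slot1_gene, slot1_is_control),
                                ("2", slot2_gene, slot2_is_control)):
        if is_ctrl and gene not in (None, ""):
            # control label strings (e.g. "nonessential") are allowed; an
            # annotated target gene on a control slot is not decidable
            if not _looks_like_control_label(gene):
                raise ScreenDataError(
                    f"slot {slot} flagged control but annotated with target {gene!r}"
                )
        if not is_ctrl and gene in (None, ""):
            raise ScreenDataError(f"slot {slot} has no target gene and is not a control")
    if slot1_is_control and slot2_is_control:
        return GROUP_CONTROL
    if slot2_is_control:
        return GROUP_GENE_N
    if slot1_is_control:
        return GROUP_N_GENE
    return GROUP_A_B


def _looks_like_control_label(label: str) -> bool:
    return label.lower() in {
        "nonessential", "non-essential", "nontargeting", "non-targeting",
        "intergenic", "egfp", "fluc", "aavs1", "control", "n",
    }


# ---------------------------------------------------------------------------
# ReferenceGeneSets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceGeneSets:
    """Reference essential and nonessential gene symbols (disjoint sets)."""

    essential: frozenset[str]
    nonessential: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "essential", frozenset(self.essential))
        object.__setattr__(self, "nonessential", frozenset(self.nonessential))
        if not self.essential or not self.nonessential:
            raise ScreenDataError("reference gene sets must be non-empty")
        overlap = self.essential & self.nonessential
        if overlap:
            raise ScreenDataError(
                f"genes in both reference sets: {sorted(overlap)[:5]}"
            )

    @classmethod
    def from_files(cls, essential_path: str | Path, nonessential_path: str | Path):
        def _load(p):
            return frozenset(
                line.strip() for line in Path(p).read_text().splitlines() if line.strip()
            )
        return cls(_load(essential_path), _load(nonessential_path))


# ---------------------------------------------------------------------------
# Exact-match read counting
# ---------------------------------------------------------------------------


@dataclass
class CountResult:
    """Exact-match counting outcome for one sample."""

    counts: pd.Series  # construct id -> reads
    unmapped: int
    total: int

    def __post_init__(self) -> None:
        assert int(self.counts.sum()) + self.unmapped == self.total


def build_match_index(
    library: LibraryAnnotation, mode: str = "array_body"
) -> dict[str, str]:
    """Map expected match sequence -> construct id.

    ``array_body`` matches the spacers-plus-internal-DRs concatenation,
    excluding the leading DR; ``full_array`` prepends the leading DR.
    Two constructs with identical match sequences are rejected.
    """
    if mode not in ("array_body", "full_array"):
        raise ScreenDataError(f"unknown counting mode {mode!r}")
    index: dict[str, str] = {}
    for _, row in library.table.iterrows():
        seq = interleave(row["spacers"], row["drs"])
        if mode == "full_array":
            seq = LEADING_DR + seq
        if seq in index:
            raise ScreenDataError(
                f"constructs {index[seq]!r} and {row['construct_id']!r} share "
                "an identical match sequence"
            )
        index[seq] = row["construct_id"]
    return index


def count_reads_exact(
    reads: Iterable[str],
    library: LibraryAnnotation,
    mode: str = "array_body",
    anchor: str | None = None,
) -> CountResult:
    """Assign reads to constructs by exact sequence match.

    The constant ``anchor`` (leading DR for ``array_body``, the
    vector-derived segment just 5' of it for ``full_array``) is located in
    each read; the fixed-length slice immediately following it is compared
    against the library index. Reads are used in sequencing orientation
    only. Each read increments at most one construct; everything else is
    tallied as unmapped.
    """
    index = build_match_index(library, mode=mode)
    if anchor is None:
        anchor = LEADING_DR if mode == "array_body" else VECTOR_ANCHOR
    lengths = sorted({len(seq) for seq in index}, reverse=True)
    counts = {cid: 0 for cid in library.table["construct_id"]}
    unmapped = 0
    total = 0
    a_len = len(anchor)
    for read in reads:
        total += 1
        pos = read.find(anchor)
        hit = None
        if pos >= 0:
            start = pos + a_len
            for L in lengths:
                candidate = read[start : start + L]
                if len(candidate) == L and candidate in index:
                    hit = index[candidate]
                    break
        if hit is None:
            unmapped += 1
        else:
            counts[hit] += 1
    series = pd.Series(counts, name="reads")
    series.index.name = "construct_id"
    return CountResult(counts=series, unmapped=unmapped, total=total)


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip transparent)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield str(record.seq)
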