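"""Ortholog filtering, MSA information content and conserved-region calls.

The sequence side of the pipeline starts from two precomputed inputs: a
BLAST tabular hit file (outfmt 6, optionally with qlen/slen columns) used
to select ortholog candidates, and per-group pre-aligned FASTA alignments
of the PsaL subunit (groups such as trimeric / far-red / tetrameric /
marine photosystem I formers).

Per-column conservation is the sequence-logo information content

    R_i = log2(20) − H_i − e_n,   H_i = −Σ_a p_a·log2(p_a),

with probabilities renormalized over the 20 amino acids (gaps and X are
excluded and reported as a separate gap fraction) and the small-sample
correction e_n = 19/(2·ln2·n) applied by default.  Conserved regions are
maximal runs of consecutive high-information, low-gap columns; naming
(e.g. CR-I…CR-V) is positional from a user-supplied list since region
identity is a labelling convention, not something derivable from one
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "BlastHit",
    "GroupMSA",
    "ConservationProfile",
    "CRSegment",
    "AMINO_ACIDS",
    "MAX_BITS",
    "read_blast_table",
    "filter_orthologs",
    "length_filter",
    "read_group_msa",
    "conservation_profile",
    "detect_conserved_regions",
    "compare_groups",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: Maximum information content of a 20-letter column, bits.
MAX_BITS = float(np.log2(20))


@dataclass
class BlastHit:
    """One row of a BLAST tabular (outfmt 6) hit file."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_length: int | None = None
    subject_length: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")

    @property
    def coverage(self) -> float | None:
        """Alignment length as a percentage of the query length."""
        if self.query_length is None or self.query_length <= 0:
            return None
        return 100.0 * self.alignment_length / self.query_length


def read_blast_table(path: str | Path, query_lengths: Mapping[str, int] | None = None) -> list[BlastHit]:
    """Parse a BLAST outfmt-6 TSV (12 standard columns, or 14 with qlen/slen).

    Malformed rows are skipped with a warning naming the row number.
    Query lengths for coverage can come from the 13th column or from
    ``query_lengths``.
    """
    hits: list[BlastHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        try:
            if len(parts) < 12:
                raise ValueError(f"{len(parts)} columns, expected >= 12")
            qlen = int(parts[12]) if len(parts) > 12 else None
            slen = int(parts[13]) if len(parts) > 13 else None
            if qlen is None and query_lengths is not None:
                qlen = query_lengths.get(parts[0])
            hits.append(
                BlastHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                    query_length=qlen,
                    subject_length=slen,
                )
            )
        except (ValueError, IndexError) as exc:
            warnings.warn(f"{path}:{lineno}: skipping malformed row ({exc})", stacklevel=2)
    return hits


def filter_orthologs(
    hits: Iterable[BlastHit],
    min_identity: float = 40.0,
    min_coverage: float = 35.0,
    max_evalue: float = 1e-10,
) -> list[BlastHit]:
    """Keep hits with identity ≥ min, coverage ≥ min and e-value ≤ max.

    Boundary values pass (the operators are inclusive).  Hits without a
    computable coverage are dropped.
    """
    kept = []
    for h in hits:
        cov = h.coverage
        if cov is None:
            continue
        if h.percent_identity >= min_identity and cov >= min_coverage and h.evalue <= max_evalue:
            kept.append(h)
    return kept


def length_filter(
    sequences: Sequence,
    min_length: int = 180,
    exempt_ids: Iterable[str] = (),
) -> list:
    """Drop sequences with ungapped length < min_length unless exempt.

    ``sequences`` are Bio.SeqRecord objects (possibly gapped); anchors
    named in ``exempt_ids`` are always kept.
    """
    exempt = set(exempt_ids)
    kept = []
    for rec in sequences:
        ungapped = len(str(rec.seq).replace("-", "").replace(".", ""))
        if ungapped >= min_length or rec.id in exempt:
            kept.append(rec)
    return kept


@dataclass
class GroupMSA:
    """A pre-aligned group of sequences (equal-length rows, '-' gaps)."""

    group: str
    ids: list[str]
    rows: list[str]
    anchor_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_group_msa(path: str | Path, group: str, anchor_ids: Iterable[str] = ()) -> GroupMSA:
    """Read an aligned FASTA file into a :class:`GroupMSA`."""
    aln = AlignIO.read(str(path), "fasta")
    return GroupMSA(
        group=group,
        ids=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
        anchor_ids=list(anchor_ids),
    )


@dataclass
class ConservationProfile:
    """Per-column information content of a group alignment."""

    group: str
    bits: np.ndarray  # R_i per column
    letter_heights: np.ndarray  # (n_columns, 20), p_a * R_i
    gap_fraction: np.ndarray
    all_gap: np.ndarray  # flag per column
    n_sequences: int
    small_sample_correction: bool

    @property
    def n_columns(self) -> int:
        return len(self.bits)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.letter_heights, columns=list(AMINO_ACIDS))
        df.insert(0, "column", np.arange(1, self.n_columns + 1))
        df.insert(1, "bits", self.bits)
        df.insert(2, "gap_frac", self.gap_fraction)
        return df


def conservation_profile(msa: GroupMSA, correction: bool = True) -> ConservationProfile:
    """Information content R_i = log2(20) − H_i − e_n per alignment column.

    Probabilities are renormalized over the 20 amino acids; gaps ('-', '.')
    and 'X' contribute to the gap fraction only.  The small-sample
    correction e_n = 19/(2·ln2·n) uses the number of residues observed in
    the column and is clamped so R_i ≥ 0.  All-gap columns get R_i = 0 and
    are flagged.
    """
    if msa.n_sequences < 2:
        raise ValueError("conservation profile requires at least 2 sequences")
    n_cols = msa.n_columns
    n_rows = msa.n_sequences
    counts = np.zeros((n_cols, len(AMINO_ACIDS)))
    gaps = np.zeros(n_cols)
    for row in msa.rows:
        for c, letter in enumerate(row):
            idx = _AA_INDEX.get(letter)
            if idx is None:
                gaps[c] += 1
            else:
                counts[c, idx] += 1

    n_obs = counts.sum(axis=1)
    bits = np.zeros(n_cols)
    heights = np.zeros_like(counts)
    all_gap = n_obs == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_obs[:, None] > 0, counts / np.maximum(n_obs, 1)[:, None], 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    r = MAX_BITS - entropy
    if correction:
        with np.errstate(divide="ignore"):
            e_n = np.where(n_obs > 0, 19.0 / (2.0 * np.log(2.0) * np.maximum(n_obs, 1)), 0.0)
        r = r - e_n
    r = np.clip(r, 0.0, None)
    bits = np.where(all_gap, 0.0, r)
    heights = p * bits[:, None]
    return ConservationProfile(
        group=msa.group,
        bits=bits,
        letter_heights=heights,
        gap_fraction=gaps / n_rows,
        all_gap=all_gap,
        n_sequences=n_rows,
        small_sample_correction=correction,
    )


@dataclass
class CRSegment:
    """A maximal run of conserved alignment columns."""

    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    mean_bits: float
    group: str
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")

    @property
    def n_columns(self) -> int:
        return self.end - self.start + 1


def detect_conserved_regions(
    profile: ConservationProfile,
    min_bits: float = 2.0,
    min_run: int = 3,
    max_gap_frac: float = 0.5,
    names: Sequence[str] | None = None,
) -> list[CRSegment]:
    """Maximal runs of ≥ min_run columns with R_i ≥ min_bits and low gaps.

    Segments come back ordered by start column; ``names`` (e.g.
    ``["CR-I", "CR-II", ...]``) are assigned positionally and any surplus
    segments stay unnamed.
    """
    if profile.n_columns == 0:
        raise ValueError("profile is empty")
    eligible = (profile.bits >= min_bits) & (profile.gap_fraction <= max_gap_frac)
    segments: list[CRSegment] = []
    start = None
    for i, ok in enumerate(list(eligible) + [False]):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_run:
                segments.append(
                    CRSegment(
                        start=start + 1,
                        end=i,
                        mean_bits=float(profile.bits[start:i].mean()),
                        group=profile.group,
                    )
                )
            start = None
    if names:
        for seg, name in zip(segments, names):
            seg.label = name
    return segments


def compare_groups(
    segments_by_group: Mapping[str, Sequence[CRSegment]],
) -> pd.DataFrame:
    """Presence/absence of named conserved regions across groups.

    Returns a DataFrame indexed by region label with one boolean column
    ``<group>`` and one ``<group>_mean_bits`` column per group; unlabeled
    segments are ignored with a warning.
    """
    labels: list[str] = []
    for group, segs in segments_by_group.items():
        for seg in segs:
            if seg.label is None:
                warnings.warn(f"unlabeled segment {seg.start}-{seg.end} in group {group!r} ignored", stacklevel=2)
            elif seg.label not in labels:
                labels.append(seg.label)
    data: dict[str, list] = {}
    for group, segs in segments_by_group.items():
        named = {s.label: s for s in segs if s.label is not None}
        data[group] = [lab in named for lab in labels]
        data[f"{group}_mean_bits"] = [named[lab].mean_bits if lab in named else np.nan for lab in labels]
    return pd.DataFrame(data, index=pd.Index(labels, name="region"))
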