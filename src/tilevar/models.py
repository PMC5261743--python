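"""Core domain types shared across the pipeline.

The types mirror the objects a tiling-mutagenesis experiment produces:
designed guides (:class:`SgRNA`), the pooled-screen count matrix
(:class:`CountMatrix`), amplicon configuration (:class:`AmpliconConfig`),
alignment results and parsed events, and the simulator configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

VALID_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_dna(seq: str, what: str) -> None:
    if not seq or set(seq) - VALID_BASES:
        raise ValidationError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene on a genomic segment: exons (CDS intervals) plus flanking intron.

    ``cds_intervals`` are half-open 0-based intervals on ``sequence`` in
    translation order; their concatenation is the CDS and must be a whole
    number of codons. ``intron_margin`` is how far into introns guide cut
    sites are still accepted.
    """

    name: str
    sequence: str
    cds_intervals: tuple[tuple[int, int], ...]
    intron_margin: int = 10

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"GeneModel({self.name}) sequence")
        if self.intron_margin < 0:
            raise ValidationError("intron_margin must be >= 0")
        ivs = tuple((int(a), int(b)) for a, b in self.cds_intervals)
        object.__setattr__(self, "cds_intervals", ivs)
        prev_end = 0
        for a, b in ivs:
            if not (0 <= a < b <= len(self.sequence)):
                raise ValidationError(f"CDS interval ({a},{b}) out of bounds")
            if a < prev_end:
                raise ValidationError("CDS intervals must be sorted and non-overlapping")
            prev_end = b
        if self.cds_length % 3 != 0:
            raise ValidationError("total CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds_intervals)

    @property
    def cds_sequence(self) -> str:
        return "".join(self.sequence[a:b] for a, b in self.cds_intervals)

    def coding_positions(self) -> list[int]:
        """Genomic (top-strand) positions of CDS bases, in translation order."""
        out: list[int] = []
        for a, b in self.cds_intervals:
            out.extend(range(a, b))
        return out


@dataclass(frozen=True)
class SgRNA:
    """A single guide: 20-nt spacer next to an NGG PAM, or a non-targeting control.

    ``cut_pos`` is the top-strand 0-based index of the base immediately 5' of
    the blunt Cas9 cut (the cut falls between ``cut_pos`` and ``cut_pos + 1``),
    for guides on either strand.
    """

    spacer: str
    pam: Optional[str] = None
    strand: Optional[str] = None
    cut_pos: Optional[int] = None
    target_codon: Optional[int] = None
    target_aa: Optional[str] = None
    is_control: bool = False
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        _check_dna(self.spacer, "spacer")
        if len(self.spacer) != 20:
            raise ValidationError(f"spacer must be 20 nt, got {len(self.spacer)}")
        if self.is_control:
            if self.cut_pos is not None or self.target_codon is not None:
                raise ValidationError("controls carry no cut position or codon")
        else:
            if self.pam is None or len(self.pam) != 3 or self.pam[1:] != "GG":
                raise ValidationError(f"targeting guide needs an NGG PAM, got {self.pam!r}")
            if self.strand not in ("+", "-"):
                raise ValidationError("strand must be '+' or '-'")

    def with_target(self, codon: Optional[int], aa: Optional[str]) -> "SgRNA":
        return replace(self, target_codon=codon, target_aa=aa)


@dataclass
class LibraryTable:
    """The pooled library: targeting guides plus non-targeting controls."""

    members: list[SgRNA]
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        spacers = [g.spacer for g in self.members]
        if len(set(spacers)) != len(spacers):
            dupes = sorted({s for s in spacers if spacers.count(s) > 1})
            raise ValidationError(f"duplicate spacers in library: {dupes[:3]}")

    @property
    def n_controls(self) -> int:
        return sum(g.is_control for g in self.members)

    def ids(self) -> list[str]:
        out = []
        t = c = 0
        for g in self.members:
            if g.is_control:
                c += 1
                out.append(f"control_{c:04d}")
            else:
                t += 1
                tag = f"{g.gene}_" if g.gene else ""
                out.append(f"{tag}sg{t:04d}")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, g in zip(self.ids(), self.members):
            rows.append(
                dict(
                    sgRNA_id=gid,
                    gene=g.gene or "",
                    spacer=g.spacer,
                    pam=g.pam or "",
                    strand=g.strand or "",
                    cut_pos=-1 if g.cut_pos is None else g.cut_pos,
                    target_codon=0 if g.target_codon is None else g.target_codon,
                    target_aa=g.target_aa or "",
                    is_control=g.is_control,
                )
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionsTable:
    """Sample sheet: equal-length barcodes mapping to sample names."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("conditions table is empty")
        lengths = {len(b) for b in self.entries}
        if len(lengths) != 1:
            raise ValidationError("barcodes must all have the same length")
        if len(set(self.entries.values())) != len(self.entries):
            raise ValidationError("sample names must be unique")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries)))

    @property
    def samples(self) -> list[str]:
        return list(self.entries.values())


@dataclass
class CountMatrix:
    """sgRNA-by-condition matrix with a named layer (raw/rpm/lognorm/lfc)."""

    data: pd.DataFrame  # rows: sgRNA ids, cols: sample names
    layer: str = "raw"
    discards: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer == "raw":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValidationError("raw counts must be >= 0")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class AmpliconConfig:
    """One amplicon target: 10-nt anchor, fixed analysis window, cut site.

    ``cut_offset`` is 1-based: the Cas9 cut falls between window positions
    ``cut_offset`` and ``cut_offset + 1`` (28 for the MEK1-style window).
    """

    name: str
    anchor: str
    reference_window: str
    cut_offset: int
    frame_offset: int = 0  # reading-frame phase of window position 1

    def __post_init__(self) -> None:
        _check_dna(self.anchor, "anchor")
        _check_dna(self.reference_window, "reference_window")
        if len(self.anchor) != 10:
            raise ValidationError("anchor must be exactly 10 nt")
        if not 1 <= self.cut_offset < len(self.reference_window):
            raise ValidationError("cut_offset must fall inside the window")
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError("frame_offset must be 0, 1 or 2")

    @property
    def window_len(self) -> int:
        return len(self.reference_window)


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap nucleotide scoring; a gap of length L costs open + L * extend."""

    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open_cost: int = 5
    gap_extend_cost: int = 2
    word_size: int = 11  # seed length; only used when seeded alignment is enabled

    def gap_cost(self, length: int) -> int:
        return self.gap_open_cost + length * self.gap_extend_cost


@dataclass(frozen=True)
class AlignmentResult:
    """Local alignment of a variant window to the reference window."""

    score: int
    btop: str
    query_span: tuple[int, int]  # 1-based inclusive on the variant
    ref_span: tuple[int, int]  # 1-based inclusive on the reference window
    full_length: bool
    columns: int  # btop columns plus reported terminal indel columns


@dataclass
class VariantEvents:
    """Parsed differences vs the reference window (1-based reference coords)."""

    mismatches: list[tuple[int, str, str]] = field(default_factory=list)  # (pos, ref, alt)
    insertions: list[tuple[int, str]] = field(default_factory=list)  # (pos of first inserted, seq)
    deletions: list[tuple[int, int]] = field(default_factory=list)  # (pos of first deleted, len)

    @property
    def net_length_change(self) -> int:
        return sum(len(s) for _, s in self.insertions) - sum(n for _, n in self.deletions)

    @property
    def category(self) -> str:
        has_mm = bool(self.mismatches)
        has_ins = bool(self.insertions)
        has_del = bool(self.deletions)
        n_kinds = has_mm + has_ins + has_del
        if n_kinds == 0:
            return "wild_type"
        if n_kinds > 1:
            return "complex"
        if has_mm:
            return "mismatch_only"
        if has_del:
            return "deletion_only"
        return "insertion_only"


@dataclass(frozen=True)
class ProteinCall:
    """Translation of a variant window in the inherited reading frame."""

    aa_seq: Optional[str]
    frameshift: bool
    stop_gained: bool


@dataclass(frozen=True)
class NhejSimConfig:
    """Parameters of the synthetic NHEJ allele-population generator.

    One repair outcome is drawn per editing event: a deletion, insertion or
    substitution, sized by truncated geometric distributions and positioned
    with Gaussian jitter around the cut site.
    """

    cfg: AmpliconConfig
    edit_fraction: float = 0.62
    p_deletion: float = 0.6
    p_insertion: float = 0.3
    p_substitution: float = 0.1
    p_del_size: float = 0.2
    min_del: int = 1
    max_del: int = 12
    p_ins_size: float = 0.5
    min_ins: int = 1
    max_ins: int = 8
    position_jitter_sd: float = 2.0
    seq_error_rate: float = 1e-3
    depth: int = 100_000
    n_edit_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p_deletion, self.p_insertion, self.p_substitution)
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("event-type probabilities must lie in [0,1] and sum to 1")
        if not 0.0 <= self.edit_fraction <= 1.0:
            raise ValidationError("edit_fraction must lie in [0,1]")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if not 1 <= self.min_del <= self.max_del or not 1 <= self.min_ins <= self.max_ins:
            raise ValidationError("indel size bounds must satisfy 1 <= min <= max")


@dataclass(frozen=True)
class SelectionSimConfig:
    """Multiplicative fitness selection over a number of doublings."""

    fitness: dict[str, float] = field(default_factory=dict)  # allele -> relative growth rate
    generations: int = 7
    bottleneck: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if any(w <= 0 for w in self.fitness.values()):
            raise ValidationError("fitness values must be > 0")
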