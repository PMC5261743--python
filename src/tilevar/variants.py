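"""Variant classification, indel spectra, and window translation.

Aligned variants fall into wild_type or one of four non-wild-type classes
(mismatch_only, deletion_only, insertion_only, complex). Indel spectra are
histograms over unique variants keyed by first-deleted/first-inserted
position and by event size. Translation inherits the reference window's
reading frame; a net length change that is not a multiple of 3 is a
frameshift.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .align import align_and_annotate
from .models import (
    AlignmentResult,
    AmpliconConfig,
    ProteinCall,
    ScoringScheme,
    VariantEvents,
)

CATEGORIES = ("wild_type", "mismatch_only", "deletion_only", "insertion_only", "complex")


def classify_variant(ev: VariantEvents) -> str:
    """One of the five categories; wild_type means no events at all."""
    return ev.category


def full_length_filter(
    results: list[AlignmentResult], cfg: AmpliconConfig
) -> list[AlignmentResult]:
    """Keep alignments spanning the full window (all columns, gaps included)."""
    return [r for r in results if r.full_length]


@dataclass
class IndelSpectra:
    """Histograms over unique variants, deletions and insertions separately."""

    deletion_positions: pd.Series
    deletion_sizes: pd.Series
    insertion_positions: pd.Series
    insertion_sizes: pd.Series


def indel_spectra(events: list[VariantEvents]) -> IndelSpectra:
    """Position and size histograms of indel events across unique variants.

    Counts are per unique variant (not read-weighted); a variant carrying two
    deletions contributes two deletion events.
    """
    del_pos: list[int] = []
    del_size: list[int] = []
    ins_pos: list[int] = []
    ins_size: list[int] = []
    for ev in events:
        for pos, length in ev.deletions:
            del_pos.append(pos)
            del_size.append(length)
        for pos, seq in ev.insertions:
            ins_pos.append(pos)
            ins_size.append(len(seq))

    def hist(values: list[int]) -> pd.Series:
        return pd.Series(values, dtype=int).value_counts().sort_index()

    return IndelSpectra(
        deletion_positions=hist(del_pos),
        deletion_sizes=hist(del_size),
        insertion_positions=hist(ins_pos),
        insertion_sizes=hist(ins_size),
    )


def translate_window(
    variant: str,
    ev: VariantEvents,
    cfg: AmpliconConfig,
    frame_offset: int | None = None,
) -> ProteinCall:
    """Translate a variant window in the frame inherited from the reference.

    ``frame_offset`` is the reading-frame phase of window position 1 (0 means
    position 1 starts a codon); defaults to the amplicon config's value. The
    trailing partial codon is dropped. ``stop_gained`` flags a stop codon
    anywhere in the translated window.
    """
    phase = cfg.frame_offset if frame_offset is None else frame_offset
    start = (3 - phase) % 3
    coding = variant[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate()) if coding else ""
    return ProteinCall(
        aa_seq=aa or None,
        frameshift=ev.net_length_change % 3 != 0,
        stop_gained="*" in aa,
    )


def annotate_variant_table(
    table: pd.DataFrame,
    cfg: AmpliconConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> pd.DataFrame:
    """Align, classify and translate every sequence of a variant table.

    Adds score, btop, full_length, category, event counts, net length change
    and the translated amino-acid sequence to the (sequence, reads, rpm) rows.
    """
    rows = []
    cache: dict[str, tuple] = {}
    for seq in table["sequence"]:
        if seq not in cache:
            res, ev = align_and_annotate(seq, cfg, scheme)
            prot = translate_window(seq, ev, cfg)
            cache[seq] = (res, ev, prot)
        res, ev, prot = cache[seq]
        rows.append(
            dict(
                score=res.score,
                btop=res.btop,
                columns=res.columns,
                full_length=res.full_length,
                category=ev.category,
                n_mismatch=len(ev.mismatches),
                n_ins=len(ev.insertions),
                n_del=len(ev.deletions),
                net_length_change=ev.net_length_change,
                aa_seq=prot.aa_seq or "",
                frameshift=prot.frameshift,
                stop_gained=prot.stop_gained,
            )
        )
    out = pd.concat([table.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    out.attrs = dict(table.attrs)
    return out
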