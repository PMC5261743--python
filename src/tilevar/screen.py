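"""Pooled tiling-screen deconvolution and enrichment statistics.

Reads are assigned to samples by an exact barcode at the read start and to
guides by the 20 nt that follow the first ``CACCG`` occurrence (the invariant
vector sequence 5' of every spacer in the construct). Counts flow through
reads-per-million (RPM), lognorm = log2(RPM + 1), and log2 fold-change against
the plasmid-DNA (pDNA) baseline; hits are guides whose replicate-averaged LFC
exceeds the non-targeting-control mean by two control standard deviations.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import ConditionsTable, CountMatrix, LibraryTable, ValidationError

logger = logging.getLogger(__name__)

SPACER_PREFIX = "CACCG"


def count_screen_reads(
    reads: Iterable[str],
    library: LibraryTable,
    conditions: ConditionsTable,
) -> CountMatrix:
    """Deconvolute raw reads into a guide-by-sample count matrix.

    Reads failing barcode, prefix, or spacer lookup are tallied by failure
    category rather than counted; assigned + discarded equals input reads.
    """
    if not library.members:
        raise ValidationError("empty library")
    ids = library.ids()
    spacer_to_id = {g.spacer: gid for gid, g in zip(ids, library.members)}
    blen = conditions.barcode_length
    samples = conditions.samples
    counts = {s: dict.fromkeys(ids, 0) for s in samples}
    discards = {"no_barcode": 0, "no_prefix": 0, "no_spacer": 0, "too_short": 0}
    for read in reads:
        sample = conditions.entries.get(read[:blen])
        if sample is None:
            discards["no_barcode"] += 1
            continue
        hit = read.find(SPACER_PREFIX)
        if hit < 0:
            discards["no_prefix"] += 1
            continue
        start = hit + len(SPACER_PREFIX)
        spacer = read[start : start + 20]
        if len(spacer) < 20:
            discards["too_short"] += 1
            continue
        gid = spacer_to_id.get(spacer)
        if gid is None:
            discards["no_spacer"] += 1
            continue
        counts[sample][gid] += 1
    data = pd.DataFrame({s: pd.Series(counts[s]) for s in samples}).loc[ids]
    logger.info("screen deconvolution discards: %s", discards)
    return CountMatrix(data=data, layer="raw", discards=discards)


def rpm_normalize(m: CountMatrix) -> CountMatrix:
    """Scale each sample column to sum to one million reads."""
    totals = m.data.sum(axis=0)
    zero_cols = totals[totals == 0].index.tolist()
    if zero_cols:
        logger.warning("columns with zero total reads left at zero: %s", zero_cols)
    safe = totals.replace(0, 1)
    data = m.data.astype(float).div(safe, axis=1) * 1e6
    return CountMatrix(data=data, layer="rpm", discards=dict(m.discards))


def lognorm(m: CountMatrix) -> CountMatrix:
    """log2(RPM + 1); the +1 pseudocount removes zeros before the log."""
    if m.layer != "rpm":
        raise ValidationError(f"lognorm expects the rpm layer, got {m.layer!r}")
    return CountMatrix(data=np.log2(m.data + 1.0), layer="lognorm", discards=dict(m.discards))


def lfc_vs_pdna(m: CountMatrix, pdna_col: str) -> CountMatrix:
    """Per-guide log2 fold-change of every sample against the pDNA baseline."""
    if m.layer != "lognorm":
        raise ValidationError(f"lfc expects the lognorm layer, got {m.layer!r}")
    if pdna_col not in m.data.columns:
        raise ValidationError(f"pDNA column {pdna_col!r} not present")
    base = m.data[pdna_col]
    data = m.data.drop(columns=[pdna_col]).sub(base, axis=0)
    return CountMatrix(data=data, layer="lfc", discards=dict(m.discards))


def call_hits(
    lfc: CountMatrix,
    library: LibraryTable,
    replicates: list[str],
    sd_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Flag guides whose replicate-mean LFC exceeds the control null band.

    Threshold = mean(control LFC) + ``sd_multiplier`` * sample SD (n-1) of the
    control LFCs; a guide is a hit when its mean LFC is strictly above it.
    """
    if lfc.layer != "lfc":
        raise ValidationError(f"call_hits expects the lfc layer, got {lfc.layer!r}")
    missing = [r for r in replicates if r not in lfc.data.columns]
    if missing:
        raise ValidationError(f"replicate columns missing: {missing}")
    ids = library.ids()
    control_ids = [gid for gid, g in zip(ids, library.members) if g.is_control]
    if len(control_ids) < 2:
        raise ValidationError("need >= 2 control guides to estimate the null SD")
    mean_lfc = lfc.data[replicates].mean(axis=1)
    ctrl = mean_lfc.loc[control_ids]
    threshold = float(ctrl.mean() + sd_multiplier * ctrl.std(ddof=1))
    out = pd.DataFrame(
        {
            "sgRNA_id": mean_lfc.index,
            "mean_lfc": mean_lfc.to_numpy(),
            "threshold": threshold,
            "is_hit": (mean_lfc > threshold).to_numpy(),
        }
    ).reset_index(drop=True)
    out["is_control"] = out["sgRNA_id"].isin(control_ids)
    return out


def percent_rank(rank: int, pool_size: int) -> float:
    """Rank over pool size as a percentage, half-up rounded to 2 decimals."""
    pct = Decimal(rank) / Decimal(pool_size) * 100
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def rank_and_percent_rank(
    m: CountMatrix, sample: str
) -> Mapping[str, tuple[int, float]]:
    """Competition ("min") ranks, 1 = most enriched, with percent ranks.

    Ties share the minimum rank (1,2,2,4 style); the percent rank is the rank
    divided by the pool size, as a percentage rounded half-up to 2 decimals.
    """
    if sample not in m.data.columns:
        raise ValidationError(f"sample {sample!r} not present")
    col = m.data[sample]
    ranks = col.rank(method="min", ascending=False).astype(int)
    pool = len(col)
    return {gid: (int(r), percent_rank(int(r), pool)) for gid, r in ranks.items()}
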