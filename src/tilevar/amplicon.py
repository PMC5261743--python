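"""Amplicon deep-sequencing quantification.

Each read is screened for an exact 10-nt anchor (the genomic sequence
immediately downstream of the primer binding site); the fixed-length window
that follows the anchor is the analyzed allele sequence. Unique windows are
counted and RPM-normalized per sample, low-abundance sequences are removed
with the >= 25 RPM filter, and selected-vs-unselected enrichment is a
pseudocounted RPM ratio.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .models import AmpliconConfig, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_RPM = 25.0
DEFAULT_PSEUDOCOUNT = 1.0

VARIANT_COLUMNS = ["sequence", "reads", "rpm"]


def _as_variant_table(counts: dict[str, int], tallies: dict[str, int]) -> pd.DataFrame:
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    t = pd.DataFrame(rows, columns=["sequence", "reads"])
    t["rpm"] = t["reads"] / total * 1e6 if total else 0.0
    t.attrs["tallies"] = dict(tallies)
    t.attrs["total_reads"] = total
    return t


def extract_windows(reads: Iterable[str], cfg: AmpliconConfig) -> pd.DataFrame:
    """Count unique window sequences among anchored, full-length reads.

    The window is the ``window_len`` nucleotides immediately after the first
    exact anchor occurrence. Reads without the anchor, or too short to supply
    a full window, are tallied (``no_anchor`` / ``too_short``) and dropped.
    """
    counts: dict[str, int] = {}
    tallies = {"retained": 0, "no_anchor": 0, "too_short": 0}
    wlen = cfg.window_len
    anchor = cfg.anchor
    alen = len(anchor)
    for read in reads:
        hit = read.find(anchor)
        if hit < 0:
            tallies["no_anchor"] += 1
            continue
        start = hit + alen
        window = read[start : start + wlen]
        if len(window) < wlen:
            tallies["too_short"] += 1
            continue
        counts[window] = counts.get(window, 0) + 1
        tallies["retained"] += 1
    return _as_variant_table(counts, tallies)


def filter_min_rpm(table: pd.DataFrame, min_rpm: float = DEFAULT_MIN_RPM) -> pd.DataFrame:
    """Keep rows at or above ``min_rpm``; RPM values are not recomputed."""
    out = table[table["rpm"] >= min_rpm].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def compare_conditions(
    unselected: pd.DataFrame,
    selected: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fold change of every sequence between two RPM-normalized samples.

    The union of sequences is taken (absent sequence -> 0 RPM), the fold
    change is (selected + pc) / (unselected + pc) with a symmetric
    pseudocount, and rows are ranked by abundance in the selected sample.
    """
    u = unselected[["sequence", "rpm"]].rename(columns={"rpm": "rpm_unselected"})
    s = selected[["sequence", "rpm"]].rename(columns={"rpm": "rpm_selected"})
    merged = u.merge(s, on="sequence", how="outer").fillna(0.0)
    merged["fold_change"] = (merged["rpm_selected"] + pseudocount) / (
        merged["rpm_unselected"] + pseudocount
    )
    merged = merged.sort_values(
        ["rpm_selected", "sequence"], ascending=[False, True]
    ).reset_index(drop=True)
    merged["rank_selected"] = range(1, len(merged) + 1)
    return merged


def wildtype_fraction(table: pd.DataFrame, cfg: AmpliconConfig) -> float:
    """Fraction of retained reads matching the reference window exactly."""
    total = int(table["reads"].sum())
    if total == 0:
        logger.warning("empty variant table; wild-type fraction reported as 0")
        return 0.0
    wt = table.loc[table["sequence"] == cfg.reference_window, "reads"].sum()
    return float(wt) / total
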