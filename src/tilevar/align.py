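"""Affine-gap local alignment of variant windows with btop traceback encoding.

The aligner is a Gotoh-style Smith-Waterman dynamic program under the
screen's nucleotide costs (match +2, mismatch -3, gap of length L costing
5 + 2L). Alignments are serialized as btop (BLAST traceback operations)
strings: decimal match-run lengths, mismatches as query-then-reference base
pairs, insertions as base+'-', deletions as '-'+base.

Because the amplicon extractor returns a fixed-length window, a net indel
shifts flanking sequence into or out of view; event extraction therefore
reports unaligned terminal reference/query bases as terminal deletions/
insertions, except for the expected viewport-shift stub at the window end
(see :func:`variant_events`).
"""

from __future__ import annotations

from .models import (
    AlignmentResult,
    AmpliconConfig,
    ScoringScheme,
    ValidationError,
    VariantEvents,
    VALID_BASES,
)

_GAP = "-"

# traceback codes
_STOP, _FROM_M, _FROM_D, _FROM_I = 0, 1, 2, 3


def align_to_reference(
    variant: str,
    cfg: AmpliconConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> AlignmentResult:
    """Optimal local alignment of ``variant`` against ``cfg.reference_window``.

    Deterministic tie-breaking: on equal scores the traceback prefers an
    aligned column over a gap (so mismatches beat gaps), prefers extending an
    open gap over opening a new one (fewer gap openings), and the first
    maximal cell in query-major order is the endpoint; together these place
    co-optimal gaps leftmost on the reference.
    """
    if not variant or set(variant) - VALID_BASES:
        raise ValidationError(f"variant must be a non-empty A/C/G/T string, got {variant!r}")
    q, r = variant, cfg.reference_window
    n, m = len(q), len(r)
    ma, mi = scheme.match_reward, scheme.mismatch_penalty
    go = scheme.gap_open_cost + scheme.gap_extend_cost  # first gap column
    ge = scheme.gap_extend_cost
    NEG = -(10**9)

    # row-rolling score arrays; full pointer matrices for traceback
    M_prev = [0] * (m + 1)
    D_prev = [NEG] * (m + 1)
    I_prev = [NEG] * (m + 1)
    ptrM = [[_STOP] * (m + 1) for _ in range(n + 1)]
    ptrD = [[_FROM_M] * (m + 1) for _ in range(n + 1)]
    ptrI = [[_FROM_M] * (m + 1) for _ in range(n + 1)]

    best, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        M_cur = [NEG] * (m + 1)
        D_cur = [NEG] * (m + 1)
        I_cur = [NEG] * (m + 1)
        pm, pd_, pi = ptrM[i], ptrD[i], ptrI[i]
        for j in range(1, m + 1):
            s = ma if qc == r[j - 1] else mi
            # aligned column: best predecessor, preferring M > D > I > fresh start
            bp, bv = _FROM_M, M_prev[j - 1]
            if D_prev[j - 1] > bv:
                bp, bv = _FROM_D, D_prev[j - 1]
            if I_prev[j - 1] > bv:
                bp, bv = _FROM_I, I_prev[j - 1]
            if bv <= 0:
                bp, bv = _STOP, 0
            M_cur[j] = bv + s
            pm[j] = bp
            # gap in query (reference base deleted): extend beats open on ties
            open_d = M_cur[j - 1] - go
            ext_d = D_cur[j - 1] - ge
            if ext_d >= open_d:
                D_cur[j], pd_[j] = ext_d, _FROM_D
            else:
                D_cur[j], pd_[j] = open_d, _FROM_M
            # gap in reference (variant base inserted)
            open_i = M_prev[j] - go
            ext_i = I_prev[j] - ge
            if ext_i >= open_i:
                I_cur[j], pi[j] = ext_i, _FROM_I
            else:
                I_cur[j], pi[j] = open_i, _FROM_M
            if M_cur[j] > best:
                best, best_i, best_j = M_cur[j], i, j
        M_prev, D_prev, I_prev = M_cur, D_cur, I_cur

    if best <= 0:
        return AlignmentResult(
            score=0, btop="", query_span=(0, 0), ref_span=(0, 0),
            full_length=(cfg.window_len == 0), columns=0,
        )

    cols: list[tuple[str, str]] = []
    i, j, state = best_i, best_j, _FROM_M
    while True:
        if state == _FROM_M:
            nxt = ptrM[i][j]
            cols.append((q[i - 1], r[j - 1]))
            i, j = i - 1, j - 1
            if nxt == _STOP:
                break
            state = nxt
        elif state == _FROM_D:
            nxt = ptrD[i][j]
            cols.append((_GAP, r[j - 1]))
            j -= 1
            state = nxt
        else:  # _FROM_I
            nxt = ptrI[i][j]
            cols.append((q[i - 1], _GAP))
            i -= 1
            state = nxt
    cols.reverse()

    res = AlignmentResult(
        score=best,
        btop=emit_btop(cols),
        query_span=(i + 1, best_i),
        ref_span=(j + 1, best_j),
        full_length=False,
        columns=len(cols),
    )
    start_del, start_ins, resid_rtail, resid_qtail = _terminal_accounting(res, n, cfg)
    columns = len(cols) + start_del + start_ins + resid_rtail
    return AlignmentResult(
        score=best,
        btop=res.btop,
        query_span=res.query_span,
        ref_span=res.ref_span,
        full_length=(columns == cfg.window_len and resid_qtail == 0),
        columns=columns,
    )


def _terminal_accounting(
    res: AlignmentResult, query_len: int, cfg: AmpliconConfig
) -> tuple[int, int, int, int]:
    """Lengths of reported terminal events: (start_del, start_ins,
    residual_end_del, residual_end_ins).

    The window-end stub whose length equals the net length change of all
    upstream events is the fixed-length window shifting its viewport, not a
    lesion, and is excluded from the residuals.
    """
    internal = parse_btop(res.btop, ref_start=res.ref_span[0])
    start_del = res.ref_span[0] - 1
    start_ins = res.query_span[0] - 1
    net = internal.net_length_change + start_ins - start_del
    rtail = cfg.window_len - res.ref_span[1]
    qtail = query_len - res.query_span[1]
    resid_rtail = max(0, rtail - max(0, net))
    resid_qtail = max(0, qtail - max(0, -net))
    return start_del, start_ins, resid_rtail, resid_qtail


def emit_btop(cols: list[tuple[str, str]]) -> str:
    """Serialize alignment columns (query_char, ref_char; '-' for gap) as btop."""
    out: list[str] = []
    run = 0
    for qc, rc in cols:
        if qc == _GAP and rc == _GAP:
            raise ValidationError("column cannot be gap/gap")
        if qc == rc and qc != _GAP:
            run += 1
            continue
        if run:
            out.append(str(run))
            run = 0
        if qc == _GAP:
            out.append(_GAP + rc)
        elif rc == _GAP:
            out.append(qc + _GAP)
        else:
            out.append(qc + rc)
    if run:
        out.append(str(run))
    return "".join(out)


def btop_columns(btop: str) -> list[tuple[str, str]]:
    """Inverse of :func:`emit_btop`; raises on malformed strings.

    Match runs expand to placeholder ('=', '=') columns.
    """
    cols: list[tuple[str, str]] = []
    i, n = 0, len(btop)
    legal = VALID_BASES | {_GAP, "N"}
    while i < n:
        c = btop[i]
        if c.isdigit():
            j = i
            while j < n and btop[j].isdigit():
                j += 1
            cols.extend([("=", "=")] * int(btop[i:j]))
            i = j
        elif c in legal:
            if i + 1 >= n or btop[i + 1] not in legal:
                raise ValidationError(f"malformed btop at offset {i}: dangling symbol {c!r}")
            if c == _GAP and btop[i + 1] == _GAP:
                raise ValidationError(f"malformed btop at offset {i}: gap/gap pair")
            cols.append((c, btop[i + 1]))
            i += 2
        else:
            raise ValidationError(f"malformed btop at offset {i}: illegal character {c!r}")
    return cols


def btop_to_cigar(btop: str) -> str:
    """CIGAR-equivalent of a btop string (M = aligned column, I/D = gaps)."""
    out: list[str] = []
    for qc, rc in btop_columns(btop):
        op = "M" if _GAP not in (qc, rc) else ("D" if qc == _GAP else "I")
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + 1, op)
        else:
            out.append((1, op))
    return "".join(f"{n}{op}" for n, op in out)


def parse_btop(btop: str, ref_start: int = 1) -> VariantEvents:
    """Parse a btop string into events, walking reference coordinates.

    ``ref_start`` is the 1-based reference position of the first alignment
    column. Mismatch positions are the mismatched reference base's position;
    indel positions follow the first-nucleotide-deleted/inserted convention.
    Adjacent gap columns of the same kind merge into a single event.
    """
    ev = VariantEvents()
    ref_pos = ref_start - 1  # last reference position consumed
    ins_pos, ins_seq = 0, []
    del_pos, del_len = 0, 0

    def flush() -> None:
        nonlocal ins_pos, ins_seq, del_pos, del_len
        if ins_seq:
            ev.insertions.append((ins_pos, "".join(ins_seq)))
            ins_pos, ins_seq = 0, []
        if del_len:
            ev.deletions.append((del_pos, del_len))
            del_pos, del_len = 0, 0

    for qc, rc in btop_columns(btop):
        if qc == "=" or (qc == rc and qc != _GAP):
            flush()
            ref_pos += 1
        elif qc == _GAP:
            if ins_seq:
                flush()
            ref_pos += 1
            if not del_len:
                del_pos = ref_pos
            del_len += 1
        elif rc == _GAP:
            if del_len:
                flush()
            if not ins_seq:
                ins_pos = ref_pos + 1
            ins_seq.append(qc)
        else:
            flush()
            ref_pos += 1
            ev.mismatches.append((ref_pos, rc, qc))
    flush()
    return ev


def variant_events(res: AlignmentResult, variant: str, cfg: AmpliconConfig) -> VariantEvents:
    """Full event summary: internal btop events plus terminal accounting.

    Unaligned reference bases at the window start are reported as a terminal
    deletion and unaligned variant bases as a terminal insertion; at the
    window end only the residual beyond the expected viewport-shift stub is
    reported (see :func:`_terminal_accounting`).
    """
    if not res.btop:
        ev = VariantEvents()
        if cfg.window_len:
            ev.deletions.append((1, cfg.window_len))
        if variant:
            ev.insertions.append((1, variant))
        return ev
    events = parse_btop(res.btop, ref_start=res.ref_span[0])
    start_del, start_ins, resid_rtail, resid_qtail = _terminal_accounting(
        res, len(variant), cfg
    )
    if start_del:
        events.deletions.insert(0, (1, start_del))
    if start_ins:
        events.insertions.insert(0, (1, variant[:start_ins]))
    r_end, q_end = res.ref_span[1], res.query_span[1]
    if resid_rtail:
        events.deletions.append((r_end + 1, resid_rtail))
    if resid_qtail:
        events.insertions.append(
            (r_end + resid_rtail + 1, variant[q_end : q_end + resid_qtail])
        )
    events.deletions.sort()
    events.insertions.sort()
    events.mismatches.sort()
    return events


def align_and_annotate(
    variant: str,
    cfg: AmpliconConfig,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[AlignmentResult, VariantEvents]:
    """Align one variant window and return the alignment plus its events."""
    res = align_to_reference(variant, cfg, scheme)
    return res, variant_events(res, variant, cfg)
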