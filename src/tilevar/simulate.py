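"""Synthetic NHEJ, sequencing, and selection data with exported truth tables.

The generator emulates the statistical structure of an amplicon deep-
sequencing experiment downstream of a Cas9 cut: a wild-type residual
fraction, edited alleles carrying a deletion, insertion or substitution
(sizes from truncated geometric distributions, positions Gaussian-jittered
around the cut), per-base sequencing substitution error, and multiplicative
fitness selection over passages. Every generator is deterministic under its
seed and emits a truth table for downstream assertions.

Indel events in truth tables are left-normalized (shifted to the smallest
reference position that yields the same allele), matching the aligner's
leftmost tie-breaking, and events are constrained to sit fully inside the
analyzed window with alignable flanks so that the fixed-length viewport can
capture the whole lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    AmpliconConfig,
    ConditionsTable,
    LibraryTable,
    NhejSimConfig,
    SelectionSimConfig,
    ValidationError,
)

# Fixed synthetic amplicon: MEK1-style 62-nt window behind a 10-nt anchor.
# Chosen once with no homopolymer >= 3, a unique anchor occurrence, no
# duplicated 8-mer in window+suffix, and no in-frame stop codon.
SYN_PREFIX = "GTTGTTACGCCGTG"
SYN_ANCHOR = "AGTAGCTACT"
SYN_WINDOW_62 = "CATTCGTGTGACGCGCTAGAAGCCTGCTTCAAGGTTGGACTTACCGACCATGATGAGCCTAT"
SYN_SUFFIX = "ATTATACGGAACTCGATTCTCCATACGCATTACCATGAACTTATC"
# BRAF-style 111-nt window (same construction rules)
SYN_WINDOW_111 = (
    "CCGCGAACAGAAGGCCAGATCATCCACATGAGCAGACAATGGTGGCCGACAAGCTTGGAAGG"
    "CTGGCAGCGCTACGGCATGGATCATGCTGTCCGACCATTACCGGTCGCT"
)


@dataclass(frozen=True)
class ReadLayout:
    """How a sequencing read wraps the allele: prefix + anchor + allele + suffix."""

    prefix: str = SYN_PREFIX
    anchor: str = SYN_ANCHOR
    suffix: str = SYN_SUFFIX


DEFAULT_LAYOUT = ReadLayout()


def default_amplicon(kind: str = "mek1-like") -> AmpliconConfig:
    """The packaged synthetic amplicon configs (62-nt or 111-nt window)."""
    if kind == "mek1-like":
        return AmpliconConfig(
            name="syn_mek1", anchor=SYN_ANCHOR, reference_window=SYN_WINDOW_62,
            cut_offset=28, frame_offset=0,
        )
    if kind == "braf-like":
        return AmpliconConfig(
            name="syn_braf", anchor=SYN_ANCHOR, reference_window=SYN_WINDOW_111,
            cut_offset=55, frame_offset=0,
        )
    raise ValidationError(f"unknown amplicon kind {kind!r}")


# ---------------------------------------------------------------------------
# event drawing and normalization

def left_normalize_deletion(ref: str, pos: int, length: int) -> int:
    """Smallest 1-based start position describing the same deletion allele."""
    while pos > 1 and ref[pos - 2] == ref[pos - 2 + length]:
        pos -= 1
    return pos


def left_normalize_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Smallest 1-based position (and rotated sequence) for the same insertion."""
    while pos > 1 and seq[-1] == ref[pos - 2]:
        seq = ref[pos - 2] + seq[:-1]
        pos -= 1
    return pos, seq


def _trunc_geometric(rng: np.random.Generator, p: float, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    while True:
        k = int(rng.geometric(p))
        if lo <= k <= hi:
            return k


def _flanks_ok(pos: int, length: int, window_len: int, gap_open: int = 5, gap_ext: int = 2) -> bool:
    """Both flanks of an indel must out-score the gap so a local affine
    alignment bridges the lesion instead of truncating (margin of one match)."""
    need = gap_open + gap_ext * length + 2
    left = 2 * (pos - 1)
    right = 2 * (window_len + 1 - pos - length)
    return left >= need and right >= need


@dataclass(frozen=True)
class _Event:
    kind: str  # deletion | insertion | substitution | wild_type
    pos: int = 0
    length: int = 0
    detail: str = ""  # inserted sequence, or "ref>alt" for substitutions

    def apply(self, ref: str) -> str:
        if self.kind == "wild_type":
            return ref
        if self.kind == "deletion":
            return ref[: self.pos - 1] + ref[self.pos - 1 + self.length :]
        if self.kind == "insertion":
            return ref[: self.pos - 1] + self.detail + ref[self.pos - 1 :]
        ref_base, alt = self.detail.split(">")
        assert ref[self.pos - 1] == ref_base
        return ref[: self.pos - 1] + alt + ref[self.pos :]

    @property
    def category(self) -> str:
        return {
            "wild_type": "wild_type",
            "deletion": "deletion_only",
            "insertion": "insertion_only",
            "substitution": "mismatch_only",
        }[self.kind]


def _draw_event(rng: np.random.Generator, c: NhejSimConfig) -> _Event:
    ref = c.cfg.reference_window
    W = c.cfg.window_len
    cut = c.cfg.cut_offset
    bases = "ACGT"
    for _ in range(10_000):
        u = rng.random()
        if u < c.p_deletion:
            length = _trunc_geometric(rng, c.p_del_size, c.min_del, c.max_del)
            # first deleted base scatters around the cut (between cut and cut+1)
            pos = int(round(cut + 0.5 + rng.normal(0.0, c.position_jitter_sd)))
            if not 1 <= pos <= W - length + 1:
                continue
            pos = left_normalize_deletion(ref, pos, length)
            if not _flanks_ok(pos, length, W):
                continue
            return _Event("deletion", pos, length)
        if u < c.p_deletion + c.p_insertion:
            length = _trunc_geometric(rng, c.p_ins_size, c.min_ins, c.max_ins)
            seq = "".join(bases[b] for b in rng.integers(0, 4, size=length))
            pos = int(round(cut + 1 + rng.normal(0.0, c.position_jitter_sd)))
            if not 2 <= pos <= W:
                continue
            pos, seq = left_normalize_insertion(ref, pos, seq)
            if not _flanks_ok(pos, length, W):
                continue
            return _Event("insertion", pos, len(seq), seq)
        pos = int(round(cut + 0.5 + rng.normal(0.0, c.position_jitter_sd)))
        if not 3 <= pos <= W - 2:
            continue
        alt = bases[int(rng.integers(0, 4))]
        if alt == ref[pos - 1]:
            continue
        return _Event("substitution", pos, 1, f"{ref[pos - 1]}>{alt}")
    raise ValidationError("could not draw a window-compatible repair event")


def expected_window(allele: str, cfg: AmpliconConfig, layout: ReadLayout) -> str:
    """The fixed-length window the extractor will see for this allele."""
    return (allele + layout.suffix)[: cfg.window_len]


def simulate_allele_population(
    c: NhejSimConfig, layout: ReadLayout = DEFAULT_LAYOUT
) -> tuple[list[tuple[str, float]], pd.DataFrame]:
    """Draw an NHEJ allele population and its truth table.

    Wild type keeps frequency ``1 - edit_fraction``; ``n_edit_draws`` repair
    outcomes share the rest. The truth table has one row per distinct allele
    with its frequency, generative event (left-normalized), expected
    classification category, and expected observed window under ``layout``.
    A redraw replaces the rare event whose observed window collides with a
    different recorded event, so windows identify events uniquely.
    """
    if len(layout.suffix) < c.max_del:
        raise ValidationError("read-layout suffix must be at least max_del long")
    rng = np.random.default_rng(c.seed)
    ref = c.cfg.reference_window
    window_of: dict[str, _Event] = {expected_window(ref, c.cfg, layout): _Event("wild_type")}
    tally: dict[str, int] = {}
    allele_of_window: dict[str, str] = {expected_window(ref, c.cfg, layout): ref}
    if c.edit_fraction < 1.0:
        tally[ref] = 0
    event_of: dict[str, _Event] = {ref: _Event("wild_type")}
    n_draws = c.n_edit_draws if c.edit_fraction > 0 else 0
    for _ in range(n_draws):
        for _attempt in range(1000):
            ev = _draw_event(rng, c)
            allele = ev.apply(ref)
            win = expected_window(allele, c.cfg, layout)
            known = window_of.get(win)
            if known is not None and known != ev:
                continue  # window collision with a different event: redraw
            break
        else:  # pragma: no cover - astronomically unlikely
            raise ValidationError("could not resolve window collisions")
        window_of[win] = ev
        allele_of_window[win] = allele
        event_of[allele] = ev
        tally[allele] = tally.get(allele, 0) + 1

    freqs: dict[str, float] = {}
    if c.edit_fraction < 1.0:
        freqs[ref] = 1.0 - c.edit_fraction
    if n_draws:
        edited_total = sum(v for k, v in tally.items() if k != ref)
        for allele, n in tally.items():
            if allele == ref:
                continue
            freqs[allele] = freqs.get(allele, 0.0) + c.edit_fraction * n / edited_total
    population = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = []
    for allele, freq in population:
        ev = event_of[allele]
        rows.append(
            dict(
                allele=allele,
                frequency=freq,
                window=expected_window(allele, c.cfg, layout),
                event_type=ev.kind,
                event_pos=ev.pos,
                event_len=ev.length,
                event_detail=ev.detail,
                category=ev.category,
            )
        )
    return population, pd.DataFrame(rows)


def simulate_reads(
    population: list[tuple[str, float]],
    c: NhejSimConfig,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> tuple[list[str], pd.DataFrame]:
    """Multinomial sampling of alleles at ``depth`` with per-base error.

    Reads are ``prefix + anchor + allele + suffix``; each base substitutes
    uniformly to another base with probability ``seq_error_rate``. The truth
    table reports pre-error counts per allele and per observed window.
    """
    rng = np.random.default_rng([c.seed, 1])
    alleles = [a for a, _ in population]
    probs = np.array([f for _, f in population], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(c.depth, probs)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads: list[str] = []
    for allele, n in zip(alleles, counts):
        if n == 0:
            continue
        template = layout.prefix + layout.anchor + allele + layout.suffix
        if c.seq_error_rate <= 0:
            reads.extend([template] * int(n))
            continue
        L = len(template)
        k_err = rng.binomial(L, c.seq_error_rate, size=int(n))
        arr = np.frombuffer(template.encode(), dtype=np.uint8)
        for k in k_err:
            if k == 0:
                reads.append(template)
                continue
            mutated = arr.copy()
            pos = rng.choice(L, size=int(k), replace=False)
            for p in pos:
                choices = bases[bases != mutated[p]]
                mutated[p] = choices[int(rng.integers(0, 3))]
            reads.append(mutated.tobytes().decode())
    truth = pd.DataFrame(
        {
            "allele": alleles,
            "count": counts,
            "window": [expected_window(a, c.cfg, layout) for a in alleles],
        }
    )
    truth = truth[truth["count"] > 0].reset_index(drop=True)
    return reads, truth


def simulate_selection(
    population: list[tuple[str, float]],
    s: SelectionSimConfig,
) -> list[tuple[str, float]]:
    """Multiplicative fitness selection: freq_i proportional to f_i * w_i^g.

    With a bottleneck, each generation's frequencies are resampled
    multinomially at the bottleneck size, modeling populations that fall
    below the maintained representation.
    """
    rng = np.random.default_rng(s.seed)
    alleles = [a for a, _ in population]
    freqs = np.array([f for _, f in population], dtype=float)
    freqs = freqs / freqs.sum()
    fitness = np.array([s.fitness.get(a, 1.0) for a in alleles], dtype=float)
    if s.bottleneck is None:
        post = freqs * fitness**s.generations
        post = post / post.sum()
    else:
        post = freqs
        for _ in range(s.generations):
            post = post * fitness
            post = post / post.sum()
            counts = rng.multinomial(s.bottleneck, post)
            post = counts / s.bottleneck
            if post.sum() == 0:  # pragma: no cover
                raise ValidationError("population went extinct in the bottleneck")
            post = post / post.sum()
    return [(a, float(f)) for a, f in zip(alleles, post)]


def simulate_screen_reads(
    library: LibraryTable,
    per_guide_lfc: dict[str, float],
    coverage: int,
    conditions: ConditionsTable,
    seed: int,
    pdna_sample: str = "pDNA",
    filler: str = "ATCGATCGAT",
) -> tuple[list[str], pd.DataFrame]:
    """Pooled-screen reads: ``barcode + CACCG + spacer + filler`` per sample.

    The pDNA sample draws from a uniform guide distribution; every other
    sample draws from abundances proportional to ``2**lfc`` (guides absent
    from ``per_guide_lfc`` sit at LFC 0). Each sample receives
    ``coverage * n_guides`` reads. Returns the shuffled reads and the truth
    count matrix (guides x samples).
    """
    if not library.members:
        raise ValidationError("empty library")
    if pdna_sample not in conditions.samples:
        raise ValidationError(f"conditions table lacks the {pdna_sample!r} sample")
    rng = np.random.default_rng(seed)
    ids = library.ids()
    spacers = [g.spacer for g in library.members]
    n = len(ids)
    lfc = np.array([per_guide_lfc.get(gid, 0.0) for gid in ids], dtype=float)
    barcode_of = {s: b for b, s in conditions.entries.items()}
    truth = pd.DataFrame(0, index=ids, columns=conditions.samples, dtype=int)
    reads: list[str] = []
    for sample in conditions.samples:
        if sample == pdna_sample:
            probs = np.full(n, 1.0 / n)
        else:
            w = np.exp2(lfc)
            probs = w / w.sum()
        counts = rng.multinomial(coverage * n, probs)
        truth[sample] = counts
        bc = barcode_of[sample]
        for spacer, k in zip(spacers, counts):
            if k:
                reads.extend([bc + "CACCG" + spacer + filler] * int(k))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, truth
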