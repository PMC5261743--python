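"""Tiling sgRNA library design.

Enumerates every SpCas9 guide (20-nt spacer + NGG PAM) along a gene on both
strands, drops guides carrying a BsmBI recognition site (they would be cut
during Golden-Gate library cloning), attaches non-targeting controls, and maps
each guide's blunt cut site to the codon / amino acid it perturbs.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .models import GeneModel, LibraryTable, SgRNA, ValidationError

BSMBI_SITE = "CGTCTC"
BSMBI_SITE_RC = "GAGACG"
SPACER_LEN = 20
#: distance from the PAM to the blunt cut: Cas9 cuts between protospacer
#: positions 17 and 18, i.e. 3 bp 5' of the PAM on the targeted strand.
CUT_OFFSET_FROM_PAM = 3


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def enumerate_sgrnas(gene: GeneModel) -> list[SgRNA]:
    """Every NGG-PAM guide on either strand whose cut site falls within the
    CDS extended by ``gene.intron_margin`` on each side.

    ``cut_pos`` is reported as the top-strand index immediately 5' of the cut
    for both strands, so the cut always falls between ``cut_pos`` and
    ``cut_pos + 1`` in top-strand coordinates.
    """
    seq = gene.sequence
    if len(seq) < SPACER_LEN + 3:
        raise ValidationError("sequence shorter than a spacer plus PAM")
    lo = gene.cds_intervals[0][0] - gene.intron_margin
    hi = gene.cds_intervals[-1][1] + gene.intron_margin  # half-open
    guides: list[SgRNA] = []
    # plus strand: PAM = seq[p:p+3] == NGG, spacer immediately 5' of it
    for p in range(SPACER_LEN, len(seq) - 2):
        if seq[p + 1 : p + 3] == "GG":
            cut_pos = p - CUT_OFFSET_FROM_PAM - 1
            if lo <= cut_pos < hi:
                guides.append(
                    SgRNA(
                        spacer=seq[p - SPACER_LEN : p],
                        pam=seq[p : p + 3],
                        strand="+",
                        cut_pos=cut_pos,
                        gene=gene.name,
                    )
                )
    # minus strand: top strand shows CCN at q, protospacer 3' of it
    for q in range(0, len(seq) - (SPACER_LEN + 3) + 1):
        if seq[q : q + 2] == "CC":
            cut_pos = q + 2 + CUT_OFFSET_FROM_PAM
            if lo <= cut_pos < hi:
                guides.append(
                    SgRNA(
                        spacer=revcomp(seq[q + 3 : q + 3 + SPACER_LEN]),
                        pam=revcomp(seq[q : q + 3]),
                        strand="-",
                        cut_pos=cut_pos,
                        gene=gene.name,
                    )
                )
    guides.sort(key=lambda g: (g.cut_pos, 0 if g.strand == "+" else 1, g.spacer))
    return guides


def filter_bsmbi(guides: list[SgRNA]) -> list[SgRNA]:
    """Drop guides whose spacer contains the BsmBI site (either orientation)."""
    return [
        g
        for g in guides
        if BSMBI_SITE not in g.spacer and BSMBI_SITE_RC not in g.spacer
    ]


def make_nontargeting_controls(
    n: int,
    references: list[str],
    seed: int,
    max_draws_per_spacer: int = 1000,
) -> list[SgRNA]:
    """``n`` distinct random 20-mers absent (both strands) from every reference.

    Controls are screened against the supplied reference sequences only, not a
    whole genome, and against the BsmBI site. Deterministic under ``seed``.
    """
    import numpy as np

    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    haystacks = [r.upper() for r in references] + [revcomp(r.upper()) for r in references]
    chosen: list[str] = []
    seen: set[str] = set()
    budget = n * max_draws_per_spacer
    draws = 0
    bases = np.array(list("ACGT"))
    while len(chosen) < n:
        if draws >= budget:
            raise ValidationError(
                f"could not find {n} non-targeting spacers within {budget} draws"
            )
        spacer = "".join(rng.choice(bases, size=SPACER_LEN))
        draws += 1
        if spacer in seen:
            continue
        seen.add(spacer)
        if BSMBI_SITE in spacer or BSMBI_SITE_RC in spacer:
            continue
        if any(spacer in h for h in haystacks):
            continue
        chosen.append(spacer)
    return [SgRNA(spacer=s, is_control=True) for s in chosen]


def map_cut_to_codon(guide: SgRNA, gene: GeneModel) -> tuple[int, str] | None:
    """Codon index (1-based) and amino acid perturbed by a guide's cut.

    The target is the codon containing the first coding base at-or-3' of the
    cut in translation order; a cut exactly at an exon 3' boundary resolves to
    the next exon's first base. Returns ``None`` for cuts in retained intron.
    """
    if guide.cut_pos is None:
        raise ValidationError("guide has no cut position")
    if not -1 <= guide.cut_pos < len(gene.sequence):
        raise ValidationError("cut position outside the gene sequence")
    coding = gene.coding_positions()
    index_of = {pos: i for i, pos in enumerate(coding)}
    after = guide.cut_pos + 1  # first base 3' of the cut, top strand
    if after in index_of:
        offset = index_of[after]
    elif guide.cut_pos in index_of:
        # cut at an exon 3' edge: resolve toward the next coding base
        nxt = index_of[guide.cut_pos] + 1
        if nxt >= len(coding):
            return None
        offset = nxt
    else:
        return None
    codon_index = offset // 3 + 1
    cds = gene.cds_sequence
    codon = cds[(codon_index - 1) * 3 : codon_index * 3]
    aa = str(Seq(codon).translate())
    return codon_index, aa


def build_library(
    genes: list[GeneModel],
    n_controls: int = 100,
    seed: int = 0,
) -> LibraryTable:
    """Design the full tiling pool: enumerate, filter, annotate, add controls."""
    members: list[SgRNA] = []
    for gene in genes:
        for g in filter_bsmbi(enumerate_sgrnas(gene)):
            mapped = map_cut_to_codon(g, gene)
            if mapped is None:
                members.append(g)
            else:
                members.append(g.with_target(*mapped))
    # duplicate spacers across positions (repeats) would break deconvolution
    seen: set[str] = set()
    unique_members = []
    for g in members:
        if g.spacer not in seen:
            seen.add(g.spacer)
            unique_members.append(g)
    if n_controls:
        unique_members.extend(
            make_nontargeting_controls(n_controls, [g.sequence for g in genes], seed)
        )
    return LibraryTable(members=unique_members, gene_names=[g.name for g in genes])
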