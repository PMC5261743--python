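"""Worked-example calculators and report bundles.

The library-size calculator contrasts a saturating single-substitution ORF
library (19 non-self substitutions per residue) with a tiling guide library
(one guide per ~8 nt of CDS, each generating on the order of a thousand
endogenous NHEJ variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .models import ValidationError


def library_size_calculator(
    protein_len_aa: int,
    guides_per_nt: float = 1 / 8,
    variants_per_guide: int = 1000,
) -> tuple[int, int, int]:
    """(single-substitution variants, tiling guides, potential NHEJ variants).

    For a 350-aa protein: 19 * 350 = 6,650 substitution variants versus
    floor(3 * 350 / 8) = 131 tiling guides, i.e. ~131,000 potential variants
    when each guide yields ~1,000 alleles.
    """
    if protein_len_aa < 1:
        raise ValidationError("protein_len_aa must be >= 1")
    n_sub = 19 * protein_len_aa
    n_guides = math.floor(3 * protein_len_aa * guides_per_nt)
    return n_sub, n_guides, n_guides * variants_per_guide


@dataclass
class ReportBundle:
    """CSV sections of a run report plus a plain-text summary."""

    sections: dict[str, pd.DataFrame]
    summary: str

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.sections.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.txt").write_text(self.summary)


def build_report(
    hits: pd.DataFrame | None = None,
    ranks: pd.DataFrame | None = None,
    enrichment: pd.DataFrame | None = None,
    variant_table: pd.DataFrame | None = None,
    top_n: int = 20,
) -> ReportBundle:
    """Assemble rank tables, top-allele listings, hit tables and category/
    spectrum summaries from whichever stage outputs are present.

    No numbers are recomputed: each section is a view of its stage output,
    so the report always equals the pipeline tables it came from.
    """
    sections: dict[str, pd.DataFrame] = {}
    lines: list[str] = ["tilevar run report", "=" * 18]
    if hits is not None:
        sections["hits"] = hits
        n_hits = int(hits["is_hit"].sum()) if len(hits) else 0
        thr = float(hits["threshold"].iloc[0]) if len(hits) else float("nan")
        lines.append(f"hit calling: {n_hits} hits above control threshold {thr:.4f}")
    if ranks is not None:
        sections["ranks"] = ranks
        lines.append(f"rank table: {len(ranks)} guides")
    if enrichment is not None:
        sections["enrichment"] = enrichment
        sections["top_alleles"] = enrichment.head(top_n)
        if len(enrichment):
            lines.append(
                "enrichment: max fold change "
                f"{float(enrichment['fold_change'].max()):.1f} over {len(enrichment)} sequences"
            )
        else:
            lines.append("enrichment: 0 sequences")
    if variant_table is not None:
        sections["variants"] = variant_table
        if len(variant_table) and "category" in variant_table:
            cats = (
                variant_table["category"].value_counts().rename_axis("category")
                .reset_index(name="n_variants")
            )
        else:
            cats = pd.DataFrame(columns=["category", "n_variants"])
        sections["category_summary"] = cats
        lines.append(f"variants: {len(variant_table)} rows")
    lines.append("")
    return ReportBundle(sections=sections, summary="\n".join(lines))
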