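"""Aggregate per-genome summary report.

One summary block per genome: size, G+C %, gene/ORF counts, unique-region
fraction, plastid-derived fraction, large-repeat lengths, short-repeat
fraction — the composition table a mitotype comparison paper would print.
Percentages use half-even rounding to 2 decimal places, and every number is
recomputable from the stage TSVs (no report-only arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN


def pct(x: float) -> str:
    """Percentage with 2 decimals, half-even rounding."""
    return str(Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


@dataclass
class GenomeSummary:
    genome_id: str
    size: int
    gc: float  # fraction
    n_protein_genes: int = 0
    n_trna: int = 0
    n_rrna: int = 0
    n_orfs: int = 0
    unique_fraction: float | None = None
    cp_fraction: float | None = None
    large_repeat_lengths: list[int] = field(default_factory=list)
    short_repeat_fraction: float | None = None


def build_report(summaries: list[GenomeSummary]) -> str:
    """Composition summary, one column per genome."""
    if not summaries:
        raise ValueError("no stage outputs to report")
    rows: list[tuple[str, list[str]]] = []

    def add(label, fn):
        rows.append((label, [fn(s) for s in summaries]))

    add("Genome size (bp)", lambda s: str(s.size))
    add("GC%", lambda s: pct(s.gc))
    add("Protein-coding genes", lambda s: str(s.n_protein_genes))
    add("tRNA", lambda s: str(s.n_trna))
    add("rRNA", lambda s: str(s.n_rrna))
    add("ORFs", lambda s: str(s.n_orfs))
    add("Unique region (%)",
        lambda s: pct(s.unique_fraction) if s.unique_fraction is not None else "-")
    add("cp-derived sequences (%)",
        lambda s: pct(s.cp_fraction) if s.cp_fraction is not None else "-")
    add("Large repeat (bp)",
        lambda s: ",".join(map(str, s.large_repeat_lengths)) or "-")
    add("Short repeat (%)",
        lambda s: pct(s.short_repeat_fraction)
        if s.short_repeat_fraction is not None else "-")

    width0 = max(len("Feature"), max(len(r[0]) for r in rows)) + 2
    widths = [
        max(len(s.genome_id), max(len(r[1][i]) for r in rows)) + 2
        for i, s in enumerate(summaries)
    ]
    out = ["Feature".ljust(width0)
           + "".join(s.genome_id.rjust(w) for s, w in zip(summaries, widths))]
    out.append("-" * (width0 + sum(widths)))
    for label, vals in rows:
        out.append(label.ljust(width0)
                   + "".join(v.rjust(w) for v, w in zip(vals, widths)))
    return "\n".join(out) + "\n"
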