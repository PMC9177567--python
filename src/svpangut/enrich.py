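"""Fisher's exact enrichment of SV-affected genes.

Genes whose body contains an SV breakpoint form the foreground; all genes of
all reference MAGs form the background.  Per pathway, a 2x2 table of
(foreground vs background-minus-foreground) x (in-pathway vs not) is tested
with the conditional two-sided Fisher exact test, and BH-adjusted across
pathways.  Gene-body inclusion only — promoter/TSS logic is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .genome import GeneModel
from .svcall import SVCall, retained
from .assoc import bh_adjust


@dataclass
class EnrichmentRecord:
    pathway_id: str
    fg_in: int
    fg_out: int
    bg_in: int
    bg_out: int
    odds_ratio: float
    p: float
    q: float = float("nan")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Conditional two-sided Fisher exact test on [[a,b],[c,d]].

    p sums hypergeometric tables at most as probable as the observed one;
    the odds ratio is ad/bc (inf when bc = 0).  A zero margin makes the
    table uninformative: p = 1 by convention, with a warning.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("zero margin; Fisher p = 1 by convention")
        odds = float("inf") if b * c == 0 and a * d > 0 else (
            a * d / (b * c) if b * c else float("nan")
        )
        return (odds, 1.0)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return (float(odds), float(p))


def sv_affected_genes(
    calls: list[SVCall],
    gene_models: list[GeneModel],
) -> dict[str, str]:
    """Genes whose body interval contains a retained SV breakpoint.

    A gene [start, end) on a reference contig is affected iff any retained
    call's ref_start or ref_end lies inside it (0-based, half-open).
    Returns {gene_id: ko}.
    """
    contigs_seen = {g.contig for g in gene_models}
    by_contig: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_contig.setdefault(g.contig, []).append(g)
    affected: dict[str, str] = {}
    for call in retained(calls):
        if call.ref_contig not in contigs_seen and contigs_seen:
            # breakpoints on a contig without annotation are simply unannotated
            pass
        for g in by_contig.get(call.ref_contig, []):
            for bp in (call.ref_start, call.ref_end):
                if g.start <= bp < g.end:
                    affected[g.gene_id] = g.ko
                    break
    return affected


def enrichment(
    foreground_genes: set[str],
    background_genes: set[str],
    gene_to_pathways: dict[str, set[str] | list[str]],
    exclusive_background: bool = True,
) -> pd.DataFrame:
    """Per-pathway Fisher enrichment of the foreground against the background.

    The default contrast is foreground vs background-minus-foreground;
    ``exclusive_background=False`` contrasts against the full background.
    Multi-pathway genes contribute to every mapped pathway; q is BH across
    pathways and records are sorted by p.
    """
    fg = set(foreground_genes)
    bg = set(background_genes)
    if not fg <= bg:
        raise ValueError("foreground genes must be a subset of the background")
    if not gene_to_pathways:
        raise ValueError("gene_to_pathways must cover at least one gene")
    rest = (bg - fg) if exclusive_background else bg
    pathways: set[str] = set()
    for paths in gene_to_pathways.values():
        pathways.update(paths)
    rows = []
    for pw in sorted(pathways):
        members = {g for g, paths in gene_to_pathways.items() if pw in paths}
        fg_in = len(fg & members)
        fg_out = len(fg) - fg_in
        bg_in = len(rest & members)
        bg_out = len(rest) - bg_in
        odds, p = fisher_exact_2x2(fg_in, fg_out, bg_in, bg_out)
        rows.append(
            {
                "pathway_id": pw, "fg_in": fg_in, "fg_out": fg_out,
                "bg_in": bg_in, "bg_out": bg_out,
                "odds_ratio": odds, "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"])
    return df.sort_values("p", kind="stable").reset_index(drop=True)
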