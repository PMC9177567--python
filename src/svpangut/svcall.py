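"""Pairwise SV calling between same-species genome assemblies.

Insertions, deletions, and inversions are called from collinear alignment
blocks between a representative (reference) MAG and a query MAG.  Blocks can
come from the built-in exact k-mer anchor/chaining aligner (desk-scale and
synthetic use) or from any external aligner via PAF (the interoperability
path for real genomes).

Calling rules
-------------
* between consecutive collinear blocks, a reference gap exceeding the query
  gap by >= ``min_sv_len`` is a deletion (in the query), the converse an
  insertion; near-balanced gaps (substitution-like breaks) are not typed;
* a '-'-strand block flanked by '+'-strand blocks on both sides is an
  inversion of that block's length; terminal strand flips are flagged, not
  typed;
* calls with any breakpoint within ``end_margin`` bp (default 10) of a
  contig terminus of either genome are emitted with ``filtered=True`` rather
  than silently dropped, for auditability;
* ``is_large`` marks calls longer than 500 bp, the class long reads resolve.

Validation re-maps long reads and requires each call to be spanned —
breakpoints plus ``flank`` bp on both sides — by at least ``min_support``
reads on the allele-carrying genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, ReadSet, reverse_complement

LARGE_SV_THRESHOLD = 500


@dataclass
class AlignmentBlock:
    """One collinear alignment block (0-based half-open on both genomes)."""

    ref_contig: str
    ref_start: int
    ref_end: int
    query_contig: str
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    n_matches: int = 0

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.query_end <= self.query_start:
            raise ValueError("block intervals must be non-empty")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SVCall:
    sv_id: str
    sv_type: str  # insertion / deletion / inversion
    ref_contig: str
    ref_start: int
    ref_end: int
    query_contig: str
    query_start: int
    query_end: int
    length_bp: int
    is_large: bool = False
    filtered: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        self.is_large = self.length_bp > LARGE_SV_THRESHOLD


@dataclass
class ValidationResult:
    sv_id: str
    supporting_reads_ref: int
    supporting_reads_query: int
    supported: bool


# ---------------------------------------------------------------------------
# anchor alignment


def _unique_kmer_index(contigs: dict[str, str], k: int) -> dict[str, tuple[str, int]]:
    counts: dict[str, int] = {}
    for seq in contigs.values():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            counts[km] = counts.get(km, 0) + 1
    index: dict[str, tuple[str, int]] = {}
    for contig, seq in contigs.items():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if counts[km] == 1:
                index[km] = (contig, i)
    return index


def anchor_align(
    reference: GenomeAssembly,
    query: GenomeAssembly,
    k: int = 21,
    min_chain_bp: int = 100,
    diag_tol: int = 0,
) -> list[AlignmentBlock]:
    """Chain exact unique k-mer anchors into maximal collinear blocks.

    Anchors are k-mers unique in both genomes, matched on both strands; a
    chain extends while the strand, reference contig, and diagonal (within
    ``diag_tol``) are preserved.  For identical genomes this returns one
    full-length block per contig.  Desk-scale substitute for a whole-genome
    aligner; not intended for divergent real genomes.
    """
    if k < 15:
        raise ValueError("k must be >= 15 to keep anchors effectively unique")
    if not reference.contigs or not query.contigs:
        raise ValueError("empty genome")
    ref_index = _unique_kmer_index(reference.contigs, k)

    # uniqueness within the query, to reject repeat-induced anchors
    q_counts: dict[str, int] = {}
    for seq in query.contigs.values():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            q_counts[km] = q_counts.get(km, 0) + 1

    blocks: list[AlignmentBlock] = []
    for q_contig, seq in query.contigs.items():
        chain: list[tuple[int, int]] = []  # (qpos, rpos)
        chain_strand = ""
        chain_rcontig = ""
        chain_diag = 0

        def flush() -> None:
            if not chain:
                return
            qs = chain[0][0]
            qe = chain[-1][0] + k
            rpositions = [r for _, r in chain]
            rs, re = min(rpositions), max(rpositions) + k
            if re - rs >= min_chain_bp:
                blocks.append(
                    AlignmentBlock(
                        ref_contig=chain_rcontig,
                        ref_start=rs,
                        ref_end=re,
                        query_contig=q_contig,
                        query_start=qs,
                        query_end=qe,
                        strand=chain_strand,
                        n_matches=len(chain),
                    )
                )

        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if q_counts[km] != 1:
                continue
            hit = ref_index.get(km)
            strand = "+"
            if hit is None:
                hit = ref_index.get(reverse_complement(km))
                strand = "-"
            if hit is None:
                continue
            rcontig, rpos = hit
            diag = rpos - i if strand == "+" else rpos + i
            if (
                chain
                and strand == chain_strand
                and rcontig == chain_rcontig
                and abs(diag - chain_diag) <= diag_tol
            ):
                chain.append((i, rpos))
            else:
                flush()
                chain = [(i, rpos)]
                chain_strand, chain_rcontig, chain_diag = strand, rcontig, diag
        flush()
        chain = []

    blocks.sort(key=lambda b: (b.ref_contig, b.ref_start))
    return blocks


# ---------------------------------------------------------------------------
# SV calling


def _near_end(pos: int, contig_len: int | None, margin: int) -> bool:
    if contig_len is None:
        return pos < margin
    return pos < margin or contig_len - pos < margin


def call_svs(
    blocks: list[AlignmentBlock],
    min_sv_len: int = 50,
    end_margin: int = 10,
    large_threshold: int = LARGE_SV_THRESHOLD,
    ref_lengths: dict[str, int] | None = None,
    query_lengths: dict[str, int] | None = None,
    overlap_tol: int = 25,
) -> list[SVCall]:
    """Type SVs from sorted collinear blocks (see module docstring for rules).

    Consecutive blocks may micro-overlap by up to ``overlap_tol`` bp (anchor
    extension across a breakpoint when adjacent bases coincide); the gap
    difference remains exact under such symmetric trims, so the calls do
    too.  Larger overlaps violate the collinearity contract and raise.
    """
    calls: list[SVCall] = []
    groups: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault((b.ref_contig, b.query_contig), []).append(b)

    def finish(call: SVCall) -> SVCall:
        call.is_large = call.length_bp > large_threshold
        ref_len = (ref_lengths or {}).get(call.ref_contig)
        q_len = (query_lengths or {}).get(call.query_contig)
        near = (
            _near_end(call.ref_start, ref_len, end_margin)
            or _near_end(call.ref_end, ref_len, end_margin)
            or _near_end(call.query_start, q_len, end_margin)
            or _near_end(call.query_end, q_len, end_margin)
        )
        if near and not call.filtered:
            call.filtered = True
            call.reason = "contig_end"
        return call

    n = 0
    for (rc, qc), grp in sorted(groups.items()):
        grp = sorted(grp, key=lambda b: b.query_start)
        for a, b in zip(grp, grp[1:]):
            if (
                b.query_start < a.query_end - overlap_tol
                or b.ref_start < a.ref_end - overlap_tol
            ):
                raise ValueError("alignment blocks overlap; contract violated")

        # inversions: '-' blocks flanked by '+' collinear blocks
        for i, blk in enumerate(grp):
            if blk.strand != "-":
                continue
            flanked = (
                0 < i < len(grp) - 1
                and grp[i - 1].strand == "+"
                and grp[i + 1].strand == "+"
            )
            n += 1
            call = SVCall(
                sv_id=f"sv_{n:05d}",
                sv_type="inversion",
                ref_contig=rc,
                ref_start=blk.ref_start,
                ref_end=blk.ref_end,
                query_contig=qc,
                query_start=blk.query_start,
                query_end=blk.query_end,
                length_bp=blk.ref_end - blk.ref_start,
            )
            if not flanked:
                call.filtered = True
                call.reason = "terminal_strand_flip"
            if call.length_bp >= min_sv_len:
                calls.append(finish(call))

        # indels from gaps between consecutive blocks
        for a, b in zip(grp, grp[1:]):
            ref_gap = b.ref_start - a.ref_end
            query_gap = b.query_start - a.query_end
            diff = ref_gap - query_gap
            if diff >= min_sv_len:
                n += 1
                calls.append(
                    finish(
                        SVCall(
                            sv_id=f"sv_{n:05d}",
                            sv_type="deletion",
                            ref_contig=rc,
                            ref_start=a.ref_end,
                            ref_end=a.ref_end + diff,
                            query_contig=qc,
                            query_start=a.query_end,
                            query_end=a.query_end,
                            length_bp=diff,
                        )
                    )
                )
            elif -diff >= min_sv_len:
                n += 1
                calls.append(
                    finish(
                        SVCall(
                            sv_id=f"sv_{n:05d}",
                            sv_type="insertion",
                            ref_contig=rc,
                            ref_start=a.ref_end,
                            ref_end=a.ref_end,
                            query_contig=qc,
                            query_start=a.query_end,
                            query_end=a.query_end - diff,
                            length_bp=-diff,
                        )
                    )
                )

    calls.sort(key=lambda c: (c.ref_contig, c.ref_start, c.sv_id))
    return calls


def call_structural_variants(
    reference: GenomeAssembly,
    query: GenomeAssembly,
    k: int = 21,
    min_chain_bp: int = 100,
    min_sv_len: int = 50,
    end_margin: int = 10,
) -> list[SVCall]:
    """End-to-end convenience: align two assemblies and call SVs."""
    blocks = anchor_align(reference, query, k=k, min_chain_bp=min_chain_bp)
    return call_svs(
        blocks,
        min_sv_len=min_sv_len,
        end_margin=end_margin,
        ref_lengths=reference.contig_lengths,
        query_lengths=query.contig_lengths,
    )


def retained(calls: list[SVCall]) -> list[SVCall]:
    return [c for c in calls if not c.filtered]


def sv_rate_per_mb(calls: list[SVCall], genome_size: int) -> float:
    """Retained SV count normalised to events per 1 Mb of genome."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return len(retained(calls)) * 1e6 / genome_size


def summarize_svs(calls: list[SVCall] | pd.DataFrame) -> dict:
    """Per-type counts, large-SV (>500 bp) counts and fractions, lengths.

    Accepts a list of calls or a DataFrame with columns sv_type / length_bp /
    filtered (counts cover retained calls only).
    """
    if isinstance(calls, pd.DataFrame):
        df = calls
    else:
        df = calls_to_dataframe(calls)
    if len(df):
        df = df[~df["filtered"].astype(bool)]
    out: dict = {"total": int(len(df)), "by_type": {}, "lengths": df["length_bp"].to_numpy() if len(df) else np.array([], dtype=int)}
    for t in ("insertion", "deletion", "inversion"):
        sub = df[df["sv_type"] == t] if len(df) else df
        count = int(len(sub))
        large = int((sub["length_bp"] > LARGE_SV_THRESHOLD).sum()) if count else 0
        out["by_type"][t] = {
            "count": count,
            "large_count": large,
            "large_fraction": large / count if count else 0.0,
        }
    return out


def calls_to_dataframe(calls: list[SVCall]) -> pd.DataFrame:
    cols = [
        "sv_id", "sv_type", "ref_contig", "ref_start", "ref_end",
        "query_contig", "query_start", "query_end", "length_bp",
        "is_large", "filtered", "reason",
    ]
    return pd.DataFrame([{c: getattr(x, c) for c in cols} for x in calls], columns=cols)


# ---------------------------------------------------------------------------
# read mapping + spanning validation


def build_read_mapper(genome: GenomeAssembly, k: int = 21, stride: int = 1):
    """Closure mapping a read sequence to (contig, start, end, strand) on
    ``genome`` via the densest consistent-diagonal cluster of unique-k-mer
    anchors; returns None for unmappable reads.

    ``stride`` subsamples anchor positions for speed; the mapped interval is
    then extended by at most stride-1 bp per side (bounded extrapolation
    along the cluster diagonal), so interval ends are exact at stride 1 and
    off by < stride otherwise.
    """
    index = _unique_kmer_index(genome.contigs, k)

    def map_read(seq: str, diag_tol: int = 50):
        anchors: dict[tuple[str, str], list[tuple[int, int]]] = {}
        rc = reverse_complement(seq)
        for strand, s in (("+", seq), ("-", rc)):
            positions = range(0, len(s) - k + 1, stride)
            for i in positions:
                hit = index.get(s[i : i + k])
                if hit is None:
                    continue
                contig, rpos = hit
                anchors.setdefault((contig, strand), []).append((rpos - i, rpos))
        best = None  # (count, contig, strand, items, j, i)
        for (contig, strand), items in anchors.items():
            items.sort()
            # densest diagonal run within tolerance (two-pointer sweep)
            j = 0
            for i in range(len(items)):
                while items[i][0] - items[j][0] > diag_tol:
                    j += 1
                if best is None or i - j + 1 > best[0]:
                    best = (i - j + 1, contig, strand, items, j, i)
        if best is None:
            return None
        _, contig, strand, items, j, i = best
        cluster = items[j : i + 1]
        rpos = [r for _, r in cluster]
        start, end = min(rpos), max(rpos) + k
        if stride > 1:
            # bounded extrapolation for anchor positions skipped by the stride
            qpos = [r - d for d, r in cluster]
            L = len(seq)
            start -= min(stride - 1, min(qpos))
            end += min(stride - 1, L - k - max(qpos))
            clen = len(genome.contigs[contig])
            start, end = max(0, start), min(clen, end)
        return (contig, start, end, strand)

    return map_read


def _window(sv: SVCall, which: str, flank: int) -> tuple[str, int, int]:
    if which == "ref":
        return (sv.ref_contig, sv.ref_start - flank, sv.ref_end + flank)
    return (sv.query_contig, sv.query_start - flank, sv.query_end + flank)


def spanning_support(
    sv: SVCall,
    ref_alignments: list[tuple[str, int, int]],
    query_alignments: list[tuple[str, int, int]],
    flank: int = 100,
    min_support: int = 2,
) -> ValidationResult:
    """Count reads whose aligned interval fully covers the SV breakpoints
    plus ``flank`` bp on both sides.

    The deleted allele's material lives on the reference, an insertion's on
    the query; an inversion needs support on both genomes.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")

    def count(alignments, which):
        contig, lo, hi = _window(sv, which, flank)
        return sum(1 for c, s, e in alignments if c == contig and s <= lo and e >= hi)

    n_ref = count(ref_alignments, "ref")
    n_query = count(query_alignments, "query")
    if sv.sv_type == "deletion":
        supported = n_ref >= min_support
    elif sv.sv_type == "insertion":
        supported = n_query >= min_support
    else:
        supported = n_ref >= min_support and n_query >= min_support
    return ValidationResult(sv.sv_id, n_ref, n_query, supported)


def validate_svs(
    calls: list[SVCall],
    reads: ReadSet,
    reference: GenomeAssembly,
    query: GenomeAssembly,
    flank: int = 100,
    min_support: int = 2,
    k: int = 21,
    stride: int = 1,
) -> tuple[pd.DataFrame, float]:
    """Map reads to both genomes and report per-call spanning support plus
    the supported fraction over retained calls (NaN when nothing is testable)."""
    keep = retained(calls)
    ref_aln: list[tuple[str, int, int]] = []
    query_aln: list[tuple[str, int, int]] = []
    if len(reads):
        map_ref = build_read_mapper(reference, k=k, stride=stride)
        map_query = build_read_mapper(query, k=k, stride=stride)
        for r in reads.reads:
            hit = map_ref(r.sequence)
            if hit is not None:
                ref_aln.append(hit[:3])
            hit = map_query(r.sequence)
            if hit is not None:
                query_aln.append(hit[:3])
        if not ref_aln and not query_aln:
            warnings.warn("no reads mapped to either genome; supported fraction is NA")
            frac = float("nan")
        else:
            frac = None
    else:
        frac = 0.0

    results = [
        spanning_support(sv, ref_aln, query_aln, flank=flank, min_support=min_support)
        for sv in keep
    ]
    table = pd.DataFrame(
        [
            {
                "sv_id": v.sv_id,
                "supporting_reads_ref": v.supporting_reads_ref,
                "supporting_reads_query": v.supporting_reads_query,
                "supported": v.supported,
            }
            for v in results
        ],
        columns=["sv_id", "supporting_reads_ref", "supporting_reads_query", "supported"],
    )
    if frac is None:
        frac = float(table["supported"].mean()) if len(table) else float("nan")
    return table, frac
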