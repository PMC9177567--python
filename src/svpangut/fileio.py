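"""Plain-text interchange: PAF, GFF3, SV/validation tables, truth JSON, YAML config.

Internal coordinates are 0-based half-open; exported SV tables use 1-based
inclusive coordinates (the convention of the field's TSV reports), and the
readers convert back.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .genome import GeneModel
from .svcall import AlignmentBlock, SVCall, calls_to_dataframe
from .synthio import SVSpec


# ---------------------------------------------------------------------------
# PAF (minimap2-style pairwise alignment)


def write_paf(
    blocks: list[AlignmentBlock],
    path: str | Path,
    query_lengths: dict[str, int],
    ref_lengths: dict[str, int],
) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fields = [
                b.query_contig, query_lengths[b.query_contig],
                b.query_start, b.query_end, b.strand,
                b.ref_contig, ref_lengths[b.ref_contig],
                b.ref_start, b.ref_end,
                b.n_matches, max(b.ref_end - b.ref_start, b.query_end - b.query_start),
                255,
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """PAF columns 1-12 map directly onto AlignmentBlock (target = reference)."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            blocks.append(
                AlignmentBlock(
                    query_contig=f[0],
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    strand=f[4],
                    ref_contig=f[5],
                    ref_start=int(f[7]),
                    ref_end=int(f[8]),
                    n_matches=int(f[9]),
                )
            )
    blocks.sort(key=lambda b: (b.ref_contig, b.ref_start))
    return blocks


# ---------------------------------------------------------------------------
# GFF3 gene models with KO tags


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "svpangut") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};KO={g.ko}"
            fh.write(
                "\t".join(
                    [
                        g.contig, source, "gene",
                        str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                    contig=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    ko=attrs.get("KO", ""),
                    strand=f[6] if f[6] in "+-" else "+",
                )
            )
    return genes


# ---------------------------------------------------------------------------
# SV tables (1-based inclusive on disk)


def write_sv_table(calls: list[SVCall], path: str | Path) -> None:
    df = calls_to_dataframe(calls)
    for col in ("ref_start", "query_start"):
        df[col] = df[col] + 1  # 1-based inclusive export
    df.to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t")
    calls = []
    for _, r in df.iterrows():
        calls.append(
            SVCall(
                sv_id=r["sv_id"], sv_type=r["sv_type"],
                ref_contig=r["ref_contig"],
                ref_start=int(r["ref_start"]) - 1, ref_end=int(r["ref_end"]),
                query_contig=r["query_contig"],
                query_start=int(r["query_start"]) - 1, query_end=int(r["query_end"]),
                length_bp=int(r["length_bp"]),
                filtered=bool(r["filtered"]),
                reason="" if pd.isna(r["reason"]) else str(r["reason"]),
            )
        )
    return calls


def write_vcf_like(calls: list[SVCall], path: str | Path, reference_name: str = "reference") -> None:
    """Minimal VCF-style export with SVTYPE/SVLEN INFO tags."""
    sign = {"deletion": -1, "insertion": 1, "inversion": 1}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_name}\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            svtype = {"deletion": "DEL", "insertion": "INS", "inversion": "INV"}[c.sv_type]
            flt = "PASS" if not c.filtered else c.reason or "filtered"
            info = f"SVTYPE={svtype};SVLEN={sign[c.sv_type] * c.length_bp};END={c.ref_end}"
            fh.write(
                f"{c.ref_contig}\t{c.ref_start + 1}\t{c.sv_id}\tN\t<{svtype}>\t.\t{flt}\t{info}\n"
            )


# ---------------------------------------------------------------------------
# truth JSON


def write_truth(truth: list[SVSpec], path: str | Path) -> None:
    payload = [
        {
            "sv_type": s.sv_type, "contig": s.contig,
            "ref_start": s.ref_start, "ref_end": s.ref_end,
            "query_start": s.query_start, "query_end": s.query_end,
            "length_bp": s.length_bp, "payload": s.payload,
        }
        for s in truth
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> list[SVSpec]:
    return [SVSpec(**d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# matrices + config


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
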