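"""Readers and writers for the on-disk formats the pipeline exchanges.

FASTA goes through Biopython. GFF3 is the flat gene/mRNA/CDS dialect the
simulator emits (1-based, closed intervals per the format); internally
everything is 0-based half-open, and the shift happens only here.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pav import GeneModel, SampleMeta

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_sample_meta",
    "write_sample_meta",
    "write_depth_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence} preserving file order."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into GeneModels (coords to 0-based)."""
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_order: dict[str, list[str]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"GFF3 line has {len(cols)} columns: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = cols
            a = _attrs(attrs)
            if ftype == "gene":
                genes[a["ID"]] = {"host": seqid, "strand": strand}
                tx_order[a["ID"]] = []
            elif ftype == "mRNA":
                tx_parent[a["ID"]] = a["Parent"]
                tx_order[a["Parent"]].append(a["ID"])
                tx_cds[a["ID"]] = []
            elif ftype == "CDS":
                tx_cds[a["Parent"]].append((int(start) - 1, int(end)))
    out = []
    for gid, info in genes.items():
        transcripts = tuple(
            tuple(sorted(tx_cds[tid])) for tid in tx_order[gid] if tx_cds[tid]
        )
        out.append(
            GeneModel(gene_id=gid, host=info["host"], strand=info["strand"], transcripts=transcripts)
        )
    return out


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            g_start = min(tx[0][0] for tx in g.transcripts)
            g_end = max(tx[-1][1] for tx in g.transcripts)
            fh.write(
                f"{g.host}\tpavpan\tgene\t{g_start + 1}\t{g_end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for ti, tx in enumerate(g.transcripts):
                tid = f"{g.gene_id}.t{ti + 1}"
                fh.write(
                    f"{g.host}\tpavpan\tmRNA\t{tx[0][0] + 1}\t{tx[-1][1]}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent={g.gene_id}\n"
                )
                for s, e in tx:
                    fh.write(
                        f"{g.host}\tpavpan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={tid}\n"
                    )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV (sample, cohort, sex, extra phenotype cols)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "cohort", "sex"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    extra = [c for c in df.columns if c not in required]
    return [
        SampleMeta(
            sample_id=row["sample"],
            cohort=row["cohort"],
            sex=row["sex"],
            phenotypes=tuple((c, row[c]) for c in extra if pd.notna(row[c])),
        )
        for _, row in df.iterrows()
    ]


def write_sample_meta(meta: list[SampleMeta], path: str | Path) -> None:
    pheno_keys = sorted({k for m in meta for k, _ in m.phenotypes})
    rows = []
    for m in meta:
        row = {"sample": m.sample_id, "cohort": m.cohort, "sex": m.sex}
        row.update(dict(m.phenotypes))
        rows.append(row)
    pd.DataFrame(rows, columns=["sample", "cohort", "sex", *pheno_keys]).to_csv(
        path, sep="\t", index=False
    )


def write_depth_tsv(per_base_depth: dict[str, "list[int]"], path: str | Path) -> None:
    """Write samtools-depth dialect rows (host, 1-based pos, depth > 0 only)."""
    with open(path, "w") as fh:
        for host, depths in per_base_depth.items():
            for i, d in enumerate(depths):
                if d > 0:
                    fh.write(f"{host}\t{i + 1}\t{d}\n")
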