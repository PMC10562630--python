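"""Readers and writers for the pipeline's standard file formats.

FASTA via Biopython; GFF3 with 1-based inclusive coordinates per the spec
(converted from the package's internal 0-based half-open convention on
write/read); TE annotations as BED-like TSV (0-based half-open); gene-family
counts and regression tables as TSV; trees as Newick via dendropy.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import PeptideRecord
from .te import GeneModel, TEAnnotation

TE_COLUMNS = ["scaffold", "start", "end", "strand", "te_family", "te_class",
              "divergence"]


def read_peptides_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptides; a ``label=`` key in the description becomes source_tag."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tag = ""
        for token in rec.description.split():
            if token.startswith("label="):
                tag = token.split("=", 1)[1]
        records.append(PeptideRecord(id=rec.id, sequence=str(rec.seq), source_tag=tag))
    return records


def write_peptides_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id,
                  description=f"label={r.source_tag}" if r.source_tag else "")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_scaffolds_fasta(scaffolds: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in scaffolds.items()],
        str(path),
        "fasta",
    )


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/exon features; GFF3 is 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id}"
            if g.family_label:
                attrs += f";family={g.family_label}"
            fh.write(
                f"{g.scaffold}\tampevo\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tampevo\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.id}.exon{i};Parent={g.id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            scaffold, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {
                    "scaffold": scaffold, "start": int(start) - 1, "end": int(end),
                    "strand": strand, "family": attr.get("family"), "exons": [],
                }
                order.append(gid)
            elif ftype == "exon":
                genes[attr["Parent"]]["exons"].append((int(start) - 1, int(end)))
    return [
        GeneModel(
            id=gid, scaffold=g["scaffold"], start=g["start"], end=g["end"],
            strand=g["strand"], exons=tuple(sorted(g["exons"])),
            family_label=g["family"],
        )
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


def write_te_table(tes: Sequence[TEAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (t.scaffold, t.start, t.end, t.strand, t.te_family, t.te_class,
             t.divergence)
            for t in tes
        ],
        columns=TE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_te_table(path: str | Path) -> list[TEAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        TEAnnotation(
            scaffold=str(r.scaffold), start=int(r.start), end=int(r.end),
            strand=str(r.strand), te_family=str(r.te_family),
            te_class=str(r.te_class), divergence=float(r.divergence),
        )
        for r in df.itertuples()
    ]


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")
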