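"""File formats: FASTA via Biopython, GFF3 (1-based inclusive), TSV/BED-like.

The GFF3 writer stores the domain partition and cluster membership in
column-9 attributes so that a written locus round-trips losslessly back to
the same `GeneModel` objects given the genome sequence.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_locus import (
    ConversionEvent,
    DomainPartition,
    FragmentPlacement,
    GeneModel,
    LocusModel,
)

CONTIG_ID = "locus"
_SOURCE = "pcdhkit"


def write_fasta(path: str | os.PathLike, records: dict[str, str]) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _partition_attr(partition: DomainPartition) -> str:
    return "|".join(f"{l}:{s}-{e}" for l, s, e in partition.segments)


def _parse_partition(attr: str, cd_label: str) -> DomainPartition:
    segs = []
    for piece in attr.split("|"):
        label, span = piece.split(":")
        s, e = span.split("-")
        segs.append((label, int(s), int(e)))
    return DomainPartition(tuple(segs), cd_label=cd_label)


def write_gff3(path: str | os.PathLike, locus: LocusModel) -> None:
    """Write gene/mRNA/CDS features; coordinates 1-based inclusive."""
    lines = ["##gff-version 3"]

    def feat(ftype: str, start: int, end: int, strand: str, attrs: str) -> None:
        lines.append(
            f"{CONTIG_ID}\t{_SOURCE}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}"
        )

    for gm in locus.gene_models:
        exons = sorted((gm.variable_exon, *gm.constant_exons))
        gstart, gend = exons[0][0], exons[-1][1]
        attrs = (
            f"ID=gene:{gm.id};cluster_id={gm.cluster_id};"
            f"domains={_partition_attr(gm.partition)};cd_label={gm.partition.cd_label}"
        )
        feat("gene", gstart, gend, gm.strand, attrs)
        feat("mRNA", gstart, gend, gm.strand, f"ID=mrna:{gm.id};Parent=gene:{gm.id}")
        s, e = gm.variable_exon
        feat("CDS", s, e, gm.strand, f"ID=cds:{gm.id}:ve;Parent=mrna:{gm.id};part=variable")
        for k, (s, e) in enumerate(gm.constant_exons):
            feat(
                "CDS", s, e, gm.strand,
                f"ID=cds:{gm.id}:ce{k};Parent=mrna:{gm.id};part=constant",
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike, genome: str) -> list[GeneModel]:
    """Reconstruct GeneModels from a pcdhkit GFF3 plus the genome sequence."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        gid = gene.id.removeprefix("gene:")
        cd_label = gene.attributes.get("cd_label", ["CD"])[0]
        partition = _parse_partition(gene.attributes["domains"][0], cd_label)
        ve = None
        ces = []
        for cds in db.children(gene, featuretype="CDS"):
            interval = (cds.start - 1, cds.end)
            if cds.attributes["part"][0] == "variable":
                ve = interval
            else:
                ces.append(interval)
        if ve is None:
            raise ValueError(f"gene {gid} lacks a variable-exon CDS")
        ces.sort()
        strand = gene.strand
        cds_seq = genome[ve[0] : ve[1]] + "".join(genome[s:e] for s, e in ces)
        from ._codons import translate_cds

        models.append(
            GeneModel(
                id=gid,
                cluster_id=gene.attributes["cluster_id"][0],
                strand=strand,
                variable_exon=ve,
                constant_exons=tuple(ces),
                cds_sequence=cds_seq,
                protein_sequence=translate_cds(cds_seq),
                partition=partition,
            )
        )
    models.sort(key=lambda g: g.variable_exon)
    return models


def write_events(path: str | os.PathLike, events: list[ConversionEvent]) -> None:
    df = pd.DataFrame(
        [
            dict(
                donor_id=e.donor_id,
                acceptor_id=e.acceptor_id,
                tract_start_codon=e.tract_start_codon,
                tract_end_codon=e.tract_end_codon,
                time_of_event=e.time_of_event,
            )
            for e in events
        ],
        columns=[
            "donor_id", "acceptor_id", "tract_start_codon",
            "tract_end_codon", "time_of_event",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | os.PathLike) -> list[ConversionEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        ConversionEvent(
            r.donor_id, r.acceptor_id,
            int(r.tract_start_codon), int(r.tract_end_codon), int(r.time_of_event),
        )
        for r in df.itertuples()
    ]


PLACEMENT_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "uniqueness"]


def write_placements(path: str | os.PathLike, placements: list[FragmentPlacement]) -> None:
    """BED6-like TSV, one row per genomic block; blocks share the fragment name."""
    rows = []
    for p in placements:
        flag = "unique" if p.unique else "multi"
        for s, e in p.blocks:
            rows.append((CONTIG_ID, s, e, p.name, 0, "+", flag))
    pd.DataFrame(rows, columns=PLACEMENT_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_placements(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a placement BED-like file, raising with the line number on error."""
    df = pd.read_csv(path, sep="\t", header=None, names=PLACEMENT_COLUMNS, dtype=str)
    for i, row in enumerate(df.itertuples(), start=1):
        try:
            s, e = int(row.start), int(row.end)
            if s < 0 or e <= s:
                raise ValueError("empty or negative interval")
            if row.uniqueness not in ("unique", "multi"):
                raise ValueError(f"bad uniqueness flag {row.uniqueness!r}")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed placement record at line {i}: {exc}") from exc
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_motif_truth(path: str | os.PathLike, truth: list[tuple[str, int]]) -> None:
    pd.DataFrame(truth, columns=["gene_id", "offset_from_atg"]).to_csv(
        path, sep="\t", index=False
    )
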