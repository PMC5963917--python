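"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, GTF via gffutils (ensembl dialect; only gene_id,
transcript_id, transcript_support_level and gene_biotype attributes are
interpreted), BED6/BED12 and TSV tables via pandas.  Internal coordinates
are 0-based half-open; GTF is converted from 1-based closed on the way in
and out.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import FlatFeature, Gene, GenomeAnnotation, Transcript


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(chromosomes: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GTF

def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Ensembl-dialect GTF with gene/transcript/exon/CDS lines."""
    lines = []

    def attrs(**kv) -> str:
        return " ".join(f'{k} "{v}";' for k, v in kv.items() if v is not None)

    for gene in annotation.genes:
        gs, ge = gene.span
        lines.append(
            "\t".join([gene.chrom, "clipflow", "gene", str(gs + 1), str(ge), ".",
                       gene.strand, ".", attrs(gene_id=gene.gene_id, gene_biotype=gene.biotype)])
        )
        for tx in gene.transcripts:
            ts, te = tx.span
            a = attrs(gene_id=gene.gene_id, transcript_id=tx.tx_id,
                      transcript_support_level=tx.tsl, gene_biotype=gene.biotype)
            lines.append("\t".join([gene.chrom, "clipflow", "transcript",
                                    str(ts + 1), str(te), ".", gene.strand, ".", a]))
            for s, e in tx.exons:
                lines.append("\t".join([gene.chrom, "clipflow", "exon",
                                        str(s + 1), str(e), ".", gene.strand, ".", a]))
            if tx.cds is not None:
                cs, ce = tx.cds
                for s, e in tx.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ < oe:
                        lines.append("\t".join([gene.chrom, "clipflow", "CDS",
                                                str(os_ + 1), str(oe), ".", gene.strand,
                                                ".", a]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path, chromosomes: dict[str, str]) -> GenomeAnnotation:
    """Parse a GTF into the internal model (needs sequences for validation)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        transcripts: list[Transcript] = []
        for t in db.children(g, featuretype="transcript"):
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            )
            cds_parts = [(f.start - 1, f.end) for f in db.children(t, featuretype="CDS")]
            cds = None
            if cds_parts:
                cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts))
            tsl = int(t.attributes.get("transcript_support_level", ["1"])[0])
            transcripts.append(Transcript(t.id, exons, tsl=tsl, cds=cds))
        biotype = g.attributes.get("gene_biotype", ["coding"])[0]
        genes.append(Gene(g.id, g.seqid, g.strand, transcripts, biotype=biotype))
    ann = GenomeAnnotation(chromosomes, genes)
    ann.validate()
    return ann


def read_bed12(path: str | Path, chromosomes: dict[str, str]) -> GenomeAnnotation:
    """BED12 transcript models; one gene per BED name (no TSL/CDS info)."""
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    genes = []
    for _, row in df.iterrows():
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = [(row.start + s, row.start + s + sz) for s, sz in zip(starts, sizes)]
        cds = None
        if int(row.thickEnd) > int(row.thickStart):
            cds = (int(row.thickStart), int(row.thickEnd))
        tx = Transcript(f"{row['name']}.t1", exons, tsl=1, cds=cds)
        genes.append(Gene(str(row["name"]), row.chrom, row.strand, [tx]))
    ann = GenomeAnnotation(chromosomes, genes)
    ann.validate()
    return ann


# ---------------------------------------------------------------- BED6

def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with chrom/start/end/name/score/strand columns."""
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        comment="#",
    )


# ---------------------------------------------------------------- flat features

def write_flat_features(features: list[FlatFeature], path: str | Path) -> None:
    rows = [
        (f.feature_id, f.gene_id, f.kind, f.chrom, f.start, f.end, f.strand)
        for f in features
    ]
    pd.DataFrame(
        rows, columns=["feature_id", "gene_id", "kind", "chrom", "start", "end", "strand"]
    ).to_csv(path, sep="\t", index=False)


def read_flat_features(path: str | Path) -> list[FlatFeature]:
    df = pd.read_csv(path, sep="\t")
    return [
        FlatFeature(r.feature_id, r.gene_id, r.kind, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------- TSV tables

def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
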