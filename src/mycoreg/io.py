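"""File I/O: FASTA via Biopython, GFF3 and TSV tables via pandas."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "mycoreg") -> None:
    """Emit gene features (1-based inclusive coordinates, strand respected)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']}"
            fh.write("\t".join(map(str, [
                g["chromosome"], source, "gene", int(g["start"]), int(g["end"]),
                ".", g["strand"], ".", attrs,
            ])) + "\n")


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Gene-model table (gene_id, chromosome, ordinal, start, end, strand).

    Reads gene-type features from a GFF3 file; the ordinal position is the
    rank of the gene by start coordinate within its chromosome, the gene
    order used for cluster calling.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", names=GFF_COLUMNS, header=None)
    genes = raw[raw["type"] == "gene"].copy()
    genes["gene_id"] = genes["attributes"].str.extract(r"ID=([^;]+)")
    genes = genes.rename(columns={"seqid": "chromosome"})
    genes = genes.sort_values(["chromosome", "start"]).reset_index(drop=True)
    genes["ordinal"] = genes.groupby("chromosome").cumcount()
    return genes[["gene_id", "chromosome", "ordinal", "start", "end", "strand"]]


def write_bed(windows: Iterable, path: str | Path) -> None:
    """0-based half-open BED for promoter windows."""
    with open(path, "w") as fh:
        for w in windows:
            chrom, start, end, name, strand = w.to_bed()
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
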