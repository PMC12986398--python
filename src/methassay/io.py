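"""File I/O: FASTA, BED6 and the TSV tables used by the statistics layer."""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import CpGIsland, GenomicLocus

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed6",
    "write_bed6",
    "islands_to_bed",
    "read_locus",
    "write_locus",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (multi-record) FASTA file into {name: sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, records: dict[str, str]) -> None:
    """Write {name: sequence} as wrapped (60-column) FASTA."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 file (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def write_bed6(path: str | os.PathLike, df: pd.DataFrame) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def islands_to_bed(
    islands: Iterable[CpGIsland], chrom: str
) -> pd.DataFrame:
    """Detected islands as a BED6 frame (score = CpG count)."""
    rows = [
        {
            "chrom": chrom,
            "start": isl.start,
            "end": isl.end,
            "name": f"CGI_{i + 1}",
            "score": isl.n_cpg,
            "strand": "+",
        }
        for i, isl in enumerate(islands)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def read_locus(
    fasta_path: str | os.PathLike, bed_path: str | os.PathLike | None = None
) -> GenomicLocus:
    """Build a GenomicLocus from a single-record FASTA plus an optional BED6
    of TSS annotations (first record = primary TSS, others become isoforms)."""
    records = read_fasta(fasta_path)
    if len(records) != 1:
        raise ValueError("locus FASTA must contain exactly one record")
    (name, seq), = records.items()
    tss, strand, isoforms = 0, "+", []
    if bed_path is not None:
        bed = read_bed6(bed_path)
        tss_rows = bed[bed["name"].str.startswith("TSS")]
        if tss_rows.empty:
            raise ValueError("BED annotation has no TSS record")
        first = tss_rows.iloc[0]
        tss, strand = int(first["start"]), str(first["strand"])
        isoforms = [
            (str(r["name"]), int(r["start"])) for _, r in tss_rows.iloc[1:].iterrows()
        ]
    return GenomicLocus(name=name, sequence=seq, tss=tss, strand=strand, isoforms=isoforms)


def write_locus(locus: GenomicLocus, fasta_path, bed_path) -> None:
    """Write a locus as FASTA + BED6 TSS annotation (inverse of read_locus)."""
    write_fasta(fasta_path, {locus.name: locus.sequence})
    rows = [
        {
            "chrom": locus.name,
            "start": locus.tss,
            "end": locus.tss + 1,
            "name": "TSS",
            "score": 0,
            "strand": locus.strand,
        }
    ]
    for iso_name, iso_tss in locus.isoforms:
        rows.append(
            {
                "chrom": locus.name,
                "start": iso_tss,
                "end": iso_tss + 1,
                "name": f"TSS_{iso_name}",
                "score": 0,
                "strand": locus.strand,
            }
        )
    write_bed6(bed_path, pd.DataFrame(rows))
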