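"""Readers and writers for the plain-text formats the pipeline consumes.

Tag-alignment collections are pandas DataFrames with the columns in
:data:`TAG_COLUMNS`; positions are 0-based 5'-most mapped bases. Supported
on disk:

* tag alignments — SAM/BAM (via pysam; read1/read2 flags give the end
  label, ``unique`` means mapping quality >= 1) or a 6-column BED dialect
  ``chrom  start  end  read_id/<1|2>  mapq  strand``;
* interacting sites — BED5 ``chrom start end site_id support``;
* peaks — BED/narrowPeak (first three columns used);
* genomes and reads — FASTA / FASTQ via Biopython.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomicInterval

TAG_COLUMNS = ["read_id", "end", "chrom", "pos", "strand", "unique"]

_END_SUFFIX = {"forward": "1", "reverse": "2"}
_SUFFIX_END = {"1": "forward", "2": "reverse"}


def tags_frame(records: Iterable[tuple]) -> pd.DataFrame:
    """Build a tag-alignment frame from (read_id, end, chrom, pos, strand, unique) tuples."""
    df = pd.DataFrame(list(records), columns=TAG_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    df["unique"] = df["unique"].astype(bool)
    return df


def read_tags_bed(path: str | Path) -> pd.DataFrame:
    """Read tag alignments from the 6-column BED dialect."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, _end, name, mapq, strand = line.split("\t")[:6]
        read_id, _, suffix = name.rpartition("/")
        rows.append(
            (read_id, _SUFFIX_END[suffix], chrom, int(start), strand, int(mapq) >= 1)
        )
    return tags_frame(rows)


def write_tags_bed(tags: pd.DataFrame, path: str | Path, tag_length: int = 20) -> None:
    with open(path, "w") as fh:
        for row in tags.itertuples(index=False):
            name = f"{row.read_id}/{_END_SUFFIX[row.end]}"
            mapq = 1 if row.unique else 0
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + tag_length}\t{name}\t{mapq}\t{row.strand}\n"
            )


def read_tags_sam(path: str | Path) -> pd.DataFrame:
    """Read tag alignments from SAM/BAM; pysam reports 0-based positions."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            end = "reverse" if aln.is_read2 else "forward"
            strand = "-" if aln.is_reverse else "+"
            rows.append(
                (
                    aln.query_name,
                    end,
                    aln.reference_name,
                    aln.reference_start,
                    strand,
                    (aln.mapping_quality or 0) >= 1,
                )
            )
    return tags_frame(rows)


def read_tag_alignments(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .sam/.bam via pysam, otherwise the BED dialect."""
    suffix = Path(path).suffix.lower()
    if suffix in {".sam", ".bam", ".cram"}:
        return read_tags_sam(path)
    return read_tags_bed(path)


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    """Write interacting sites as BED5 (chrom, start, end, site_id, support)."""
    with open(path, "w") as fh:
        for i, row in enumerate(sites.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tsite_{i}\t{row.support}\n")


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        support = int(fields[4]) if len(fields) > 4 else 1
        rows.append((chrom, start, end, (start + end - 1) // 2, support))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "rep_pos", "support"])


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read plain BED/narrowPeak intervals (first three columns)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
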