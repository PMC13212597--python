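"""Readers/writers for the plain-text formats the pipeline exchanges.

BED is parsed as 0-based half-open. RepeatMasker-style tables are 1-based
inclusive and converted on read. All readers accept plain or gzip files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Blacklist, GeneModel, GenomeSpec, Interval, TEAnnotation


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


# ---------------------------------------------------------------- BED


def read_bed(path, genome: GenomeSpec | None = None) -> list[Interval]:
    """Read a 3-6 column BED file into intervals.

    Column 6, when present, supplies the strand. Intervals are validated
    against ``genome`` when given.
    """
    out: list[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 tab-separated fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinates: {exc}") from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
            try:
                iv = Interval(chrom, start, end, strand)
                if genome is not None:
                    genome.validate_interval(iv)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            out.append(iv)
    return out


def write_bed(path, intervals: Iterable[Interval], names: Sequence[str] | None = None) -> None:
    intervals = list(intervals)
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '.'}\n")


def read_blacklist(path, genome: GenomeSpec | None = None) -> Blacklist:
    return Blacklist(read_bed(path, genome))


# ------------------------------------------------- RepeatMasker-style TE table


TE_COLUMNS = ["chrom", "begin", "end", "strand", "subfamily", "subclass"]


def read_repeatmasker_table(path, genome: GenomeSpec | None = None) -> TEAnnotation:
    """Read a RepeatMasker-style TSV (1-based inclusive coordinates).

    Expected header columns: chrom, begin, end, strand, subfamily, subclass.
    Coordinates are converted to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            iv = Interval(str(row.chrom), int(row.begin) - 1, int(row.end),
                          row.strand if row.strand in {"+", "-"} else ".")
            if genome is not None:
                genome.validate_interval(iv)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        records.append((iv, str(row.subclass), str(row.subfamily)))
    return TEAnnotation(records)


def write_repeatmasker_table(path, te: TEAnnotation) -> None:
    rows = [
        {
            "chrom": iv.chrom,
            "begin": iv.start + 1,
            "end": iv.end,
            "strand": iv.strand if iv.strand != "." else "+",
            "subfamily": sf,
            "subclass": sc,
        }
        for iv, sc, sf in te
    ]
    pd.DataFrame(rows, columns=TE_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- gene table


def read_gene_table(path, genome: GenomeSpec | None = None) -> list[GeneModel]:
    """TSV with header gene_id, chrom, tss, tes, strand (0-based positions)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "tss", "tes", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    genes = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            g = GeneModel(str(row.gene_id), str(row.chrom), int(row.tss),
                          int(row.tes), str(row.strand))
            if genome is not None:
                genome.validate_interval(g.body)
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
        genes.append(g)
    return genes


def write_gene_table(path, genes: Iterable[GeneModel]) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss,
             "tes": g.tes, "strand": g.strand}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- SNP table


def read_snp_table(path) -> pd.DataFrame:
    """TSV with header chrom, pos (0-based), maternal, paternal."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "maternal", "paternal"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[required]


def write_snp_table(path, snps: pd.DataFrame) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_site_observations(path) -> pd.DataFrame:
    """Per-read site observations: read_id, chrom, pos, base (base or DEL)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "base": str})
    required = ["read_id", "chrom", "pos", "base"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[required]


# ------------------------------------------------------------- methylation


METH_COLUMNS = ["chrom", "pos", "strand", "context", "methylated"]


def read_meth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[METH_COLUMNS]


def write_meth_table(path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- FASTA


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
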