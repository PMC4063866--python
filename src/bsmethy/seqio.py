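"""Readers, writers and the shared sequence / coordinate conventions.

Coordinate convention
---------------------
Every file this package reads or writes uses **1-based, inclusive**
positions on the Watson (forward) strand of the reference.  Internally
most code works with 0-based offsets into numpy arrays; the conversion
happens only at file boundaries.  Cytosines on the Crick strand are
reported at the Watson coordinate of the paired guanine, so both strands
share one coordinate axis.

Quality scores are Phred+33 throughout; no autodetection is attempted.

BED input follows the BED standard (0-based, half-open) and is converted
to 1-based inclusive on read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

WATSON = "W"
CRICK = "C"

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """An ordered collection of named chromosome sequences.

    Sequences are uppercase strings over {A,C,G,T,N}.  Names must be
    unique and non-empty, sequences non-empty.
    """

    def __init__(self, chromosomes: dict[str, str]):
        self.chromosomes: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if not name:
                raise ValueError("empty chromosome name")
            if name in self.chromosomes:
                raise ValueError(f"duplicate chromosome name: {name}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name}")
            if set(seq) - _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"illegal characters in {name}: {bad}")
            self.chromosomes[name] = seq

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes.items()}

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.chromosomes == other.chromosomes


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities.

    ``mate`` is 0 for single-end reads, 1 or 2 for paired-end mates.
    """

    id: str
    bases: str
    quals: np.ndarray
    mate: int = 0

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} quals"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """A uniquely placed read in Watson coordinates.

    ``start`` is the 1-based leftmost Watson position of the read.
    ``bases``/``quals`` are the original (pre-conversion) read exactly as
    sequenced; orientation back onto Watson coordinates is a function of
    (strand, mate) and is handled by the pileup code.
    """

    read_id: str
    chrom: str
    start: int
    strand: str  # WATSON or CRICK: strand of origin
    mismatches: int
    bases: str
    quals: np.ndarray
    mate: int = 0
    mate_start: Optional[int] = None
    insert_size: Optional[int] = None

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if self.start < 1:
            raise ValueError(f"record {self.read_id}: start {self.start} < 1")
        if self.strand not in (WATSON, CRICK):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost position."""
        return self.start + len(self.bases) - 1


#: Column layout of a per-cytosine methylation-call table.
CALL_COLUMNS = ["chrom", "pos", "strand", "context3", "context_class", "c_count", "t_count"]

#: Column layout of a region table (1-based inclusive coordinates).
REGION_COLUMNS = ["chrom", "start", "end", "label"]


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context3": pd.Series(dtype=str),
            "context_class": pd.Series(dtype=str),
            "c_count": pd.Series(dtype=np.int64),
            "t_count": pd.Series(dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Lowercase bases are folded to uppercase; duplicate names, empty
    records and characters outside {A,C,G,T,N} raise ``ValueError``.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name: {rec.id}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(chroms)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)
# ---------------------------------------------------------------------------

def decode_quals(qual_string: str) -> np.ndarray:
    return np.frombuffer(qual_string.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33


def encode_quals(quals: np.ndarray) -> str:
    return (np.asarray(quals, dtype=np.int16) + 33).astype(np.uint8).tobytes().decode("ascii")


def read_fastq(path, mate: int = 0) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus.startswith("+") or not qual:
                raise ValueError(f"truncated FASTQ record near {header!r} in {path}")
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ header {header!r} in {path}")
            if len(seq) != len(qual):
                raise ValueError(f"base/quality length mismatch for {header!r}")
            yield Read(header[1:].split()[0], seq.upper(), decode_quals(qual), mate=mate)


def read_fastq_paired(path1, path2) -> Iterator[tuple[Read, Read]]:
    """Yield mate pairs from two FASTQ files in lockstep."""
    it1 = read_fastq(path1, mate=1)
    it2 = read_fastq(path2, mate=2)
    for r1, r2 in itertools.zip_longest(it1, it2):
        if r1 is None or r2 is None:
            raise ValueError("paired FASTQ files have unequal record counts")
        yield r1, r2


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{encode_quals(r.quals)}\n")


# ---------------------------------------------------------------------------
# .bsalign: uniquely aligned reads, tab separated
# ---------------------------------------------------------------------------

BSALIGN_COLUMNS = [
    "read_id",
    "chrom",
    "start",
    "strand",
    "mate",
    "mismatches",
    "bases",
    "quals",
    "mate_start",
    "insert_size",
]


def write_bsalign(records: Iterable[AlignmentRecord], path) -> None:
    """Write aligned reads as a ``.bsalign`` TSV.

    One line per read, sorted by (chrom, start, read_id, mate).  Missing
    mate_start / insert_size (single-end data) are written as ``.``.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.read_id, r.mate))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BSALIGN_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.chrom,
                        str(r.start),
                        r.strand,
                        str(r.mate),
                        str(r.mismatches),
                        r.bases,
                        encode_quals(r.quals),
                        "." if r.mate_start is None else str(r.mate_start),
                        "." if r.insert_size is None else str(r.insert_size),
                    ]
                )
                + "\n"
            )


def read_bsalign(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                AlignmentRecord(
                    read_id=f[0],
                    chrom=f[1],
                    start=int(f[2]),
                    strand=f[3],
                    mate=int(f[4]),
                    mismatches=int(f[5]),
                    bases=f[6],
                    quals=decode_quals(f[7]),
                    mate_start=None if f[8] == "." else int(f[8]),
                    insert_size=None if f[9] == "." else int(f[9]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Methylation-call tables
# ---------------------------------------------------------------------------

def write_methcalls(calls: pd.DataFrame, path_watson, path_crick) -> None:
    """Write per-cytosine calls to separate Watson and Crick TSV files.

    Both files are always written, sorted by (chrom, pos), even when one
    strand has no calls.
    """
    cols = ["chrom", "pos", "context3", "context_class", "c_count", "t_count"]
    for strand, path in ((WATSON, path_watson), (CRICK, path_crick)):
        sub = calls[calls["strand"] == strand]
        sub = sub.sort_values(["chrom", "pos"])[cols]
        sub.to_csv(path, sep="\t", index=False)


def read_methcalls(path_watson, path_crick) -> pd.DataFrame:
    parts = []
    for strand, path in ((WATSON, path_watson), (CRICK, path_crick)):
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["strand"] = strand
        parts.append(df)
    out = pd.concat(parts, ignore_index=True)
    return out[CALL_COLUMNS]


# ---------------------------------------------------------------------------
# BED and array beta tables
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a 3- or 6-column BED file into a 1-based inclusive region table.

    Returns columns chrom, start, end, label and, when present, strand.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"BED line {i + 1}: fewer than 3 columns")
            row = {
                "chrom": f[0],
                "start": int(f[1]) + 1,  # 0-based half-open -> 1-based inclusive
                "end": int(f[2]),
                "label": f[3] if len(f) >= 4 else f"region{i + 1}",
            }
            if len(f) >= 6:
                row["strand"] = f[5]
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) and (df["start"] > df["end"]).any():
        raise ValueError("BED record with start > end after conversion")
    return df


def write_bed(regions: pd.DataFrame, path, score_col: Optional[str] = None) -> None:
    """Write a 1-based inclusive region table as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fields = [r["chrom"], str(int(r["start"]) - 1), str(int(r["end"])), str(r.get("label", "."))]
            if score_col is not None:
                fields.append(str(r[score_col]))
                fields.append(str(r.get("strand", "+")))
            fh.write("\t".join(fields) + "\n")


def read_beta_table(path) -> pd.DataFrame:
    """Read an array beta-value table: chrom, 1-based CpG position, beta."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = {"chrom", "pos", "beta"}
    if not expected.issubset(df.columns):
        raise ValueError(f"beta table must have columns {sorted(expected)}")
    if ((df["beta"] < 0) | (df["beta"] > 1)).any():
        raise ValueError("beta values outside [0, 1]")
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) in beta table")
    return df


def write_beta_table(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "beta"]].to_csv(path, sep="\t", index=False)
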