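"""Per-cytosine methylation calling and methylation-density computation.

At every reference cytosine the number of sequenced Cs (methylated) and
Ts (unmethylated, i.e. bisulfite converted) is counted.  The methylation
density of a set of cytosines is the pooled percentage

    MD = 100 * sum_i C_i / sum_i (C_i + T_i)

over the selected sites; with a single site this is the per-base
methylation level.  Zero total depth yields a missing value, never 0.

Read bases other than C or T over a reference cytosine (sequencing
errors, variants) are ignored: MD is defined purely on C and T counts.

Strand handling: Watson-strand cytosines are informed only by
Watson-origin fragments; Crick-strand cytosines (reported at the Watson
coordinate of the paired G) only by Crick-origin fragments.  Within one
paired-end fragment whose mates overlap, each overlapping position is
counted once, taking the mate with the higher base quality (ties go to
mate 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import CALL_COLUMNS, CRICK, WATSON, AlignmentRecord, Genome, revcomp


@dataclass
class MDValue:
    """A pooled methylation density: percentage, site count, total depth.

    ``value`` is None when no site has coverage.
    """

    value: Optional[float]
    n_sites: int
    depth: int


class PileupCounts:
    """Per-position C/T counts for both strands of every chromosome.

    Arrays are indexed by 0-based Watson position; Crick-strand cytosines
    live at the Watson position of their G.
    """

    def __init__(self, genome: Genome):
        self.genome = genome
        self.c_w: dict[str, np.ndarray] = {}
        self.t_w: dict[str, np.ndarray] = {}
        self.c_c: dict[str, np.ndarray] = {}
        self.t_c: dict[str, np.ndarray] = {}
        self._is_c: dict[str, np.ndarray] = {}
        self._is_g: dict[str, np.ndarray] = {}
        for name, seq in genome.chromosomes.items():
            n = len(seq)
            for store in (self.c_w, self.t_w, self.c_c, self.t_c):
                store[name] = np.zeros(n, dtype=np.int64)
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            self._is_c[name] = arr == ord("C")
            self._is_g[name] = arr == ord("G")


def orient_to_watson(record: AlignmentRecord) -> tuple[str, np.ndarray]:
    """Return the read's bases and quals laid out along ascending Watson
    coordinates starting at ``record.start``.

    Watson-origin mate 2 and Crick-origin mate 1 are sequenced
    antiparallel to Watson and are reverse complemented.
    """
    needs_rc = (record.strand == WATSON and record.mate == 2) or (
        record.strand == CRICK and record.mate == 1
    )
    if needs_rc:
        return revcomp(record.bases), record.quals[::-1]
    return record.bases, record.quals


def pileup(records: Iterable[AlignmentRecord], genome: Genome) -> PileupCounts:
    """Accumulate C/T counts over reference cytosines from aligned reads.

    Raises ``ValueError`` for a record extending past its chromosome end.
    """
    counts = PileupCounts(genome)
    frags: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        frags.setdefault(rec.read_id, []).append(rec)
    for recs in frags.values():
        contribs: list[tuple[AlignmentRecord, str, np.ndarray, np.ndarray]] = []
        for rec in recs:
            n = len(genome[rec.chrom])
            if rec.end > n:
                raise ValueError(
                    f"record {rec.read_id} extends past end of {rec.chrom} ({rec.end} > {n})"
                )
            bases, quals = orient_to_watson(rec)
            mask = np.ones(len(bases), dtype=bool)
            contribs.append((rec, bases, quals, mask))
        if len(contribs) == 2:
            _mask_fragment_overlap(contribs)
        for rec, bases, quals, mask in contribs:
            _accumulate(counts, rec, bases, mask)
    return counts


def _mask_fragment_overlap(contribs) -> None:
    """For an overlapping mate pair, keep each overlapped position on the
    mate with the higher base quality (ties -> mate 1)."""
    contribs.sort(key=lambda t: t[0].mate)
    (r1, b1, q1, m1), (r2, b2, q2, m2) = contribs
    lo = max(r1.start, r2.start)
    hi = min(r1.end, r2.end)
    if lo > hi or r1.chrom != r2.chrom:
        return
    s1, s2 = lo - r1.start, lo - r2.start
    n = hi - lo + 1
    use2 = q2[s2 : s2 + n] > q1[s1 : s1 + n]
    m1[s1 : s1 + n] = ~use2
    m2[s2 : s2 + n] = use2


def _accumulate(counts: PileupCounts, rec: AlignmentRecord, bases: str, mask: np.ndarray) -> None:
    barr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    start0 = rec.start - 1
    span = slice(start0, start0 + len(barr))
    if rec.strand == WATSON:
        site = counts._is_c[rec.chrom][span]
        counts.c_w[rec.chrom][span] += site & mask & (barr == ord("C"))
        counts.t_w[rec.chrom][span] += site & mask & (barr == ord("T"))
    else:
        # Crick cytosines pair with Watson Gs; in Watson orientation a
        # methylated Crick C reads as G, a converted one as A.
        site = counts._is_g[rec.chrom][span]
        counts.c_c[rec.chrom][span] += site & mask & (barr == ord("G"))
        counts.t_c[rec.chrom][span] += site & mask & (barr == ord("A"))


def assign_context(genome: Genome, chrom: str, pos: int, strand: str) -> tuple[str, str]:
    """Trinucleotide context of the cytosine at 1-based ``pos``, read 5'→3'
    on its own strand, and its class (CpG / CHG / CHH).

    Positions within 2 bp of the chromosome end pad with N; a padded
    context classifies as CHH unless the CG dinucleotide is complete.
    """
    seq = genome[chrom]
    i = pos - 1
    if strand == WATSON:
        if seq[i] != "C":
            raise ValueError(f"{chrom}:{pos} ({strand}) is not a cytosine")
        ctx = seq[i : i + 3]
    else:
        if seq[i] != "G":
            raise ValueError(f"{chrom}:{pos} ({strand}) is not a cytosine")
        ctx = revcomp(seq[max(0, i - 2) : i + 1])
    ctx = ctx + "N" * (3 - len(ctx))
    return ctx, classify_context(ctx)


def classify_context(context3: str) -> str:
    if context3[1] == "G":
        return "CpG"
    if context3[2] == "G":
        return "CHG"
    return "CHH"


def calls_from_pileup(counts: PileupCounts, min_depth: int = 1) -> pd.DataFrame:
    """Tabulate covered cytosines as a call table (contexts annotated).

    Only sites with depth >= ``min_depth`` are reported.
    """
    genome = counts.genome
    frames = []
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for strand, c_arr, t_arr, is_site in (
            (WATSON, counts.c_w[chrom], counts.t_w[chrom], counts._is_c[chrom]),
            (CRICK, counts.c_c[chrom], counts.t_c[chrom], counts._is_g[chrom]),
        ):
            depth = c_arr + t_arr
            idx = np.nonzero(is_site & (depth >= min_depth))[0]
            if len(idx) == 0:
                continue
            ctx3 = _contexts_vectorised(arr, idx, strand)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": strand,
                        "context3": ctx3,
                        "context_class": [classify_context(c) for c in ctx3],
                        "c_count": c_arr[idx],
                        "t_count": t_arr[idx],
                    }
                )
            )
    if not frames:
        from .seqio import empty_calls

        return empty_calls()
    return pd.concat(frames, ignore_index=True)[CALL_COLUMNS]


def _contexts_vectorised(arr: np.ndarray, idx: np.ndarray, strand: str) -> list[str]:
    n = len(arr)
    padded = np.concatenate([np.full(2, ord("N"), np.uint8), arr, np.full(2, ord("N"), np.uint8)])
    if strand == WATSON:
        tri = np.stack([padded[idx + 2], padded[idx + 3], padded[idx + 4]], axis=1)
        return [t.tobytes().decode("ascii") for t in tri.astype(np.uint8)]
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    tri = np.stack([comp[padded[idx + 2]], comp[padded[idx + 1]], comp[padded[idx]]], axis=1)
    return [t.tobytes().decode("ascii") for t in tri.astype(np.uint8)]


def methylation_density(
    calls: pd.DataFrame,
    region: Optional[tuple[str, int, int]] = None,
    strand: Optional[str] = None,
    context: Optional[str] = None,
) -> MDValue:
    """Pooled MD over the selected cytosine calls.

    ``region`` is (chrom, start, end), 1-based inclusive; ``context``
    selects a context class (CpG/CHG/CHH) or an exact trinucleotide.
    """
    sub = calls
    if region is not None:
        chrom, start, end = region
        sub = sub[(sub["chrom"] == chrom) & (sub["pos"] >= start) & (sub["pos"] <= end)]
    if strand is not None:
        sub = sub[sub["strand"] == strand]
    if context is not None:
        col = "context_class" if context in ("CpG", "CHG", "CHH") else "context3"
        sub = sub[sub[col] == context]
    c = int(sub["c_count"].sum())
    t = int(sub["t_count"].sum())
    depth = c + t
    if depth == 0:
        return MDValue(None, len(sub), 0)
    return MDValue(100.0 * c / depth, len(sub), depth)


def conversion_rate(calls: pd.DataFrame, spike_chrom: str) -> Optional[float]:
    """Bisulfite conversion rate from an unmethylated spike-in chromosome:
    100 * sum(T) / sum(C + T) over every cytosine of the spike.  Returns
    None when the spike is absent or uncovered.
    """
    sub = calls[calls["chrom"] == spike_chrom]
    c = int(sub["c_count"].sum())
    t = int(sub["t_count"].sum())
    if c + t == 0:
        return None
    return 100.0 * t / (c + t)
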