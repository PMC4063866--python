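"""Bisulfite-aware read alignment against C-to-T converted references.

Strategy
--------
Bisulfite treatment converts unmethylated C to T, so a converted read no
longer matches the reference exactly.  Alignment is made methylation
neutral by collapsing the C/T distinction on both sides: every C in the
read is replaced by T in silico, and two C-depleted references are built
— the Watson strand with C→T, and the Crick strand (reverse complement
of Watson) with C→T.  A read pair's mate 1 is queried as-is; mate 2 is
sequenced from the complementary strand of the converted molecule, so
its reverse complement is what carries the original C/T states and is
the sequence that is queried.

Hits are found with an exact k-mer seed table plus full Hamming-distance
verification (substitutions only, no indels).  For a read of length L
with at most ``max_mismatches`` = q mismatches, q+1 disjoint seeds
guarantee at least one exact seed (pigeonhole); reads too short for
disjoint seeding fall back to a vectorised scan over every offset, so
the hit set is always complete.

Filters applied after hit enumeration, in order: best-stratum
uniqueness (unique at the minimum mismatch count), removal of reads that
align to both strands at that minimum, and finally fragment-level
duplicate removal.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from .seqio import CRICK, WATSON, AlignmentRecord, Genome, Read, revcomp

_CT_TABLE = str.maketrans("C", "T")


def convert_read_ct(read: Read) -> Read:
    """Replace every C by T; id, qualities and other bases are untouched."""
    return Read(read.id, read.bases.translate(_CT_TABLE), read.quals, mate=read.mate)


@dataclass
class AlignParams:
    """Alignment and trimming parameters.

    max_mismatches : maximum Hamming distance per read (default 2)
    insert_min/max : accepted outer insert size range for pairs (50..600)
    qual_trim_threshold : 3' bases below this Phred score are stripped
    adapter : optional adapter sequence trimmed from the 3' end
    seed_len : exact-seed length for the k-mer index
    min_read_len : reads shorter than this after trimming are discarded
    trim_5prime : also strip low-quality bases from the 5' end (off by
        default; standard libraries only degrade at the 3' end)
    """

    max_mismatches: int = 2
    insert_min: int = 50
    insert_max: int = 600
    qual_trim_threshold: int = 5
    adapter: Optional[str] = None
    seed_len: int = 20
    min_read_len: int = 20
    trim_5prime: bool = False

    def __post_init__(self):
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min > insert_max")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches < 0")


class Hit(NamedTuple):
    """One candidate placement, in Watson coordinates (0-based leftmost)."""

    strand: str
    chrom: str
    start0: int
    mismatches: int


class Outcome(enum.Enum):
    KEPT = "kept"
    UNMAPPED = "unmapped"
    MULTI = "multi"
    BOTH_STRAND = "both_strand"


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def _find_adapter(bases: str, adapter: str, min_overlap: int = 3) -> Optional[int]:
    """Leftmost position where a suffix of the read matches a prefix of the
    adapter (overlap >= min_overlap, <= 1 mismatch per 10 overlap bases)."""
    n = len(bases)
    best = None
    for start in range(0, n - min_overlap + 1):
        overlap = min(n - start, len(adapter))
        allowed = overlap // 10
        mism = sum(1 for a, b in zip(bases[start : start + overlap], adapter) if a != b)
        if mism <= allowed:
            best = start
            break
    return best


def trim_read(read: Read, params: AlignParams) -> Read:
    """Trim adapter then low-quality 3' bases; may return an empty read."""
    bases, quals = read.bases, read.quals
    if params.adapter:
        pos = _find_adapter(bases, params.adapter)
        if pos is not None:
            bases, quals = bases[:pos], quals[:pos]
    end = len(bases)
    while end > 0 and quals[end - 1] < params.qual_trim_threshold:
        end -= 1
    start = 0
    if params.trim_5prime:
        while start < end and quals[start] < params.qual_trim_threshold:
            start += 1
    return Read(read.id, bases[start:end], quals[start:end], mate=read.mate)


# ---------------------------------------------------------------------------
# Converted references and seed index
# ---------------------------------------------------------------------------

def _to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class ConvertedReference:
    """Per-chromosome C-depleted Watson and Crick sequences.

    ``crick_ct[c]`` is the reverse complement of the Watson sequence with
    every C replaced by T; positions in it are Crick offsets and are
    translated back to Watson coordinates when hits are reported.
    """

    def __init__(self, genome: Genome):
        self.lengths = genome.lengths()
        self.watson_ct: dict[str, np.ndarray] = {}
        self.crick_ct: dict[str, np.ndarray] = {}
        for name, seq in genome.chromosomes.items():
            self.watson_ct[name] = _to_u8(seq.translate(_CT_TABLE))
            self.crick_ct[name] = _to_u8(revcomp(seq).translate(_CT_TABLE))

    def ref(self, chrom: str, strand: str) -> np.ndarray:
        return self.watson_ct[chrom] if strand == WATSON else self.crick_ct[chrom]


class SeedIndex:
    """Exact-substring index over both converted references.

    Contract: ``lookup(chrom, strand, seed)`` returns every start offset
    at which ``seed`` occurs in that converted sequence (verifiable
    against a naive scan).  Backed by a k-mer hash table; the k-mer
    length equals ``AlignParams.seed_len``.
    """

    def __init__(self, genome: Genome, seed_len: int = 20):
        self.seed_len = seed_len
        self.converted = ConvertedReference(genome)
        self._tables: dict[tuple[str, str], dict[bytes, np.ndarray]] = {}
        for chrom in genome.names():
            for strand in (WATSON, CRICK):
                seq = self.converted.ref(chrom, strand).tobytes()
                table: dict[bytes, list[int]] = defaultdict(list)
                for i in range(0, len(seq) - seed_len + 1):
                    table[seq[i : i + seed_len]].append(i)
                self._tables[(chrom, strand)] = {
                    k: np.asarray(v, dtype=np.int64) for k, v in table.items()
                }

    def chroms(self) -> list[str]:
        return list(self.converted.lengths)

    def lookup(self, chrom: str, strand: str, seed: bytes) -> np.ndarray:
        return self._tables[(chrom, strand)].get(seed, _EMPTY_I64)


_EMPTY_I64 = np.empty(0, dtype=np.int64)


def build_converted_references(genome: Genome) -> ConvertedReference:
    return ConvertedReference(genome)


def build_index(genome: Genome, params: AlignParams | None = None) -> SeedIndex:
    params = params or AlignParams()
    return SeedIndex(genome, seed_len=params.seed_len)


# ---------------------------------------------------------------------------
# Hit enumeration
# ---------------------------------------------------------------------------

def _scan_candidates(ref: np.ndarray, query: np.ndarray, max_mm: int) -> tuple[np.ndarray, np.ndarray]:
    """All offsets where query matches ref with <= max_mm mismatches
    (vectorised full scan; used for reads too short for disjoint seeds)."""
    L = len(query)
    n_win = len(ref) - L + 1
    if n_win <= 0:
        return _EMPTY_I64, _EMPTY_I64
    starts, mms = [], []
    chunk = max(1, 2_000_000 // max(L, 1))
    for lo in range(0, n_win, chunk):
        hi = min(lo + chunk, n_win)
        win = np.lib.stride_tricks.sliding_window_view(ref[lo : hi + L - 1], L)
        mm = (win != query).sum(axis=1)
        ok = np.nonzero(mm <= max_mm)[0]
        starts.append(ok + lo)
        mms.append(mm[ok])
    return np.concatenate(starts), np.concatenate(mms)


def align_read(read: Read, index: SeedIndex, params: AlignParams, mate: int | None = None) -> list[Hit]:
    """Enumerate ALL placements of a read on both converted strands with
    Hamming distance <= max_mismatches.

    ``mate`` defaults to ``read.mate``; mate 2 is queried as the C→T
    conversion of its reverse complement (see module docstring).  Reads
    shorter than the seed length return no hits.
    """
    if mate is None:
        mate = read.mate
    L = len(read)
    if L < index.seed_len:
        return []
    query = read.bases if mate != 2 else revcomp(read.bases)
    query = query.translate(_CT_TABLE)
    qarr = _to_u8(query)
    qbytes = qarr.tobytes()
    k = params.max_mismatches + 1
    use_seeds = L >= k * index.seed_len
    if use_seeds:
        chunk = L // k
        offsets = [i * chunk for i in range(k)]
    hits: list[Hit] = []
    for chrom in index.chroms():
        N = index.converted.lengths[chrom]
        for strand in (WATSON, CRICK):
            ref = index.converted.ref(chrom, strand)
            if use_seeds:
                cands: set[int] = set()
                for off in offsets:
                    seed = qbytes[off : off + index.seed_len]
                    for p in index.lookup(chrom, strand, seed):
                        start = int(p) - off
                        if 0 <= start <= N - L:
                            cands.add(start)
                starts = sorted(cands)
                mms = None
            else:
                starts, mms = _scan_candidates(ref, qarr, params.max_mismatches)
                starts = starts.tolist()
            for j, s in enumerate(starts):
                if mms is None:
                    mm = int(np.count_nonzero(ref[s : s + L] != qarr))
                    if mm > params.max_mismatches:
                        continue
                else:
                    mm = int(mms[j])
                # translate Crick offsets to Watson coordinates
                start0 = s if strand == WATSON else N - s - L
                hits.append(Hit(strand, chrom, start0, mm))
    return hits


# ---------------------------------------------------------------------------
# Uniqueness / strand-ambiguity resolution
# ---------------------------------------------------------------------------

def resolve_single(hits: Sequence[Hit], read: Read) -> tuple[Optional[AlignmentRecord], Outcome]:
    """Keep a read iff it has exactly one hit at the minimum mismatch count
    and no hit at that minimum on the other strand's reference.

    The returned record carries the ORIGINAL (unconverted) bases.
    """
    if not hits:
        return None, Outcome.UNMAPPED
    best = min(h.mismatches for h in hits)
    at_best = [h for h in hits if h.mismatches == best]
    if len(at_best) > 1:
        strands = {h.strand for h in at_best}
        return None, (Outcome.BOTH_STRAND if len(strands) > 1 else Outcome.MULTI)
    h = at_best[0]
    rec = AlignmentRecord(
        read_id=read.id,
        chrom=h.chrom,
        start=h.start0 + 1,
        strand=h.strand,
        mismatches=h.mismatches,
        bases=read.bases,
        quals=read.quals,
        mate=read.mate,
    )
    return rec, Outcome.KEPT


def resolve_pair(
    hits1: Sequence[Hit],
    hits2: Sequence[Hit],
    read1: Read,
    read2: Read,
    params: AlignParams,
) -> tuple[Optional[tuple[AlignmentRecord, AlignmentRecord]], Outcome]:
    """Resolve a mate pair to a unique, properly oriented placement.

    A qualifying pair has both mates on the same chromosome and strand of
    origin, inward facing (mate 1 leftmost for Watson origin, mate 2
    leftmost for Crick), with outer insert in [insert_min, insert_max].
    The pair is kept iff exactly one qualifying pair exists at the
    minimum total mismatch count and none on the opposite strand ties it.
    """
    if not hits1 or not hits2:
        return None, Outcome.UNMAPPED
    L1, L2 = len(read1), len(read2)
    candidates = []
    by_key2: dict[tuple[str, str], list[Hit]] = defaultdict(list)
    for h in hits2:
        by_key2[(h.chrom, h.strand)].append(h)
    for h1 in hits1:
        for h2 in by_key2.get((h1.chrom, h1.strand), ()):
            if h1.strand == WATSON:
                if h1.start0 > h2.start0:
                    continue
                insert = h2.start0 + L2 - h1.start0
            else:
                if h2.start0 > h1.start0:
                    continue
                insert = h1.start0 + L1 - h2.start0
            if params.insert_min <= insert <= params.insert_max:
                candidates.append((h1, h2, insert, h1.mismatches + h2.mismatches))
    if not candidates:
        return None, Outcome.UNMAPPED
    best = min(c[3] for c in candidates)
    at_best = [c for c in candidates if c[3] == best]
    if len(at_best) > 1:
        strands = {c[0].strand for c in at_best}
        return None, (Outcome.BOTH_STRAND if len(strands) > 1 else Outcome.MULTI)
    h1, h2, insert, _ = at_best[0]
    rec1 = AlignmentRecord(
        read_id=read1.id,
        chrom=h1.chrom,
        start=h1.start0 + 1,
        strand=h1.strand,
        mismatches=h1.mismatches,
        bases=read1.bases,
        quals=read1.quals,
        mate=1,
        mate_start=h2.start0 + 1,
        insert_size=insert,
    )
    rec2 = AlignmentRecord(
        read_id=read2.id,
        chrom=h2.chrom,
        start=h2.start0 + 1,
        strand=h2.strand,
        mismatches=h2.mismatches,
        bases=read2.bases,
        quals=read2.quals,
        mate=2,
        mate_start=h1.start0 + 1,
        insert_size=insert,
    )
    return (rec1, rec2), Outcome.KEPT


# ---------------------------------------------------------------------------
# Duplicate removal
# ---------------------------------------------------------------------------

def remove_duplicates(records: Sequence[AlignmentRecord]) -> tuple[list[AlignmentRecord], int]:
    """Collapse fragments sharing (chrom, fragment start, strand, insert
    size or read length) to the one with the greatest total base quality;
    ties break to the lexicographically smallest read id.

    Returns (kept records, number of duplicate fragments removed).
    """
    frags: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in records:
        frags[r.read_id].append(r)
    keyed: dict[tuple, list[tuple[int, str, list[AlignmentRecord]]]] = defaultdict(list)
    for rid, recs in frags.items():
        first = recs[0]
        if len(recs) == 2 and first.insert_size is not None:
            start = min(r.start for r in recs)
            key = (first.chrom, start, first.strand, first.insert_size)
        else:
            key = (first.chrom, first.start, first.strand, len(first.bases))
        qual_sum = int(sum(int(r.quals.sum()) for r in recs))
        keyed[key].append((qual_sum, rid, recs))
    kept: list[AlignmentRecord] = []
    n_removed = 0
    for group in keyed.values():
        group.sort(key=lambda t: (-t[0], t[1]))
        kept.extend(group[0][2])
        n_removed += len(group) - 1
    kept.sort(key=lambda r: (r.chrom, r.start, r.read_id, r.mate))
    return kept, n_removed


# ---------------------------------------------------------------------------
# Full pipelines
# ---------------------------------------------------------------------------

@dataclass
class AlignStats:
    """Fragment-level alignment accounting.

    mapped = unique + both_strand_discarded + multi_discarded (fragments
    that had at least one qualifying placement).
    """

    total_fragments: int = 0
    dropped_short: int = 0
    unmapped: int = 0
    unique: int = 0
    both_strand_discarded: int = 0
    multi_discarded: int = 0
    duplicates_removed: int = 0

    @property
    def mapped(self) -> int:
        return self.unique + self.both_strand_discarded + self.multi_discarded

    @property
    def kept(self) -> int:
        return self.unique - self.duplicates_removed

    def to_dict(self) -> dict:
        d = {
            "total_fragments": self.total_fragments,
            "dropped_short": self.dropped_short,
            "unmapped": self.unmapped,
            "mapped": self.mapped,
            "unique": self.unique,
            "both_strand_discarded": self.both_strand_discarded,
            "multi_discarded": self.multi_discarded,
            "duplicates_removed": self.duplicates_removed,
            "kept": self.kept,
        }
        return d

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{v}\n")


def align_single_end(
    index: SeedIndex, reads: Iterable[Read], params: AlignParams
) -> tuple[list[AlignmentRecord], AlignStats]:
    """Trim, align and filter single-end reads; deduplicate at the end."""
    stats = AlignStats()
    records: list[AlignmentRecord] = []
    for read in reads:
        stats.total_fragments += 1
        read = trim_read(read, params)
        if len(read) < params.min_read_len:
            stats.dropped_short += 1
            continue
        hits = align_read(read, index, params, mate=read.mate)
        rec, outcome = resolve_single(hits, read)
        _tally(stats, outcome)
        if rec is not None:
            records.append(rec)
    records, stats.duplicates_removed = remove_duplicates(records)
    return records, stats


def align_paired_end(
    index: SeedIndex, pairs: Iterable[tuple[Read, Read]], params: AlignParams
) -> tuple[list[AlignmentRecord], AlignStats]:
    """Trim, align and filter mate pairs; deduplicate fragments at the end."""
    stats = AlignStats()
    records: list[AlignmentRecord] = []
    for r1, r2 in pairs:
        stats.total_fragments += 1
        r1 = trim_read(r1, params)
        r2 = trim_read(r2, params)
        if len(r1) < params.min_read_len or len(r2) < params.min_read_len:
            stats.dropped_short += 1
            continue
        hits1 = align_read(r1, index, params, mate=1)
        hits2 = align_read(r2, index, params, mate=2)
        recs, outcome = resolve_pair(hits1, hits2, r1, r2, params)
        _tally(stats, outcome)
        if recs is not None:
            records.extend(recs)
    records, stats.duplicates_removed = remove_duplicates(records)
    return records, stats


def _tally(stats: AlignStats, outcome: Outcome) -> None:
    if outcome is Outcome.KEPT:
        stats.unique += 1
    elif outcome is Outcome.UNMAPPED:
        stats.unmapped += 1
    elif outcome is Outcome.MULTI:
        stats.multi_discarded += 1
    elif outcome is Outcome.BOTH_STRAND:
        stats.both_strand_discarded += 1
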