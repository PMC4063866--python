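"""Naive all-offsets Hamming-scan alignment oracle used by the tests.

Independent of the package's seeded index: hits are enumerated by
scanning every offset of both converted strands with a direct windowed
comparison, and the uniqueness / strand-ambiguity / pairing rules are
re-stated here from first principles.
"""

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _scan(ref: str, query: str, max_mm: int):
    """(offset, mismatches) for every placement of query in ref."""
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    if len(r) < len(q):
        return []
    win = np.lib.stride_tricks.sliding_window_view(r, len(q))
    mm = (win != q).sum(axis=1)
    return [(int(i), int(m)) for i, m in enumerate(mm) if m <= max_mm]


def oracle_hits(genome: dict[str, str], bases: str, mate: int, max_mm: int):
    """All (strand, chrom, watson_start0, mm) hits of a read."""
    q = bases if mate != 2 else _revcomp(bases)
    q = q.replace("C", "T")
    hits = []
    for chrom, seq in genome.items():
        n = len(seq)
        for off, mm in _scan(seq.replace("C", "T"), q, max_mm):
            hits.append(("W", chrom, off, mm))
        for off, mm in _scan(_revcomp(seq).replace("C", "T"), q, max_mm):
            hits.append(("C", chrom, n - off - len(q), mm))
    return hits


def oracle_resolve_single(hits):
    """(strand, chrom, start0) if kept, else None."""
    if not hits:
        return None
    best = min(h[3] for h in hits)
    at_best = [h for h in hits if h[3] == best]
    if len(at_best) != 1:
        return None
    return at_best[0][:3]


def oracle_resolve_pair(hits1, hits2, len1, len2, insert_min, insert_max):
    """((strand, chrom, start0_1, start0_2, insert)) if kept, else None."""
    pairs = []
    for s1, c1, p1, m1 in hits1:
        for s2, c2, p2, m2 in hits2:
            if s1 != s2 or c1 != c2:
                continue
            if s1 == "W":
                if p1 > p2:
                    continue
                insert = p2 + len2 - p1
            else:
                if p2 > p1:
                    continue
                insert = p1 + len1 - p2
            if insert_min <= insert <= insert_max:
                pairs.append((s1, c1, p1, p2, insert, m1 + m2))
    if not pairs:
        return None
    best = min(p[5] for p in pairs)
    at_best = [p for p in pairs if p[5] == best]
    if len(at_best) != 1:
        return None
    return at_best[0][:5]
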