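"""Sliding-window identification of differentially methylated regions.

Two samples are compared in four stages:

1. **Seed search.**  A w-base window (default 500 bp) slides along each
   chromosome in s-base steps (default 100).  A window is a *seed* when
   it holds at least m CpG sites (default 5) covered by at least n reads
   (default 5) in BOTH samples at the same position and strand.
2. **Seed testing.**  The per-CpG methylation densities of the two
   samples inside a seed are compared with a two-sided Mann-Whitney U
   test; a seed with p below ``p_seed`` (default 0.01) is differentially
   methylated.
3. **Extension.**  A significant seed is extended by whole adjacent
   downstream windows while each next window is itself a significant
   seed in the same direction, stopping once the extended region is
   longer than k bases (default 1000) or the next window fails.
4. **Merging and region test.**  Nearby regions (gap <= ``merge_dist``,
   same direction, pooled-MD difference under ``md_diff_merge``
   percentage points within each sample) are unioned, then each region's
   pooled C/T counts go into a 2x2 chi-square test (1 df, no continuity
   correction); regions with chi-square p <= ``p_region`` are reported.

Direction is expressed for sample 2 relative to sample 1: *hyper* means
sample 2 is more methylated.  Regions whose Mann-Whitney p exceeds
``p_unchanged`` (default 0.25) may instead be classified as unchanged.

Only CpG-context cytosines participate.  By default Watson and Crick
CpG sites are distinct observations; ``merge_strands`` pools the two
strands of each CpG dinucleotide before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import CRICK, WATSON


@dataclass
class DMRParams:
    """Tuning parameters of the four-stage scan (defaults in brackets).

    w: window length in bases [500]
    s: slide increment in bases [100]
    m: minimum valid CpG sites per window, required in both samples [5]
    n: minimum reads covering a CpG for it to be valid [5]
    k: extension stops once the region is longer than this [1000]
    p_seed: Mann-Whitney threshold for a differentially methylated seed [0.01]
    p_region: chi-square threshold for a reported DMR [0.01]
    p_unchanged: regions with Mann-Whitney p above this are "unchanged" [0.25]
    merge_dist: maximum gap between merged regions [1000]
    md_diff_merge: maximum within-sample pooled-MD difference, in
        percentage points, for two regions to merge [10]
    merge_strands: pool Watson+Crick counts per CpG dinucleotide [False]
    """

    w: int = 500
    s: int = 100
    m: int = 5
    n: int = 5
    k: int = 1000
    p_seed: float = 0.01
    p_region: float = 0.01
    p_unchanged: float = 0.25
    merge_dist: int = 1000
    md_diff_merge: float = 10.0
    merge_strands: bool = False

    def __post_init__(self):
        for name in ("w", "s", "m", "n", "k", "merge_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_seed", "p_region", "p_unchanged"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class SeedRegion:
    chrom: str
    start: int
    end: int
    mds_a: np.ndarray
    mds_b: np.ndarray
    mw_p: float


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    direction: str  # 'hyper' | 'hypo' (sample 2 relative to sample 1)
    mw_p: float  # worst (largest) constituent seed p


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    direction: str
    md1: float
    md2: float
    c1: int
    t1: int
    c2: int
    t2: int
    mw_p: float
    chi2: float
    chi2_p: float


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def mann_whitney_u(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midranks for ties.

    For pooled sizes up to 20 the p-value is an exact permutation
    enumeration over every group assignment (midranks make it valid in
    the presence of ties; tie-free it coincides with the classical exact
    U distribution).  Larger samples use the tie-corrected normal
    approximation with continuity correction.  Returns (U of the first
    sample, two-sided p).  When all values across both groups are
    identical, p = 1.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n, m = len(xs), len(ys)
    comb = np.concatenate([xs, ys])
    if np.all(comb == comb[0]):
        return n * m / 2.0, 1.0
    ranks = stats.rankdata(comb)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2)
    if n + m <= 20:
        from itertools import combinations

        combos = np.fromiter(
            (i for c in combinations(range(n + m), n) for i in c), dtype=np.intp
        ).reshape(-1, n)
        u_all = ranks[combos].sum(axis=1) - n * (n + 1) / 2
        mean = n * m / 2.0
        obs_dev = abs(u_x - mean)
        p = float(np.mean(np.abs(u_all - mean) >= obs_dev - 1e-9))
        return u_x, p
    res = stats.mannwhitneyu(
        xs, ys, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_region(pooled_a: tuple[int, int], pooled_b: tuple[int, int]) -> tuple[float, float]:
    """Chi-square test (1 df, no continuity correction) on the 2x2 table
    [[C1, T1], [C2, T2]].  A zero marginal yields (0, 1)."""
    c1, t1 = pooled_a
    c2, t2 = pooled_b
    n = c1 + t1 + c2 + t2
    row1, row2 = c1 + t1, c2 + t2
    col1, col2 = c1 + c2, t1 + t2
    if row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
        return 0.0, 1.0
    chi2 = n * (c1 * t2 - t1 * c2) ** 2 / (row1 * row2 * col1 * col2)
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Call-table preparation
# ---------------------------------------------------------------------------

def _cpg_table(calls: pd.DataFrame, merge_strands: bool) -> pd.DataFrame:
    cpg = calls[calls["context_class"] == "CpG"]
    if merge_strands:
        # report the dinucleotide at the Watson C position (Crick G sits 1 bp right)
        pos = np.where(cpg["strand"] == CRICK, cpg["pos"] - 1, cpg["pos"])
        cpg = cpg.assign(pos=pos, strand=WATSON)
        cpg = (
            cpg.groupby(["chrom", "pos", "strand"], as_index=False)[["c_count", "t_count"]]
            .sum()
        )
    return cpg[["chrom", "pos", "strand", "c_count", "t_count"]]


class _JoinedCalls:
    """Per-chromosome sorted arrays of CpG sites present in both samples."""

    def __init__(self, calls_a: pd.DataFrame, calls_b: pd.DataFrame, params: DMRParams):
        a = _cpg_table(calls_a, params.merge_strands)
        b = _cpg_table(calls_b, params.merge_strands)
        joined = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
        joined = joined.sort_values(["chrom", "pos"]).reset_index(drop=True)
        self.by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, grp in joined.groupby("chrom", sort=True):
            ca = grp["c_count_a"].to_numpy(np.int64)
            ta = grp["t_count_a"].to_numpy(np.int64)
            cb = grp["c_count_b"].to_numpy(np.int64)
            tb = grp["t_count_b"].to_numpy(np.int64)
            valid = ((ca + ta) >= params.n) & ((cb + tb) >= params.n)
            self.by_chrom[str(chrom)] = {
                "pos": grp["pos"].to_numpy(np.int64)[valid],
                "ca": ca[valid],
                "ta": ta[valid],
                "cb": cb[valid],
                "tb": tb[valid],
            }

    def window(self, chrom: str, start: int, end: int) -> dict[str, np.ndarray]:
        d = self.by_chrom.get(chrom)
        if d is None:
            return {k: np.empty(0, dtype=np.int64) for k in ("pos", "ca", "ta", "cb", "tb")}
        lo = np.searchsorted(d["pos"], start, side="left")
        hi = np.searchsorted(d["pos"], end, side="right")
        return {k: v[lo:hi] for k, v in d.items()}


def valid_cpgs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    interval: tuple[str, int, int],
    n: int = 5,
    merge_strands: bool = False,
) -> pd.DataFrame:
    """CpG sites inside ``interval`` with depth >= n in both samples.

    Returns a frame with pos, per-sample MDs (percent) and counts,
    ascending by position.
    """
    params = DMRParams(n=n, merge_strands=merge_strands)
    joined = _JoinedCalls(calls_a, calls_b, params)
    chrom, start, end = interval
    w = joined.window(chrom, start, end)
    with np.errstate(invalid="ignore"):
        md_a = 100.0 * w["ca"] / (w["ca"] + w["ta"])
        md_b = 100.0 * w["cb"] / (w["cb"] + w["tb"])
    return pd.DataFrame(
        {
            "pos": w["pos"],
            "md_a": md_a,
            "md_b": md_b,
            "c_a": w["ca"],
            "t_a": w["ta"],
            "c_b": w["cb"],
            "t_b": w["tb"],
        }
    )


# ---------------------------------------------------------------------------
# Scan internals
# ---------------------------------------------------------------------------

def _window_mds(w: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    md_a = 100.0 * w["ca"] / (w["ca"] + w["ta"])
    md_b = 100.0 * w["cb"] / (w["cb"] + w["tb"])
    return md_a, md_b


def _pooled_md(c: int, t: int) -> Optional[float]:
    return None if c + t == 0 else 100.0 * c / (c + t)


def _direction(w: dict[str, np.ndarray]) -> Optional[str]:
    md1 = _pooled_md(int(w["ca"].sum()), int(w["ta"].sum()))
    md2 = _pooled_md(int(w["cb"].sum()), int(w["tb"].sum()))
    if md1 is None or md2 is None or md1 == md2:
        return None
    return "hyper" if md2 > md1 else "hypo"


def find_next_seed(
    joined: _JoinedCalls, chrom: str, from_pos: int, chrom_len: int, params: DMRParams
) -> Optional[SeedRegion]:
    """Leftmost w-base window at or after ``from_pos`` on the s-grid
    anchored at ``from_pos`` that holds >= m valid CpGs in both samples."""
    x = from_pos
    while x + params.w - 1 <= chrom_len:
        w = joined.window(chrom, x, x + params.w - 1)
        if len(w["pos"]) >= params.m:
            md_a, md_b = _window_mds(w)
            _, p = mann_whitney_u(md_a, md_b)
            return SeedRegion(chrom, x, x + params.w - 1, md_a, md_b, p)
        x += params.s
    return None


def _window_is_dm_seed(
    joined: _JoinedCalls, chrom: str, start: int, params: DMRParams
) -> tuple[bool, Optional[str], float]:
    w = joined.window(chrom, start, start + params.w - 1)
    if len(w["pos"]) < params.m:
        return False, None, 1.0
    md_a, md_b = _window_mds(w)
    _, p = mann_whitney_u(md_a, md_b)
    direction = _direction(w)
    return (p < params.p_seed and direction is not None), direction, p


def extend_and_merge(
    seed: SeedRegion, joined: _JoinedCalls, chrom_len: int, params: DMRParams
) -> Optional[CandidateRegion]:
    """Greedy rightward extension of a significant seed by whole windows.

    The next downstream window is interrogated only while the current
    region is not yet longer than k bases; extension also stops when the
    window fails validity, significance, or direction consistency.
    Returns None when the seed itself is not a significant seed.
    """
    ok, direction, p = _window_is_dm_seed(joined, seed.chrom, seed.start, params)
    if not ok:
        return None
    start, end = seed.start, seed.end
    worst_p = p
    while (end - start + 1) <= params.k:
        nxt = end + 1
        if nxt + params.w - 1 > chrom_len:
            break
        ok, d2, p2 = _window_is_dm_seed(joined, seed.chrom, nxt, params)
        if not ok or d2 != direction:
            break
        end = nxt + params.w - 1
        worst_p = max(worst_p, p2)
    return CandidateRegion(seed.chrom, start, end, direction, worst_p)


def merge_adjacent(
    regions: list[CandidateRegion], joined: _JoinedCalls, params: DMRParams
) -> list[CandidateRegion]:
    """Union consecutive same-direction regions separated by at most
    ``merge_dist`` bases whose pooled MDs differ by less than
    ``md_diff_merge`` percentage points within each sample.  Applied left
    to right, transitively; CpGs in the gap join the pooled counts."""
    if not regions:
        return []
    def region_mds(r: CandidateRegion) -> tuple[Optional[float], Optional[float]]:
        w = joined.window(r.chrom, r.start, r.end)
        return (
            _pooled_md(int(w["ca"].sum()), int(w["ta"].sum())),
            _pooled_md(int(w["cb"].sum()), int(w["tb"].sum())),
        )

    merged = [regions[0]]
    for nxt in regions[1:]:
        cur = merged[-1]
        gap = nxt.start - cur.end - 1
        if cur.chrom == nxt.chrom and gap <= params.merge_dist and cur.direction == nxt.direction:
            md1a, md1b = region_mds(cur)
            md2a, md2b = region_mds(nxt)
            if (
                None not in (md1a, md1b, md2a, md2b)
                and abs(md1a - md2a) < params.md_diff_merge
                and abs(md1b - md2b) < params.md_diff_merge
            ):
                merged[-1] = CandidateRegion(
                    cur.chrom, cur.start, nxt.end, cur.direction, max(cur.mw_p, nxt.mw_p)
                )
                continue
        merged.append(nxt)
    return merged


def classify_unchanged(
    region: tuple[str, int, int],
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    params: DMRParams | None = None,
) -> bool:
    """True iff the region's valid-CpG Mann-Whitney two-sided p exceeds
    ``p_unchanged`` (i.e. no evidence of differential methylation)."""
    params = params or DMRParams()
    joined = _JoinedCalls(calls_a, calls_b, params)
    chrom, start, end = region
    w = joined.window(chrom, start, end)
    if len(w["pos"]) < params.m:
        raise ValueError(f"region {region} has fewer than m={params.m} valid CpGs")
    md_a, md_b = _window_mds(w)
    _, p = mann_whitney_u(md_a, md_b)
    return p > params.p_unchanged


def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    params: DMRParams | None = None,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[DMR]:
    """Run the full four-stage scan and return DMRs sorted by coordinate.

    ``chrom_lengths`` bounds the scan per chromosome; when omitted, the
    last valid CpG position is used.
    """
    params = params or DMRParams()
    joined = _JoinedCalls(calls_a, calls_b, params)
    out: list[DMR] = []
    for chrom in sorted(joined.by_chrom):
        pos = joined.by_chrom[chrom]["pos"]
        if len(pos) == 0:
            continue
        chrom_len = (chrom_lengths or {}).get(chrom, int(pos[-1]) + params.w)
        candidates: list[CandidateRegion] = []
        from_pos = 1
        while True:
            seed = find_next_seed(joined, chrom, from_pos, chrom_len, params)
            if seed is None:
                break
            cand = extend_and_merge(seed, joined, chrom_len, params) if seed.mw_p < params.p_seed else None
            if cand is not None:
                candidates.append(cand)
                from_pos = cand.end + params.s
            else:
                from_pos = seed.start + params.s
        candidates = merge_adjacent(candidates, joined, params)
        for cand in candidates:
            w = joined.window(chrom, cand.start, cand.end)
            c1, t1 = int(w["ca"].sum()), int(w["ta"].sum())
            c2, t2 = int(w["cb"].sum()), int(w["tb"].sum())
            chi2, chi2_p = chi_square_region((c1, t1), (c2, t2))
            if chi2_p > params.p_region:
                continue
            md1, md2 = _pooled_md(c1, t1), _pooled_md(c2, t2)
            out.append(
                DMR(
                    chrom,
                    cand.start,
                    cand.end,
                    cand.direction,
                    md1,
                    md2,
                    c1,
                    t1,
                    c2,
                    t2,
                    cand.mw_p,
                    chi2,
                    chi2_p,
                )
            )
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "direction",
    "md1",
    "md2",
    "C1",
    "T1",
    "C2",
    "T2",
    "mw_p",
    "chi2",
    "chi2_p",
]


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "direction": d.direction,
                "md1": d.md1,
                "md2": d.md2,
                "C1": d.c1,
                "T1": d.t1,
                "C2": d.c2,
                "T2": d.t2,
                "mw_p": d.mw_p,
                "chi2": d.chi2,
                "chi2_p": d.chi2_p,
            }
            for d in dmrs
        ],
        columns=DMR_COLUMNS,
    )
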