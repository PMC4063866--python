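"""Genome-wide and region-level methylation profiling, DMR annotation,
and concordance with methylation-array beta values.

Array beta values live on the [0, 1] fraction scale while methylation
densities are percentages; every comparison here converts MD to a
fraction before joining, and the 25% / 3% gold-standard thresholds are
applied on the beta scale as 0.25 / 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import DMR, classify_unchanged
from .seqio import CRICK, WATSON


# ---------------------------------------------------------------------------
# Fixed-window and context profiles
# ---------------------------------------------------------------------------

def fixed_window_profile(calls: pd.DataFrame, window_len: int = 100_000) -> pd.DataFrame:
    """Pooled MD per (chromosome, fixed window, strand).

    Windows tile each chromosome from position 1 without overlap; a
    window/strand with no coverage gets a missing MD.
    Returns chrom, window_start (1-based), strand, md, n_sites, depth.
    """
    df = calls.copy()
    df["window_start"] = ((df["pos"] - 1) // window_len) * window_len + 1
    grp = df.groupby(["chrom", "window_start", "strand"], as_index=False).agg(
        c=("c_count", "sum"), t=("t_count", "sum"), n_sites=("pos", "size")
    )
    depth = grp["c"] + grp["t"]
    grp["md"] = np.where(depth > 0, 100.0 * grp["c"] / depth.replace(0, 1), np.nan)
    grp["depth"] = depth
    return grp[["chrom", "window_start", "strand", "md", "n_sites", "depth"]]


ALL_CONTEXTS = [
    "C" + a + b for a in "ACGT" for b in "ACGT"
]  # CAA ... CTT, 16 trinucleotides


def context_spectrum(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trinucleotide pooled MDs and per-class fractional methylated C.

    Returns (spectrum, fractions).  ``spectrum`` has one row per observed
    trinucleotide context with its pooled MD; ``fractions`` gives, for
    CpG/CHG/CHH, the share of all sequenced methylated Cs that fall in
    that class (missing when no methylated C was sequenced at all).
    """
    grp = calls.groupby("context3", as_index=False).agg(
        c=("c_count", "sum"), t=("t_count", "sum"), n_sites=("pos", "size")
    )
    depth = grp["c"] + grp["t"]
    grp["md"] = np.where(depth > 0, 100.0 * grp["c"] / depth.replace(0, 1), np.nan)
    spectrum = grp[["context3", "md", "c", "t", "n_sites"]]

    cls = calls.groupby("context_class", as_index=False).agg(c=("c_count", "sum"))
    total_c = cls["c"].sum()
    rows = []
    for klass in ("CpG", "CHG", "CHH"):
        sub = cls[cls["context_class"] == klass]
        c = int(sub["c"].iloc[0]) if len(sub) else 0
        rows.append(
            {
                "context_class": klass,
                "methylated_c": c,
                "fraction": (c / total_c) if total_c > 0 else np.nan,
            }
        )
    return spectrum, pd.DataFrame(rows)


def region_profile(
    calls: pd.DataFrame, regions: pd.DataFrame, chrom_lengths: Optional[dict[str, int]] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled MD per labelled region plus the per-cytosine long table.

    ``regions`` uses 1-based inclusive coordinates (chrom, start, end,
    label).  Raises ``ValueError`` for a region off its chromosome.
    Returns (per_region, per_site); per_site is box-plot ready (one row
    per covered cytosine per region, with the region label attached).
    """
    per_region_rows = []
    site_frames = []
    for _, r in regions.iterrows():
        chrom, start, end, label = r["chrom"], int(r["start"]), int(r["end"]), r["label"]
        if start < 1 or (chrom_lengths and end > chrom_lengths.get(chrom, end)):
            raise ValueError(f"region {label} off chromosome {chrom}")
        sub = calls[(calls["chrom"] == chrom) & (calls["pos"] >= start) & (calls["pos"] <= end)]
        c, t = int(sub["c_count"].sum()), int(sub["t_count"].sum())
        per_region_rows.append(
            {
                "label": label,
                "chrom": chrom,
                "start": start,
                "end": end,
                "md": (100.0 * c / (c + t)) if c + t > 0 else np.nan,
                "n_sites": len(sub),
                "depth": c + t,
            }
        )
        if len(sub):
            depth = sub["c_count"] + sub["t_count"]
            site_frames.append(
                sub.assign(label=label, md=100.0 * sub["c_count"] / depth)
            )
    per_site = (
        pd.concat(site_frames, ignore_index=True)
        if site_frames
        else pd.DataFrame(columns=list(calls.columns) + ["label", "md"])
    )
    return pd.DataFrame(per_region_rows), per_site


# ---------------------------------------------------------------------------
# DMR annotation
# ---------------------------------------------------------------------------

def annotate_dmrs(dmrs: pd.DataFrame, genes: pd.DataFrame, tss_window: int = 2000) -> pd.DataFrame:
    """Attach the closest gene (by distance to its TSS) to each DMR.

    ``genes`` needs chrom, start, end, label and strand ('+'/'-'); the
    TSS is the start for '+' genes and the end for '-' genes.  The
    promoter flag is set when the DMR overlaps the ``tss_window`` bases
    immediately upstream of the TSS.  Distance is 0 when the TSS falls
    inside the DMR; equidistant genes break ties to the smallest name.
    """
    rows = []
    for _, d in dmrs.iterrows():
        best = None
        for _, g in genes[genes["chrom"] == d["chrom"]].iterrows():
            tss = int(g["start"]) if g["strand"] == "+" else int(g["end"])
            if d["start"] <= tss <= d["end"]:
                dist = 0
            else:
                dist = min(abs(int(d["start"]) - tss), abs(int(d["end"]) - tss))
            if g["strand"] == "+":
                prom_lo, prom_hi = tss - tss_window, tss - 1
            else:
                prom_lo, prom_hi = tss + 1, tss + tss_window
            promoter = d["start"] <= prom_hi and d["end"] >= prom_lo
            key = (dist, str(g["label"]))
            if best is None or key < best[0]:
                best = (key, str(g["label"]), dist, promoter)
        row = dict(d)
        if best is None:
            row.update(closest_gene=None, tss_distance=np.nan, promoter=False)
        else:
            row.update(closest_gene=best[1], tss_distance=best[2], promoter=best[3])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Array concordance and the array-derived gold standard
# ---------------------------------------------------------------------------

def _cpg_dinucleotide_mds(calls: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    """Pool Watson+Crick CpG counts per dinucleotide (keyed at the Watson
    C position) and return sites with pooled depth >= min_depth."""
    cpg = calls[calls["context_class"] == "CpG"]
    pos = np.where(cpg["strand"] == CRICK, cpg["pos"] - 1, cpg["pos"])
    pooled = (
        cpg.assign(pos=pos)
        .groupby(["chrom", "pos"], as_index=False)[["c_count", "t_count"]]
        .sum()
    )
    depth = pooled["c_count"] + pooled["t_count"]
    pooled["depth"] = depth
    pooled = pooled[depth >= min_depth].copy()
    pooled["md_fraction"] = pooled["c_count"] / pooled["depth"]
    return pooled


def correlate_with_array(
    calls: pd.DataFrame, beta_table: pd.DataFrame, min_depth: int = 10
) -> tuple[Optional[float], int, pd.DataFrame]:
    """Pearson correlation between sequencing MDs and array beta values.

    CpG counts are pooled across strands per dinucleotide, sites with
    fewer than ``min_depth`` reads are dropped, the join is on
    (chrom, pos) with MD converted to the beta fraction scale.
    Returns (r, number of joined loci, the joined table); r is None with
    fewer than 3 joined loci.
    """
    pooled = _cpg_dinucleotide_mds(calls, min_depth)
    joined = pooled.merge(beta_table, on=["chrom", "pos"])
    if len(joined) < 3:
        return None, len(joined), joined
    r = float(stats.pearsonr(joined["md_fraction"], joined["beta"]).statistic)
    return r, len(joined), joined


@dataclass
class GoldStandardSet:
    """Array-derived 500-bp reference windows, classified by the change in
    mean beta between the two samples (sample 2 minus sample 1)."""

    hyper: pd.DataFrame
    hypo: pd.DataFrame
    unchanged: pd.DataFrame


def gold_standard_regions(
    beta_a: pd.DataFrame,
    beta_b: pd.DataFrame,
    window: int = 500,
    diff_changed: float = 0.25,
    diff_unchanged: float = 0.03,
) -> GoldStandardSet:
    """Classify 500-bp windows from per-probe beta values of two samples.

    Windows tile from position 1; only windows with at least one probe in
    BOTH samples are classified.  With d = mean(betaB) - mean(betaA):
    d > 0.25 hyper, d < -0.25 hypo, |d| <= 0.03 unchanged; anything in
    between is unassigned.
    """
    def window_means(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out["wstart"] = ((out["pos"] - 1) // window) * window + 1
        return out.groupby(["chrom", "wstart"], as_index=False)["beta"].mean()

    ma = window_means(beta_a)
    mb = window_means(beta_b)
    j = ma.merge(mb, on=["chrom", "wstart"], suffixes=("_a", "_b"))
    j["diff"] = j["beta_b"] - j["beta_a"]
    j["start"] = j["wstart"]
    j["end"] = j["wstart"] + window - 1
    cols = ["chrom", "start", "end", "beta_a", "beta_b", "diff"]
    return GoldStandardSet(
        hyper=j[j["diff"] > diff_changed][cols].reset_index(drop=True),
        hypo=j[j["diff"] < -diff_changed][cols].reset_index(drop=True),
        unchanged=j[j["diff"].abs() <= diff_unchanged][cols].reset_index(drop=True),
    )


def _overlaps_any(region, others: pd.DataFrame) -> bool:
    return bool(
        (
            (others["chrom"] == region["chrom"])
            & (others["start"] <= region["end"])
            & (others["end"] >= region["start"])
        ).any()
    )


def evaluate_dmr_calls(
    dmrs: pd.DataFrame, unchanged_regions: pd.DataFrame, gold: GoldStandardSet
) -> dict[str, Optional[float]]:
    """Fraction of each gold class recovered by the sequencing-based calls.

    A gold hyper/hypo window counts as detected when at least one DMR of
    the matching direction overlaps it by >= 1 bp; a gold unchanged
    window when an interval classified unchanged overlaps it.  An empty
    gold class yields a missing proportion.
    """
    out: dict[str, Optional[float]] = {}
    for klass, gold_df in (("hyper", gold.hyper), ("hypo", gold.hypo)):
        if len(gold_df) == 0:
            out[klass] = None
            continue
        calls = dmrs[dmrs["direction"] == klass]
        hits = sum(_overlaps_any(g, calls) for _, g in gold_df.iterrows())
        out[klass] = 100.0 * hits / len(gold_df)
    if len(gold.unchanged) == 0:
        out["unchanged"] = None
    else:
        hits = sum(_overlaps_any(g, unchanged_regions) for _, g in gold.unchanged.iterrows())
        out["unchanged"] = 100.0 * hits / len(gold.unchanged)
    return out
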