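"""Run-level quality control: summary statistics and a self-contained
HTML report with the two standard diagnostic plots (per-cycle base
composition and the paired-end insert-size distribution).

In a well-converted bisulfite library the per-cycle composition shows a
high T and a low C fraction; a drift away from that pattern usually
flags incomplete conversion or other library problems.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .methcall import conversion_rate, methylation_density
from .seqio import AlignmentRecord, Genome, Read
from .align import AlignStats


@dataclass
class RunStats:
    """The per-sample summary the QC report renders.

    Percentages are on [0, 100]; ratios with a zero denominator are
    recorded as None ("n/a" in the report).
    """

    total_fragments: int
    trimmed_discarded: int
    mapped: int
    unique: int
    both_strand_discarded: int
    duplicates_removed: int
    mappability: Optional[float]
    dup_rate: Optional[float]
    pct_cytosines_covered: Optional[float]
    pct_cpg_covered: Optional[float]
    mean_depth: float
    md_by_class: dict[str, Optional[float]]
    conversion_rate: Optional[float]
    per_cycle_base_freq: pd.DataFrame
    insert_histogram: dict[int, int]


def per_cycle_composition(reads: Iterable[Read]) -> pd.DataFrame:
    """Fraction of A/C/G/T among non-N bases at each sequencing cycle."""
    counts: dict[int, np.ndarray] = {}
    order = {b: i for i, b in enumerate("ACGT")}
    for read in reads:
        for cycle, base in enumerate(read.bases):
            if base == "N":
                continue
            if cycle not in counts:
                counts[cycle] = np.zeros(4, dtype=np.int64)
            counts[cycle][order[base]] += 1
    rows = []
    for cycle in sorted(counts):
        total = counts[cycle].sum()
        f = counts[cycle] / total if total else np.zeros(4)
        rows.append({"cycle": cycle + 1, "fA": f[0], "fC": f[1], "fG": f[2], "fT": f[3]})
    return pd.DataFrame(rows, columns=["cycle", "fA", "fC", "fG", "fT"])


def insert_size_distribution(records: Iterable[AlignmentRecord]) -> dict[int, int]:
    """Histogram of fragment insert sizes, one count per kept pair."""
    hist: dict[int, int] = {}
    for rec in records:
        if rec.mate == 1 and rec.insert_size is not None:
            hist[rec.insert_size] = hist.get(rec.insert_size, 0) + 1
    return dict(sorted(hist.items()))


def compute_run_stats(
    align_stats: AlignStats,
    calls: pd.DataFrame,
    genome: Genome,
    reads: Iterable[Read],
    records: Iterable[AlignmentRecord] = (),
    spike_chrom: Optional[str] = None,
    covered_threshold: int = 1,
) -> RunStats:
    """Assemble the QC summary from the aligner, the call table, the
    reference and the raw reads.

    mappability = 100*mapped/total fragments; dup_rate is relative to
    mapped fragments; mean depth averages C+T over every genomic cytosine
    (both strands), spike chromosome excluded.
    """
    total = align_stats.total_fragments
    mapped = align_stats.mapped
    n_cyt = 0
    n_cpg = 0
    for name, seq in genome.chromosomes.items():
        if name == spike_chrom:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c, is_g = arr == ord("C"), arr == ord("G")
        n_cyt += int(is_c.sum() + is_g.sum())
        n_cpg += int((is_c[:-1] & is_g[1:]).sum()) * 2  # both strands of each CpG

    main = calls[calls["chrom"] != spike_chrom] if spike_chrom else calls
    depth = main["c_count"] + main["t_count"]
    covered = main[depth >= covered_threshold]
    cpg_covered = covered[covered["context_class"] == "CpG"]
    md_by_class = {
        k: methylation_density(main, context=k).value for k in ("CpG", "CHG", "CHH")
    }
    return RunStats(
        total_fragments=total,
        trimmed_discarded=align_stats.dropped_short,
        mapped=mapped,
        unique=align_stats.unique,
        both_strand_discarded=align_stats.both_strand_discarded,
        duplicates_removed=align_stats.duplicates_removed,
        mappability=(100.0 * mapped / total) if total else None,
        dup_rate=(100.0 * align_stats.duplicates_removed / mapped) if mapped else None,
        pct_cytosines_covered=(100.0 * len(covered) / n_cyt) if n_cyt else None,
        pct_cpg_covered=(100.0 * len(cpg_covered) / n_cpg) if n_cpg else None,
        mean_depth=(float(depth.sum()) / n_cyt) if n_cyt else 0.0,
        md_by_class=md_by_class,
        conversion_rate=conversion_rate(calls, spike_chrom) if spike_chrom else None,
        per_cycle_base_freq=per_cycle_composition(reads),
        insert_histogram=insert_size_distribution(records),
    )


def _fmt(value, suffix="") -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "n/a"
    if isinstance(value, float):
        return f"{value:.2f}{suffix}"
    return f"{value}{suffix}"


def _plot_base64(plot_fn) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    plot_fn(ax)
    buf = io.BytesIO()
    fig.tight_layout()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def render_html(run_stats: RunStats, out_path) -> None:
    """Write a single-file HTML QC report: the statistics table plus the
    per-cycle composition and insert-size plots embedded as base64 PNGs,
    with intra-page navigation links."""
    table_rows = [
        ("Total sequenced fragments", _fmt(run_stats.total_fragments)),
        ("Fragments discarded by trimming", _fmt(run_stats.trimmed_discarded)),
        ("Mapped fragments", _fmt(run_stats.mapped)),
        ("Uniquely aligned fragments", _fmt(run_stats.unique)),
        ("Both-strand ambiguous (discarded)", _fmt(run_stats.both_strand_discarded)),
        ("Duplicate fragments removed", _fmt(run_stats.duplicates_removed)),
        ("Mappability", _fmt(run_stats.mappability, "%")),
        ("Duplication rate", _fmt(run_stats.dup_rate, "%")),
        ("Cytosines covered (&ge;1 read)", _fmt(run_stats.pct_cytosines_covered, "%")),
        ("CpG cytosines covered (&ge;1 read)", _fmt(run_stats.pct_cpg_covered, "%")),
        ("Mean sequencing depth (fold)", _fmt(run_stats.mean_depth)),
        ("Methylation density CpG", _fmt(run_stats.md_by_class.get("CpG"), "%")),
        ("Methylation density CHG", _fmt(run_stats.md_by_class.get("CHG"), "%")),
        ("Methylation density CHH", _fmt(run_stats.md_by_class.get("CHH"), "%")),
        ("Bisulfite conversion rate", _fmt(run_stats.conversion_rate, "%")),
    ]
    rows_html = "\n".join(
        f"<tr><td>{name}</td><td>{val}</td></tr>" for name, val in table_rows
    )

    comp = run_stats.per_cycle_base_freq
    if len(comp):
        def plot_comp(ax):
            for base in "ACGT":
                ax.plot(comp["cycle"], comp[f"f{base}"], label=base)
            ax.set_xlabel("sequencing cycle")
            ax.set_ylabel("base frequency")
            ax.set_ylim(0, 1)
            ax.legend(ncol=4, fontsize=8)

        comp_html = (
            f'<img alt="per-cycle base composition" '
            f'src="data:image/png;base64,{_plot_base64(plot_comp)}"/>'
        )
    else:
        comp_html = "<p>No reads available for per-cycle composition.</p>"

    hist = run_stats.insert_histogram
    if hist:
        def plot_hist(ax):
            sizes = list(hist)
            ax.bar(sizes, [hist[s] for s in sizes], width=max(1, (max(sizes) - min(sizes)) // 200 or 1))
            ax.set_xlabel("insert size (bp)")
            ax.set_ylabel("fragments")

        insert_html = (
            f'<img alt="insert size distribution" '
            f'src="data:image/png;base64,{_plot_base64(plot_hist)}"/>'
        )
    else:
        insert_html = "<p>No paired-end insert sizes available (single-end data?).</p>"

    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Bisulfite sequencing QC report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td {{ border: 1px solid #999; padding: 4px 10px; }}
</style></head>
<body>
<h1>Bisulfite sequencing QC report</h1>
<p><a href="#stats">Basic statistics</a> | <a href="#composition">Base composition</a> | <a href="#insert">Insert sizes</a></p>
<h2 id="stats">Basic statistics</h2>
<table>{rows_html}</table>
<h2 id="composition">Per-cycle base composition</h2>
{comp_html}
<h2 id="insert">Insert-size distribution</h2>
{insert_html}
</body></html>
"""
    with open(out_path, "w") as fh:
        fh.write(html)
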