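"""Bisulfite read simulation with full truth tracking.

The simulator builds (i) a random genome of configurable length and GC
content (a stand-in for the ~48.5 kb lambda phage genome used as the
classic alignment benchmark and conversion spike-in), (ii) a methylome
assigning every cytosine on both strands the methylation level of its
context class, and (iii) paired-end reads: fragments drop uniformly on
either strand, each cytosine on the fragment is methylated with its
site-level probability, unmethylated cytosines convert C→T with the
configured conversion rate, and i.i.d. substitution errors are applied
after conversion.  Mate 1 is the 5' end of the converted fragment on its
strand of origin, mate 2 the reverse complement of the 3' end, matching
a directional (MethylC-seq style) library.

Fragment coordinates are drawn from an RNG stream separate from the
methylation/error stream, so the same seed plants identical fragments
across different methylation settings — this makes the
methylation-neutral-mapping property exactly testable.

Truth tables record, per pair, the chromosome, both mates' leftmost
Watson start coordinates and the strand of origin; evaluation helpers
score mappability, placement accuracy and methylation-level recovery
against them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .methcall import classify_context
from .seqio import CRICK, WATSON, AlignmentRecord, Genome, Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for a simulated bisulfite run.

    Defaults reproduce the lambda-scale benchmark: a 48,500 bp genome at
    50% GC, 75-base mates, inserts uniform on [75, 600], fully methylated
    CpGs, unmethylated CHG/CHH, complete conversion and a 1e-3 per-base
    substitution error rate.
    """

    genome_len: int = 48_500
    gc: float = 0.5
    n_pairs: int = 50_000
    read_len: int = 75
    insert_min: int = 75
    insert_max: int = 600
    meth_cpg: float = 100.0
    meth_chg: float = 0.0
    meth_chh: float = 0.0
    error_rate: float = 0.001
    conversion_rate: float = 100.0
    base_quality: int = 40
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be a fraction in [0, 1]")
        for name in ("meth_cpg", "meth_chg", "meth_chh", "conversion_rate"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be a probability")
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min > insert_max")
        if self.insert_min < self.read_len:
            raise ValueError("insert_min below read_len: mates would read past the fragment")


def simulate_genome(config: SimConfig, name: str = "chr1", rng: Optional[np.random.Generator] = None) -> Genome:
    """An i.i.d. random genome at the configured GC content."""
    rng = rng or np.random.default_rng(config.seed)
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    arr = rng.choice(_BASES, size=config.genome_len, p=p)
    return Genome({name: arr.tobytes().decode("ascii")})


def simulate_methylome(genome: Genome, config: SimConfig) -> pd.DataFrame:
    """Assign every cytosine (both strands) the level of its context class.

    Returns chrom, pos (Watson coordinate; Crick cytosines at their G),
    strand, context_class, level (percent).  The ``level`` column may be
    freely edited before read simulation to model site heterogeneity.
    """
    by_class = {"CpG": config.meth_cpg, "CHG": config.meth_chg, "CHH": config.meth_chh}
    frames = []
    for chrom, seq in genome.chromosomes.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pad = np.full(2, ord("N"), np.uint8)
        padded = np.concatenate([pad, arr, pad])
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        for strand, idx in ((WATSON, np.nonzero(is_c)[0]), (CRICK, np.nonzero(is_g)[0])):
            if strand == WATSON:
                nxt1, nxt2 = padded[idx + 3], padded[idx + 4]
            else:
                comp = np.zeros(256, np.uint8)
                for a, b in zip(b"ACGTN", b"TGCAN"):
                    comp[a] = b
                nxt1, nxt2 = comp[padded[idx + 1]], comp[padded[idx]]
            klass = np.where(
                nxt1 == ord("G"), "CpG", np.where(nxt2 == ord("G"), "CHG", "CHH")
            )
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": strand,
                        "context_class": klass,
                        "level": [by_class[k] for k in klass],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def draw_fragments(genome: Genome, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform fragment placement: chrom by length, insert uniform on
    [insert_min, insert_max], start uniform, strand a fair coin."""
    names = genome.names()
    lengths = np.array([len(genome[n]) for n in names])
    if config.insert_max > lengths.min():
        raise ValueError("insert_max exceeds the shortest chromosome length")
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names), size=config.n_pairs, p=probs)
    inserts = rng.integers(config.insert_min, config.insert_max + 1, size=config.n_pairs)
    starts = np.empty(config.n_pairs, dtype=np.int64)
    for i, n in enumerate(lengths):
        sel = chrom_idx == i
        starts[sel] = rng.integers(0, n - inserts[sel] + 1)
    strands = np.where(rng.random(config.n_pairs) < 0.5, WATSON, CRICK)
    return pd.DataFrame(
        {
            "chrom": [names[i] for i in chrom_idx],
            "start0": starts,
            "insert": inserts,
            "strand": strands,
        }
    )


def simulate_read_pairs(
    genome: Genome,
    methylome: pd.DataFrame,
    config: SimConfig,
    fragments: Optional[pd.DataFrame] = None,
) -> tuple[list[Read], list[Read], pd.DataFrame]:
    """Simulate paired bisulfite reads and their truth table.

    Returns (mate-1 reads, mate-2 reads, truth).  Truth columns:
    read_id, chrom, start1, start2 (1-based leftmost Watson coordinate
    of each mate), strand, insert.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    frag_rng, meth_rng = [np.random.default_rng(s) for s in seed_seq.spawn(2)]
    if fragments is None:
        fragments = draw_fragments(genome, config, frag_rng)

    # per-chromosome, per-strand site methylation levels as fractions
    level_w: dict[str, np.ndarray] = {}
    level_c: dict[str, np.ndarray] = {}
    arrs: dict[str, np.ndarray] = {}
    for chrom, seq in genome.chromosomes.items():
        n = len(seq)
        level_w[chrom] = np.zeros(n)
        level_c[chrom] = np.zeros(n)
        arrs[chrom] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for (chrom, strand), grp in methylome.groupby(["chrom", "strand"]):
        tgt = level_w if strand == WATSON else level_c
        tgt[chrom][grp["pos"].to_numpy() - 1] = grp["level"].to_numpy() / 100.0

    conv_p = config.conversion_rate / 100.0
    L = config.read_len
    qual = np.full(L, config.base_quality, dtype=np.int16)
    reads1: list[Read] = []
    reads2: list[Read] = []
    truth_rows = []
    comp = np.zeros(256, np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    base_idx = np.full(256, 255, np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_idx[b] = i

    for i, frag in enumerate(fragments.itertuples(index=False)):
        chrom, f0, ins, strand = frag.chrom, int(frag.start0), int(frag.insert), frag.strand
        f1 = f0 + ins - 1
        if strand == WATSON:
            seg = arrs[chrom][f0 : f1 + 1].copy()
            levels = level_w[chrom][f0 : f1 + 1]
        else:
            seg = comp[arrs[chrom][f0 : f1 + 1]][::-1].copy()
            levels = level_c[chrom][f0 : f1 + 1][::-1]
        c_pos = np.nonzero(seg == ord("C"))[0]
        if len(c_pos):
            meth = meth_rng.random(len(c_pos)) < levels[c_pos]
            unmeth = c_pos[~meth]
            if conv_p >= 1.0:
                converted = unmeth
            else:
                converted = unmeth[meth_rng.random(len(unmeth)) < conv_p]
            seg[converted] = ord("T")
        m1 = seg[:L]
        m2 = comp[seg[ins - L :]][::-1]
        if config.error_rate > 0:
            for m in (m1, m2):
                errs = np.nonzero(meth_rng.random(len(m)) < config.error_rate)[0]
                if len(errs):
                    shift = meth_rng.integers(1, 4, size=len(errs)).astype(np.uint8)
                    m[errs] = _BASES[(base_idx[m[errs]] + shift) % 4]
        rid = f"sim{i}"
        reads1.append(Read(rid, m1.tobytes().decode("ascii"), qual[: len(m1)], mate=1))
        reads2.append(Read(rid, m2.tobytes().decode("ascii"), qual[: len(m2)], mate=2))
        if strand == WATSON:
            start1, start2 = f0 + 1, f1 - L + 2
        else:
            start1, start2 = f1 - L + 2, f0 + 1
        truth_rows.append(
            {
                "read_id": rid,
                "chrom": chrom,
                "start1": start1,
                "start2": start2,
                "strand": strand,
                "insert": ins,
            }
        )
    return reads1, reads2, pd.DataFrame(truth_rows)


def simulate_single_end_reads(
    genome: Genome,
    methylome: pd.DataFrame,
    config: SimConfig,
    fragments: Optional[pd.DataFrame] = None,
) -> tuple[list[Read], pd.DataFrame]:
    """Single-end variant: mate 1 of each simulated fragment."""
    reads1, _, truth = simulate_read_pairs(genome, methylome, config, fragments)
    reads = [Read(r.id, r.bases, r.quals, mate=0) for r in reads1]
    truth = truth.rename(columns={"start1": "start"})[["read_id", "chrom", "start", "strand"]]
    return reads, truth


# ---------------------------------------------------------------------------
# Evaluation against truth
# ---------------------------------------------------------------------------

def evaluate_alignment(records: list[AlignmentRecord], truth: pd.DataFrame) -> dict[str, float]:
    """Score kept alignments against the simulation truth.

    mappability = 100 * kept pairs / simulated pairs;
    accuracy     = 100 * kept pairs at their true chromosome, starts and
    strand / kept pairs.  Raises on a read id missing from the truth.
    """
    tr = truth.set_index("read_id")
    paired = "start1" in truth.columns
    by_id: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_id.setdefault(rec.read_id, []).append(rec)
    kept = correct = 0
    for rid, recs in by_id.items():
        if rid not in tr.index:
            raise ValueError(f"aligned read {rid} absent from truth table")
        t = tr.loc[rid]
        kept += 1
        if paired:
            if len(recs) != 2:
                continue
            r1 = next(r for r in recs if r.mate == 1)
            r2 = next(r for r in recs if r.mate == 2)
            ok = (
                r1.chrom == t["chrom"]
                and r1.strand == t["strand"]
                and r2.strand == t["strand"]
                and r1.start == t["start1"]
                and r2.start == t["start2"]
            )
        else:
            r = recs[0]
            ok = r.chrom == t["chrom"] and r.strand == t["strand"] and r.start == t["start"]
        correct += bool(ok)
    n_sim = len(truth)
    return {
        "mappability": 100.0 * kept / n_sim if n_sim else float("nan"),
        "accuracy": 100.0 * correct / kept if kept else float("nan"),
        "n_simulated": n_sim,
        "n_kept": kept,
    }


def evaluate_md_recovery(calls: pd.DataFrame, methylome: pd.DataFrame) -> pd.DataFrame:
    """Pooled estimated MD per context class next to the simulated truth.

    ``true_level`` is the depth-independent mean of the simulated site
    levels per class (exact when levels are uniform within a class).
    """
    rows = []
    for klass in ("CpG", "CHG", "CHH"):
        sub = calls[calls["context_class"] == klass]
        c, t = int(sub["c_count"].sum()), int(sub["t_count"].sum())
        truth_sub = methylome[methylome["context_class"] == klass]
        rows.append(
            {
                "context_class": klass,
                "true_level": float(truth_sub["level"].mean()) if len(truth_sub) else np.nan,
                "estimated_md": (100.0 * c / (c + t)) if c + t else np.nan,
                "n_sites": len(sub),
                "depth": c + t,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planted-DMR call-table simulation
# ---------------------------------------------------------------------------

@dataclass
class DMRSimConfig:
    """Conditions of the planted-DMR validation experiment.

    One replicate is a chromosome with CpG sites on a regular grid (6 per
    500 bp), every site covered by exactly ``depth`` reads in both
    samples.  As in the standard simulated-methylome design, background
    CpG methylation is a deterministic 100% in both samples; a single
    planted block sets sample 2 to ``dmr_level`` (50%, i.e. a 50
    percentage-point contrast).  C counts are Binomial(depth, level).
    """

    chrom_len: int = 20_000
    cpg_spacing: int = 83  # ~6 CpG sites per 500-bp window
    depth: int = 10
    background_level: float = 100.0
    dmr_level: float = 50.0
    dmr_len: int = 1000
    seed: Optional[int] = None


def simulate_dmr_calls(
    config: DMRSimConfig, rng: Optional[np.random.Generator] = None, chrom: str = "chr1"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """One planted-DMR replicate: call tables for two samples plus truth.

    Returns (calls_a, calls_b, truth) where truth has one row: chrom,
    start, end, direction (of sample 2 relative to sample 1).
    """
    rng = rng or np.random.default_rng(config.seed)
    positions = np.arange(config.cpg_spacing, config.chrom_len - 1, config.cpg_spacing)
    block_start = int(
        rng.integers(config.chrom_len // 4, config.chrom_len * 3 // 4 - config.dmr_len)
    )
    block_end = block_start + config.dmr_len - 1
    in_block = (positions >= block_start) & (positions <= block_end)

    lvl_a = np.full(len(positions), config.background_level / 100.0)
    lvl_b = np.where(in_block, config.dmr_level / 100.0, config.background_level / 100.0)
    c_a = rng.binomial(config.depth, lvl_a)
    c_b = rng.binomial(config.depth, lvl_b)

    def table(c: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "strand": WATSON,
                "context3": "CGT",
                "context_class": "CpG",
                "c_count": c,
                "t_count": config.depth - c,
            }
        )

    direction = "hyper" if config.dmr_level > config.background_level else "hypo"
    truth = pd.DataFrame(
        [{"chrom": chrom, "start": block_start, "end": block_end, "direction": direction}]
    )
    return table(c_a), table(c_b), truth


# ---------------------------------------------------------------------------
# Helpers for concordance experiments
# ---------------------------------------------------------------------------

def assign_bimodal_cpg_levels(
    methylome: pd.DataFrame,
    rng: np.random.Generator,
    low: float = 5.0,
    high: float = 95.0,
    p_high: float = 0.7,
) -> pd.DataFrame:
    """Give CpG *dinucleotides* bimodal methylation levels (both strands of
    a dinucleotide share the level), leaving other contexts untouched —
    a simple model of the bimodal CpG landscape real methylomes show."""
    out = methylome.copy()
    cpg = out["context_class"] == "CpG"
    dinuc = np.where(out["strand"] == CRICK, out["pos"] - 1, out["pos"])
    out["_dinuc"] = dinuc
    keys = out.loc[cpg, ["chrom", "_dinuc"]].drop_duplicates()
    draw = np.where(rng.random(len(keys)) < p_high, high, low)
    lut = {(c, p): v for (c, p), v in zip(zip(keys["chrom"], keys["_dinuc"]), draw)}
    out.loc[cpg, "level"] = [
        lut[(c, p)] for c, p in zip(out.loc[cpg, "chrom"], out.loc[cpg, "_dinuc"])
    ]
    return out.drop(columns="_dinuc")


def beta_table_from_methylome(
    methylome: pd.DataFrame, rng: np.random.Generator, noise_sd: float = 0.02
) -> pd.DataFrame:
    """Array-style beta values at CpG dinucleotides: the true level as a
    fraction plus Gaussian measurement noise, clipped to [0, 1].  Probes
    are keyed at the Watson-C position of each dinucleotide."""
    cpg = methylome[
        (methylome["context_class"] == "CpG") & (methylome["strand"] == WATSON)
    ]
    beta = np.clip(cpg["level"].to_numpy() / 100.0 + rng.normal(0, noise_sd, len(cpg)), 0, 1)
    return pd.DataFrame({"chrom": cpg["chrom"].to_numpy(), "pos": cpg["pos"].to_numpy(), "beta": beta})
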