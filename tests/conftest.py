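import numpy as np
import pandas as pd
import pytest

from bsmethy import Genome, Read


@pytest.fixture
def toy_genome() -> Genome:
    # 60 bp with a mix of CpG, CHG and CHH contexts
    return Genome({"chr1": "AACGTTACAGTACCGGATCGATTACGCATGCAAGCTTGGCACGTGATCCGTACGATTAGC"})


def make_read(bases: str, qual: int = 40, rid: str = "r1", mate: int = 0) -> Read:
    return Read(rid, bases, np.full(len(bases), qual, dtype=np.int16), mate=mate)


def make_calls(rows) -> pd.DataFrame:
    """Build a call table from (chrom, pos, strand, context3, c, t) tuples."""
    from bsmethy.methcall import classify_context

    return pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "context3": ctx,
                "context_class": classify_context(ctx),
                "c_count": c,
                "t_count": t,
            }
            for chrom, pos, strand, ctx, c, t in rows
        ]
    )


def cpg_grid_calls(
    positions, c_counts, depth: int = 10, chrom: str = "chr1"
) -> pd.DataFrame:
    """CpG-only call table on given positions with given methylated counts."""
    return make_calls(
        [
            (chrom, int(p), "W", "CGT", int(c), depth - int(c))
            for p, c in zip(positions, c_counts)
        ]
    )
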