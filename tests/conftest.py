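import numpy as np
import pandas as pd
import pytest

from methscreen.methylome import CALL_COLUMNS, MethylomeSample
from methscreen.synthgen import (
    PlantedDMR,
    SimConfig,
    simulate_annotation,
    simulate_expression,
    simulate_methylome,
)


def make_sample(
    positions,
    n_meth,
    n_unmeth,
    sample_id="s",
    group="tumor",
    chrom="chr1",
    context="CG",
    strand="+",
):
    """Build a MethylomeSample from parallel arrays (scalars broadcast)."""
    n = len(positions)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "strand": strand,
            "context": context,
            "n_meth": np.broadcast_to(np.asarray(n_meth, dtype=int), n).copy(),
            "n_unmeth": np.broadcast_to(np.asarray(n_unmeth, dtype=int), n).copy(),
        },
        columns=CALL_COLUMNS,
    )
    return MethylomeSample(sample_id, group, df)


def two_group_samples(positions, level_tumor, level_normal, coverage=30, n_per_group=3):
    """Deterministic 3v3 samples with exact per-site methylated fractions."""
    positions = np.asarray(positions)
    out = []
    for group, level, prefix in (
        ("tumor", level_tumor, "T"),
        ("normal", level_normal, "N"),
    ):
        nm = np.rint(np.broadcast_to(level, len(positions)) * coverage).astype(int)
        for i in range(n_per_group):
            out.append(
                make_sample(
                    positions, nm, coverage - nm, f"{prefix}{i + 1}", group
                )
            )
    return out


@pytest.fixture(scope="session")
def planted_study():
    """A small end-to-end study: 10 planted promoter hyper-DMRs, coupled DEGs."""
    config = SimConfig(
        seed=42,
        planted_dmrs=[PlantedDMR(8, 0.8, 0.2) for _ in range(10)],
        n_genes=60,
        chrom_length=1_500_000,
        n_cpg_sites=4000,
        coupling_prob=1.0,
    )
    genes = simulate_annotation(config)
    samples, truth = simulate_methylome(config, genes)
    matrix, truth = simulate_expression(config, genes, truth)
    return config, genes, samples, matrix, truth
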