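"""Methylation-expression integration: DMR-to-gene annotation, the DEG
threshold screen, crossover candidate sets, a Spearman co-expression screen
and the 2x2 Pearson chi-square association test.

The crossover logic nominates methylation-regulated tumor suppressors:
genes that are both hypermethylated (a hyper-DMR over their promoter or
body) and transcriptionally down-regulated, and symmetrically hypo/up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import DEFAULT_PROMOTER_WINDOW, GeneSet
from .errors import (
    ParameterError,
    UndefinedCorrelationError,
    UndefinedTestError,
)
from .synthgen import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "ExpressionMatrix",
    "DEGRecord",
    "DmgAssignment",
    "CandidateGeneSets",
    "ContingencyResult",
    "assign_dmrs_to_genes",
    "deg_screen",
    "crossover_sets",
    "spearman_screen",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result."""

    gene_id: str
    log2fc: float
    p_value: float
    label: str  # up | down | neutral


@dataclass
class DmgAssignment:
    """Genes hit by hyper-/hypo-DMRs; a gene hit by both is flagged."""

    hyper_dmg: list[str] = field(default_factory=list)
    hypo_dmg: list[str] = field(default_factory=list)
    both: list[str] = field(default_factory=list)


def assign_dmrs_to_genes(
    dmrs,
    genes: GeneSet,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    scope: str = "gene-region",
) -> DmgAssignment:
    """Annotate DMRs to genes by interval overlap.

    ``dmrs`` is a list of DMR objects or a DataFrame with chrom/start/end/
    direction columns (0-based half-open).  ``scope`` is ``gene-region``
    (promoter union gene body, the default) or ``promoter`` only.  Each gene
    appears at most once per direction set; genes hit by both directions
    join both sets and are flagged.
    """
    if scope not in ("gene-region", "promoter"):
        raise ParameterError(f"unknown scope {scope!r}")
    if not isinstance(dmrs, pd.DataFrame):
        dmrs = pd.DataFrame(
            [
                {"chrom": d.chrom, "start": d.start, "end": d.end,
                 "direction": d.direction}
                for d in dmrs
            ],
            columns=["chrom", "start", "end", "direction"],
        )
    proms = genes.promoter_intervals(promoter_window)
    bodies = genes.records
    gene_chroms = set(bodies["chrom"].unique())

    hits: dict[str, set[str]] = {"hyper": set(), "hypo": set()}
    for row in dmrs.itertuples(index=False):
        if row.chrom not in gene_chroms:
            logger.warning("DMR chromosome %s absent from annotation; skipped",
                           row.chrom)
            continue
        p = proms[proms["chrom"] == row.chrom]
        overlap = (np.maximum(p["start"], row.start)
                   < np.minimum(p["end"], row.end))
        hit_genes = set(p.loc[overlap, "gene_id"])
        if scope == "gene-region":
            b = bodies[bodies["chrom"] == row.chrom]
            overlap_b = (np.maximum(b["start"], row.start)
                         < np.minimum(b["end"], row.end))
            hit_genes |= set(b.loc[overlap_b, "gene_id"])
        hits[row.direction] |= hit_genes

    both = sorted(hits["hyper"] & hits["hypo"])
    if both:
        logger.warning("genes hit by both DMR directions: %s", ", ".join(both))
    return DmgAssignment(sorted(hits["hyper"]), sorted(hits["hypo"]), both)


# ---------------------------------------------------------------------------
# DEG screen


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample (library-size normalization)."""
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ParameterError("sample with zero library size")
    return counts * 1e6 / libsize


def deg_screen(
    matrix: ExpressionMatrix,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Threshold screen for differentially expressed genes.

    log2FC = log2((mean CPM_tumor + 1) / (mean CPM_normal + 1)); p from a
    two-sided Welch t-test on log2(CPM + 1).  A gene is ``down`` when
    log2FC <= -1 and p < 0.05, ``up`` when log2FC >= 1 and p < 0.05
    (thresholds inclusive), else ``neutral``.  Genes with zero counts in
    every sample are neutral with p = 1 and flagged.

    Returns a DataFrame indexed by gene_id with columns log2fc, p_value,
    label, flag.
    """
    t_cols = matrix.samples_in("tumor")
    n_cols = matrix.samples_in("normal")
    if len(t_cols) < 2 or len(n_cols) < 2:
        raise ParameterError("need >= 2 samples per group for the DEG screen")
    norm = cpm(matrix.counts)
    log_t = np.log2(norm[t_cols] + 1)
    log_n = np.log2(norm[n_cols] + 1)
    log2fc = np.log2((norm[t_cols].mean(axis=1) + 1)
                     / (norm[n_cols].mean(axis=1) + 1))
    res = sps.ttest_ind(log_t, log_n, axis=1, equal_var=False)
    p = pd.Series(res.pvalue, index=norm.index).fillna(1.0)

    all_zero = (matrix.counts == 0).all(axis=1)
    p[all_zero] = 1.0
    label = pd.Series("neutral", index=norm.index)
    label[(log2fc <= -lfc_threshold) & (p < p_threshold)] = "down"
    label[(log2fc >= lfc_threshold) & (p < p_threshold)] = "up"
    label[all_zero] = "neutral"
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "label": label,
            "flag": np.where(all_zero, "all_zero", ""),
        }
    )
    out.index.name = "gene_id"
    return out


def deg_records(deg_table: pd.DataFrame) -> list[DEGRecord]:
    return [
        DEGRecord(str(g), float(r.log2fc), float(r.p_value), str(r.label))
        for g, r in deg_table.iterrows()
    ]


# ---------------------------------------------------------------------------
# crossover sets


@dataclass
class CandidateGeneSets:
    """Direction-matched intersections of DMG and DEG sets with Venn counts."""

    hyper_dmg: list[str]
    hypo_dmg: list[str]
    up_deg: list[str]
    down_deg: list[str]
    hyper_down: list[str]
    hypo_up: list[str]
    venn_counts: dict[str, int]


def crossover_sets(
    hyper_dmg, hypo_dmg, degs: pd.DataFrame
) -> CandidateGeneSets:
    """Intersect hyper-DMGs with down-DEGs and hypo-DMGs with up-DEGs.

    All output lists are lexicographically sorted; the Venn counts describe
    the two 2-set diagrams (set sizes, intersection, exclusive parts).
    """
    hyper = set(map(str, hyper_dmg))
    hypo = set(map(str, hypo_dmg))
    down = set(degs.index[degs["label"] == "down"].astype(str))
    up = set(degs.index[degs["label"] == "up"].astype(str))
    hyper_down = sorted(hyper & down)
    hypo_up = sorted(hypo & up)
    venn = {
        "hyper_dmg": len(hyper),
        "down_deg": len(down),
        "hyper_down": len(hyper_down),
        "hyper_only": len(hyper - down),
        "down_only": len(down - hyper),
        "hypo_dmg": len(hypo),
        "up_deg": len(up),
        "hypo_up": len(hypo_up),
        "hypo_only": len(hypo - up),
        "up_only": len(up - hypo),
    }
    return CandidateGeneSets(
        sorted(hyper), sorted(hypo), sorted(up), sorted(down),
        hyper_down, hypo_up, venn,
    )


# ---------------------------------------------------------------------------
# co-expression screen


def spearman_screen(
    matrix: ExpressionMatrix, anchor_gene: str, threshold: float = 0.3
) -> list[tuple[str, float]]:
    """Spearman rank correlation of every gene with an anchor gene.

    Average ranks for ties; genes with |rho| >= threshold are retained
    (the anchor itself excluded), sorted by gene id.  Genes with a constant
    expression vector are skipped; a constant anchor is an error.
    """
    counts = matrix.counts
    if anchor_gene not in counts.index:
        raise ParameterError(f"anchor gene {anchor_gene!r} not in matrix")
    if counts.shape[1] < 3:
        raise ParameterError("need >= 3 samples for a rank correlation")
    anchor = counts.loc[anchor_gene].to_numpy(dtype=float)
    if np.all(anchor == anchor[0]):
        raise UndefinedCorrelationError("anchor expression vector is constant")
    anchor_rank = sps.rankdata(anchor)
    out = []
    for gene in counts.index:
        if gene == anchor_gene:
            continue
        v = counts.loc[gene].to_numpy(dtype=float)
        if np.all(v == v[0]):
            continue
        rho = float(np.corrcoef(anchor_rank, sps.rankdata(v))[0, 1])
        if abs(rho) >= threshold:
            out.append((str(gene), rho))
    return sorted(out)


# ---------------------------------------------------------------------------
# 2x2 association


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def chi_square_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    No continuity correction; p from chi-square with 1 df.  Statistic is
    sum((O - E)^2 / E) with expectations from the margins.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ParameterError("counts must be non-negative")
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise UndefinedTestError("zero margin: chi-square undefined")
    expected = np.outer(rows, cols) / n
    statistic = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(statistic, df=1))
    return ContingencyResult(statistic, p, ((int(a), int(b)), (int(c), int(d))))
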