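"""Seeded synthetic data emulating a small paired tumor/normal WGBS + RNA-seq
study (3 vs 3 by default).

The generator plants differentially methylated regions (DMRs) inside gene
promoters and, with configurable probability, couples each promoter
hyper-DMR to a planted down-regulated gene (and hypo-DMR to up-regulated),
so the full methylome -> DMR -> expression -> crossover pipeline can be
exercised against known ground truth.

Count models
------------
* per-site coverage: Poisson(coverage_mean) truncated at >= 1, so every
  emitted site is covered;
* methylated reads: beta-binomial with mean mu and intra-class correlation
  rho, parameterized a = mu(1-rho)/rho, b = (1-mu)(1-rho)/rho; rho = 0
  degenerates to an exact binomial;
* RNA counts: negative binomial with var = mu + alpha * mu^2.

Identical SimConfig (including seed) yields byte-identical outputs; each
stage draws from its own seed-derived stream so stages are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import DEFAULT_PROMOTER_WINDOW, GeneSet
from .errors import ParameterError, SizingError
from .methylome import CALL_COLUMNS, MethylomeSample

#: low constant level for CHG/CHH sites: human non-CG methylation is near zero
NON_CG_LEVEL = 0.01

#: default 4-unit demethylation panel: per CpG unit, methylation fraction in
#: untreated tumor cells, after 5-Aza treatment, and in a normal-cell reference
DEFAULT_DEMETH_UNITS = {
    "CpG_1": (0.81, 0.10, 0.12),
    "CpG_2": (0.51, 0.27, 0.22),
    "CpG_3": (0.61, 0.61, 0.37),
    "CpG_4": (0.96, 0.89, 0.35),
}


def _check_level(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {x}")


@dataclass(frozen=True)
class PlantedDMR:
    """A region to plant: >= 5 CpGs at distinct levels in the two groups."""

    width_in_cpgs: int = 8
    level_tumor: float = 0.8
    level_normal: float = 0.2

    def __post_init__(self) -> None:
        if self.width_in_cpgs < 5:
            raise ParameterError("planted DMR width must be >= 5 CpGs")
        _check_level(self.level_tumor, "level_tumor")
        _check_level(self.level_normal, "level_normal")

    @property
    def direction(self) -> str:
        return "hyper" if self.level_tumor > self.level_normal else "hypo"


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the small-design defaults."""

    seed: int = 0
    n_per_group: int = 3
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    n_cpg_sites: int = 10_000  # background CpGs, planted sites come on top
    other_context_fraction: float = 0.05
    baseline_cg_level: float = 0.64
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    coverage_mean: float = 30.0
    overdispersion_rho: float = 0.0
    n_genes: int = 50
    gene_length_range: tuple[int, int] = (3000, 8000)
    nb_dispersion: float = 0.1
    planted_deg_log2fc: float = 2.0
    coupling_prob: float = 1.0
    n_planted_up: int = 0  # extra DEGs planted independent of methylation
    n_planted_down: int = 0
    read_length: int = 100
    demeth_units: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_DEMETH_UNITS)
    )

    def __post_init__(self) -> None:
        if self.coverage_mean <= 0:
            raise ParameterError("coverage_mean must be > 0")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ParameterError("overdispersion_rho must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        _check_level(self.baseline_cg_level, "baseline_cg_level")
        _check_level(self.other_context_fraction, "other_context_fraction")
        _check_level(self.coupling_prob, "coupling_prob")
        self.planted_dmrs = [
            d if isinstance(d, PlantedDMR) else PlantedDMR(**d)
            for d in self.planted_dmrs
        ]

    def rng(self, stream: int) -> np.random.Generator:
        """A per-stage generator: streams are decoupled so e.g. adding a
        methylome draw never perturbs the expression draw."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for parameter-recovery tests."""

    #: (chrom, start, end, direction), 0-based half-open
    dmr_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    #: gene -> {"up", "down", "neutral"}
    deg_labels: dict[str, str] = field(default_factory=dict)
    #: per-site true levels: columns pos, context, level_tumor, level_normal
    site_levels: pd.DataFrame | None = None
    #: genes whose promoter hosts a planted DMR: gene_id -> direction
    planted_gene_dirs: dict[str, str] = field(default_factory=dict)
    #: planted promoter-DMR genes actually coupled to a planted DEG
    coupled_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimConfig) -> GeneSet:
    """Place non-overlapping gene bodies on the chromosome.

    Genes get uniform random lengths from ``gene_length_range``, a minimum
    inter-gene gap of 2500 bp (room for a promoter), random strands (both
    strands guaranteed when n_genes >= 2), and a strand-appropriate TSS.
    """
    n = config.n_genes
    if n == 0:
        return GeneSet()
    rng = config.rng(1)
    lo, hi = config.gene_length_range
    gap = 2500
    margin = 3000  # keep promoters on-chromosome at both ends
    lengths = rng.integers(lo, hi + 1, size=n)
    need = int(lengths.sum()) + gap * (n - 1) + 2 * margin
    if need > config.chrom_length:
        raise SizingError(
            f"{n} genes need ~{need} bp but chrom_length is "
            f"{config.chrom_length}; shrink n_genes or gene_length_range"
        )
    slack = config.chrom_length - need
    # distribute the slack randomly between consecutive genes
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    starts = margin + cuts + np.concatenate(([0], np.cumsum(lengths[:-1] + gap)))
    strands = rng.choice(["+", "-"], size=n)
    if n >= 2 and len(set(strands)) == 1:
        strands[-1] = "-" if strands[0] == "+" else "+"
    ends = starts + lengths
    tss = np.where(strands == "+", starts + 1, ends)  # 1-based
    return GeneSet(
        pd.DataFrame(
            {
                "gene_id": [f"gene{i:04d}" for i in range(n)],
                "chrom": config.chrom,
                "strand": strands,
                "start": starts.astype(int),
                "end": ends.astype(int),
                "tss": tss.astype(int),
            }
        )
    )


# ---------------------------------------------------------------------------
# methylome


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    cov = rng.poisson(mean, size=size)
    while (zero := cov == 0).any():
        cov[zero] = rng.poisson(mean, size=int(zero.sum()))
    return cov


def _beta_binomial(
    rng: np.random.Generator, cov: np.ndarray, mu: np.ndarray, rho: float
) -> np.ndarray:
    """Methylated counts; exact binomial when rho = 0."""
    if rho == 0.0:
        return rng.binomial(cov, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    # guard the degenerate mu in {0,1} corners where Beta is undefined
    p = np.where(
        (mu <= 0) | (mu >= 1),
        mu,
        rng.beta(np.clip(a, 1e-12, None), np.clip(b, 1e-12, None)),
    )
    return rng.binomial(cov, p)


def _sample_distinct_positions(
    rng: np.random.Generator, n: int, length: int, taken: set[int]
) -> np.ndarray:
    """n distinct 1-based positions in [1, length], avoiding ``taken``."""
    if n + len(taken) > length:
        raise SizingError("chromosome too short for requested site count")
    out: set[int] = set()
    while len(out) < n:
        draw = rng.integers(1, length + 1, size=2 * (n - len(out)) + 8)
        out.update(int(p) for p in draw if p not in taken and p not in out)
    return np.sort(np.fromiter(list(out)[:n], dtype=int, count=n))


def simulate_methylome(
    config: SimConfig, genes: GeneSet
) -> tuple[list[MethylomeSample], SimTruth]:
    """Simulate per-cytosine count profiles for both groups.

    Each planted DMR is laid down as an evenly spaced CpG run inside the
    promoter of a distinct randomly chosen gene (so methylation-expression
    coupling is testable); background CpGs and CHG/CHH sites are scattered
    uniformly.  Returns the samples (tumor first) and the ground truth.
    """
    rng = config.rng(2)
    chrom = config.chrom
    truth = SimTruth()

    planted_pos: list[np.ndarray] = []
    planted_lvl_t: list[np.ndarray] = []
    planted_lvl_n: list[np.ndarray] = []
    taken: set[int] = set()
    if config.planted_dmrs:
        if len(genes) < len(config.planted_dmrs):
            raise SizingError(
                f"{len(config.planted_dmrs)} planted DMRs need as many genes, "
                f"have {len(genes)}"
            )
        proms = genes.promoter_intervals(DEFAULT_PROMOTER_WINDOW)
        host_idx = rng.choice(len(genes), size=len(config.planted_dmrs), replace=False)
        for dmr, gi in zip(config.planted_dmrs, host_idx):
            prow = proms.iloc[int(gi)]
            w = dmr.width_in_cpgs
            # dense, evenly spaced CpG run inside the promoter (island-like
            # spacing, well under typical inter-CpG window gaps)
            span = int(prow["end"]) - int(prow["start"])
            step = min(50, max(2, span // (w + 1)))
            pos = int(prow["start"]) + 1 + step * np.arange(1, w + 1)
            pos = pos[pos <= config.chrom_length]
            if len(pos) < w:
                raise SizingError("promoter too short for planted DMR width")
            planted_pos.append(pos)
            planted_lvl_t.append(np.full(w, dmr.level_tumor))
            planted_lvl_n.append(np.full(w, dmr.level_normal))
            taken.update(int(p) for p in pos)
            truth.dmr_intervals.append(
                (chrom, int(pos[0]) - 1, int(pos[-1]), dmr.direction)
            )
            truth.planted_gene_dirs[str(prow["gene_id"])] = dmr.direction

    n_bg = config.n_cpg_sites
    frac = config.other_context_fraction
    n_other = int(round(n_bg * frac / (1 - frac))) if frac < 1 else 0
    bg_pos = _sample_distinct_positions(rng, n_bg + n_other, config.chrom_length, taken)
    other_mask = np.zeros(len(bg_pos), dtype=bool)
    if n_other:
        other_mask[rng.choice(len(bg_pos), size=n_other, replace=False)] = True

    pos = np.concatenate([bg_pos] + planted_pos) if planted_pos else bg_pos
    context = np.concatenate(
        [
            np.where(other_mask, rng.choice(["CHG", "CHH"], size=len(bg_pos)), "CG"),
            np.full(sum(len(p) for p in planted_pos), "CG"),
        ]
    )
    bg_level = np.where(other_mask, NON_CG_LEVEL, config.baseline_cg_level)
    lvl_t = np.concatenate([bg_level] + planted_lvl_t) if planted_pos else bg_level
    lvl_n = np.concatenate([bg_level] + planted_lvl_n) if planted_pos else bg_level

    order = np.argsort(pos, kind="stable")
    pos, context, lvl_t, lvl_n = pos[order], context[order], lvl_t[order], lvl_n[order]
    # a planted DMR is a region: background CG sites that land inside a
    # planted interval take the planted levels too
    for dmr, (_, start, end, _) in zip(config.planted_dmrs, truth.dmr_intervals):
        inside = (pos > start) & (pos <= end) & (context == "CG")
        lvl_t[inside] = dmr.level_tumor
        lvl_n[inside] = dmr.level_normal
    truth.site_levels = pd.DataFrame(
        {"pos": pos, "context": context, "level_tumor": lvl_t, "level_normal": lvl_n}
    )

    samples: list[MethylomeSample] = []
    for group, lvl, prefix in (("tumor", lvl_t, "T"), ("normal", lvl_n, "N")):
        for i in range(config.n_per_group):
            cov = _truncated_poisson(rng, config.coverage_mean, len(pos))
            nm = _beta_binomial(rng, cov, lvl, config.overdispersion_rho)
            df = pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strand": "+",
                    "context": context,
                    "n_meth": nm,
                    "n_unmeth": cov - nm,
                },
                columns=CALL_COLUMNS,
            )
            samples.append(MethylomeSample(f"{prefix}{i + 1}", group, df))
    return samples, truth


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative count matrix with per-sample group labels."""

    counts: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("negative expression count")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ParameterError(f"samples without group label: {sorted(missing)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def simulate_expression(
    config: SimConfig, genes: GeneSet, truth: SimTruth
) -> tuple[ExpressionMatrix, SimTruth]:
    """Negative-binomial counts coupled to the planted promoter DMRs.

    A gene hosting a planted promoter hyper-DMR becomes a planted
    down-regulated gene with probability ``coupling_prob`` (hypo -> up,
    symmetrically); optional extra DEGs are planted uncoupled.  Tumor-group
    means are scaled by 2**(+-planted_deg_log2fc) for planted genes.
    """
    rng = config.rng(3)
    gene_ids = [str(g) for g in genes.records["gene_id"]]
    labels = {g: "neutral" for g in gene_ids}

    if config.planted_deg_log2fc != 0.0:
        for gene, direction in truth.planted_gene_dirs.items():
            if rng.random() < config.coupling_prob:
                labels[gene] = "down" if direction == "hyper" else "up"
                truth.coupled_genes.append(gene)
        free = [g for g in gene_ids if labels[g] == "neutral"]
        n_extra = config.n_planted_up + config.n_planted_down
        if n_extra > len(free):
            raise SizingError("not enough neutral genes for extra planted DEGs")
        extra = rng.choice(len(free), size=n_extra, replace=False)
        for k, gi in enumerate(extra):
            labels[free[int(gi)]] = "up" if k < config.n_planted_up else "down"

    base = rng.lognormal(mean=5.0, sigma=1.0, size=len(gene_ids))
    fc = np.array(
        [
            {"up": 1.0, "down": -1.0, "neutral": 0.0}[labels[g]]
            for g in gene_ids
        ]
    ) * config.planted_deg_log2fc
    mu_t = base * np.power(2.0, fc)
    mu_n = base

    alpha = config.nb_dispersion
    size = 1.0 / alpha
    cols = {}
    for group, mu, prefix in (("tumor", mu_t, "T"), ("normal", mu_n, "N")):
        for i in range(config.n_per_group):
            p = size / (size + mu)
            cols[f"{prefix}{i + 1}"] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in counts.columns}
    truth.deg_labels = labels
    return ExpressionMatrix(counts, groups), truth


# ---------------------------------------------------------------------------
# demethylation panel and FASTQ fixtures


def simulate_demeth_panel(config: SimConfig):
    """Build a DemethPanel exactly from the configured per-unit levels."""
    from .demeth import DemethPanel

    rows = []
    for unit, levels in config.demeth_units.items():
        if len(levels) == 2:
            before, after = levels
            ref = None
        else:
            before, after, ref = levels
        for name, x in (("untreated", before), ("treated", after)):
            _check_level(x, f"{unit} {name} level")
        if ref is not None:
            _check_level(ref, f"{unit} reference level")
        rows.append((unit, before, after, ref))
    return DemethPanel(
        pd.DataFrame(
            rows,
            columns=["unit_id", "level_untreated", "level_treated", "level_reference"],
        )
    )


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    qualities: tuple[int, ...]


def simulate_fastq(
    config: SimConfig, n_reads: int, frac_n: float = 0.0, frac_lowq: float = 0.0
) -> list[FastqRead]:
    """Reads where a Bernoulli(frac_n) subset carries > 10% N bases and a
    Bernoulli(frac_lowq) subset > 10% bases under Q20 (clean otherwise)."""
    if n_reads < 0:
        raise ParameterError("n_reads must be >= 0")
    for name, f in (("frac_n", frac_n), ("frac_lowq", frac_lowq)):
        _check_level(f, name)
    if frac_n + frac_lowq > 1.0:
        raise ParameterError("frac_n + frac_lowq must be <= 1")
    rng = config.rng(4)
    length = config.read_length
    n_bad = max(int(0.10 * length) + 1, 1)  # strictly over the 10% rule
    reads = []
    for i in range(n_reads):
        seq = rng.choice(list("ACGT"), size=length)
        qual = rng.integers(30, 41, size=length)
        u = rng.random()
        if u < frac_n:
            idx = rng.choice(length, size=n_bad, replace=False)
            seq[idx] = "N"
        elif u < frac_n + frac_lowq:
            idx = rng.choice(length, size=n_bad, replace=False)
            qual[idx] = rng.integers(2, 20, size=n_bad)
        reads.append(FastqRead(f"read{i}", "".join(seq), tuple(int(q) for q in qual)))
    return reads


def write_fastq(reads: list[FastqRead], path) -> None:
    """Sanger FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path) -> list[FastqRead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            reads.append(
                FastqRead(header[1:], seq, tuple(ord(c) - 33 for c in qual))
            )
    return reads


# ---------------------------------------------------------------------------
# truth serialization


def write_truth_json(truth: SimTruth, path) -> None:
    payload = {
        "dmr_intervals": [list(t) for t in truth.dmr_intervals],
        "deg_labels": truth.deg_labels,
        "planted_gene_dirs": truth.planted_gene_dirs,
        "coupled_genes": truth.coupled_genes,
        "site_levels": (
            truth.site_levels.to_dict(orient="list")
            if truth.site_levels is not None
            else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth_json(path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimTruth(
        dmr_intervals=[tuple(t) for t in payload["dmr_intervals"]],
        deg_labels=payload["deg_labels"],
        planted_gene_dirs=payload["planted_gene_dirs"],
        coupled_genes=payload["coupled_genes"],
        site_levels=(
            pd.DataFrame(payload["site_levels"])
            if payload["site_levels"] is not None
            else None
        ),
    )
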