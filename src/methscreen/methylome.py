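"""Per-cytosine methylation calls: parsing, QC, levels and summaries.

The central statistic is the per-site methylation level

    Rm = Nm / (Nm + Nnm)

where Nm is the number of reads supporting methylation at a cytosine and
Nnm the number of unmethylated reads.  Cytosines carry one of three
sequence contexts — CG, CHG, CHH (H = A, C or T) — and in human tissue
nearly all methylation falls in CG context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .annotation import DEFAULT_PROMOTER_WINDOW, GeneSet
from .errors import (
    DegenerateInputError,
    ParameterError,
    ParseError,
    UndefinedLevelError,
)

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


@dataclass(frozen=True)
class CytosineCall:
    """One cytosine: locus, context and methylated/unmethylated read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ParameterError(f"unknown context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"bad strand {self.strand!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ParameterError("negative read count")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        return methylation_level(self.n_meth, self.n_unmeth)


class MethylomeSample:
    """A sample's coordinate-sorted cytosine calls plus its group label.

    ``calls`` is a DataFrame with columns chrom, pos (1-based), strand,
    context, n_meth, n_unmeth; strictly sorted by (chrom, pos) with unique
    (chrom, pos, strand).
    """

    def __init__(self, sample_id: str, group: str, calls: pd.DataFrame):
        self.sample_id = sample_id
        self.group = group
        df = pd.DataFrame(calls, columns=CALL_COLUMNS).copy()
        if len(df):
            bad = ~df["context"].isin(CONTEXTS)
            if bad.any():
                raise ParameterError(
                    f"unknown context {df.loc[bad, 'context'].iloc[0]!r}"
                )
            if (df[["n_meth", "n_unmeth"]] < 0).any().any():
                raise ParameterError("negative read count")
            df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
            if df.duplicated(["chrom", "pos", "strand"]).any():
                raise ParameterError("duplicate (chrom, pos, strand) locus")
            df = df.reset_index(drop=True)
        self.calls = df

    def __len__(self) -> int:
        return len(self.calls)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MethylomeSample)
            and self.sample_id == other.sample_id
            and self.group == other.group
            and self.calls.reset_index(drop=True).equals(
                other.calls.reset_index(drop=True)
            )
        )


def methylation_level(n_meth: int, n_unmeth: int) -> float:
    """Per-site methylation level Nm / (Nm + Nnm).

    Raises UndefinedLevelError on zero coverage: uncovered sites must be
    filtered out before levels are taken.
    """
    if n_meth < 0 or n_unmeth < 0:
        raise ParameterError("negative read count")
    total = n_meth + n_unmeth
    if total == 0:
        raise UndefinedLevelError("zero coverage: level undefined")
    return n_meth / total


def qc_flag_read(bases: Sequence[str] | str, qualities: Sequence[int]) -> str:
    """Flag a read as 'pass', 'fail_n' or 'fail_quality'.

    A read fails when strictly more than 10% of its bases are unknown (N),
    or strictly more than 10% have Phred quality below 20.  The N rule
    takes precedence when both hold.  Base case is ignored.
    """
    n = len(bases)
    if n == 0:
        raise ParameterError("empty read")
    if len(qualities) != n:
        raise ParameterError(
            f"length mismatch: {n} bases vs {len(qualities)} qualities"
        )
    n_unknown = sum(1 for b in bases if b in ("N", "n"))
    if n_unknown / n > 0.10:
        return "fail_n"
    n_lowq = sum(1 for q in qualities if q < 20)
    if n_lowq / n > 0.10:
        return "fail_quality"
    return "pass"


# ---------------------------------------------------------------------------
# parsing / writing


def write_cytosine_table(sample: MethylomeSample, path) -> None:
    """Six-column TSV: chrom, pos (1-based), strand, context, n_meth, n_unmeth."""
    sample.calls.to_csv(path, sep="\t", header=False, index=False)


def parse_cytosine_table(
    path, dialect: str = "auto", sample_id: str = "sample", group: str = ""
) -> MethylomeSample:
    """Parse a per-cytosine call table into a MethylomeSample.

    Dialects (auto-detected by column count):
      * ``cytosine`` — 6 columns: chrom, pos, strand, context, n_meth, n_unmeth
      * ``cx``       — 7 columns (Bismark CX-report variant): chrom, pos,
        strand, n_meth, n_unmeth, context, trinucleotide

    Malformed rows raise ParseError naming the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            d = dialect
            if d == "auto":
                d = {6: "cytosine", 7: "cx"}.get(len(fields), "")
            try:
                if d == "cytosine" and len(fields) == 6:
                    chrom, pos, strand, context, nm, nu = fields
                elif d == "cx" and len(fields) == 7:
                    chrom, pos, strand, nm, nu, context, _tri = fields
                else:
                    raise ValueError(f"expected 6 or 7 columns, got {len(fields)}")
                pos_i, nm_i, nu_i = int(pos), int(nm), int(nu)
                if context not in CONTEXTS:
                    raise ValueError(f"unknown context token {context!r}")
                if strand not in ("+", "-"):
                    raise ValueError(f"bad strand {strand!r}")
                if nm_i < 0 or nu_i < 0:
                    raise ValueError("negative count")
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            rows.append((chrom, pos_i, strand, context, nm_i, nu_i))
    if not rows:
        logger.warning("empty cytosine table: %s", path)
        return MethylomeSample(sample_id, group, pd.DataFrame(columns=CALL_COLUMNS))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    try:
        return MethylomeSample(sample_id, group, df)
    except ParameterError as exc:
        raise ParseError(f"{path}: {exc}") from None


def destrand(sample: MethylomeSample) -> MethylomeSample:
    """Merge CpG dyads: minus-strand CG calls are added to the plus-strand
    coordinate one bp upstream.  Non-CG contexts are left untouched."""
    df = sample.calls.copy()
    cg_minus = (df["context"] == "CG") & (df["strand"] == "-")
    df.loc[cg_minus, "pos"] -= 1
    df.loc[cg_minus, "strand"] = "+"
    merged = (
        df.groupby(["chrom", "pos", "strand", "context"], as_index=False)[
            ["n_meth", "n_unmeth"]
        ]
        .sum()
        .loc[:, CALL_COLUMNS]
    )
    return MethylomeSample(sample.sample_id, sample.group, merged)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class ContextSummary:
    """Context breakdown of methylated cytosines (mC), Table-2 style.

    ``share`` holds, per context, the percentage of all mC falling in that
    context (3 decimals); None when the sample contains no mC at all.
    """

    n_mc: dict[str, int]
    share: dict[str, float | None]
    total_mc: int
    percent_mc_of_covered_c: float | None
    mean_level: dict[str, float | None] = field(default_factory=dict)


def context_share_from_counts(n_cg: int, n_chg: int, n_chh: int) -> ContextSummary:
    """Context shares from pre-tabulated mC counts per context."""
    counts = {"CG": int(n_cg), "CHG": int(n_chg), "CHH": int(n_chh)}
    if any(v < 0 for v in counts.values()):
        raise ParameterError("negative mC count")
    total = sum(counts.values())
    if total == 0:
        share = {c: None for c in CONTEXTS}
    else:
        share = {c: round_half_away(100.0 * v / total, 3) for c, v in counts.items()}
    return ContextSummary(counts, share, total, None)


def context_share(sample: MethylomeSample, mc_rule=None) -> ContextSummary:
    """Count methylated cytosines per context and their shares.

    ``mc_rule`` maps (n_meth, n_unmeth) arrays to a boolean methylated-site
    mask; the default calls a site methylated when n_meth >= 1.
    """
    df = sample.calls
    if mc_rule is None:
        mc_rule = lambda nm, nu: np.asarray(nm) >= 1  # noqa: E731
    is_mc = mc_rule(df["n_meth"].to_numpy(), df["n_unmeth"].to_numpy())
    counts = {
        c: int(((df["context"] == c).to_numpy() & is_mc).sum()) for c in CONTEXTS
    }
    summary = context_share_from_counts(counts["CG"], counts["CHG"], counts["CHH"])
    covered = len(df)
    summary.percent_mc_of_covered_c = (
        round_half_away(100.0 * summary.total_mc / covered, 3) if covered else None
    )
    for c in CONTEXTS:
        sub = df[df["context"] == c]
        tot = (sub["n_meth"] + sub["n_unmeth"]).sum()
        summary.mean_level[c] = (
            round_half_away(100.0 * sub["n_meth"].sum() / tot, 3) if tot else None
        )
    return summary


@dataclass
class GroupSummaryRow:
    """A report row: label, mean and sample (n-1) standard deviation."""

    label: str
    mean: float
    sd: float | None


def group_mean_sd(
    values: Iterable[float], label: str = "", with_sd: bool = True
) -> GroupSummaryRow:
    """Mean and sample standard deviation, rounded to 3 decimals for report
    output (half away from zero, as printed tables round)."""
    vals = [Fraction(float(v)) for v in values]
    if not vals:
        raise DegenerateInputError("mean of empty value list")
    mean = sum(vals) / len(vals)
    sd = None
    if with_sd:
        if len(vals) < 2:
            raise DegenerateInputError("sample SD needs at least 2 values")
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        sd = round_half_away(float(var) ** 0.5, 3)
    return GroupSummaryRow(label, round_half_away(float(mean), 3), sd)


# ---------------------------------------------------------------------------
# regional profiles


def regional_profile(
    sample: MethylomeSample,
    genes: GeneSet,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    contexts: tuple[str, ...] = ("CG",),
) -> pd.DataFrame:
    """Coverage-weighted mean methylation level per genomic feature.

    Features are promoter, gene_body and intergenic; a site in both a
    promoter and a gene body is counted as promoter.  Features with no
    covered sites are absent from the result (missing, not zero).

    Returns a DataFrame indexed by feature with one column per context.
    """
    df = sample.calls[sample.calls["context"].isin(contexts)]
    sample_chroms = set(df["chrom"].unique())
    proms = genes.promoter_intervals(promoter_window)
    bodies = genes.records
    for chrom in set(bodies["chrom"].unique()) - sample_chroms:
        logger.warning("annotation chromosome %s absent from sample; skipped", chrom)

    out: dict[str, dict[str, float]] = {}
    for context in contexts:
        sub = df[df["context"] == context]
        meth = {f: 0 for f in ("promoter", "gene_body", "intergenic")}
        cov = {f: 0 for f in ("promoter", "gene_body", "intergenic")}
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos0 = grp["pos"].to_numpy() - 1  # 0-based site coordinate
            in_prom = _in_any_interval(pos0, proms[proms["chrom"] == chrom])
            in_body = _in_any_interval(pos0, bodies[bodies["chrom"] == chrom])
            feat = np.where(in_prom, 0, np.where(in_body, 1, 2))
            nm = grp["n_meth"].to_numpy()
            tot = nm + grp["n_unmeth"].to_numpy()
            for i, name in enumerate(("promoter", "gene_body", "intergenic")):
                mask = feat == i
                meth[name] += int(nm[mask].sum())
                cov[name] += int(tot[mask].sum())
        for name in ("promoter", "gene_body", "intergenic"):
            if cov[name] > 0:
                out.setdefault(name, {})[context] = meth[name] / cov[name]
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("feature")


def _in_any_interval(pos0: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of 0-based positions in any [start, end) interval."""
    hit = np.zeros(len(pos0), dtype=bool)
    for start, end in zip(intervals["start"], intervals["end"]):
        hit |= (pos0 >= start) & (pos0 < end)
    return hit
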