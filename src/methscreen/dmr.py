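"""Differentially methylated region (DMR) calling on pooled group counts.

A DMR here is a run of at least 5 CG-context cytosines whose pooled
methylation levels differ by strictly more than 2-fold between the two
groups at a two-sided Fisher exact P < 0.05.  Candidate regions are fixed
5-CpG sliding windows (step 1 CpG) over sites covered in every sample;
significant overlapping windows of the same direction are unioned, their
statistics recomputed over all contained sites and re-checked, and adjacent
same-direction regions are merged when the full span from the start of one
to the end of the other still satisfies the criterion.

Pooling: within a group, methylated and unmethylated read counts are summed
over all sites of the region and all samples; the region level is the
pooled ratio.  Pooling is the only well-defined choice at 3 samples per
group, and admits an exact hypergeometric oracle; it is anti-conservative
when replicates are overdispersed (calibration checks use rho = 0).

The fold is regularized as (max(Lt, Ln) + eps) / (min(Lt, Ln) + eps) with
eps = 0.01 so fully unmethylated regions do not divide by zero.

Coordinates: input cytosine positions are 1-based; all region intervals are
0-based half-open (BED).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .errors import ContractError, ParameterError, UndefinedTestError
from .methylome import MethylomeSample

logger = logging.getLogger(__name__)


@dataclass
class DmrParams:
    """Tuning knobs of the caller; defaults match the documented criterion."""

    min_coverage: int = 4  # per site, per sample, to call the site usable
    max_gap: int = 300  # bp between consecutive usable CpGs in a window
    window_cpgs: int = 5  # "at least 5 CpG loci"
    min_fold: float = 2.0  # strict: fold must exceed this
    max_p: float = 0.05  # strict: p must be below this
    fold_epsilon: float = 0.01


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate interval and the ordered CpG loci it contains."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    site_positions: tuple[int, ...]  # 1-based, strictly increasing

    def __post_init__(self) -> None:
        pos = self.site_positions
        if len(pos) < 5:
            raise ParameterError("candidate region needs >= 5 CpG loci")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ParameterError("site positions must be strictly increasing")
        if pos[0] - 1 < self.start or pos[-1] > self.end:
            raise ParameterError("site positions outside [start, end)")

    @property
    def n_cpg(self) -> int:
        return len(self.site_positions)


@dataclass(frozen=True)
class RegionStats:
    level_tumor: float
    level_normal: float
    fold: float
    p_value: float


@dataclass(frozen=True)
class DMR:
    region: CandidateRegion
    stats: RegionStats
    direction: str  # hyper = tumor above normal

    @property
    def chrom(self) -> str:
        return self.region.chrom

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


# ---------------------------------------------------------------------------
# pooled site table


@dataclass
class _SiteTable:
    """Per-chromosome pooled counts at usable CG sites.

    A site is usable when it is CG context and covered at least
    ``min_coverage`` reads in every sample of both groups.
    """

    pos: dict[str, np.ndarray] = field(default_factory=dict)
    meth_t: dict[str, np.ndarray] = field(default_factory=dict)
    unmeth_t: dict[str, np.ndarray] = field(default_factory=dict)
    meth_n: dict[str, np.ndarray] = field(default_factory=dict)
    unmeth_n: dict[str, np.ndarray] = field(default_factory=dict)

    def chroms(self) -> list[str]:
        return sorted(self.pos)


def build_site_table(
    samples: list[MethylomeSample], params: DmrParams | None = None
) -> _SiteTable:
    params = params or DmrParams()
    tumor = [s for s in samples if s.group == "tumor"]
    normal = [s for s in samples if s.group == "normal"]
    if not tumor or not normal:
        raise ParameterError("need at least one sample in each group")

    frames = []
    for s in samples:
        df = s.calls
        df = df[df["context"] == "CG"]
        frames.append(
            df.set_index(["chrom", "pos"])[["n_meth", "n_unmeth"]].add_prefix(
                f"{s.sample_id}:"
            )
        )
    wide = pd.concat(frames, axis=1, join="inner")
    if wide.empty:
        logger.info("no CG site shared across all samples")
        return _SiteTable()

    cov_cols = {
        s.sample_id: wide[f"{s.sample_id}:n_meth"] + wide[f"{s.sample_id}:n_unmeth"]
        for s in samples
    }
    usable = np.logical_and.reduce(
        [cov >= params.min_coverage for cov in cov_cols.values()]
    )
    wide = wide[usable]
    if wide.empty:
        logger.info("no site passes min_coverage=%d in all samples", params.min_coverage)
        return _SiteTable()

    table = _SiteTable()
    mt = sum(wide[f"{s.sample_id}:n_meth"] for s in tumor)
    ut = sum(wide[f"{s.sample_id}:n_unmeth"] for s in tumor)
    mn = sum(wide[f"{s.sample_id}:n_meth"] for s in normal)
    un = sum(wide[f"{s.sample_id}:n_unmeth"] for s in normal)
    idx = wide.index.to_frame(index=False)
    for chrom, grp_idx in idx.groupby("chrom", sort=True).groups.items():
        order = np.argsort(idx.loc[grp_idx, "pos"].to_numpy(), kind="stable")
        sel = np.asarray(grp_idx)[order]
        table.pos[chrom] = idx.loc[sel, "pos"].to_numpy()
        table.meth_t[chrom] = mt.to_numpy()[sel]
        table.unmeth_t[chrom] = ut.to_numpy()[sel]
        table.meth_n[chrom] = mn.to_numpy()[sel]
        table.unmeth_n[chrom] = un.to_numpy()[sel]
    return table


# ---------------------------------------------------------------------------
# candidate windows


def segment_candidates(
    samples: list[MethylomeSample], params: DmrParams | None = None
) -> list[CandidateRegion]:
    """Every window of ``window_cpgs`` consecutive usable CG sites whose
    consecutive gaps are all <= ``max_gap``, in coordinate order."""
    params = params or DmrParams()
    table = build_site_table(samples, params)
    return _windows_from_table(table, params)


def _windows_from_table(table: _SiteTable, params: DmrParams) -> list[CandidateRegion]:
    w = params.window_cpgs
    out: list[CandidateRegion] = []
    for chrom in table.chroms():
        pos = table.pos[chrom]
        if len(pos) < w:
            continue
        gaps = np.diff(pos)
        for i in range(len(pos) - w + 1):
            if (gaps[i : i + w - 1] <= params.max_gap).all():
                sites = tuple(int(p) for p in pos[i : i + w])
                out.append(
                    CandidateRegion(chrom, sites[0] - 1, sites[-1], sites)
                )
    return out


# ---------------------------------------------------------------------------
# region statistics


def _stats_from_pooled(
    mt: int, ut: int, mn: int, un: int, params: DmrParams
) -> RegionStats:
    if mt + ut == 0 or mn + un == 0:
        raise UndefinedTestError("zero pooled coverage in a group")
    lt = mt / (mt + ut)
    ln = mn / (mn + un)
    eps = params.fold_epsilon
    fold = (max(lt, ln) + eps) / (min(lt, ln) + eps)
    _, p = fisher_exact([[mt, ut], [mn, un]], alternative="two-sided")
    return RegionStats(lt, ln, fold, float(p))


def region_test(
    region: CandidateRegion,
    samples: list[MethylomeSample] | None = None,
    params: DmrParams | None = None,
    table: _SiteTable | None = None,
) -> RegionStats:
    """Pooled two-group test of one region.

    Levels are pooled ratios over the region's sites and the group's
    samples; p is a two-sided Fisher exact test of the pooled 2x2 table
    [methylated, unmethylated] x [tumor, normal].
    """
    params = params or DmrParams()
    if table is None:
        if samples is None:
            raise ParameterError("region_test needs samples or a site table")
        table = build_site_table(samples, params)
    chrom = region.chrom
    if chrom not in table.pos:
        raise UndefinedTestError(f"no usable sites on {chrom}")
    sel = np.isin(table.pos[chrom], region.site_positions)
    return _stats_from_pooled(
        int(table.meth_t[chrom][sel].sum()),
        int(table.unmeth_t[chrom][sel].sum()),
        int(table.meth_n[chrom][sel].sum()),
        int(table.unmeth_n[chrom][sel].sum()),
        params,
    )


def _passes(stats: RegionStats, params: DmrParams) -> bool:
    return stats.fold > params.min_fold and stats.p_value < params.max_p


def _span_region(
    table: _SiteTable, chrom: str, start: int, end: int
) -> CandidateRegion | None:
    """Region over all usable CpGs inside [start, end); None if < 5 sites."""
    pos = table.pos[chrom]
    sel = (pos > start) & (pos <= end)  # 1-based pos in 0-based half-open span
    sites = tuple(int(p) for p in pos[sel])
    if len(sites) < 5:
        return None
    return CandidateRegion(chrom, start, end, sites)


def _direction(stats: RegionStats) -> str:
    return "hyper" if stats.level_tumor > stats.level_normal else "hypo"


# ---------------------------------------------------------------------------
# calling and merging


def call_dmrs(
    samples: list[MethylomeSample], params: DmrParams | None = None
) -> list[DMR]:
    """Call DMRs: test all candidate windows, union overlapping significant
    windows of the same direction, re-check the unions, then merge adjacent
    regions to a fixpoint.  Emitted DMRs all satisfy the full criterion."""
    params = params or DmrParams()
    table = build_site_table(samples, params)
    windows = _windows_from_table(table, params)
    hits: list[DMR] = []
    for win in windows:
        stats = region_test(win, params=params, table=table)
        if _passes(stats, params):
            hits.append(DMR(win, stats, _direction(stats)))

    merged: list[DMR] = []
    for direction in ("hyper", "hypo"):
        same = [d for d in hits if d.direction == direction]
        for chrom in sorted({d.chrom for d in same}):
            runs = _union_overlapping(
                [(d.start, d.end) for d in same if d.chrom == chrom]
            )
            for start, end in runs:
                region = _span_region(table, chrom, start, end)
                if region is None:
                    continue
                stats = region_test(region, params=params, table=table)
                if _passes(stats, params) and _direction(stats) == direction:
                    merged.append(DMR(region, stats, direction))
    merged.sort(key=lambda d: (d.chrom, d.start, d.end))
    return merge_dmrs(merged, samples, params, table=table)


def _union_overlapping(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals that overlap or touch."""
    out: list[list[int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1][1] = max(out[-1][1], end)
        else:
            out.append([start, end])
    return [(a, b) for a, b in out]


def merge_dmrs(
    dmrs: list[DMR],
    samples: list[MethylomeSample] | None = None,
    params: DmrParams | None = None,
    table: _SiteTable | None = None,
) -> list[DMR]:
    """Combine adjacent same-direction DMRs whose full span still passes.

    Left-to-right scan over the sorted list: for two neighbouring DMRs of
    the same chromosome and direction with no opposite-direction DMR
    between them, the span from the start of the first to the end of the
    second is evaluated over all usable CpGs it contains; if that span
    satisfies fold > 2 and P < 0.05 the pair is replaced by the merged
    region.  Iterates to a fixpoint, so the result is idempotent.
    """
    params = params or DmrParams()
    if any(
        (a.chrom, a.start) > (b.chrom, b.start) for a, b in zip(dmrs, dmrs[1:])
    ):
        raise ContractError("merge_dmrs requires DMRs sorted by (chrom, start)")
    if table is None:
        if samples is None:
            if dmrs:
                raise ParameterError("merge_dmrs needs samples or a site table")
            return []
        table = build_site_table(samples, params)

    current = list(dmrs)
    changed = True
    while changed:
        changed = False
        for i in range(len(current) - 1):
            a, b = current[i], current[i + 1]
            if a.chrom != b.chrom or a.direction != b.direction:
                continue
            region = _span_region(table, a.chrom, a.start, b.end)
            if region is None:
                continue
            stats = region_test(region, params=params, table=table)
            if _passes(stats, params) and _direction(stats) == a.direction:
                current[i : i + 2] = [DMR(region, stats, a.direction)]
                changed = True
                break
    return current


# ---------------------------------------------------------------------------
# output


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6+ table: name, -log10(p) score, then the criterion's quantities."""
    rows = []
    for i, d in enumerate(dmrs):
        rows.append(
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "name": f"DMR{i + 1:05d}",
                "score": round(-np.log10(max(d.stats.p_value, 1e-300)), 3),
                "strand": ".",
                "n_cpg": d.region.n_cpg,
                "level_tumor": round(d.stats.level_tumor, 6),
                "level_normal": round(d.stats.level_normal, 6),
                "fold": round(d.stats.fold, 6),
                "p_value": d.stats.p_value,
                "direction": d.direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "n_cpg",
            "level_tumor",
            "level_normal",
            "fold",
            "p_value",
            "direction",
        ],
    )


def write_dmr_bed(dmrs: list[DMR], path) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", header=False, index=False)


def write_dmr_tsv(dmrs: list[DMR], path) -> None:
    """Headered mirror of the BED6+ output."""
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False)


def read_dmr_bed(path) -> pd.DataFrame:
    cols = dmrs_to_frame([]).columns
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=cols)
    return df
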