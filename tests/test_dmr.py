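"""DMR caller: windowing, pooled Fisher test, strict criterion, merging."""

import numpy as np
import pytest
from scipy.stats import fisher_exact, hypergeom

from methscreen.dmr import (
    CandidateRegion,
    DmrParams,
    call_dmrs,
    merge_dmrs,
    region_test,
    segment_candidates,
)
from methscreen.errors import ContractError, ParameterError, UndefinedTestError

from conftest import make_sample, two_group_samples


# ---------------------------------------------------------------------------
# independent reference implementation (plain loops, own union/merge logic)


def brute_force_dmrs(samples, params):
    """Exhaustive 5-CpG window enumeration + the same union/merge rules,
    written as direct loops over per-site dictionaries."""
    per_sample = []
    for s in samples:
        d = {}
        for row in s.calls.itertuples(index=False):
            if row.context == "CG":
                d[(row.chrom, row.pos)] = (row.n_meth, row.n_unmeth)
        per_sample.append((s.group, d))
    keys = set(per_sample[0][1])
    for _, d in per_sample[1:]:
        keys &= set(d)
    usable = sorted(
        k
        for k in keys
        if all(sum(d[k]) >= params.min_coverage for _, d in per_sample)
    )

    def pooled(sites):
        mt = ut = mn = un = 0
        for k in sites:
            for group, d in per_sample:
                nm, nu = d[k]
                if group == "tumor":
                    mt, ut = mt + nm, ut + nu
                else:
                    mn, un = mn + nm, un + nu
        return mt, ut, mn, un

    def evaluate(sites):
        mt, ut, mn, un = pooled(sites)
        lt, ln = mt / (mt + ut), mn / (mn + un)
        eps = params.fold_epsilon
        fold = (max(lt, ln) + eps) / (min(lt, ln) + eps)
        _, p = fisher_exact([[mt, ut], [mn, un]])
        ok = fold > params.min_fold and p < params.max_p
        return ok, ("hyper" if lt > ln else "hypo")

    w = params.window_cpgs
    sig = []
    for i in range(len(usable) - w + 1):
        sites = usable[i : i + w]
        if any(sites[j][0] != sites[0][0] for j in range(w)):
            continue
        if any(
            sites[j + 1][1] - sites[j][1] > params.max_gap for j in range(w - 1)
        ):
            continue
        ok, direction = evaluate(sites)
        if ok:
            sig.append((sites[0][0], sites[0][1] - 1, sites[-1][1], direction))

    def span_sites(chrom, start, end):
        return [k for k in usable if k[0] == chrom and start < k[1] <= end]

    regions = []
    for direction in ("hyper", "hypo"):
        mine = sorted(
            (c, s, e) for (c, s, e, d) in sig if d == direction
        )
        unions = []
        for c, s, e in mine:
            if unions and unions[-1][0] == c and s <= unions[-1][2]:
                unions[-1][2] = max(unions[-1][2], e)
            else:
                unions.append([c, s, e])
        for c, s, e in unions:
            sites = span_sites(c, s, e)
            if len(sites) < 5:
                continue
            ok, d = evaluate(sites)
            if ok and d == direction:
                regions.append((c, s, e, direction))
    regions.sort()

    changed = True
    while changed:
        changed = False
        for i in range(len(regions) - 1):
            (c1, s1, e1, d1), (c2, s2, e2, d2) = regions[i], regions[i + 1]
            if c1 != c2 or d1 != d2:
                continue
            sites = span_sites(c1, s1, e2)
            if len(sites) < 5:
                continue
            ok, d = evaluate(sites)
            if ok and d == d1:
                regions[i : i + 2] = [(c1, s1, e2, d1)]
                changed = True
                break
    return regions


def as_tuples(dmrs):
    return [(d.chrom, d.start, d.end, d.direction) for d in dmrs]


# ---------------------------------------------------------------------------
# candidate segmentation


class TestSegmentCandidates:
    def test_four_usable_cpgs_give_no_candidate(self):
        samples = two_group_samples([10, 40, 70, 100], 0.5, 0.5)
        assert segment_candidates(samples) == []

    def test_five_usable_cpgs_give_one_candidate(self):
        samples = two_group_samples([10, 40, 70, 100, 130], 0.5, 0.5)
        regions = segment_candidates(samples)
        assert len(regions) == 1
        assert regions[0].site_positions == (10, 40, 70, 100, 130)
        assert (regions[0].start, regions[0].end) == (9, 130)

    def test_twenty_cpgs_give_sixteen_windows(self):
        pos = np.arange(100, 2100, 100)
        samples = two_group_samples(pos, 0.5, 0.5)
        regions = segment_candidates(samples)
        assert len(regions) == 16
        # exhaustive window oracle
        expected = [tuple(pos[i : i + 5]) for i in range(16)]
        assert [r.site_positions for r in regions] == expected

    def test_large_gap_splits_windows(self):
        pos = [10, 40, 70, 100, 130, 5000, 5030, 5060, 5090, 5120]
        samples = two_group_samples(pos, 0.5, 0.5)
        regions = segment_candidates(samples)
        assert len(regions) == 2
        assert all(r.n_cpg == 5 for r in regions)

    def test_low_coverage_site_breaks_usability(self):
        samples = two_group_samples([10, 40, 70, 100, 130], 0.5, 0.5, coverage=30)
        # knock one site below min_coverage in one sample
        calls = samples[0].calls
        calls.loc[calls["pos"] == 70, ["n_meth", "n_unmeth"]] = [1, 2]
        assert segment_candidates(samples) == []

    def test_region_invariants_enforced(self):
        with pytest.raises(ParameterError):
            CandidateRegion("chr1", 9, 100, (10, 20, 30, 40))
        with pytest.raises(ParameterError):
            CandidateRegion("chr1", 9, 100, (10, 20, 20, 40, 50))


# ---------------------------------------------------------------------------
# region statistics


class TestRegionTest:
    def _region(self, pos):
        return CandidateRegion("chr1", pos[0] - 1, pos[-1], tuple(pos))

    def test_identical_groups_fold_one_p_one(self):
        pos = [10, 40, 70, 100, 130]
        samples = two_group_samples(pos, 0.5, 0.5)
        stats = region_test(self._region(pos), samples)
        assert stats.fold == 1.0
        assert stats.p_value == 1.0

    def test_p_matches_hypergeometric_enumeration(self):
        # pooled 2x2: tumor 40/10, normal 10/40
        pos = [10, 40, 70, 100, 130]
        samples = []
        samples += two_group_samples(pos, 0.8, 0.2, coverage=10, n_per_group=1)
        samples = [samples[0], samples[1]]
        stats = region_test(self._region(pos), samples)
        # enumeration oracle: sum of hypergeometric pmf <= pmf(observed)
        mt, ut, mn, un = 40, 10, 10, 40
        n, K, N = mt + ut, mt + mn, mt + ut + mn + un
        obs = hypergeom.pmf(mt, N, K, n)
        p_enum = sum(
            hypergeom.pmf(k, N, K, n)
            for k in range(max(0, n + K - N), min(n, K) + 1)
            if hypergeom.pmf(k, N, K, n) <= obs * (1 + 1e-7)
        )
        assert stats.p_value == pytest.approx(p_enum, rel=1e-9)

    def test_fold_follows_epsilon_regularization(self):
        pos = [10, 40, 70, 100, 130]
        samples = two_group_samples(pos, 0.8, 0.2, coverage=10)
        stats = region_test(self._region(pos), samples)
        assert stats.fold == pytest.approx(0.81 / 0.21, rel=1e-12)
        assert stats.level_tumor == pytest.approx(0.8)
        assert stats.level_normal == pytest.approx(0.2)

    def test_levels_reproduce_pooled_counts_exactly(self):
        rng = np.random.default_rng(0)
        pos = [10, 40, 70, 100, 130]
        cov = 20
        samples = []
        for group, prefix in (("tumor", "T"), ("normal", "N")):
            for i in range(3):
                nm = rng.integers(4, cov, size=5)
                samples.append(
                    make_sample(pos, nm, cov - nm, f"{prefix}{i}", group)
                )
        stats = region_test(self._region(pos), samples)
        mt = sum(s.calls["n_meth"].sum() for s in samples if s.group == "tumor")
        assert stats.level_tumor == mt / (3 * 5 * cov)

    def test_zero_pooled_coverage_is_an_error(self):
        region = CandidateRegion("chr2", 0, 200, (10, 40, 70, 100, 130))
        samples = two_group_samples([10, 40, 70, 100, 130], 0.5, 0.5)
        with pytest.raises(UndefinedTestError):
            region_test(region, samples)


# ---------------------------------------------------------------------------
# calling


class TestCallDmrs:
    def test_planted_region_recovered_with_direction(self):
        pos = list(range(100, 500, 50))  # 8 CpGs
        samples = two_group_samples(pos, 0.8, 0.2, coverage=30)
        dmrs = call_dmrs(samples)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.start < pos[-1] and d.end > pos[0]
        assert d.region.n_cpg == 8

    def test_fold_exactly_two_rejected(self):
        # levels 0.59 and 0.29: (0.59+0.01)/(0.29+0.01) = 2 exactly
        pos = [10, 40, 70, 100, 130]
        samples = two_group_samples(pos, 0.59, 0.29, coverage=100)
        stats = region_test(
            CandidateRegion("chr1", 9, 130, tuple(pos)), samples
        )
        assert stats.fold == pytest.approx(2.0, rel=1e-12)
        assert stats.p_value < 0.05  # significant, but the fold gate holds
        assert call_dmrs(samples) == []

    def test_every_emitted_dmr_reverifies_from_raw_counts(self, planted_study):
        _, _, samples, _, _ = planted_study
        params = DmrParams()
        dmrs = call_dmrs(samples, params)
        assert dmrs
        for d in dmrs:
            stats = region_test(d.region, samples, params)
            assert stats.fold > 2.0
            assert stats.p_value < 0.05
            assert d.region.n_cpg >= 5
            assert (stats.level_tumor > stats.level_normal) == (
                d.direction == "hyper"
            )

    def test_matches_brute_force_on_small_instances(self):
        params = DmrParams()
        rng = np.random.default_rng(21)
        for trial in range(6):
            n_sites = int(rng.integers(6, 31))
            pos = np.cumsum(rng.integers(20, 200, size=n_sites)) + 10
            samples = []
            for group, prefix in (("tumor", "T"), ("normal", "N")):
                for i in range(3):
                    cov = rng.integers(8, 40, size=n_sites)
                    base = 0.7 if group == "tumor" else 0.25
                    lvl = np.clip(
                        base + rng.normal(0, 0.15, size=n_sites), 0, 1
                    )
                    nm = rng.binomial(cov, lvl)
                    samples.append(
                        make_sample(pos, nm, cov - nm, f"{prefix}{i}", group)
                    )
            assert as_tuples(call_dmrs(samples, params)) == brute_force_dmrs(
                samples, params
            ), f"trial {trial}"


# ---------------------------------------------------------------------------
# merging


class TestMergeDmrs:
    def test_single_dmr_unchanged(self):
        pos = list(range(100, 500, 50))
        samples = two_group_samples(pos, 0.8, 0.2)
        dmrs = call_dmrs(samples)
        assert merge_dmrs(dmrs, samples) == dmrs

    def test_adjacent_same_direction_merged_across_hot_gap(self):
        # two separated hyper runs; the CpGs between them are also
        # tumor-high, so the full span still passes the criterion
        run1 = list(range(100, 350, 50))
        between = list(range(1000, 1250, 50))
        run2 = list(range(2000, 2250, 50))
        pos = run1 + between + run2
        samples = two_group_samples(pos, 0.8, 0.2)
        params = DmrParams(max_gap=400)  # splits runs, allows no single window
        dmrs = call_dmrs(samples, params)
        assert len(dmrs) == 1
        assert dmrs[0].start == run1[0] - 1
        assert dmrs[0].end == run2[-1]
        # verify the merged span with a direct region test
        stats = region_test(dmrs[0].region, samples, params)
        assert stats.fold > 2 and stats.p_value < 0.05

    def test_opposite_directions_never_merged(self):
        run1 = list(range(100, 350, 50))
        run2 = list(range(2000, 2250, 50))
        lvl_t = [0.8] * 5 + [0.1] * 5
        lvl_n = [0.2] * 5 + [0.7] * 5
        samples = two_group_samples(run1 + run2, lvl_t, lvl_n)
        dmrs = call_dmrs(samples)
        assert [d.direction for d in dmrs] == ["hyper", "hypo"]

    def test_merge_is_idempotent(self, planted_study):
        _, _, samples, _, _ = planted_study
        dmrs = call_dmrs(samples)
        once = merge_dmrs(dmrs, samples)
        twice = merge_dmrs(once, samples)
        assert as_tuples(once) == as_tuples(twice)

    def test_unsorted_input_is_a_contract_error(self):
        run1 = list(range(100, 350, 50))
        run2 = list(range(2000, 2250, 50))
        lvl_t = [0.8] * 5 + [0.1] * 5
        lvl_n = [0.2] * 5 + [0.7] * 5
        samples = two_group_samples(run1 + run2, lvl_t, lvl_n)
        dmrs = call_dmrs(samples)
        assert len(dmrs) == 2
        with pytest.raises(ContractError):
            merge_dmrs(list(reversed(dmrs)), samples)
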