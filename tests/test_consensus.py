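"""Technical-replicate consensus, score distributions, CIs and cut-offs."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rsmscope.consensus import (
    ConsensusPeak,
    ci_lower_limit,
    filter_targets,
    score_distributions,
    select_cutoffs,
    technical_consensus,
)
from rsmscope.formats import Peak
from rsmscope.reference import CFCR_RSMA_FE, REFERENCE_CUTOFFS


def mk_peak(start, end, fe=2.0, pv=100.0, replicon="chr"):
    return Peak(
        replicon=replicon, start=start, end=end, summit=(start + end) // 2,
        tag_count=10, pv_score=pv, fold_enrichment=fe,
    )


def mk_consensus(start, end, fe=2.0, pv=100.0, replicon="chr"):
    return ConsensusPeak(
        replicon=replicon, start=start, end=end, summit=(start + end) // 2,
        fe=fe, pv=pv, members=(),
    )


def brute_force_consensus_count(lists):
    """Oracle: greedy left-to-right chain matching by explicit enumeration."""
    used = [set() for _ in lists]
    count = 0
    for i0, anchor in enumerate(lists[0]):
        # lexicographically-first unused chain, one peak per other replicate,
        # all pairwise overlapping
        choices = []
        members = [anchor]
        ok = True
        for r in range(1, len(lists)):
            found = None
            for j, cand in enumerate(lists[r]):
                if j in used[r]:
                    continue
                if all(
                    cand.replicon == m.replicon
                    and cand.start < m.end
                    and m.start < cand.end
                    for m in members
                ):
                    found = j
                    break
            if found is None:
                ok = False
                break
            members.append(lists[r][found])
            choices.append((r, found))
        if ok:
            count += 1
            for r, j in choices:
                used[r].add(j)
    return count


class TestTechnicalConsensus:
    def test_identical_lists_are_idempotent(self):
        peaks = [mk_peak(0, 100, fe=3.0, pv=80.0), mk_peak(500, 700, fe=5.0, pv=200.0)]
        cons = technical_consensus([peaks, peaks, peaks])
        assert [(c.start, c.end, c.fe, c.pv) for c in cons] == [
            (0, 100, 3.0, 80.0),
            (500, 700, 5.0, 200.0),
        ]

    def test_peak_missing_in_one_replicate_is_dropped(self):
        r1 = [mk_peak(0, 100), mk_peak(500, 700)]
        r2 = [mk_peak(10, 110), mk_peak(510, 690)]
        r3 = [mk_peak(505, 705)]
        cons = technical_consensus([r1, r2, r3])
        assert len(cons) == 1
        assert cons[0].start == 500

    def test_consensus_interval_is_union_and_scores_mean(self):
        cons = technical_consensus(
            [[mk_peak(0, 100, 2.0, 60.0)],
             [mk_peak(20, 140, 4.0, 120.0)],
             [mk_peak(90, 160, 6.0, 90.0)]]
        )
        # chain requires pairwise overlap: 0-100 vs 90-160 overlap at 90-100
        assert len(cons) == 1
        c = cons[0]
        assert (c.start, c.end) == (0, 160)
        assert c.fe == pytest.approx(4.0)
        assert c.pv == pytest.approx(90.0)

    def test_unsorted_input_rejected(self):
        bad = [mk_peak(500, 700), mk_peak(0, 100)]
        with pytest.raises(ValueError, match="sorted"):
            technical_consensus([bad, bad])

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(40):
            lists = []
            for _r in range(3):
                n = int(rng.integers(0, 15))
                starts = np.sort(rng.choice(np.arange(0, 8000, 80), n, replace=False))
                lists.append(
                    [mk_peak(int(s), int(s) + int(rng.integers(20, 75))) for s in starts]
                )
            got = technical_consensus(lists) if all(
                len(l) or True for l in lists
            ) else []
            assert len(got) == brute_force_consensus_count(lists)

    def test_consensus_count_bounded_by_smallest_replicate(self, rng):
        lists = []
        for _ in range(3):
            n = int(rng.integers(1, 10))
            starts = np.sort(rng.choice(np.arange(0, 2000, 50), n, replace=False))
            lists.append([mk_peak(int(s), int(s) + 45) for s in starts])
        assert len(technical_consensus(lists)) <= min(len(l) for l in lists)


class TestScoreDistributions:
    def test_single_peak(self):
        fe, pv = score_distributions([mk_consensus(0, 100, fe=2.5, pv=90.0)])
        assert sum(fe.frequencies) == 1
        assert fe.cumulative_percent[-1] == 100.0

    def test_upper_limit_inclusive_binning(self):
        peaks = [mk_consensus(i * 200, i * 200 + 100, fe=v) for i, v in enumerate([2, 3, 4])]
        fe, _ = score_distributions(peaks, fe_bins=[3, 5], pv_bins=[200])
        assert fe.frequencies == (2, 1)

    def test_matches_bruteforce_binning(self, rng):
        values = rng.uniform(1, 20, size=80)
        peaks = [
            mk_consensus(i * 300, i * 300 + 100, fe=float(v))
            for i, v in enumerate(values)
        ]
        uppers = [4.0, 8.0, 12.0, 16.0, 20.0]
        fe, _ = score_distributions(peaks, fe_bins=uppers, pv_bins=[200])
        lowers = [-np.inf] + uppers[:-1]
        expected = [
            int(np.sum((values > lo) & (values <= up)))
            for lo, up in zip(lowers, uppers)
        ]
        assert list(fe.frequencies) == expected
        assert fe.cumulative_percent[-1] == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            score_distributions([])


class TestCiLowerLimit:
    def test_zero_variance_returns_common_value(self):
        assert ci_lower_limit([3.7, 3.7, 3.7]) == 3.7

    def test_textbook_t_interval(self):
        # mean 4, s = sqrt(2.5) = 1.5811388, t_{0.975,4} = 2.7764451;
        # 4 - 2.7764451 * 1.5811388 / sqrt(5) = 2.0367568 (computed offline)
        got = ci_lower_limit([2, 3, 4, 5, 6])
        assert got == pytest.approx(2.0367568, abs=1e-6)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ci_lower_limit([1.0])

    @given(st.floats(-50, 50))
    def test_translation_equivariance(self, delta):
        base = [2.0, 3.0, 4.0, 5.0, 6.0]
        shifted = [v + delta for v in base]
        assert ci_lower_limit(shifted) == pytest.approx(
            ci_lower_limit(base) + delta, abs=1e-9
        )

    def test_limit_below_mean_unless_degenerate(self, rng):
        for _ in range(20):
            vals = rng.uniform(0, 100, size=int(rng.integers(2, 30)))
            limit = ci_lower_limit(list(vals))
            if np.std(vals) > 0:
                assert limit < np.mean(vals)

    def test_percentile_method_is_conservative_order_statistic(self):
        vals = list(range(1, 101))
        assert ci_lower_limit(vals, method="percentile") == 3  # 2.5th pct, 'lower'
        assert ci_lower_limit([5.0, 9.0, 11.0], method="percentile") == 5.0


class TestSelectCutoffs:
    @pytest.mark.parametrize(
        "fe_limits, expected",
        [((2.15, 2.33, 2.33), 2.15), ((2.68, 2.53), 2.5), ((4.0, 4.22, 4.62), 4.0)],
    )
    def test_fe_rule_min_floor_005(self, fe_limits, expected):
        cs = select_cutoffs(fe_limits, (100.0,), "RsmA")
        assert cs.fe_cutoff == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pv_limits, expected",
        [((130.0, 135.0, 128.0), 130.0), ((180.0, 150.0, 181.0), 170.0),
         ((153.0, 137.0), 145.0)],
    )
    def test_pv_rule_mean_floor_5(self, pv_limits, expected):
        cs = select_cutoffs((2.5,), pv_limits, "RsmA")
        assert cs.pv_cutoff == pytest.approx(expected)

    def test_empty_limits_rejected(self):
        with pytest.raises(ValueError):
            select_cutoffs((), (100.0,), "RsmA")


def _matched_targets(rng, n_reps, n_targets):
    """Per-rep consensus lists where target i occupies slot [1000i, 1000i+200)."""
    reps = []
    values = []
    for _ in range(n_reps):
        row = []
        for i in range(n_targets):
            fe = float(rng.uniform(1.0, 6.0))
            pv = float(rng.uniform(50.0, 400.0))
            row.append((fe, pv))
        values.append(row)
    for r in range(n_reps):
        reps.append(
            [
                mk_consensus(1000 * i, 1000 * i + 200, fe=values[r][i][0],
                             pv=values[r][i][1])
                for i in range(n_targets)
            ]
        )
    return reps, values


class TestFilterTargets:
    def _cutoffs(self, fe, pv):
        return select_cutoffs([fe], [pv], "RsmA")

    def test_cfcr_style_exclusion(self):
        """A target enriched in both replicates but below the RsmA FE
        cut-off is discarded regardless of its p-value score."""
        ref = REFERENCE_CUTOFFS["RsmA"]
        cutoffs = select_cutoffs(
            [ref["fe"] + 0.0], [ref["pv"]], "RsmA"
        )
        assert cutoffs.fe_cutoff == 2.15
        reps = [
            [mk_consensus(0, 300, fe=CFCR_RSMA_FE[0], pv=5000.0)],
            [mk_consensus(10, 310, fe=CFCR_RSMA_FE[1], pv=5000.0)],
        ]
        assert filter_targets(reps, cutoffs) == []

    def test_empty_tables(self):
        assert filter_targets([[], []], self._cutoffs(2.0, 100.0)) == []

    def test_survivor_requires_presence_in_every_replicate(self):
        reps = [
            [mk_consensus(0, 200, fe=5.0, pv=500.0), mk_consensus(1000, 1200, 5.0, 500.0)],
            [mk_consensus(20, 230, fe=5.0, pv=500.0)],
        ]
        out = filter_targets(reps, self._cutoffs(2.0, 100.0))
        assert len(out) == 1 and out[0].start == 0

    def test_matches_bruteforce_row_check(self, rng):
        reps, values = _matched_targets(rng, 2, 12)
        cutoffs = self._cutoffs(2.5, 150.0)
        got = {t.start // 1000 for t in filter_targets(reps, cutoffs)}
        expected = {
            i
            for i in range(12)
            if all(
                values[r][i][0] >= cutoffs.fe_cutoff
                and values[r][i][1] > cutoffs.pv_cutoff
                for r in range(2)
            )
        }
        assert got == expected

    def test_raising_cutoffs_never_increases_survivors(self, rng):
        reps, _ = _matched_targets(rng, 3, 15)
        counts = []
        for fe in [1.0, 2.0, 3.0, 4.0]:
            row = []
            for pv in [50.0, 150.0, 250.0, 350.0]:
                row.append(len(filter_targets(reps, self._cutoffs(fe, pv))))
            assert row == sorted(row, reverse=True)
            counts.append(row[0])
        assert counts == sorted(counts, reverse=True)
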