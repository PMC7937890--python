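"""Poisson scoring, local background estimation and the peak caller."""

import dataclasses

import numpy as np
import pytest
from mpmath import mp

from rsmscope.formats import TagLibrary
from rsmscope.peakcall import (
    PeakCallParams,
    call_peaks,
    empirical_fdr,
    local_lambda,
    poisson_sf_score,
)
from rsmscope.synthio import (
    SimulationConfig,
    generate_genome_annotation,
    plant_targets,
    simulate_tag_libraries,
)

from conftest import uniform_library


def mp_poisson_score(k: int, lam: float) -> float:
    """Independent oracle: -10*log10 sum_{j>=k} e^-lam lam^j / j! summed in
    50-digit arithmetic until terms fall below 1e-30 of the partial sum."""
    mp.dps = 50
    lam_mp = mp.mpf(lam)
    term = mp.e ** (-lam_mp) * lam_mp ** k / mp.factorial(k)
    total = term
    j = k
    while term > total * mp.mpf("1e-30"):
        j += 1
        term *= lam_mp / j
        total += term
    return float(-10 * mp.log(total, 10))


class TestPoissonScore:
    def test_zero_count_scores_zero(self):
        assert poisson_sf_score(0, 5.0) == 0.0
        assert poisson_sf_score(0, 0.001) == 0.0

    def test_matches_summation_oracle_on_grid(self):
        ks = np.arange(0, 501, 7)  # stride keeps runtime low; full grid in
        lams = [0.1, 0.5, 1, 2, 5, 10, 50]  # test_acceptance exercises all k
        for lam in lams:
            for k in ks:
                if k == 0:
                    continue
                got = poisson_sf_score(int(k), lam)
                want = mp_poisson_score(int(k), lam)
                assert got == pytest.approx(want, rel=1e-9)

    def test_monotone_in_k_and_lambda(self):
        assert poisson_sf_score(6, 5.0) > poisson_sf_score(5, 5.0)
        assert poisson_sf_score(10, 2.0) > poisson_sf_score(10, 3.0)

    def test_no_underflow_deep_in_tail(self):
        score = poisson_sf_score(500, 0.1)
        assert np.isfinite(score) and score > 3000

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            poisson_sf_score(3, 0.0)


class TestLocalLambda:
    params = PeakCallParams()

    def test_uniform_control_equals_background(self):
        mass = np.full(20_000, 0.25)
        lam_bg = 0.25 * 110 * 1.0  # rate x effective length x depth ratio
        for interval in [(100, 110), (5000, 5010), (19_900, 19_910)]:
            lam = local_lambda(
                mass, interval, self.params, lam_bg, 1.0, effective_length=110
            )
            assert lam == pytest.approx(lam_bg, rel=1e-9)

    def test_spike_in_small_window_raises_lambda(self):
        mass = np.zeros(20_000)
        mass[10_200] = 50  # inside the 1 kb window around 10_000 only
        lam_bg = mass.sum() * 10 / 20_000
        lam = local_lambda(mass, (10_000, 10_010), self.params, lam_bg, 1.0)
        assert lam > lam_bg
        assert lam == pytest.approx(50 * 10 / 1000, rel=1e-9)

    def test_matches_bruteforce_window_sums(self, rng):
        mass = rng.poisson(0.3, size=30_000).astype(float)
        lam_bg = mass.sum() * 10 / mass.size * 0.7
        for _ in range(25):
            s = int(rng.integers(0, mass.size - 10))
            interval = (s, s + 10)
            centre = s + 5
            expected = lam_bg
            for w in self.params.all_windows:
                lo, hi = max(0, centre - w // 2), min(mass.size, centre + (w + 1) // 2)
                expected = max(expected, mass[lo:hi].sum() * 10 / (hi - lo) * 0.7)
            got = local_lambda(mass, interval, self.params, lam_bg, 0.7)
            assert got == pytest.approx(expected, rel=1e-12)


class TestCallPeaks:
    def test_identical_libraries_give_no_peaks_20_seeds(self):
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            lib = uniform_library(rng, n_tags=20_000, length=50_000)
            control = dataclasses.replace(lib, role="total_control")
            assert call_peaks(lib, control) == []

    def test_single_planted_locus_detected(self):
        cfg = SimulationConfig(
            genome_length=60_000,
            n_features=25,
            n_divergent_pairs=0,
            n_repeat_groups=0,
            frac_ncrna=0.0,
            venn_design={("RsmA",): 1},
            enrichment_lo=16.0,
            enrichment_hi=16.0,
            pulldown_depth=40_000,
            control_depth=80_000,
            n_bio_reps={"RsmA": 2},
            carryover_n_loci=0,
        )
        ann = generate_genome_annotation(cfg, 7)
        truth = plant_targets(ann, cfg, 7)
        libs = simulate_tag_libraries(ann, truth, cfg, 7)
        treatment = next(l for l in libs if l.role == "pulldown")
        control = next(l for l in libs if l.role == "total_control")
        peaks = call_peaks(treatment, control)
        assert len(peaks) == 1
        (locus,) = truth.target_sets["RsmA"]
        feat = ann.by_locus()[locus]
        assert peaks[0].start < feat.end and peaks[0].end > feat.start
        assert peaks[0].fold_enrichment > 4

    def test_single_tag_treatment_yields_nothing(self):
        lib = TagLibrary(
            sample_id="one", protein="RsmA", role="pulldown", bio_rep=1,
            tech_rep=1, replicons=(("chr", 10_000),), tags=(("chr", 55, "+"),),
        )
        control = uniform_library(
            np.random.default_rng(0), n_tags=2000, length=10_000,
            role="total_control",
        )
        assert call_peaks(lib, control) == []

    def test_peak_geometry_invariants(self, rng, small_sim_config):
        ann = generate_genome_annotation(small_sim_config, 3)
        truth = plant_targets(ann, small_sim_config, 3)
        libs = simulate_tag_libraries(ann, truth, small_sim_config, 3)
        treatment = next(
            l for l in libs if l.role == "pulldown" and l.protein == "RsmE"
        )
        control = next(
            l for l in libs if l.role == "total_control" and l.protein == "RsmE"
        )
        params = PeakCallParams()
        peaks = call_peaks(treatment, control, params)
        assert peaks
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start or a.replicon != b.replicon
        for p in peaks:
            assert p.length >= params.minimum_length
            assert p.start <= p.summit < p.end

    def test_doubling_tags_preserves_fe_and_scores(self, small_sim_config):
        ann = generate_genome_annotation(small_sim_config, 4)
        truth = plant_targets(ann, small_sim_config, 4)
        libs = simulate_tag_libraries(ann, truth, small_sim_config, 4)
        t = next(l for l in libs if l.role == "pulldown" and l.protein == "RsmA")
        c = next(l for l in libs if l.role == "total_control" and l.protein == "RsmA")
        t2 = dataclasses.replace(t, tags=t.tags + t.tags)
        c2 = dataclasses.replace(c, tags=c.tags + c.tags)
        peaks = call_peaks(t, c)
        doubled = call_peaks(t2, c2)
        by_summit = {p.summit: p for p in doubled}
        for p in peaks:
            assert p.summit in by_summit
            q = by_summit[p.summit]
            assert q.fold_enrichment == pytest.approx(p.fold_enrichment, rel=1e-9)
            assert q.pv_score >= p.pv_score - 1e-9

    def test_determinism(self, small_sim_config):
        ann = generate_genome_annotation(small_sim_config, 5)
        truth = plant_targets(ann, small_sim_config, 5)
        libs = simulate_tag_libraries(ann, truth, small_sim_config, 5)
        t = next(l for l in libs if l.role == "pulldown")
        c = next(l for l in libs if l.role == "total_control")
        assert call_peaks(t, c) == call_peaks(t, c)

    def test_replicon_mismatch_rejected(self, rng):
        a = uniform_library(rng, n_tags=100, length=1000)
        b = TagLibrary(
            sample_id="c", protein="RsmA", role="total_control", bio_rep=1,
            tech_rep=1, replicons=(("other", 1000),), tags=(("other", 5, "+"),),
        )
        with pytest.raises(ValueError):
            call_peaks(a, b)


class TestEmpiricalFdr:
    def _peak(self, score, start=0):
        from rsmscope.formats import Peak

        return Peak("chr", start, start + 100, start + 50, 10, score, 2.0)

    def test_empty_swapped_gives_zero_fdr(self):
        fwd = [self._peak(80), self._peak(120, 200)]
        out = empirical_fdr(fwd, [])
        assert all(p.fdr_percent == 0.0 for p in out)

    def test_forward_equal_swapped_gives_100(self):
        fwd = [self._peak(80), self._peak(120, 200), self._peak(55, 400)]
        out = empirical_fdr(fwd, list(fwd))
        assert all(p.fdr_percent == 100.0 for p in out)

    def test_direct_counting_example(self):
        fwd = [self._peak(100), self._peak(50, 200)]
        swapped = [self._peak(60)]
        out = {p.pv_score: p.fdr_percent for p in empirical_fdr(fwd, swapped)}
        assert out[100] == 0.0
        assert out[50] == 50.0

    def test_fdr_nonincreasing_in_score(self, rng):
        fwd = [self._peak(float(s), i * 200) for i, s in enumerate(rng.uniform(50, 500, 30))]
        swp = [self._peak(float(s), i * 200) for i, s in enumerate(rng.uniform(50, 500, 10))]
        out = sorted(empirical_fdr(fwd, swp), key=lambda p: p.pv_score)
        fdrs = [p.fdr_percent for p in out]
        assert all(a >= b for a, b in zip(fdrs, fdrs[1:]))
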