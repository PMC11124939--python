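"""Association statistics: SNP-index, ED, smoothing, thresholds, regions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bulkscan import (
    BulkSegregantScan,
    Region,
    call_regions,
    ed,
    ed_power,
    ed_threshold,
    fit_distance,
    intersect_regions,
    simulate_ci,
    snp_index,
)
from bulkscan.assoc import ScanTrack
from bulkscan.intervals import union_regions
from tests.conftest import make_site, sites_frame


def _oriented(rows):
    table = sites_frame(rows)
    table["pp05_allele"] = "alt"
    return table


class TestSnpIndex:
    def test_fixed_bulks(self):
        table = _oriented([make_site(green=(30, 0), purple=(0, 30))])
        out = snp_index(table)
        assert out.loc[0, "index_green"] == 0.0
        assert out.loc[0, "index_purple"] == 1.0
        assert out.loc[0, "delta"] == 1.0

    def test_identical_depth_vectors_give_zero_delta(self):
        table = _oriented([make_site(green=(12, 8), purple=(12, 8))])
        assert snp_index(table).loc[0, "delta"] == 0.0

    def test_hand_arithmetic(self):
        table = _oriented([make_site(green=(12, 8), purple=(5, 15))])
        out = snp_index(table)
        assert out.loc[0, "index_green"] == pytest.approx(0.4)
        assert out.loc[0, "index_purple"] == pytest.approx(0.75)
        assert out.loc[0, "delta"] == pytest.approx(0.35)

    def test_zero_depth_flagged(self):
        table = _oriented([make_site(green=(0, 0))])
        out = snp_index(table)
        assert not out.loc[0, "ok"]
        assert np.isnan(out.loc[0, "delta"])

    def test_unoriented_sites_rejected(self):
        table = sites_frame([make_site()])
        with pytest.raises(ValueError, match="orient"):
            snp_index(table)

    def test_indices_bounded(self, small_filtered):
        out = snp_index(small_filtered)
        ok = out[out["ok"]]
        assert ok["index_green"].between(0, 1).all()
        assert ok["index_purple"].between(0, 1).all()
        assert ok["delta"].between(-1, 1).all()


class TestEd:
    def test_equal_frequencies_zero(self):
        table = sites_frame([make_site(green=(12, 8), purple=(24, 16))])
        assert ed(table).loc[0, "ed"] == 0.0

    def test_opposite_fixation_maximal(self):
        table = sites_frame([make_site(green=(30, 0), purple=(0, 30))])
        assert ed(table).loc[0, "ed"] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_closed_form_oracle(self, rng):
        """ED equals sqrt(2)|Δf_alt| to 1e-12 on random biallelic depths."""
        rows = []
        for pos in range(100):
            rows.append(
                make_site(
                    pos=pos + 1,
                    green=tuple(rng.integers(1, 80, 2)),
                    purple=tuple(rng.integers(1, 80, 2)),
                )
            )
        table = sites_frame(rows)
        out = ed(table)
        f_g = table["green_alt"] / (table["green_ref"] + table["green_alt"])
        f_p = table["purple_alt"] / (table["purple_ref"] + table["purple_alt"])
        oracle = np.sqrt(2.0) * np.abs(f_g - f_p)
        assert np.max(np.abs(out["ed"].to_numpy() - oracle.to_numpy())) < 1e-12

    @pytest.mark.parametrize("value,k,expected", [(1.0, 7.0, 1.0), (0.5, 5.0, 0.03125)])
    def test_power_transform(self, value, k, expected):
        records = pd.DataFrame({"ed": [value]})
        assert ed_power(records, k=k).loc[0, "ed_k"] == pytest.approx(expected, abs=1e-15)

    def test_power_one_is_identity(self, rng):
        records = pd.DataFrame({"ed": rng.random(50)})
        out = ed_power(records, k=1.0)
        assert np.allclose(out["ed_k"], out["ed"], atol=1e-15)


class TestFitDistance:
    def test_constant_preserved(self):
        pos = np.arange(20) * 1e5
        fitted = fit_distance(pos, np.full(20, 3.7), bandwidth_bp=1e6)
        assert np.allclose(fitted, 3.7, atol=1e-12)

    @pytest.mark.parametrize("degree", [0, 1])
    def test_matches_brute_force_oracle(self, degree, rng):
        """Independently coded tricube weighted fit agrees to 1e-10."""
        pos = np.sort(rng.uniform(0, 5e6, 50))
        val = rng.normal(size=50)
        h = 8e5
        fitted = fit_distance(pos, val, bandwidth_bp=h, degree=degree)
        for i in range(50):
            d = np.abs(pos - pos[i]) / h
            w = np.where(d < 1, (1 - d**3) ** 3, 0.0)
            if degree == 0:
                expect = np.sum(w * val) / np.sum(w)
            else:
                # weighted least squares, centred at the evaluation point
                X = np.stack([np.ones_like(pos), pos - pos[i]], axis=1)
                beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * val))
                expect = beta[0]
            assert fitted[i] == pytest.approx(expect, abs=1e-10)

    def test_infinite_bandwidth_gives_global_mean(self, rng):
        pos = np.sort(rng.uniform(0, 1e6, 30))
        val = rng.normal(size=30)
        fitted = fit_distance(pos, val, bandwidth_bp=1e18, degree=0)
        assert np.allclose(fitted, val.mean(), atol=1e-9)

    def test_missing_values_still_fitted(self):
        pos = np.arange(10) * 1e5
        val = np.arange(10.0)
        val[4] = np.nan
        fitted = fit_distance(pos, val, bandwidth_bp=2e5)
        assert np.isfinite(fitted).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="bandwidth"):
            fit_distance(np.arange(5.0), np.arange(5.0), bandwidth_bp=0)
        with pytest.raises(ValueError, match="non-missing"):
            fit_distance(np.arange(5.0), np.full(5, np.nan), bandwidth_bp=1e5)


def _exact_ci_oracle(depth, n_bulk, level):
    """Exhaustive enumeration of the null |delta| distribution."""
    from scipy.stats import binom

    geno_p = {0: 0.25, 1: 0.5, 2: 0.25}
    # distribution of one bulk's read-fraction
    freq_dist = {}
    for combo in itertools.product([0, 1, 2], repeat=n_bulk):
        p_g = np.prod([geno_p[g] for g in combo])
        f_true = sum(combo) / (2 * n_bulk)
        for reads in range(depth + 1):
            p = p_g * binom.pmf(reads, depth, f_true)
            freq_dist[reads / depth] = freq_dist.get(reads / depth, 0.0) + p
    # |delta| distribution over two independent bulks
    abs_delta = {}
    for fa, pa in freq_dist.items():
        for fb, pb in freq_dist.items():
            d = abs(fb - fa)
            abs_delta[d] = abs_delta.get(d, 0.0) + pa * pb
    values = sorted(abs_delta)
    cdf = np.cumsum([abs_delta[v] for v in values])
    return values[int(np.searchsorted(cdf, level))]


class TestSimulateCi:
    def test_level_one_is_max(self):
        ci = simulate_ci([10], n_bulk=5, reps=2000, levels=(1.0,), seed=0)
        rng = np.random.default_rng(0)
        assert ci.thresholds[0, 0] <= 1.0

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo thresholds at depth 2, n_bulk 1 agree with the exact
        null distribution within 0.02."""
        ci = simulate_ci([2], n_bulk=1, reps=100_000, levels=(0.95, 0.99), seed=123)
        for j, level in enumerate((0.95, 0.99)):
            exact = _exact_ci_oracle(depth=2, n_bulk=1, level=level)
            assert abs(ci.thresholds[0, j] - exact) <= 0.02

    def test_thresholds_shrink_with_depth_and_bulk_size(self):
        """Null |delta| quantiles are non-increasing in depth and n_bulk."""
        grid = [10, 20, 50, 100]
        ci = simulate_ci(grid, n_bulk=30, reps=50_000, levels=(0.99,), seed=7)
        assert (np.diff(ci.thresholds[:, 0]) <= 0.01).all()
        by_bulk = [
            simulate_ci([30], n_bulk=nb, reps=50_000, levels=(0.99,), seed=7).thresholds[0, 0]
            for nb in grid
        ]
        assert (np.diff(by_bulk) <= 0.01).all()

    def test_interpolation_clamped(self):
        ci = simulate_ci([10, 20], n_bulk=5, reps=2000, seed=1)
        assert ci.at(5, 0.99) == ci.at(10, 0.99)
        assert ci.at(100, 0.99) == ci.at(20, 0.99)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="level"):
            simulate_ci([10], n_bulk=5, reps=2000, levels=(1.5,))
        with pytest.raises(ValueError, match="reps"):
            simulate_ci([10], n_bulk=5, reps=10)


class TestEdThreshold:
    def test_constant_vector(self):
        assert ed_threshold([2.5] * 10) == 2.5

    def test_hand_computation(self):
        """{1,2,3}: median 2 + 3 * sample SD 1 = 5."""
        assert ed_threshold([1.0, 2.0, 3.0]) == pytest.approx(5.0, abs=1e-12)

    def test_matches_independent_one_liner(self, rng):
        for _ in range(5):
            v = rng.normal(size=200)
            assert ed_threshold(v) == pytest.approx(
                float(np.median(v) + 3 * np.std(v, ddof=1)), abs=1e-12
            )

    def test_median_robust_to_inserted_median(self):
        v = [1.0, 2.0, 3.0]
        assert np.median(v + [2.0]) == np.median(v)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ed_threshold([1.0])


def _track(positions, fitted, chrom="chr10"):
    return ScanTrack(
        chrom=chrom,
        positions=np.asarray(positions),
        raw=np.asarray(fitted),
        fitted=np.asarray(fitted, dtype=float),
        statistic="ed_k",
        site_type="SNP",
    )


class TestCallRegions:
    def test_all_below_threshold_empty(self):
        track = _track(np.arange(50) * 1e5 + 1, np.zeros(50))
        assert call_regions(track, threshold=1.0) == []

    def test_paper_scale_run_length(self):
        """A 50-marker run spanning 62.6-82.4 Mb yields one 19.80 Mb region."""
        pos = np.linspace(62_600_000, 82_400_000, 50).astype(int)
        track = _track(pos, np.full(50, 5.0))
        regions = call_regions(track, threshold=1.53, min_sites=10)
        assert len(regions) == 1
        assert regions[0].start == 62_600_000 and regions[0].end == 82_400_000
        assert regions[0].length_mb == 19.80

    def test_nearby_runs_merged(self):
        """Two runs 0.5 Mb apart merge under the default 1 Mb gap."""
        pos = np.concatenate([np.arange(20) * 5e4 + 1, np.arange(20) * 5e4 + 1.5e6])
        fitted = np.full(40, 2.0)
        track = _track(pos, fitted)
        regions = call_regions(track, threshold=1.0, gap_bp=1_000_000, min_sites=10)
        assert len(regions) == 1 and regions[0].n_sites == 40

    def test_min_sites_filter(self):
        track = _track(np.arange(5) * 1e5 + 1, np.full(5, 9.0))
        assert call_regions(track, threshold=1.0, min_sites=10) == []
        assert len(call_regions(track, threshold=1.0, min_sites=5)) == 1

    def test_per_site_threshold_array(self):
        pos = np.arange(30) * 1e5 + 1
        fitted = np.full(30, 0.5)
        thr = np.full(30, 0.6)
        thr[10:25] = 0.4  # lower threshold exposes a 15-marker run
        track = _track(pos, fitted)
        regions = call_regions(track, threshold=thr, min_sites=10)
        assert len(regions) == 1 and regions[0].n_sites == 15


class TestIntersectRegions:
    def test_disjoint_empty(self):
        a = [Region("chr1", 1, 100)]
        b = [Region("chr1", 200, 300)]
        regions, total = intersect_regions(a, b)
        assert regions == [] and total == 0.0

    def test_paper_interval(self):
        """[62.6-82.4] ∩ [50.0-82.4] Mb on chromosome 10 is 19.80 Mb."""
        a = [Region("chr10", 62_600_000, 82_400_000)]
        b = [Region("chr10", 50_000_000, 82_400_000)]
        regions, total = intersect_regions(a, b)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (62_600_000, 82_400_000)
        assert total == 19.80

    @given(
        st.lists(
            st.tuples(st.integers(1, 500), st.integers(1, 500)).map(
                lambda t: Region("chr1", min(t), max(t))
            ),
            min_size=0,
            max_size=6,
        ),
        st.lists(
            st.tuples(st.integers(1, 500), st.integers(1, 500)).map(
                lambda t: Region("chr1", min(t), max(t))
            ),
            min_size=0,
            max_size=6,
        ),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_commutative_and_idempotent(self, a, b):
        ab, total_ab = intersect_regions(a, b)
        ba, total_ba = intersect_regions(b, a)
        assert [(r.start, r.end) for r in ab] == [(r.start, r.end) for r in ba]
        assert total_ab == total_ba
        again, total_again = intersect_regions(ab, ab)
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in ab]


class TestScanModel:
    def test_scan_recovers_qtl_region(self, small_filtered, small_config):
        res = BulkSegregantScan(small_filtered, n_bulk=30).fit(reps=3000, seed=9)
        chrom, pos = small_config.qtl_position
        assert any(r.contains(chrom, pos) for r in res.regions_delta)
        assert res.summary()  # renders without error

    def test_union_merge_of_marker_types(self, small_filtered):
        res = BulkSegregantScan(small_filtered, n_bulk=30).fit(reps=3000, seed=9)
        merged = union_regions(res.regions_delta)
        assert [(r.start, r.end) for r in merged] == [
            (r.start, r.end) for r in res.regions_delta
        ]

    def test_requires_orientation(self, small_sites):
        with pytest.raises(ValueError, match="pp05_allele"):
            BulkSegregantScan(small_sites)
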