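"""Occlusion maps, hotspots, matching and the exact 2x2 statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from tkrisk.occlusion import (
    ContingencyResult,
    OcclusionConfig,
    OcclusionMap,
    biomarker_table,
    contingency_counts,
    cornfield_ci,
    fisher_exact_two_tailed,
    hotspot_mask,
    match_controls,
    occlusion_map,
    odds_ratio,
    tissue_hotspot_flags,
)
from tkrisk.synthetic import PhantomSpec, SubjectRecord, TissueSpec, generate_atlas


def make_record(pid, stratum="none", koos=80.0, label="control"):
    return SubjectRecord(
        patient_id=pid, visit_time=0.0, kl_grade=0, stratum=stratum,
        tkr_time=None, label=label, nonimaging={}, koos_pain=koos,
    )


class TestOcclusionMap:
    def test_constant_risk_fn_zero_map(self):
        vol = np.random.default_rng(0).uniform(size=(12, 12, 12))
        cfg = OcclusionConfig(voxel_shape=(4, 4, 4), stride=(4, 4, 4))
        omap = occlusion_map(lambda v: 0.5, vol, cfg)
        assert (omap.values == 0).all()
        assert (omap.coverage == 1).all()

    def test_full_scale_position_count_and_coverage(self):
        # 120x320x320 with 12x32x32 occluder at stride 12: 10 x 25 x 25
        shape = (120, 320, 320)
        occ, stride = (12, 32, 32), (12, 12, 12)
        per_axis = [(s - o) // st + 1 for s, o, st in zip(shape, occ, stride)]
        assert per_axis == [10, 25, 25] and int(np.prod(per_axis)) == 6250
        covered = np.zeros(shape, dtype=bool)
        for z in range(0, shape[0] - occ[0] + 1, stride[0]):
            for y in range(0, shape[1] - occ[1] + 1, stride[1]):
                for x in range(0, shape[2] - occ[2] + 1, stride[2]):
                    covered[z : z + 12, y : y + 32, x : x + 32] = True
        assert covered.all()

    def test_position_count_matches_enumeration_on_desk_grid(self):
        vol = np.zeros((10, 15, 15))
        cfg = OcclusionConfig(voxel_shape=(4, 6, 6), stride=(3, 4, 4))
        calls = []
        occlusion_map(lambda v: float(len(calls)) if calls.append(1) is None
                      else 0.0, vol, cfg)
        expected = ((10 - 4) // 3 + 1) * ((15 - 6) // 4 + 1) ** 2
        assert len(calls) == expected + 1  # + 1 baseline call

    def test_linear_risk_fn_maximal_inside_scoring_region(self):
        # risk = mean intensity inside region R: occluding R's block is the
        # only occlusion that changes the score
        vol = np.ones((12, 12, 12))
        region = np.zeros_like(vol, dtype=bool)
        region[4:8, 4:8, 4:8] = True

        def risk(v):
            return float(v[region].mean()) / 2.0

        cfg = OcclusionConfig(voxel_shape=(4, 4, 4), stride=(4, 4, 4),
                              fill_value=0.0)
        omap = occlusion_map(risk, vol, cfg)
        assert omap.values[region].min() > omap.values[~region].max()

    def test_vectorized_equals_loop(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(size=(8, 8, 8))
        w = rng.uniform(size=(8, 8, 8))

        def risk(v):
            return float((v * w).sum())

        def risk_batch(batch):
            return (batch * w).sum(axis=(1, 2, 3))

        cfg = OcclusionConfig(voxel_shape=(4, 4, 4), stride=(2, 2, 2))
        a = occlusion_map(risk, vol, cfg)
        b = occlusion_map(risk_batch, vol, cfg, vectorized=True)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-6)
        np.testing.assert_array_equal(a.coverage, b.coverage)
        assert a.coverage.max() > 1  # overlapping strides covered repeatedly

    def test_occluder_larger_than_volume_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            occlusion_map(lambda v: 0.0, np.zeros((4, 4, 4)),
                          OcclusionConfig(voxel_shape=(8, 8, 8)))


class TestHotspotMask:
    def _map(self, values, coverage=None):
        values = np.asarray(values, float)
        cov = np.ones_like(values, dtype=np.int32) if coverage is None else coverage
        return OcclusionMap(values=values, coverage=cov)

    def test_exactly_five_percent_of_thousand(self):
        rng = np.random.default_rng(0)
        omap = self._map(rng.uniform(size=(10, 10, 10)))
        mask = hotspot_mask(omap, 0.05)
        assert int(mask.sum()) == 50

    def test_constant_map_ties_broken_by_linear_index(self):
        omap = self._map(np.ones((10, 10, 10)))
        mask = hotspot_mask(omap, 0.05)
        assert mask.ravel()[:50].all() and not mask.ravel()[50:].any()

    def test_strictly_decreasing_values_prefix_flagged(self):
        vals = np.arange(1000, 0, -1, dtype=float).reshape(10, 10, 10)
        mask = hotspot_mask(self._map(vals), 0.05)
        assert mask.ravel()[:50].all() and not mask.ravel()[50:].any()

    def test_uncovered_voxels_excluded_from_ranking(self):
        vals = np.zeros((10, 10, 10))
        cov = np.zeros_like(vals, dtype=np.int32)
        cov.ravel()[:200] = 1
        vals.ravel()[300] = 99.0  # high value but uncovered: ignored
        mask = hotspot_mask(self._map(vals, cov), 0.05)
        assert int(mask.sum()) == 10  # floor(0.05 * 200)
        assert not mask.ravel()[300]

    def test_fraction_too_small_raises(self):
        with pytest.raises(ValueError):
            hotspot_mask(self._map(np.ones((2, 2, 2))), 0.05)


class TestMatchControls:
    def test_strata_distribution_identical(self):
        cases = [make_record("c1"), make_record("c2"),
                 make_record("c3", stratum="moderate")]
        pool = [make_record(f"p{i}") for i in range(5)] + [
            make_record(f"q{i}", stratum="moderate") for i in range(3)
        ]
        controls = match_controls(cases, pool, seed=0)
        assert [r.stratum for r in controls] == [r.stratum for r in cases]

    def test_identical_koos_accepted_first_draw(self):
        cases = [make_record(f"c{i}", koos=70.0) for i in range(4)]
        pool = [make_record(f"p{i}", koos=70.0) for i in range(4)]
        controls = match_controls(cases, pool, seed=1, max_attempts=1)
        assert len(controls) == 4

    def test_divergent_koos_exhausts_attempts(self):
        cases = [make_record(f"c{i}", koos=20.0) for i in range(10)]
        pool = [make_record(f"p{i}", koos=95.0) for i in range(10)]
        with pytest.raises(ValueError, match="attempts"):
            match_controls(cases, pool, seed=2, max_attempts=5)

    def test_insufficient_pool_raises(self):
        cases = [make_record("c1", stratum="severe")]
        with pytest.raises(ValueError, match="severe"):
            match_controls(cases, [make_record("p1")], seed=0)


class TestTissueFlags:
    def _atlas(self):
        spec = PhantomSpec(
            grid_shape=(8, 10, 10),
            tissue_specs=[
                TissueSpec("a", "box", (2, 2, 2), (1, 1, 1)),
                TissueSpec("b", "box", (5, 7, 7), (1, 1, 1)),
            ],
            n_patients=1,
            seed=0,
        )
        return generate_atlas(spec)

    def test_empty_mask_no_flags(self):
        atlas = self._atlas()
        flags = tissue_hotspot_flags(np.zeros((8, 10, 10), bool), atlas)
        assert flags == {"a": False, "b": False}

    def test_mask_equal_to_one_region(self):
        atlas = self._atlas()
        flags = tissue_hotspot_flags(atlas.label_grid == 1, atlas)
        assert flags == {"a": True, "b": False}

    def test_random_masks_match_brute_force_intersection(self):
        atlas = self._atlas()
        rng = np.random.default_rng(3)
        for _ in range(20):
            mask = rng.random((8, 10, 10)) < 0.02
            flags = tissue_hotspot_flags(mask, atlas)
            for label, name in atlas.names.items():
                brute = any(
                    mask[z, y, x] and atlas.label_grid[z, y, x] == label
                    for z in range(8) for y in range(10) for x in range(10)
                )
                assert flags[name] == brute

    def test_response_floor_suppresses_flat_map_flags(self):
        atlas = self._atlas()
        mask = atlas.label_grid > 0  # both tissues fully in the mask
        values = np.zeros((8, 10, 10))
        values[atlas.label_grid == 1] = 0.4   # strong response in tissue a
        values[atlas.label_grid == 2] = 0.001  # noise-level response in b
        flags = tissue_hotspot_flags(mask, atlas, values=values,
                                     min_response=0.05)
        assert flags == {"a": True, "b": False}
        # floor of zero falls back to pure intersection
        assert tissue_hotspot_flags(mask, atlas, values=values) == {
            "a": True, "b": True,
        }

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            tissue_hotspot_flags(np.zeros((2, 2, 2), bool), self._atlas())


class TestContingencyAndOddsRatio:
    def test_counts(self):
        a, b, c, d = contingency_counts([True] * 124, [False] * 124)
        assert (a, b, c, d) == (124, 0, 0, 124)
        a, b, c, d = contingency_counts([False] * 5, [False] * 5)
        assert (a, b, c, d) == (0, 5, 0, 5)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        cf = list(rng.random(30) < 0.4)
        gf = list(rng.random(30) < 0.4)
        a, b, c, d = contingency_counts(cf, gf)
        assert a + b == 30 and c + d == 30

    def test_cross_product_formula(self):
        assert odds_ratio(10, 114, 5, 119) == pytest.approx(1190 / 570)

    def test_conventions(self):
        assert odds_ratio(0, 5, 5, 5) == 0.0
        assert odds_ratio(5, 0, 5, 5) == math.inf
        assert odds_ratio(3, 4, 4, 3) != 1.0
        assert odds_ratio(4, 3, 4, 3) == 1.0
        with pytest.raises(ValueError):
            odds_ratio(0, 5, 0, 5)


def nchg_tails_oracle(a, b, c, d, psi):
    """Exact conditional tails by direct noncentral-hypergeometric summation.

    P(X = x | psi) proportional to C(a+b, x) C(c+d, a+c-x) psi^x over the
    support; computed with exact integer/float arithmetic independent of
    the implementation's scipy distribution object.
    """
    n1, n2, m = a + b, c + d, a + c
    lo, hi = max(0, m - n2), min(m, n1)
    weights = {
        x: math.comb(n1, x) * math.comb(n2, m - x) * psi**x
        for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    upper = sum(w for x, w in weights.items() if x >= a) / total
    lower = sum(w for x, w in weights.items() if x <= a) / total
    return upper, lower


class TestCornfieldCI:
    def test_null_table_contains_one(self):
        lo, hi = cornfield_ci(5, 5, 5, 5)
        assert lo < 1.0 < hi

    def test_zero_cell_conventions(self):
        lo, hi = cornfield_ci(0, 10, 5, 5)
        assert lo == 0.0
        lo, hi = cornfield_ci(5, 0, 5, 5)
        assert hi == math.inf

    @pytest.mark.parametrize(
        "table", [(10, 114, 5, 119), (3, 7, 6, 4), (12, 2, 5, 9), (1, 9, 4, 6)]
    )
    def test_endpoints_reproduce_exact_tail_probability(self, table):
        lo, hi = cornfield_ci(*table)
        upper_at_lo, _ = nchg_tails_oracle(*table, lo)
        _, lower_at_hi = nchg_tails_oracle(*table, hi)
        assert upper_at_lo == pytest.approx(0.025, abs=1e-4)
        assert lower_at_hi == pytest.approx(0.025, abs=1e-4)

    @pytest.mark.parametrize(
        "table", [(10, 114, 5, 119), (3, 7, 6, 4), (8, 2, 3, 7)]
    )
    def test_matches_scipy_conditional_interval(self, table):
        from scipy.stats.contingency import odds_ratio as scipy_or

        lo, hi = cornfield_ci(*table)
        a, b, c, d = table
        ref = scipy_or([[a, b], [c, d]], kind="conditional").confidence_interval(
            0.95
        )
        assert lo == pytest.approx(ref.low, rel=1e-4)
        assert hi == pytest.approx(ref.high, rel=1e-4)

    def test_interval_contains_conditional_mle(self):
        from scipy.stats.contingency import odds_ratio as scipy_or

        for table in [(10, 114, 5, 119), (3, 7, 6, 4), (12, 2, 5, 9)]:
            lo, hi = cornfield_ci(*table)
            a, b, c, d = table
            mle = scipy_or([[a, b], [c, d]], kind="conditional").statistic
            assert lo <= mle <= hi


class TestFisherExact:
    def test_null_table_is_one(self):
        assert fisher_exact_two_tailed(5, 5, 5, 5) == 1.0

    def test_small_table_full_enumeration(self):
        # margins (2, 2): tables a = 0, 1, 2 have probs 1/6, 4/6, 1/6;
        # observed a = 2 -> p = (1/6 + 1/6) = 1/3
        assert fisher_exact_two_tailed(2, 0, 0, 2) == pytest.approx(1 / 3)

    def test_exact_rational_oracle(self):
        # independent enumeration in exact rational arithmetic
        def oracle(a, b, c, d):
            n1, n2, m = a + b, c + d, a + c
            lo, hi = max(0, m - n2), min(m, n1)
            probs = {
                x: Fraction(math.comb(n1, x) * math.comb(n2, m - x),
                            math.comb(n1 + n2, m))
                for x in range(lo, hi + 1)
            }
            obs = probs[a]
            return float(sum(p for p in probs.values() if p <= obs))

        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
                continue
            assert fisher_exact_two_tailed(a, b, c, d) == pytest.approx(
                oracle(a, b, c, d), abs=1e-12
            )

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 25, size=4)
            p_ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert fisher_exact_two_tailed(a, b, c, d) == pytest.approx(
                p_ref, abs=1e-10
            )


class TestBiomarkerTable:
    def _atlas(self):
        spec = PhantomSpec(
            grid_shape=(6, 6, 6),
            tissue_specs=[
                TissueSpec("alpha", "box", (1, 1, 1), (1, 1, 1)),
                TissueSpec("beta", "box", (4, 4, 4), (1, 1, 1)),
            ],
            n_patients=1,
            seed=0,
        )
        return generate_atlas(spec)

    def test_rows_cover_all_tissues_with_invariants(self):
        atlas = self._atlas()
        case_flags = [{"alpha": True, "beta": False} for _ in range(8)]
        ctrl_flags = [{"alpha": i < 2, "beta": False} for i in range(8)]
        rows = biomarker_table(case_flags, ctrl_flags, atlas)
        assert [r.tissue for r in rows] == ["alpha", "beta"]
        for r in rows:
            assert r.a + r.b == 8 and r.c + r.d == 8

    def test_undefined_or_emitted_with_note_not_dropped(self):
        atlas = self._atlas()
        flags = [{"alpha": False, "beta": False} for _ in range(5)]
        rows = biomarker_table(flags, flags, atlas)
        assert len(rows) == 2
        for r in rows:
            assert not r.significant
            assert "undefined" in r.note

    def test_dual_significance_rule(self):
        atlas = self._atlas()
        case_flags = [{"alpha": True, "beta": i % 2 == 0} for i in range(20)]
        ctrl_flags = [{"alpha": i < 2, "beta": i % 2 == 1} for i in range(20)]
        rows = biomarker_table(case_flags, ctrl_flags, atlas)
        for r in rows:
            if r.significant:
                assert r.p < 0.05
                assert r.ci_low > 1.0 or r.ci_high < 1.0
        alpha_row = next(r for r in rows if r.tissue == "alpha")
        assert alpha_row.significant and alpha_row.odds_ratio > 1.0
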