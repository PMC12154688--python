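"""Rs curves, heterogeneity metrics, resample aggregation, scaling fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromhet import (
    RsProfile,
    SeparationGrid,
    aggregate_resamples,
    compute_ch,
    compute_relative_ch,
    compute_rs_profile,
    compute_rs_profiles,
    fit_scaling_exponent,
    generate_reference_ensemble,
    ReferenceEnsembleSpec,
)

from conftest import make_cell, random_rigid_motion


def profile(values, cell_id="c", bp=10_000):
    values = np.asarray(values, float)
    return RsProfile(cell_id, SeparationGrid(np.arange(1, len(values) + 1), bp),
                     values)


class TestRsProfile:
    def test_two_beads(self):
        cell = make_cell("c", [[0, 0, 0], [0, 0, 2.5]])
        grid = SeparationGrid(np.array([1]), 10_000)
        assert compute_rs_profile(cell, grid).values[0] == pytest.approx(2.5)

    def test_collinear_chain_is_linear_in_s(self):
        a = 0.7
        cell = make_cell("c", [[a * i, 0, 0] for i in range(8)])
        grid = SeparationGrid.full(8, 10_000)
        np.testing.assert_allclose(
            compute_rs_profile(cell, grid).values, a * np.arange(1, 8))

    def test_unit_square_corners(self):
        cell = make_cell("c", [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        grid = SeparationGrid.full(4, 10_000)
        vals = compute_rs_profile(cell, grid).values
        np.testing.assert_allclose(vals, [1.0, np.sqrt(2), 1.0])

    def test_separation_beyond_chain_rejected(self):
        cell = make_cell("c", [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="out of range"):
            compute_rs_profile(cell, SeparationGrid(np.array([2]), 10_000))

    def test_last_separation_uses_single_pair(self):
        cell = make_cell("c", [[0, 0, 0], [1, 0, 0], [5, 0, 0]])
        grid = SeparationGrid.full(3, 10_000)
        vals = compute_rs_profile(cell, grid).values
        assert vals[1] == pytest.approx(5.0)  # only the (0, 2) pair


class TestConformationalHeterogeneity:
    def test_identical_profiles_give_zero(self):
        p = profile([1.0, 2.0, 3.0])
        _, ch = compute_ch([p, p, p])
        np.testing.assert_array_equal(ch, 0.0)

    def test_two_cell_closed_form(self):
        # population sd (divisor n) of {1, 3} is 1
        _, ch = compute_ch([profile([1.0]), profile([3.0])])
        assert ch[0] == pytest.approx(1.0)

    def test_three_cell_closed_form(self):
        _, ch = compute_ch([profile([1.0]), profile([2.0]), profile([3.0])])
        assert ch[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    @given(st.integers(0, 10_000))
    def test_matches_two_pass_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0.1, 5.0, size=(rng.integers(2, 8), 6))
        profs = [profile(v, cell_id=f"c{i}") for i, v in enumerate(vals)]
        mean, ch = compute_ch(profs)
        n = len(vals)
        oracle_mean = vals.sum(axis=0) / n
        oracle_ch = np.sqrt(((vals - oracle_mean) ** 2).sum(axis=0) / n)
        np.testing.assert_allclose(mean, oracle_mean, rtol=1e-12)
        np.testing.assert_allclose(ch, oracle_ch, rtol=1e-12, atol=1e-15)

    def test_mismatched_grids_rejected(self):
        a = profile([1.0, 2.0])
        b = RsProfile("b", SeparationGrid(np.array([1, 3]), 10_000),
                      np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="mismatched"):
            compute_ch([a, b])

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_ch([profile([1.0])])


class TestRelativeHeterogeneity:
    def test_scale_invariance(self, rng):
        vals = rng.uniform(0.5, 3.0, size=(5, 7))
        profs = [profile(v, f"c{i}") for i, v in enumerate(vals)]
        scaled = [profile(17.3 * v, f"c{i}") for i, v in enumerate(vals)]
        np.testing.assert_allclose(
            compute_relative_ch(profs).relative_ch,
            compute_relative_ch(scaled).relative_ch,
            rtol=1e-12,
        )

    def test_identical_cells_give_zero(self):
        p = profile([1.0, 2.0])
        het = compute_relative_ch([p, p])
        np.testing.assert_array_equal(het.relative_ch, 0.0)

    def test_per_cell_relative_mean_is_one(self, rng):
        vals = rng.uniform(0.5, 3.0, size=(6, 5))
        het = compute_relative_ch([profile(v, f"c{i}")
                                   for i, v in enumerate(vals)])
        np.testing.assert_allclose(het.relative_rs.mean(axis=0), 1.0,
                                   rtol=1e-12)

    def test_degenerate_zero_mean_is_flagged_nan(self):
        a = profile([0.0, 1.0])
        b = profile([0.0, 3.0])
        het = compute_relative_ch([a, b])
        assert np.isnan(het.relative_ch[0])
        assert het.relative_ch[1] == pytest.approx(0.5)

    def test_rigid_motions_leave_metrics_unchanged(self, rng):
        cells = [make_cell(f"c{i}", rng.normal(size=(10, 3)))
                 for i in range(4)]
        grid = SeparationGrid.full(10, 10_000)
        base = compute_relative_ch([compute_rs_profile(c, grid) for c in cells])
        moved = []
        for c in cells:  # an independent rigid motion per cell
            Q, t = random_rigid_motion(rng)
            moved.append(make_cell(c.cell_id, c.positions @ Q.T + t))
        after = compute_relative_ch(
            [compute_rs_profile(c, grid) for c in moved])
        np.testing.assert_allclose(after.ch, base.ch, atol=1e-10)
        np.testing.assert_allclose(after.relative_ch, base.relative_ch,
                                   atol=1e-10)

    def test_translated_copies_have_exactly_zero_ch(self, rng):
        pos = rng.normal(size=(8, 3))
        cells = [make_cell(f"c{i}", pos + rng.normal(scale=10, size=3))
                 for i in range(5)]
        grid = SeparationGrid.full(8, 10_000)
        _, ch = compute_ch([compute_rs_profile(c, grid) for c in cells])
        # zero up to floating-point rounding of the translated coordinates
        np.testing.assert_allclose(ch, 0.0, atol=1e-12)


class TestResampleAggregation:
    def test_identical_resamples_have_zero_sd(self):
        het = compute_relative_ch([profile([1.0, 2.0]), profile([2.0, 3.0])])
        agg = aggregate_resamples([het, het, het])
        np.testing.assert_array_equal(agg.resample_sd, 0.0)

    def test_two_resample_closed_form_uses_sample_sd(self):
        h1 = compute_relative_ch([profile([1.0]), profile([1.0])])
        h2 = compute_relative_ch([profile([1.0]), profile([1.0])])
        h1.relative_ch = np.array([0.1])
        h2.relative_ch = np.array([0.3])
        agg = aggregate_resamples([h1, h2])
        assert agg.resample_mean[0] == pytest.approx(0.2)
        assert agg.resample_sd[0] == pytest.approx(np.sqrt(2) * 0.1)  # 0.1414

    def test_seeded_resamples_are_reproducible(self):
        def once():
            out = []
            for seed in range(3):
                ens = generate_reference_ensemble(ReferenceEnsembleSpec(
                    kind="fjc", n_replicas=4, n_segments=32, seed=seed))
                out.append(compute_relative_ch(compute_rs_profiles(ens)))
            return aggregate_resamples(out)
        a, b = once(), once()
        np.testing.assert_array_equal(a.resample_sd, b.resample_sd)


class TestScalingExponent:
    def test_exact_power_law(self):
        s = np.arange(1, 50)
        alpha, sd = fit_scaling_exponent(profile(np.sqrt(s)),
                                         fit_range=(2, 40))
        assert alpha == pytest.approx(0.5, abs=1e-12)
        assert np.isnan(sd)

    def test_constant_curve_gives_zero(self):
        alpha, _ = fit_scaling_exponent(profile(np.full(30, 2.0)),
                                        fit_range=(2, 25))
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_replica_spread_reported(self):
        s = np.arange(1, 30)
        profs = [profile(s ** 0.4), profile(s ** 0.6)]
        alpha, sd = fit_scaling_exponent(profs, fit_range=(2, 25))
        assert alpha == pytest.approx(0.5, abs=1e-10)
        assert sd == pytest.approx(np.sqrt(2) * 0.1, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_scaling_exponent(profile([1.0, 2.0, 3.0]), fit_range=(1, 2))


class TestFjcAnalyticLimits:
    def test_mean_square_distance_matches_fjc_law(self):
        # <Rs^2> = s * l^2 for the ideal chain; Monte-Carlo check at modest s
        ens = generate_reference_ensemble(ReferenceEnsembleSpec(
            kind="fjc", n_replicas=600, n_segments=40, seed=3))
        for s in (5, 20, 40):
            d2 = []
            for c in ens.cells:
                d = c.positions[s:] - c.positions[:-s]
                d2.append(np.einsum("ij,ij->i", d, d).mean())
            d2 = np.array(d2)
            se = d2.std(ddof=1) / np.sqrt(len(d2))
            assert abs(d2.mean() - s) < 4 * se + 1e-9
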