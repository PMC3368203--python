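"""Core identification machinery: basis rows, OLS, inversion, series mapping."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxmap import (
    GroupDataset,
    MappingModel,
    NoRootError,
    RankDeficiencyError,
    StructuralError,
    build_regression_rows,
    fit_mapping_model,
    invert_static_nonlinearity,
    invert_static_nonlinearity_many,
    map_series,
    signed_power,
)

P = 0.3


def _dataset(inputs, outputs, block_sizes=None, direction="L->R"):
    inputs = np.asarray(inputs, dtype=float)
    block_sizes = block_sizes or (inputs.size,)
    return GroupDataset(
        group="A",
        direction=direction,
        input_values=inputs,
        output_values=np.asarray(outputs, dtype=float),
        subject_ids=tuple(f"s{i}" for i in range(len(block_sizes))),
        block_sizes=tuple(block_sizes),
    )


def _brute_rows(y, u):
    """Independent enumeration oracle for the lagged regression layout."""
    rows, resp = [], []
    for k in range(1, len(y)):
        rows.append([y[k - 1], np.sign(y[k - 1]) * abs(y[k - 1]) ** P,
                     u[k], np.sign(u[k]) * abs(u[k]) ** P])
        resp.append(y[k])
    return np.array(rows), np.array(resp)


class TestSignedPower:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (-1.0, -1.0)])
    def test_anchor_values(self, x, expected):
        assert signed_power(x, P) == expected

    @given(x=st.floats(-1e6, 1e6, allow_nan=False), p=st.floats(0.05, 3.0))
    def test_odd_symmetry(self, x, p):
        assert signed_power(-x, p) == pytest.approx(-signed_power(x, p), abs=1e-12)

    @given(
        x=st.floats(-1e3, 1e3), y=st.floats(-1e3, 1e3), p=st.floats(0.05, 2.0)
    )
    def test_strictly_increasing(self, x, y, p):
        if x < y:
            assert signed_power(x, p) < signed_power(y, p)

    def test_vectorized_and_exponent_validation(self):
        out = signed_power(np.array([-8.0, 0.0, 8.0]), P)
        assert out[0] == -out[2] and out[1] == 0.0
        with pytest.raises(ValueError):
            signed_power(1.0, 0.0)


class TestBuildRegressionRows:
    def test_row_counts_match_enumeration_oracle(self, rng):
        # one subject with 60 pairs -> 59 rows; 40 subjects -> 2360
        for n_sub in (1, 40):
            vals = rng.uniform(30, 120, size=n_sub * 60)
            outs = rng.uniform(30, 120, size=n_sub * 60)
            ds = _dataset(vals, outs, block_sizes=(60,) * n_sub)
            X, y = build_regression_rows(ds)
            assert X.shape == (n_sub * 59, 4) and y.size == n_sub * 59

    def test_rows_equal_brute_force_oracle(self, rng):
        iv = rng.uniform(20, 90, 25)
        ov = rng.uniform(20, 90, 25)
        ds = _dataset(iv, ov, block_sizes=(12, 13))
        X, y = build_regression_rows(ds)
        Xa, ya = _brute_rows(iv[:12], ov[:12])
        Xb, yb = _brute_rows(iv[12:], ov[12:])
        assert np.allclose(X, np.vstack([Xa, Xb]), atol=0, rtol=1e-15)
        assert np.allclose(y, np.concatenate([ya, yb]), atol=0, rtol=1e-15)

    def test_constant_unit_series_gives_unit_rows(self):
        ds = _dataset(np.ones(10), np.ones(10))
        X, y = build_regression_rows(ds)
        assert np.array_equal(X, np.ones((9, 4))) and np.array_equal(y, np.ones(9))

    def test_direct_mode_swaps_regressand(self, rng):
        iv = rng.uniform(20, 90, 10)
        ov = rng.uniform(20, 90, 10)
        ds = _dataset(iv, ov)
        Xi, yi = build_regression_rows(ds, "regress-and-invert")
        Xd, yd = build_regression_rows(ds, "direct-regression")
        assert np.allclose(yi, iv[1:]) and np.allclose(yd, ov[1:])
        assert np.allclose(Xi[:, 2], ov[1:]) and np.allclose(Xd[:, 2], iv[1:])

    def test_short_block_error_names_subject(self, rng):
        ds = _dataset(rng.uniform(20, 90, 6), rng.uniform(20, 90, 6),
                      block_sizes=(5, 1))
        with pytest.raises(StructuralError, match="s1"):
            build_regression_rows(ds)


class TestFitMappingModel:
    def _noiseless_rows(self, rng, coeffs, n=120):
        a, b, c, d = coeffs
        u = rng.uniform(10, 200, n)
        y = np.empty(n)
        y[0] = 50.0
        for k in range(1, n):
            y[k] = (a * y[k - 1] + b * signed_power(y[k - 1], P)
                    + c * u[k] + d * signed_power(u[k], P))
        return _brute_rows(y, u)

    def test_noiseless_identifiability(self, rng):
        coeffs = (0.5, 1.0, 0.8, 2.0)
        X, y = self._noiseless_rows(rng, coeffs)
        m = fit_mapping_model(X, y)
        assert np.allclose(m.coefficients, coeffs, atol=1e-8, rtol=1e-8)
        assert m.residual_sse < 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(6, 50)
            X = rng.normal(size=(n, 4)) * [1.0, 3.0, 0.5, 2.0]
            y = rng.normal(size=n)
            beta = np.linalg.inv(X.T @ X) @ X.T @ y
            m = fit_mapping_model(X, y)
            assert np.allclose(m.coefficients, beta, rtol=1e-8, atol=1e-10)

    def test_zero_response_gives_zero_coefficients(self, rng):
        X = rng.normal(size=(20, 4))
        m = fit_mapping_model(X, np.zeros(20))
        assert np.allclose(m.coefficients, 0.0, atol=1e-12)

    def test_constant_input_rank_deficiency_names_columns(self, rng):
        iv = rng.uniform(20, 90, 30)
        ds = _dataset(iv, np.full(30, 55.0))
        X, y = build_regression_rows(ds)
        with pytest.raises(RankDeficiencyError) as err:
            fit_mapping_model(X, y)
        assert {2, 3} <= set(err.value.columns)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(StructuralError):
            fit_mapping_model(rng.normal(size=(3, 4)), np.zeros(3))

    def test_standard_errors_cover_truth_scale(self, rng):
        X = rng.normal(size=(500, 4)) + 2.0
        beta = np.array([0.3, -1.2, 2.0, 0.7])
        y = X @ beta + rng.normal(0, 0.5, 500)
        m = fit_mapping_model(X, y)
        assert m.coef_se is not None
        assert np.all(np.abs(np.array(m.coefficients) - beta)
                      < 6 * np.array(m.coef_se))

    def test_json_round_trip_is_lossless(self):
        m = MappingModel(group="A", direction="L->R", mode="regress-and-invert",
                         a=0.1, b=-2.5, c=0.03125, d=7.0, n_rows=2360,
                         residual_sse=123.456, coef_se=(0.1, 0.2, 0.3, 0.4),
                         init_value=61.5)
        again = MappingModel.from_json(m.to_json())
        assert again == m
        assert json.loads(m.to_json())["power"] == P


class TestInversion:
    @pytest.mark.parametrize(
        "c,d,target,expected",
        [(1.0, 0.0, 7.0, 7.0), (0.0, 1.0, 1.0, 1.0), (0.0, 1.0, 0.0, 0.0)],
    )
    def test_anchor_cases(self, c, d, target, expected):
        assert invert_static_nonlinearity(c, d, target).root == pytest.approx(
            expected, abs=1e-9
        )

    def test_round_trip_example(self):
        target = 2.0 * 5.0 + 3.0 * 5.0**P  # independent forward evaluation
        res = invert_static_nonlinearity(2.0, 3.0, target)
        assert res.root == pytest.approx(5.0, abs=1e-9)
        assert res.n_roots == 1

    @given(
        c=st.floats(0.1, 10.0),
        d=st.floats(0.1, 10.0),
        x=st.floats(1e-6, 1e3),
    )
    @settings(max_examples=200)
    def test_round_trip_property(self, c, d, x):
        g = c * x + d * x**P
        root = invert_static_nonlinearity(c, d, g, bracket_hint=1.0).root
        assert abs(root - x) <= 1e-9 * max(1.0, x)

    def test_negative_targets_by_oddness(self):
        res = invert_static_nonlinearity(2.0, 3.0, -(2.0 * 5 + 3 * 5**P))
        assert res.root == pytest.approx(-5.0, abs=1e-9)

    def test_both_zero_coefficients_rejected(self):
        with pytest.raises(ValueError):
            invert_static_nonlinearity(0.0, 0.0, 1.0)

    def test_unreachable_target_reports_searched_interval(self):
        with pytest.raises(NoRootError) as err:
            invert_static_nonlinearity(0.0, 1.0, 1e30, bracket_hint=1.0)
        assert err.value.interval is not None

    def test_mixed_signs_multiple_roots_flagged_and_nearest_returned(self):
        # g(x) = x - x^0.3 has three roots for small positive targets
        c, d, target = 1.0, -1.0, 0.3
        near_large = invert_static_nonlinearity(c, d, target, bracket_hint=3.0)
        assert near_large.n_roots >= 2
        assert c * near_large.root + d * signed_power(near_large.root, P) == pytest.approx(
            target, abs=1e-9
        )
        near_small = invert_static_nonlinearity(c, d, target, bracket_hint=1e-3)
        assert near_small.root != pytest.approx(near_large.root)

    def test_vectorized_agrees_with_scalar(self, rng):
        for c, d in [(0.4, 2.0), (-0.4, -2.0), (0.0, 3.0), (1.5, -0.2)]:
            targets = rng.uniform(-200, 200, 64)
            roots = invert_static_nonlinearity_many(c, d, targets, bracket_hint=50.0)
            for t, r in zip(targets, roots):
                assert c * r + d * signed_power(r, P) == pytest.approx(
                    t, abs=1e-9 * max(1.0, abs(t))
                )


class TestMapSeries:
    def test_identity_model_reproduces_input(self, rng):
        m = MappingModel(group="A", direction="L->R", mode="regress-and-invert",
                         a=0.0, b=0.0, c=1.0, d=0.0)
        u = rng.uniform(10, 90, 30)
        assert np.allclose(map_series(m, u), u[1:], atol=1e-9)

    def test_exact_inversion_of_noiseless_synthetic_data(self, layout, noiseless_truth):
        from fluxmap import apply_phase_exclusion, simulate_subject

        left, right = simulate_subject(layout, noiseless_truth, "C", "C01", 17)
        drv = apply_phase_exclusion(left, layout).values
        resp = apply_phase_exclusion(right, layout).values
        t = noiseless_truth
        m = MappingModel(group="C", direction="R->L", mode="regress-and-invert",
                         a=t.a, b=t.b, c=t.c, d=t.d)
        # model places the response side on the left-hand side; mapping its
        # series must recover the generating driver series exactly
        mapped = map_series(m, resp)
        assert np.allclose(mapped, drv[1:], atol=1e-8)

    def test_toy_series_matches_per_point_bisection_oracle(self):
        m = MappingModel(group="A", direction="L->R", mode="regress-and-invert",
                         a=0.5, b=1.0, c=2.0, d=3.0)
        u = np.array([4.0, 9.0, 2.5, 16.0, 7.0])
        mapped = map_series(m, u)

        def oracle(target):
            lo, hi = 0.0, 1.0
            sign = 1.0 if target >= 0 else -1.0
            t = abs(target)
            while 2 * hi + 3 * hi**P < t:
                hi *= 2
            for _ in range(200):
                mid = (lo + hi) / 2
                if 2 * mid + 3 * mid**P < t:
                    lo = mid
                else:
                    hi = mid
            return sign * (lo + hi) / 2

        for k in range(1, 5):
            target = u[k] - 0.5 * u[k - 1] - 1.0 * u[k - 1] ** P
            assert mapped[k - 1] == pytest.approx(oracle(target), abs=1e-8)

    def test_lag_seed_keeps_full_length(self, rng):
        m = MappingModel(group="A", direction="L->R", mode="regress-and-invert",
                         a=0.0, b=0.0, c=1.0, d=0.0)
        u = rng.uniform(10, 90, 25)
        assert map_series(m, u, lag_seed_value=40.0).size == 25

    def test_blocks_restart_lag(self, rng):
        m = MappingModel(group="A", direction="L->R", mode="regress-and-invert",
                         a=0.0, b=0.0, c=1.0, d=0.0)
        u = rng.uniform(10, 90, 20)
        joint = map_series(m, u, block_sizes=(10, 10))
        assert joint.size == 18
        assert np.allclose(joint[:9], u[1:10]) and np.allclose(joint[9:], u[11:])

    def test_direct_mode_matches_hand_recursion(self):
        m = MappingModel(group="A", direction="L->R", mode="direct-regression",
                         a=0.4, b=0.5, c=0.2, d=1.0, init_value=30.0)
        u = np.array([50.0, 60.0, 45.0])
        out = map_series(m, u, lag_seed_value=0.0)
        prev, expect = 30.0, []
        for uk in u:
            prev = 0.4 * prev + 0.5 * prev**P + 0.2 * uk + 1.0 * uk**P
            expect.append(prev)
        assert np.allclose(out, expect, atol=1e-12)

    def test_direct_mode_without_init_value_rejected(self):
        m = MappingModel(group="A", direction="L->R", mode="direct-regression",
                         a=0.4, b=0.5, c=0.2, d=1.0)
        with pytest.raises(StructuralError):
            map_series(m, np.array([50.0, 60.0]))

    def test_failed_inversion_reports_sample_index(self):
        m = MappingModel(group="A", direction="L->R", mode="regress-and-invert",
                         a=0.0, b=0.0, c=0.0, d=1.0)
        u = np.array([1.0, 1e40, 1.0])
        with pytest.raises(NoRootError) as err:
            map_series(m, u)
        assert err.value.k is not None
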