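"""Cumulative-labeling model: curve shape, fitting, derived quantities."""

import math

import numpy as np
import pytest

from axoregen.cell_cycle import (
    CellCycleParams,
    CumulativeLabelingModel,
    LabelingTimecourse,
    MissingSaturationError,
    _rprime_raw,
    derive_phase_lengths,
    estimate_tg2m,
    extrapolate_full_cycle_differentiation,
    fit_cell_cycle,
    growth_fraction,
    labeled_fraction,
    rprime,
    sse,
)


def random_valid_params(rng: np.random.Generator, r: float) -> CellCycleParams:
    T_C = rng.uniform(40.0, 400.0)
    T_S = rng.uniform(0.1, 0.5) * T_C
    T_G2M = rng.uniform(0.01, 0.15) * T_C
    GF = rng.uniform(0.4, 1.0)
    return CellCycleParams(T_C=T_C, T_S=T_S, T_G2M=T_G2M, GF=GF, r=r)


# ---------------------------------------------------------------------------
# parameter and timecourse contracts
# ---------------------------------------------------------------------------


def test_params_validation():
    with pytest.raises(ValueError):
        CellCycleParams(T_C=100, T_S=95, T_G2M=9, GF=0.9, r=1)  # S+G2M >= C
    with pytest.raises(ValueError):
        CellCycleParams(T_C=100, T_S=10, T_G2M=9, GF=0.0, r=1)
    with pytest.raises(ValueError):
        CellCycleParams(T_C=100, T_S=10, T_G2M=9, GF=0.9, r=3)


def test_timecourse_requires_increasing_times():
    with pytest.raises(ValueError):
        LabelingTimecourse("x", (0.0, 0.0), (0.1, 0.2), (0.01, 0.01))


# ---------------------------------------------------------------------------
# R'(t), g(t), R(t)
# ---------------------------------------------------------------------------


def test_rprime_t0_is_sphase_fraction_r1():
    p = CellCycleParams(T_C=100, T_S=10, T_G2M=5, GF=1.0, r=1)
    assert rprime(0.0, p) == pytest.approx(0.10)


def test_rprime_saturates_at_complete_labeling_time():
    for r in (1, 2):
        p = CellCycleParams(T_C=119, T_S=20, T_G2M=9, GF=0.9, r=r)
        assert rprime(p.T_C - p.T_S, p) == pytest.approx(1.0)
        assert rprime(p.T_C - p.T_S + 50, p) == pytest.approx(1.0)


def test_rprime_breakpoint_continuity_random_params():
    """|R'(T_G2M-) - R'(T_G2M+)| < 1e-9 and R'((T_C-T_S)-) -> 1 over
    1,000 random valid parameter sets."""
    rng = np.random.default_rng(7)
    eps = 1e-9
    for _ in range(1000):
        p = random_valid_params(rng, r=2)
        left = rprime(p.T_G2M * (1 - 1e-12) - eps, p)
        right = rprime(p.T_G2M + eps, p)
        assert abs(left - right) < 1e-9
        assert abs(rprime((p.T_C - p.T_S) - 1e-9, p) - 1.0) < 1e-6
        assert rprime(p.T_C - p.T_S, p) == pytest.approx(1.0, abs=1e-12)


def test_rprime_r_to_1_limit():
    """The r != 1 branch converges to the printed r = 1 line as r -> 1."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        p = random_valid_params(rng, r=1)
        t = np.linspace(0, p.T_C, 257)
        near_one = _rprime_raw(t, p.T_C, p.T_S, p.T_G2M, 1 + 1e-6)
        exact = _rprime_raw(t, p.T_C, p.T_S, p.T_G2M, 1)
        assert np.max(np.abs(near_one - exact)) < 1e-4


def test_rprime_monotone_nondecreasing():
    rng = np.random.default_rng(13)
    for r in (1, 2):
        for _ in range(200):
            p = random_valid_params(rng, r=r)
            t = np.linspace(0, 1.5 * p.T_C, 400)
            vals = np.asarray(rprime(t, p))
            assert np.all(np.diff(vals) >= -1e-12)


def test_rprime_zero_is_asynchronous_sphase_fraction_r2():
    rng = np.random.default_rng(17)
    for _ in range(100):
        p = random_valid_params(rng, r=2)
        expected = (
            p.r ** ((p.T_G2M + p.T_S) / p.T_C) - p.r ** (p.T_G2M / p.T_C)
        ) / (p.r - 1)
        assert rprime(0.0, p) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "GF, r, t, T_C, expected",
    [
        (1.0, 2, 37.0, 100.0, 1.0),
        (0.8, 1, 500.0, 100.0, 0.8),
        (0.5, 2, 100.0, 100.0, 2.0 / 3.0),
    ],
)
def test_growth_fraction_values(GF, r, t, T_C, expected):
    assert growth_fraction(t, GF, r, T_C) == pytest.approx(expected)


def test_labeled_fraction_plateaus():
    p = CellCycleParams(T_C=324, T_S=132, T_G2M=9, GF=0.8, r=1)
    t_plateau = p.T_C - p.T_S
    assert labeled_fraction(t_plateau, p) == pytest.approx(0.8)
    assert labeled_fraction(t_plateau + 100, p) == pytest.approx(0.8)
    p1 = CellCycleParams(T_C=100, T_S=10, T_G2M=5, GF=1.0, r=1)
    assert labeled_fraction(0.0, p1) == pytest.approx(0.1)


def test_labeled_fraction_monotone_for_proliferative():
    rng = np.random.default_rng(19)
    for _ in range(200):
        p = random_valid_params(rng, r=2)
        t = np.linspace(0, 2 * p.T_C, 300)
        vals = np.asarray(labeled_fraction(t, p))
        assert np.all(np.diff(vals) >= -1e-12)


# ---------------------------------------------------------------------------
# SSE
# ---------------------------------------------------------------------------


def test_sse_perfect_fit_and_one_sigma_point():
    p = CellCycleParams(T_C=119, T_S=88, T_G2M=9, GF=0.96, r=2)
    t = np.arange(0, 121, 12.0)
    f = np.clip(np.asarray(labeled_fraction(t, p)), 0, 1)
    tc = LabelingTimecourse("synthetic", tuple(t), tuple(f), (0.01,) * len(t))
    assert sse(tc, p) == pytest.approx(0.0, abs=1e-18)

    single = LabelingTimecourse(
        "synthetic", (10.0,), (min(1.0, float(labeled_fraction(10.0, p)) + 0.02),), (0.02,)
    )
    assert sse(single, p) == pytest.approx(1.0, rel=1e-9)


def test_sse_matches_direct_evaluation():
    p = CellCycleParams(T_C=100, T_S=20, T_G2M=10, GF=0.9, r=1)
    tc = LabelingTimecourse("x", (0.0, 30.0, 90.0), (0.2, 0.5, 0.9), (0.05, 0.1, 0.02))
    expected = sum(
        ((obs - labeled_fraction(t, p)) / sd) ** 2
        for t, obs, sd in zip(tc.time_h, tc.fraction, tc.sd)
    )
    assert sse(tc, p) == pytest.approx(expected, rel=1e-12)


def test_sse_rejects_zero_sd():
    p = CellCycleParams(T_C=100, T_S=20, T_G2M=10, GF=0.9, r=1)
    tc = LabelingTimecourse("x", (0.0, 30.0), (0.2, 0.5), (1e-9, 0.1))
    # timecourse accepts tiny sd; sse only rejects exact zeros
    bad = LabelingTimecourse.__new__(LabelingTimecourse)
    object.__setattr__(bad, "population", "x")
    object.__setattr__(bad, "time_h", (0.0, 30.0))
    object.__setattr__(bad, "fraction", (0.2, 0.5))
    object.__setattr__(bad, "sd", (0.0, 0.1))
    object.__setattr__(bad, "n_animals", ())
    with pytest.raises(ValueError):
        sse(bad, p)
    assert sse(tc, p) > 0


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_fit_recovers_noiseless_parameters():
    """Fitting exact model output recovers the free parameters."""
    truth = CellCycleParams(T_C=119, T_S=88, T_G2M=9, GF=0.96, r=2)
    t = np.arange(0, 121, 12.0)
    f = np.clip(np.asarray(labeled_fraction(t, truth)), 0, 1)
    tc = LabelingTimecourse("synthetic", tuple(t), tuple(f), (0.01,) * len(t))
    res = fit_cell_cycle(tc, r=2, fixed={"T_G2M": 9.0})
    assert res.converged
    assert res.sse == pytest.approx(0.0, abs=1e-8)
    assert res.params.T_C == pytest.approx(119.0, abs=0.1)
    assert res.params.T_S == pytest.approx(88.0, abs=0.1)
    assert res.params.GF == pytest.approx(0.96, abs=1e-3)
    assert res.fixed == {"T_G2M": 9.0}
    for name in ("T_C", "T_S", "GF"):
        assert res.ci68[name] > 0


def test_fit_neurogenic_mode_recovers_slow_population():
    truth = CellCycleParams(T_C=324, T_S=132, T_G2M=9, GF=0.8, r=1)
    t = np.arange(0, 221, 24.0)
    f = np.clip(np.asarray(labeled_fraction(t, truth)), 0, 1)
    tc = LabelingTimecourse("uninjured", tuple(t), tuple(f), (0.01,) * len(t))
    res = fit_cell_cycle(tc, r=1, fixed={"T_G2M": 9.0})
    assert res.converged
    assert res.params.T_C == pytest.approx(324.0, rel=0.01)
    assert res.params.GF == pytest.approx(0.8, abs=0.01)


def test_fit_requires_enough_points():
    tc = LabelingTimecourse("x", (0.0, 10.0), (0.1, 0.2), (0.01, 0.01))
    with pytest.raises(ValueError):
        CumulativeLabelingModel(tc, r=2, fixed={"T_G2M": 9.0})


def test_fit_summary_mentions_fixed_and_free():
    truth = CellCycleParams(T_C=119, T_S=88, T_G2M=9, GF=0.96, r=2)
    t = np.arange(0, 121, 24.0)
    f = np.clip(np.asarray(labeled_fraction(t, truth)), 0, 1)
    tc = LabelingTimecourse("synthetic", tuple(t), tuple(f), (0.01,) * len(t))
    res = fit_cell_cycle(tc, r=2)
    text = res.summary()
    assert "T_G2M" in text and "fixed" in text and "proliferative" in text
    d = res.to_dict()
    assert d["estimates"]["r"] == 2.0


# ---------------------------------------------------------------------------
# derived phase lengths
# ---------------------------------------------------------------------------


class _FakeFit:
    """Minimal stand-in exposing the fields derive_phase_lengths reads."""

    def __init__(self, params, ci68):
        self.params = params
        self.ci68 = ci68
        self.converged = True


def test_phase_lengths_hand_propagation():
    fit = _FakeFit(
        CellCycleParams(T_C=100, T_S=30, T_G2M=9, GF=0.9, r=1),
        {"T_C": 10.0, "T_S": 4.0},
    )
    pl = derive_phase_lengths(fit, mi=0.02, dmi=0.0)
    assert pl.T_G1 == pytest.approx(61.0)
    assert pl.dT_G1 == pytest.approx(math.sqrt(10**2 + 4**2), rel=1e-12)  # 10.770
    assert pl.T_M == pytest.approx(2.0)
    assert pl.dT_M == pytest.approx(0.2)


def test_phase_lengths_mi_error_only():
    fit = _FakeFit(
        CellCycleParams(T_C=119, T_S=88, T_G2M=9, GF=0.96, r=2), {"T_C": 0.0}
    )
    pl = derive_phase_lengths(fit, mi=0.05, dmi=0.01)
    assert pl.T_M == pytest.approx(5.95)
    assert pl.dT_M == pytest.approx(1.19)


def test_phase_lengths_zero_mi():
    fit = _FakeFit(CellCycleParams(T_C=100, T_S=30, T_G2M=9, GF=0.9, r=1), {})
    assert derive_phase_lengths(fit, mi=0.0).T_M == 0.0
    with pytest.raises(ValueError):
        derive_phase_lengths(fit, mi=1.5)


# ---------------------------------------------------------------------------
# T_G2+M estimation and full-cycle extrapolation
# ---------------------------------------------------------------------------


def test_estimate_tg2m():
    assert estimate_tg2m([(3, 0.2), (6, 0.8), (9, 1.0), (12, 1.0)]) == 9
    assert estimate_tg2m([(1, 1.0)]) == 1
    with pytest.raises(MissingSaturationError):
        estimate_tg2m([(3, 0.5), (6, 0.9)])
    # a dip after reaching 1 disqualifies the earlier time
    assert estimate_tg2m([(3, 1.0), (6, 0.9), (9, 1.0)]) == 9


def test_full_cycle_extrapolation():
    res = extrapolate_full_cycle_differentiation(0.16, 0.5)
    assert res.differentiated == pytest.approx(0.32)
    assert res.stem_retained == pytest.approx(0.68)
    assert extrapolate_full_cycle_differentiation(0.0, 0.7).differentiated == 0.0
    assert extrapolate_full_cycle_differentiation(0.3, 1.0).differentiated == 0.3
    assert extrapolate_full_cycle_differentiation(0.9, 0.5).differentiated == 1.0
    with pytest.raises(ValueError):
        extrapolate_full_cycle_differentiation(0.2, 0.0)
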