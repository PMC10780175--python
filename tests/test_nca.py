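"""Non-compartmental analysis against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalpk.nca import ConcProfile, NCAError, auc, fit_lambda_z, run_nca
from renalpk.reference import RAT_SAMPLING_TIMES
from renalpk.synthetic import monoexponential_fixture


def brute_force_lambda_z(times, conc):
    """Independent oracle: enumerate all suffix windows with numpy.polyfit."""
    t, c = np.asarray(times), np.asarray(conc)
    i_max = int(np.argmax(c))
    keep = (np.arange(len(t)) > i_max) & (c > 0)
    t, logc = t[keep], np.log(c[keep])
    best = None
    for start in range(len(t) - 2):
        n = len(t) - start
        slope = np.polyfit(t[start:], logc[start:], 1)[0]
        pred = np.polyval(np.polyfit(t[start:], logc[start:], 1), t[start:])
        ss_res = np.sum((logc[start:] - pred) ** 2)
        ss_tot = np.sum((logc[start:] - logc[start:].mean()) ** 2)
        r2a = 1 - (1 - (1 - ss_res / ss_tot)) * (n - 1) / (n - 2)
        if best is None or r2a > best[0] + 1e-9:
            best = (r2a, -slope)
    return best[1]


def test_lambda_z_exact_on_monoexponential():
    profile = monoexponential_fixture(100.0, 1.0, RAT_SAMPLING_TIMES)
    lam, r2, n = fit_lambda_z(profile)
    assert lam == pytest.approx(math.log(2.0), abs=1e-6)
    assert r2 == pytest.approx(1.0, abs=1e-9)
    assert n >= 3


def test_lambda_z_flat_profile_is_an_error():
    flat = ConcProfile(times=(0.5, 1, 2, 4, 8), conc=(5, 5, 5, 5, 5), dose=1.0)
    with pytest.raises(NCAError):
        fit_lambda_z(flat)


def test_lambda_z_biexponential_matches_brute_force_oracle():
    t = np.array(RAT_SAMPLING_TIMES)
    c = 300.0 * np.exp(-3.0 * t) + 20.0 * np.exp(-0.1 * t)
    profile = ConcProfile(times=tuple(t), conc=tuple(c), dose=0.36)
    lam, _, _ = fit_lambda_z(profile)
    assert 0.095 <= lam <= 0.105
    assert lam == pytest.approx(brute_force_lambda_z(t, c), rel=1e-9)


def test_auc_closed_form_monoexponential():
    profile = monoexponential_fixture(100.0, 1.0, (0.0, *RAT_SAMPLING_TIMES))
    auc_t, auc_inf = auc(profile, extrapolate=True)
    assert auc_inf == pytest.approx(100.0 / math.log(2.0), rel=0.01)  # 144.27


def test_auc_single_constant_interval_is_exact():
    profile = ConcProfile(times=(0.0, 1.0, 3.0), conc=(2.0, 2.0, 2.0), dose=1.0)
    auc_t, _ = auc(profile)
    assert auc_t == pytest.approx(2.0 * 3.0)


def test_linear_trapezoid_overestimates_exponential_decay():
    profile = monoexponential_fixture(100.0, 1.0, RAT_SAMPLING_TIMES)
    lulb, _ = auc(profile, method="lin_up_log_down")
    linear, _ = auc(profile, method="linear")
    assert linear > lulb    # chord above a convex decay


def test_run_nca_dose_auc_arithmetic():
    """CL = dose / AUC(0, inf): 0.36 mg/kg over 278 h*ng/mL -> 1295 mL/h/kg."""
    k = math.log(2.0) / 0.44
    c0 = 278.0 * k          # fixes AUC(0, inf) to exactly 278 h*ng/mL
    profile = monoexponential_fixture(c0, 0.44, (0.0, *RAT_SAMPLING_TIMES),
                                      dose=0.36)
    res = run_nca(profile)
    assert res.auc_0_inf == pytest.approx(278.0, rel=0.01)
    assert res.cl == pytest.approx(0.36e6 / 278.0, rel=0.01)   # 1295
    assert res.cl == pytest.approx(1295.0, rel=0.01)


def test_run_nca_recovers_monoexponential_parameters_within_1pct():
    c0, t_half, dose = 100.0, 1.0, 0.36
    k = math.log(2.0) / t_half
    res = run_nca(monoexponential_fixture(c0, t_half, (0.0, *RAT_SAMPLING_TIMES),
                                          dose=dose))
    assert res.lambda_z == pytest.approx(k, rel=0.01)
    assert res.auc_0_inf == pytest.approx(c0 / k, rel=0.01)
    assert res.cl == pytest.approx(dose * 1e6 / (c0 / k), rel=0.01)
    assert res.vz == pytest.approx(dose * 1e6 / c0 / 1000.0, rel=0.01)
    assert res.t_half == pytest.approx(t_half, rel=0.01)
    # internal consistency invariants hold exactly
    assert res.auc_0_inf >= res.auc_0_t
    assert res.t_half == pytest.approx(math.log(2.0) / res.lambda_z)


def test_cmax_tmax_are_the_literal_maximum_sample():
    profile = ConcProfile(times=(0.1, 0.5, 1, 2, 4), conc=(10, 80, 40, 9, 2),
                          dose=1.0)
    res = run_nca(profile)
    assert res.cmax == 80.0 and res.tmax == 0.5


def test_point_order_permutation_invariance():
    t = np.array(RAT_SAMPLING_TIMES)
    c = 200.0 * np.exp(-1.2 * t) + 5.0 * np.exp(-0.2 * t)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(t))
    res_a = run_nca(ConcProfile(tuple(t), tuple(c), dose=0.36))
    res_b = run_nca(ConcProfile(tuple(t[perm]), tuple(c[perm]), dose=0.36))
    assert res_a == res_b


@given(st.floats(min_value=0.1, max_value=10.0))
@settings(deadline=None, max_examples=30, derandomize=True)
def test_auc_scales_linearly_with_concentration(scale):
    t = np.array(RAT_SAMPLING_TIMES)
    c = 100.0 * np.exp(-0.8 * t)
    base, _ = auc(ConcProfile(tuple(t), tuple(c), dose=1.0))
    scaled, _ = auc(ConcProfile(tuple(t), tuple(scale * c), dose=1.0))
    assert scaled == pytest.approx(scale * base, rel=1e-9)


def test_auc_additive_over_time_splits():
    t = np.array(RAT_SAMPLING_TIMES)
    c = 100.0 * np.exp(-0.8 * t)
    full, _ = auc(ConcProfile(tuple(t), tuple(c), dose=1.0))
    head, _ = auc(ConcProfile(tuple(t[:5]), tuple(c[:5]), dose=1.0))
    tail, _ = auc(ConcProfile(tuple(t[4:]), tuple(c[4:]), dose=1.0))
    assert head + tail == pytest.approx(full, rel=1e-12)


def test_lloq_censoring_drops_low_samples():
    t = np.array(RAT_SAMPLING_TIMES)
    c = 50.0 * np.exp(-1.5 * t)     # falls below 1 ng/mL before 8 h
    profile = ConcProfile(tuple(t), tuple(c), dose=0.36)
    censored, dropped = profile.censored(1.0)
    assert dropped >= 1
    assert min(censored.conc) >= 1.0
    full = run_nca(profile)
    trimmed = run_nca(profile, lloq=1.0)
    assert trimmed.auc_0_t <= full.auc_0_t


def test_profile_validation_errors():
    with pytest.raises(NCAError):
        ConcProfile(times=(0, 1), conc=(1, 2), dose=1.0)          # too short
    with pytest.raises(NCAError):
        ConcProfile(times=(0, 1, 1), conc=(1, 2, 3), dose=1.0)    # duplicates
    with pytest.raises(NCAError):
        ConcProfile(times=(0, 1, 2), conc=(0, 0, 0), dose=1.0)    # all zero
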