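"""Summary statistics and fits: hand-checked values, closed-form MLE
properties, parameter recovery, and cross-checks against scipy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from latticedrift import (
    GenotypeCounts,
    allele_frequency,
    expected_heterozygosity,
    fit_het_decay,
    fit_inverse_gaussian,
    fit_slope,
    heterozygosity,
    inbreeding_coefficient,
    size_ratio,
    t_ave,
)
from latticedrift.exceptions import (
    AllRunsCappedError,
    DegenerateSampleError,
    NoDecayError,
    UndefinedInbreedingError,
)


@pytest.mark.parametrize(
    "counts, f",
    [
        (GenotypeCounts(10, 0, 0), 1.0),
        (GenotypeCounts(1, 2, 1), 0.5),
        (GenotypeCounts(2, 1, 1), 0.625),  # 5 A copies among 8
    ],
)
def test_allele_frequency_hand_values(counts, f):
    assert allele_frequency(counts) == f


@pytest.mark.parametrize(
    "counts, h",
    [
        (GenotypeCounts(0, 10, 0), 1.0),
        (GenotypeCounts(10, 0, 0), 0.0),
        (GenotypeCounts(3, 2, 3), 0.25),
    ],
)
def test_heterozygosity_hand_values(counts, h):
    assert heterozygosity(counts) == h


def test_inbreeding_coefficient_hand_values():
    assert inbreeding_coefficient(GenotypeCounts(25, 50, 25)) == 0.0  # HWE
    assert inbreeding_coefficient(GenotypeCounts(50, 0, 50)) == 1.0
    # f = 0.5, H_obs = 0.25, 2pq = 0.5 -> F = 0.5
    assert inbreeding_coefficient(GenotypeCounts(3, 2, 3)) == 0.5


def test_inbreeding_undefined_when_fixed():
    with pytest.raises(UndefinedInbreedingError):
        inbreeding_coefficient(GenotypeCounts(7, 0, 0))


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        GenotypeCounts(-1, 2, 1)
    with pytest.raises(ValueError):
        GenotypeCounts(0, 0, 0)


@settings(derandomize=True, max_examples=60)
@given(
    n_AA=st.integers(0, 40), n_Aa=st.integers(0, 40), n_aa=st.integers(0, 40)
)
def test_frequency_heterozygosity_consistency(n_AA, n_Aa, n_aa):
    """2pq bounds H_obs relationships: f in [0,1], H_obs in [0,1], and the
    identity H_obs = (1 - F) 2pq whenever F is defined."""
    if n_AA + n_Aa + n_aa == 0:
        return
    c = GenotypeCounts(n_AA, n_Aa, n_aa)
    f = allele_frequency(c)
    assert 0.0 <= f <= 1.0
    assert 0.0 <= heterozygosity(c) <= 1.0
    if 0.0 < f < 1.0:
        F = inbreeding_coefficient(c)
        assert heterozygosity(c) == pytest.approx(
            (1 - F) * expected_heterozygosity(c)
        )


# ---------------------------------------------------------------------------
# inverse-Gaussian MLE
# ---------------------------------------------------------------------------


def test_ig_mle_closed_form_hand_value():
    """{1,2,3}: mu = 2 and lam = 3 / (11/6 - 3/2) = 9."""
    fit = fit_inverse_gaussian([1.0, 2.0, 3.0])
    assert fit.mu == pytest.approx(2.0)
    assert fit.lam == pytest.approx(9.0)
    assert fit.n == 3


def test_ig_fitted_mu_equals_sample_mean_exactly():
    rng = np.random.default_rng(3)
    x = rng.gamma(5.0, 2.0, size=257)
    assert fit_inverse_gaussian(x).mu == x.mean()


def test_ig_degenerate_and_invalid_samples():
    with pytest.raises(DegenerateSampleError):
        fit_inverse_gaussian([4.0, 4.0, 4.0, 4.0])
    with pytest.raises(ValueError):
        fit_inverse_gaussian([1.0, -2.0, 3.0])
    with pytest.raises(DegenerateSampleError):
        fit_inverse_gaussian([1.0])


def test_ig_parameter_recovery_from_large_sample():
    """50,000 draws from IG(mu=5, lam=20): MLE within 3 SE of the truth
    (SE(mu) = sqrt(mu^3/(lam n)), SE(lam) ~ lam sqrt(2/n))."""
    mu, lam, n = 5.0, 20.0, 50_000
    rng = np.random.default_rng(21)
    x = sps.invgauss.rvs(mu / lam, scale=lam, size=n, random_state=rng)
    fit = fit_inverse_gaussian(x)
    assert abs(fit.mu - mu) < 3 * np.sqrt(mu**3 / (lam * n))
    assert abs(fit.lam - lam) < 3 * lam * np.sqrt(2.0 / n)


def test_ig_mle_agrees_with_scipy_fit():
    """Independent route: scipy's numerical MLE with fixed loc=0 matches the
    closed form."""
    rng = np.random.default_rng(22)
    x = sps.invgauss.rvs(2.0, scale=10.0, size=2000, random_state=rng)
    fit = fit_inverse_gaussian(x)
    shape, loc, scale = sps.invgauss.fit(x, floc=0)
    assert fit.mu == pytest.approx(shape * scale, rel=1e-3)
    assert fit.lam == pytest.approx(scale, rel=1e-3)


# ---------------------------------------------------------------------------
# heterozygosity decay
# ---------------------------------------------------------------------------


def test_decay_fit_recovers_exact_geometric_series():
    gens = np.arange(201)
    h = 0.5 * (1 - 1 / 100.0) ** gens  # N_e = 50
    fit = fit_het_decay(list(zip(gens, h)))
    assert fit.N_e == pytest.approx(50.0, rel=1e-6)
    assert fit.H0 == pytest.approx(0.5, rel=1e-6)
    assert fit.n_dropped == 0


def test_decay_fit_constant_series_is_no_decay():
    series = [(t, 0.5) for t in range(50)]
    with pytest.raises(NoDecayError):
        fit_het_decay(series)


def test_decay_fit_drops_nonpositive_and_respects_window():
    gens = np.arange(101)
    h = 0.8 * (1 - 1 / 40.0) ** gens
    series = list(zip(gens, h)) + [(101, 0.0), (102, -1.0)]
    fit = fit_het_decay(series, window=(0, 102))
    assert fit.n_dropped == 2
    assert fit.N_e == pytest.approx(20.0, rel=1e-6)
    with pytest.raises(DegenerateSampleError):
        fit_het_decay(series, window=(101, 102))


# ---------------------------------------------------------------------------
# T_ave and size scaling
# ---------------------------------------------------------------------------


def test_t_ave_mean_and_capped_exclusion():
    assert t_ave([10, 20, 30]) == (20.0, 0)
    assert t_ave([5]) == (5.0, 0)
    mean, excluded = t_ave([10, 20, 30], capped_count=2)
    assert mean == 20.0 and excluded == 2
    with pytest.raises(AllRunsCappedError):
        t_ave([], capped_count=4)


def test_slope_exactly_proportional_input():
    fit = fit_slope([100, 400], [473.0, 1892.0])
    assert fit.slope == pytest.approx(4.73)


def test_slope_underdetermined():
    with pytest.raises(ValueError):
        fit_slope([100], [844.0])


def test_slope_recovery_under_noise():
    """T_ave = 8.44 N with 2% noise: through-origin slope within 3%."""
    rng = np.random.default_rng(9)
    sizes = np.array([100, 400, 900])
    t_aves = 8.44 * sizes * (1 + rng.normal(0, 0.02, 3))
    fit = fit_slope(sizes, t_aves)
    assert fit.slope == pytest.approx(8.44, rel=0.03)
    # diagnostic with-intercept slope is also close
    assert fit.slope_with_intercept == pytest.approx(8.44, rel=0.1)


def test_size_ratio_values():
    assert size_ratio(4.73, 4.73) == 1.0
    assert size_ratio(8.44, 4.73) == pytest.approx(0.5604, abs=5e-4)
    assert size_ratio(6.96, 4.73) == pytest.approx(0.6796, abs=5e-4)
    with pytest.raises(ValueError):
        size_ratio(-1.0, 4.73)
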