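import math

import numpy as np
import pytest

from poolmaf import (Distribution, ErrorRates, FrequencyGrid, PriorSpec,
                     batch_call, build_prior, call_site, harmonic_number,
                     likelihood, likelihood_curve, posterior, summarize)
from poolmaf.model import PriorConfigError
from poolmaf.pileup import SiteCounts

CLEAN = ErrorRates(eps_R=0.0, eps_A=0.0, rho=0.0, alpha=0.0)
MILD = ErrorRates.from_class_rates(eps_R=1e-3, eps_A=1e-3)


def brute_force_likelihood(n_A, C, N, f, rates):
    """Literal double-sum enumeration of the pooled likelihood."""
    total = 0.0
    for k in range(N + 1):
        p = (1 - rates.rho) * (k / N) + rates.alpha * (1 - k / N)
        total += (
            math.comb(C, n_A) * p ** n_A * (1 - p) ** (C - n_A)
            * math.comb(N, k) * f ** k * (1 - f) ** (N - k)
        )
    return total


# ---------------------------------------------------------------- priors

def test_flat_unfolded_prior_values():
    spec = PriorSpec(kind="flat", folded=False, theta=0.001, divergence=0.1)
    mass = build_prior(spec).mass
    assert mass[0] == pytest.approx(0.899, abs=1e-15)
    assert mass[-1] == pytest.approx(0.1, abs=1e-15)
    assert np.allclose(mass[1:-1], 0.001 / 99)


def test_informative_unfolded_prior_harmonic_oracle():
    beta = sum(1 / i for i in range(1, 100))
    spec = PriorSpec(kind="informative", folded=False, theta=0.001,
                     divergence=0.01)
    mass = build_prior(spec).mass
    assert mass[0] == pytest.approx(1 - 0.001 * beta - 0.01, rel=1e-12)
    # interior follows theta/(N_d * f) = theta/i
    assert mass[37] == pytest.approx(0.001 / 37, rel=1e-12)


def test_informative_folded_prior_harmonic_oracle():
    beta = sum(1 / i for i in range(1, 100))
    spec = PriorSpec(kind="informative", folded=True, theta=0.001)
    mass = build_prior(spec).mass
    assert mass[0] == pytest.approx((1 - 0.001 * beta) / 2, rel=1e-12)
    assert mass[0] == mass[-1]
    assert mass[1:-1].sum() == pytest.approx(0.001 * beta, rel=1e-12)
    assert mass[0] == pytest.approx(0.497411, abs=5e-7)


@pytest.mark.parametrize("kind", ["flat", "informative"])
@pytest.mark.parametrize("folded", [False, True])
@pytest.mark.parametrize("theta", [1e-4, 1e-3, 1e-2])
@pytest.mark.parametrize("divergence", [0.01, 0.1])
def test_prior_normalization(kind, folded, theta, divergence):
    spec = PriorSpec(kind=kind, folded=folded, theta=theta,
                     divergence=divergence)
    assert build_prior(spec).mass.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("kind", ["flat", "informative"])
def test_folded_priors_invariant_under_reversal(kind):
    mass = build_prior(PriorSpec(kind=kind, folded=True, theta=0.003)).mass
    assert np.allclose(mass, mass[::-1], rtol=0, atol=1e-15)


def test_prior_rejects_negative_mass():
    with pytest.raises(PriorConfigError, match="P\\(f=0\\)"):
        build_prior(PriorSpec(kind="informative", folded=False, theta=0.15,
                              divergence=0.5))


# ------------------------------------------------------------ likelihood

def test_likelihood_half_frequency_example():
    # N=2, C=2, n_A=1, error-free, f=0.5: only k=1 contributes
    assert likelihood(1, 2, 2, 0.5, CLEAN) == pytest.approx(0.25, rel=1e-12)


def test_likelihood_fixed_reference_error_free():
    assert likelihood(0, 7, 4, 0.0, CLEAN) == pytest.approx(1.0)
    assert likelihood(3, 7, 4, 0.0, CLEAN) == 0.0


def test_likelihood_fixed_reference_with_errors():
    rates = ErrorRates.from_class_rates(eps_R=0.01, eps_A=0.02)
    C, n_A = 9, 2
    expected = (math.comb(C, n_A) * rates.alpha ** n_A
                * (1 - rates.alpha) ** (C - n_A))
    assert likelihood(n_A, C, 5, 0.0, rates) == pytest.approx(expected,
                                                              rel=1e-12)


def test_likelihood_matches_brute_force_on_grid_sample():
    grid = FrequencyGrid().values
    rates = ErrorRates.from_class_rates(eps_R=0.01, eps_A=0.003)
    for N in (2, 4):
        for C in (3, 6):
            for n_A in (0, 1, C):
                for f in grid[::20]:
                    expected = brute_force_likelihood(n_A, C, N, f, rates)
                    got = likelihood(n_A, C, N, f, rates)
                    assert got == pytest.approx(expected, rel=1e-10)


def test_likelihood_deep_site_does_not_underflow():
    rates = MILD
    value = likelihood(500, 1000, 50, 0.5, rates)
    assert np.isfinite(value) and value > 0


def test_likelihood_curve_matches_scalar():
    grid = FrequencyGrid()
    rates = ErrorRates.from_class_rates(eps_R=0.002, eps_A=0.03)
    curve = likelihood_curve(4, 18, 10, grid, rates)
    for i in (0, 1, 50, 99, 100):
        assert curve[i] == pytest.approx(likelihood(4, 18, 10, grid.values[i],
                                                    rates), rel=1e-10)


def test_likelihood_validates_arguments():
    with pytest.raises(ValueError):
        likelihood(5, 3, 10, 0.5, CLEAN)


# -------------------------------------------------------------- posterior

def _counts(n_A, C, pos=1):
    return SiteCounts(chrom="c", pos=pos, ref="A",
                      alt="C" if n_A else None, C=C, n_A=n_A,
                      quals_R=[1e-3] * (C - n_A), quals_A=[1e-3] * n_A)


def test_posterior_with_no_data_equals_prior():
    prior = build_prior(PriorSpec(kind="informative", folded=True))
    post = posterior(_counts(0, 0), prior, N=10, rates=MILD)
    assert np.allclose(post.mass, prior.mass, rtol=1e-12)


def test_posterior_monomorphic_site_not_segregating():
    prior = build_prior(PriorSpec(kind="informative", folded=True,
                                  theta=0.001))
    post = posterior(_counts(0, 20), prior, N=50)
    res = summarize(post)
    assert res.p_seg < 0.01
    assert not res.called


def test_posterior_balanced_site_called_at_half():
    prior = build_prior(PriorSpec(kind="flat", folded=True, theta=0.001))
    res = call_site(_counts(10, 20), prior, N=50, rates=MILD)
    assert res.map_f == pytest.approx(0.5)
    assert res.p_seg > 0.99 and res.called


def test_posterior_symmetry_under_count_reversal():
    prior = build_prior(PriorSpec(kind="informative", folded=True))
    post_a = posterior(_counts(3, 20), prior, N=10, rates=MILD)
    post_b = posterior(_counts(17, 20), prior, N=10, rates=MILD)
    assert np.allclose(post_a.mass, post_b.mass[::-1], atol=1e-12)
    res = call_site(_counts(10, 20), prior, N=10, rates=MILD)
    assert res.mean_f == pytest.approx(0.5, abs=1e-9)


@pytest.mark.parametrize("kind", ["flat", "informative"])
def test_p_seg_monotone_in_alt_count(kind):
    prior = build_prior(PriorSpec(kind=kind, folded=True, theta=0.001))
    p_segs = [call_site(_counts(n_A, 20), prior, N=50, rates=MILD).p_seg
              for n_A in range(11)]
    assert all(a <= b + 1e-12 for a, b in zip(p_segs, p_segs[1:]))


# -------------------------------------------------------------- summaries

def test_summarize_point_mass_at_zero():
    grid = FrequencyGrid()
    mass = np.zeros(101)
    mass[0] = 1.0
    res = summarize(Distribution(grid, mass), threshold=0.5)
    assert res.p_seg == 0.0 and not res.called and res.map_f == 0.0


def test_summarize_uniform_mass_counting():
    grid = FrequencyGrid()
    res = summarize(Distribution(grid, np.full(101, 1 / 101)), threshold=0.9)
    assert res.p_seg == pytest.approx(99 / 101, rel=1e-12)
    assert res.called
    assert res.p_f0 + res.p_f1 + res.p_seg == pytest.approx(1.0, abs=1e-9)
    assert res.mean_f == pytest.approx(0.5, abs=1e-12)
    # MAP tie across the whole grid resolves to the smallest frequency
    assert res.map_f == 0.0


def test_batch_call_matches_scalar_path():
    """The vectorized caller and the per-site path agree to near machine
    precision on a spread of counts and error rates."""
    import pandas as pd
    prior = build_prior(PriorSpec(kind="informative", folded=True,
                                  theta=0.001, divergence=0.01))
    cases = [(0, 20, 1e-3, 1e-3), (1, 20, 1e-3, 1e-2), (10, 20, 1e-3, 1e-3),
             (5, 40, 2e-3, 5e-4), (39, 40, 1e-4, 1e-4), (2, 5, 0.01, 0.01)]
    frame = pd.DataFrame([
        {"chrom": "c", "pos": i + 1, "ref": "A", "alt": "C",
         "C": C, "n_A": n_A, "eps_R": er, "eps_A": ea}
        for i, (n_A, C, er, ea) in enumerate(cases)
    ])
    batch = batch_call(frame, N=30, prior=prior, threshold=0.9,
                       return_posteriors=True)
    for i, (n_A, C, er, ea) in enumerate(cases):
        rates = ErrorRates.from_class_rates(eps_R=er, eps_A=ea)
        post = posterior(_counts(n_A, C), prior, N=30, rates=rates)
        assert np.allclose(batch.posteriors[i], post.mass, atol=1e-12)
        row = batch.results.iloc[i]
        ref = summarize(post)
        assert row["p_seg"] == pytest.approx(ref.p_seg, abs=1e-12)
        assert row["mean_f"] == pytest.approx(ref.mean_f, abs=1e-12)
        assert row["map_f"] == ref.map_f


def test_harmonic_number():
    assert harmonic_number(1) == 1.0
    assert harmonic_number(4) == pytest.approx(1 + 0.5 + 1 / 3 + 0.25)
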