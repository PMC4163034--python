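"""Power model and causal-variant-count inference for ascertained GWAS.

A variant explaining a fraction ``vL`` of liability variance explains
``vO = vL * p(1-p) z^2 / (K^2 (1-K)^2)`` of variance on the observed 0/1
scale (the inverse of the liability transformation).  The marginal 1-df
association statistic for that variant in a sample of size ``n`` is then
noncentral chi-square with noncentrality ``NCP = n * vO``, giving

    power = Phi(sqrt(NCP) - sqrt(c)) + Phi(-sqrt(NCP) - sqrt(c)),

with ``c`` the (1 - alpha) quantile of a central chi-square(1) — the
exact tail of a noncentral chi-square(1), since the statistic is the
square of an N(sqrt(NCP), 1) variable.

From a null scan (no variant significant at some threshold alpha) one
can infer how many causal variants the observed total heritability must
be spread over: assuming a spectrum family for the per-variant
heritabilities, the probability of zero discoveries is the product of
per-variant non-detection probabilities, which increases with the number
of causal variants m.  The point estimate (lower bound) of m is the
smallest count at which this probability exceeds 0.5 (0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, expon, gamma, norm, uniform

from .liability import LiabilityDesign, design_from_prevalence

__all__ = [
    "PowerSettings",
    "ArchitectureSpectrum",
    "variant_power",
    "required_variance",
    "make_spectrum",
    "prob_zero_discoveries",
    "infer_num_causal",
    "project_discoveries",
    "spectrum_histogram",
]

FAMILIES = ("equal", "uniform", "exponential", "chi2")


@dataclass(frozen=True)
class PowerSettings:
    """Sample size, case fraction, prevalence and significance threshold."""

    n: int
    p: float
    K: float
    alpha: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("sample size must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def design(self) -> LiabilityDesign:
        return design_from_prevalence(self.K, self.p)


@dataclass(frozen=True)
class ArchitectureSpectrum:
    """Per-variant liability heritabilities under a named distribution family.

    ``v`` holds the m per-variant heritabilities in descending order and
    sums to ``total``.  The families are realized by deterministic
    mid-quantiles of a base distribution (constant; U(0,1); Exp(1);
    Gamma(shape 0.5) — the last is the distribution of heritability
    contributions when effect sizes are Gaussian), rescaled to the total.
    """

    family: str
    m: int
    v: np.ndarray = field(repr=False)
    total: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if len(self.v) != self.m:
            raise ValueError("spectrum length does not match m")


_BASE_PPF = {
    "equal": lambda q: np.ones_like(q),
    "uniform": uniform.ppf,
    "exponential": expon.ppf,
    "chi2": lambda q: gamma.ppf(q, 0.5),
}


def make_spectrum(total: float, m: int, family: str) -> ArchitectureSpectrum:
    """Deterministic mid-quantile spectrum: ``v_j ∝ F^-1((j - 0.5)/m)``.

    Rescaled so the per-variant heritabilities sum exactly to ``total``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < total < 1.0):
        raise ValueError("total heritability must lie in (0, 1)")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    q = (np.arange(m) + 0.5) / m
    raw = _BASE_PPF[family](q)
    v = raw * (total / raw.sum())
    return ArchitectureSpectrum(family=family, m=m, v=np.sort(v)[::-1], total=total)


def _threshold(alpha: float) -> float:
    return chi2.isf(alpha, 1)


def liability_to_observed_variance(vL, design: LiabilityDesign):
    """Observed-scale variance fraction of a variant explaining ``vL`` of liability."""
    K, p, z = design.K, design.p, design.z
    return np.asarray(vL) * p * (1 - p) * z**2 / (K**2 * (1 - K) ** 2)


def variant_power(vL, s: PowerSettings):
    """Detection probability for a variant explaining ``vL`` of liability variance.

    Vectorized over ``vL``.  Exact noncentral chi-square(1) tail via the
    two-Phi closed form.
    """
    vL = np.asarray(vL, dtype=float)
    if np.any(vL < 0) or np.any(vL >= 1):
        raise ValueError("per-variant liability variance must lie in [0, 1)")
    vO = liability_to_observed_variance(vL, s.design)
    if np.any(vO >= 1):
        raise ValueError("observed-scale variant variance >= 1; settings inconsistent")
    ncp = s.n * vO
    root_c = np.sqrt(_threshold(s.alpha))
    root_n = np.sqrt(ncp)
    out = norm.sf(root_c - root_n) + norm.cdf(-root_c - root_n)
    return out if out.ndim else float(out)


def required_variance(power_target: float, s: PowerSettings) -> float:
    """Liability variance at which :func:`variant_power` reaches ``power_target``.

    Inverts the power curve (strictly increasing in ``vL``) by bisection.
    """
    if not (s.alpha < power_target < 1.0):
        raise ValueError("power target must exceed alpha and be below 1")
    from scipy.optimize import brentq

    return brentq(lambda v: variant_power(v, s) - power_target, 1e-10, 0.5, xtol=1e-12)


def prob_zero_discoveries(spec: ArchitectureSpectrum, s: PowerSettings) -> float:
    """Probability that no causal variant reaches significance.

    Independence across variants is assumed:
    ``prod_j (1 - power(v_j))`` — computed in log space for stability.
    """
    pw = np.minimum(variant_power(spec.v, s), 1.0 - 1e-16)
    return float(np.exp(np.sum(np.log1p(-pw))))


def infer_num_causal(
    total: float,
    family: str,
    s: PowerSettings,
    target: float,
    grid_step: int = 10,
    grid_cap: int = 10**6,
) -> int:
    """Smallest causal-variant count with zero-discovery probability >= target.

    Searches the grid {grid_step, 2*grid_step, ...}; the zero-discovery
    probability is increasing in m at fixed total (more variants, each
    weaker), which is verified while scanning.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target probability must lie in (0, 1)")
    prev = -np.inf
    m = grid_step
    while m <= grid_cap:
        p0 = prob_zero_discoveries(make_spectrum(total, m, family), s)
        if p0 < prev - 1e-9:
            raise RuntimeError("zero-discovery probability not increasing in m")
        if p0 >= target:
            return m
        prev = p0
        m += grid_step
    raise RuntimeError(f"target {target} not reached below grid cap {grid_cap}")


def project_discoveries(spec: ArchitectureSpectrum, s: PowerSettings) -> tuple[float, float]:
    """Expected discoveries and liability variance they explain at larger n.

    Returns ``(sum_j power_j, sum_j power_j * v_j)`` — the mean of the
    Bernoulli-sum of per-variant detections and the expected variance
    captured by the detected variants.
    """
    pw = variant_power(spec.v, s)
    return float(np.sum(pw)), float(np.sum(pw * spec.v))


def spectrum_histogram(
    spec: ArchitectureSpectrum, edges
) -> tuple[np.ndarray, np.ndarray]:
    """Bin the spectrum: per-bin variant counts and shares of total heritability.

    ``edges`` are increasing per-variant-heritability bin boundaries;
    values outside the edges are dropped from the counts (shares are
    normalised by the full total, so they sum to 1 only when the edges
    cover the spectrum).
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(spec.v, bins=edges)
    shares, _ = np.histogram(spec.v, bins=edges, weights=spec.v)
    return counts, shares / spec.total
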