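"""Scalar machinery of the liability threshold model.

A binary trait is modelled through a latent liability ``L ~ N(0, 1)``:
an individual is affected when ``L`` exceeds the threshold
``T = Phi^-1(1 - K)``, where ``K`` is the population prevalence.  This
module collects the closed-form geometry of that model: threshold,
truncated-normal moments, the observed-to-liability scale transformation
under case-control ascertainment, the attenuation caused by misclassified
controls, and the familial (Falconer/Reich) estimator of total liability
heritability from prevalence and sibling relative risk.

All functions work in double precision and use :mod:`scipy.stats.norm`
for quantiles and densities (accurate to well below 1e-10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "LiabilityDesign",
    "FamilialRisk",
    "HeritabilityEstimate",
    "design_from_prevalence",
    "observed_to_liability",
    "liability_to_observed",
    "transformation_factor",
    "misclassification_factor",
    "familial_h2",
    "familial_h2_ci",
]


@dataclass(frozen=True)
class LiabilityDesign:
    """Threshold geometry for prevalence ``K`` and sample case fraction ``p``.

    Attributes
    ----------
    K : float
        Population prevalence of the trait.
    p : float
        Proportion of cases in the analysed sample (``p >> K`` under
        ascertainment).
    T : float
        Liability threshold, ``Phi^-1(1 - K)``.
    z : float
        Standard normal density at ``T``.
    i : float
        Mean liability of affected individuals, ``z / K`` (the selection
        intensity of truncation at ``T``).
    """

    K: float
    p: float
    T: float
    z: float
    i: float


@dataclass(frozen=True)
class FamilialRisk:
    """Prevalence plus sibling relative risk, the inputs of Falconer's method.

    ``lambda_s`` is the ratio of the recurrence risk in siblings of
    affected individuals to the population prevalence; an optional
    ``lambda_ci`` carries a (low, high) confidence interval for it.
    """

    K: float
    lambda_s: float
    lambda_ci: tuple[float, float] | None = None


@dataclass
class HeritabilityEstimate:
    """A SNP-heritability estimate and its scale transforms.

    ``h_obs`` is the proportion of variance explained on the observed
    (0/1) scale, ``h_liab`` its liability-scale transform, and
    ``h_corrected`` the liability-scale value after subtracting inflation
    fractions (population structure, genotyping errors).
    """

    h_obs: float
    se_obs: float | None = None
    h_liab: float | None = None
    h_corrected: float | None = None
    loglik: float | None = None
    n_samples: int | None = None
    scale_tag: str = "observed"


def _check_prob(x: float, name: str) -> None:
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {x!r}")


def design_from_prevalence(K: float, p: float) -> LiabilityDesign:
    """Build the :class:`LiabilityDesign` for prevalence ``K``, case fraction ``p``.

    ``T`` is the upper-``K`` quantile of the standard normal, ``z`` the
    density there and ``i = z/K`` the mean liability of cases.
    """
    _check_prob(K, "prevalence K")
    _check_prob(p, "case fraction p")
    T = norm.isf(K)
    z = norm.pdf(T)
    return LiabilityDesign(K=K, p=p, T=T, z=z, i=z / K)


def transformation_factor(design: LiabilityDesign) -> float:
    """Observed-to-liability scale factor ``K^2 (1-K)^2 / (p (1-p) z^2)``.

    For an unascertained sample (``p = K``) this reduces to
    ``K (1-K) / z^2``.
    """
    K, p, z = design.K, design.p, design.z
    return K**2 * (1 - K) ** 2 / (p * (1 - p) * z**2)


def observed_to_liability(h_obs: float, design: LiabilityDesign) -> float:
    """Transform variance explained on the 0/1 scale to the liability scale."""
    if not (0.0 <= h_obs <= 1.0):
        raise ValueError(f"h_obs must lie in [0, 1]; got {h_obs!r}")
    return h_obs * transformation_factor(design)


def liability_to_observed(h_liab: float, design: LiabilityDesign) -> float:
    """Inverse of :func:`observed_to_liability` (exact round-trip)."""
    return h_liab / transformation_factor(design)


def misclassification_factor(c: float) -> float:
    """Attenuation of the heritability estimate when a fraction ``c`` of
    controls are unrecognised cases.

    Each misclassified control shrinks the case-control contrast linearly,
    so the variance-explained estimate is multiplied by ``(1 - c)^2``
    (about a 1% loss at ``c = 0.005``).
    """
    if not (0.0 <= c < 1.0):
        raise ValueError(f"misclassified fraction must lie in [0, 1); got {c!r}")
    return (1.0 - c) ** 2


def familial_h2(risk: FamilialRisk, reich_correction: bool = True) -> float:
    """Total liability heritability from prevalence and sibling relative risk.

    Uses Falconer's threshold-model argument: siblings of probands have
    recurrence risk ``Ks = lambda_s * K``, hence their own liability
    threshold ``Ts = Phi^-1(1 - Ks)``; the regression of sibling liability
    on proband liability recovers ``h^2/2``.  By default the Reich, James
    & Morris second-order correction for the curvature of the truncated
    regression is applied:

        hT^2 = 2 [ T - Ts * sqrt(1 - (T^2 - Ts^2)(1 - T/i)) ]
               / [ i + Ts^2 (i - T) ]

    With ``reich_correction=False`` the first-order form ``2 (T - Ts)/i``
    is returned instead (slightly smaller for rare traits).
    """
    K, lam = risk.K, risk.lambda_s
    _check_prob(K, "prevalence K")
    if lam <= 0:
        raise ValueError(f"sibling relative risk must be positive; got {lam!r}")
    Ks = lam * K
    if not (0.0 < Ks < 1.0):
        raise ValueError(f"sibling recurrence risk lambda_s*K = {Ks!r} outside (0, 1)")
    d = design_from_prevalence(K, K)
    T, i = d.T, d.i
    Ts = norm.isf(Ks)
    if not reich_correction:
        return 2.0 * (T - Ts) / i
    inner = 1.0 - (T * T - Ts * Ts) * (1.0 - T / i)
    if inner < 0:
        raise ValueError("threshold-model correction undefined for these inputs")
    return 2.0 * (T - Ts * np.sqrt(inner)) / (i + Ts * Ts * (i - T))


def familial_h2_ci(risk: FamilialRisk, reich_correction: bool = True) -> tuple[float, float]:
    """Confidence interval for :func:`familial_h2` by endpoint transformation.

    The estimator is monotone increasing in ``lambda_s`` at fixed ``K``,
    so the interval for heritability is the image of the ``lambda_s``
    interval.
    """
    if risk.lambda_ci is None:
        raise ValueError("FamilialRisk.lambda_ci is required for a CI")
    lo, hi = risk.lambda_ci
    h_lo = familial_h2(FamilialRisk(risk.K, lo), reich_correction=reich_correction)
    h_hi = familial_h2(FamilialRisk(risk.K, hi), reich_correction=reich_correction)
    return (h_lo, h_hi)
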