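"""Performance of a liability-correlated polygenic score.

A polygenic score ``G`` and the liability ``L`` are modelled as bivariate
standard normal with correlation ``r = sqrt(rL^2)``, where ``rL^2`` is the
squared score-liability correlation (upper-bounded by the SNP
heritability on the liability scale).  Cases are individuals with
``L > T = Phi^-1(1 - K)``.

Two settings are covered:

* population screening — controls are everyone below the threshold;
  AUC, and the disease risk among the top score quantile.
* first-seizure triage — distinguishing single-seizure individuals who
  will have further seizures (cases, ``G | L > T``) from those for whom
  the seizure remains isolated.  Their liability distribution is
  unknown, so two bracketing scenarios are offered: ``population``
  (best case: non-recurrent liabilities look like the general
  population) and ``at_threshold`` (worst case: liabilities sit just
  below the case threshold, formalised as the degenerate conditioning
  ``L = T``; a narrow truncation window (T - eps, T) is available as an
  alternative).

All printed quantities are computed by deterministic quadrature; a
Monte-Carlo engine is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

__all__ = [
    "PredictionScenario",
    "RocCurve",
    "screening_auc",
    "screening_topq_risk",
    "triage_auc",
    "triage_roc",
    "triage_topq",
    "required_r2",
    "mc_screening_auc",
    "mc_triage_auc",
]

_LIAB_HI = 9.0  # integration limit; Phi(-9) ~ 1e-19


@dataclass(frozen=True)
class PredictionScenario:
    """Score quality plus the epidemiological frame it is evaluated in."""

    r2: float
    K: float = 0.005
    prev1: float = 0.45
    control_dist: str = "population"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")
        if not (0.0 < self.prev1 < 1.0):
            raise ValueError("prev1 must lie in (0, 1)")
        if self.control_dist not in ("population", "at_threshold"):
            raise ValueError("control_dist must be 'population' or 'at_threshold'")


@dataclass(frozen=True)
class RocCurve:
    """Receiver operating curve: ordered (FPR, TPR) pairs and the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _check_r2(r2: float) -> None:
    if not (0.0 <= r2 <= 1.0):
        raise ValueError(f"r2 must lie in [0, 1]; got {r2!r}")


def screening_auc(r2: float, K: float) -> float:
    """Population-screening AUC, ``P(G_case > G_control)``.

    Integrates ``Phi(r (l1 - l2) / sqrt(2 (1 - r^2)))`` over the truncated
    case (``l1 > T``) and control (``l2 <= T``) liability densities.
    """
    _check_r2(r2)
    if r2 == 0.0:
        return 0.5
    if r2 == 1.0:
        return 1.0
    r = np.sqrt(r2)
    T = norm.isf(K)
    s = np.sqrt(2.0 * (1.0 - r2))

    def inner(l1: float) -> float:
        val, _ = quad(lambda l2: norm.pdf(l2) * norm.cdf(r * (l1 - l2) / s), -_LIAB_HI, T)
        return val / (1.0 - K)

    val, _ = quad(lambda l1: norm.pdf(l1) * inner(l1), T, _LIAB_HI)
    return val / K


def screening_topq_risk(r2: float, K: float, q: float) -> float:
    """Disease probability among the top-``q`` fraction of predicted risk.

    ``P(L > T | G > Phi^-1(1 - q))`` by bivariate-normal orthant
    integration with correlation ``sqrt(r2)``.
    """
    _check_r2(r2)
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if r2 == 0.0:
        return K
    r = np.sqrt(r2)
    T = norm.isf(K)
    gq = norm.isf(q)
    # P(L > T, G > gq) = P(L < -T, G < -gq) by central symmetry
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    return float(mvn.cdf([-T, -gq])) / q


def _case_score_sf(t: float, r: float, T: float, K: float) -> float:
    """P(G > t) for cases, integrating G | L = l over the truncated liability."""
    s = np.sqrt(1.0 - r * r)
    val, _ = quad(lambda l: norm.pdf(l) * norm.sf((t - r * l) / s), T, _LIAB_HI)
    return val / K


def _ctrl_score_sf(t: float, r: float, T: float, control_dist: str, window: float | None):
    """P(G > t) for non-recurrent individuals under the chosen scenario."""
    if control_dist == "population":
        return norm.sf(t)
    s = np.sqrt(1.0 - r * r)
    if window is None:  # degenerate: L = T exactly
        return norm.sf((t - r * T) / s)
    lo = T - window
    mass = norm.cdf(T) - norm.cdf(lo)
    val, _ = quad(lambda l: norm.pdf(l) * norm.sf((t - r * l) / s), lo, T)
    return val / mass


def triage_auc(
    r2: float, control_dist: str = "population", K: float = 0.005, window: float | None = None
) -> float:
    """Triage AUC — prevalence-free, depends only on the two score distributions."""
    _check_r2(r2)
    if r2 == 0.0:
        return 0.5
    r = np.sqrt(r2)
    T = norm.isf(K)
    if control_dist == "population":
        # G_case - G_ctrl | l ~ N(r l, 2 - r^2)
        f = lambda l: norm.pdf(l) * norm.cdf(r * l / np.sqrt(2.0 - r2))
        val, _ = quad(f, T, _LIAB_HI)
        return val / K
    if window is None:
        f = lambda l: norm.pdf(l) * norm.cdf(r * (l - T) / np.sqrt(2.0 * (1.0 - r2)))
        val, _ = quad(f, T, _LIAB_HI)
        return val / K
    # windowed worst case: numeric double integral over case and control liabilities
    lo = T - window
    mass = norm.cdf(T) - norm.cdf(lo)
    s = np.sqrt(2.0 * (1.0 - r2))

    def inner(l1: float) -> float:
        val, _ = quad(lambda l2: norm.pdf(l2) * norm.cdf(r * (l1 - l2) / s), lo, T)
        return val / mass

    val, _ = quad(lambda l1: norm.pdf(l1) * inner(l1), T, _LIAB_HI)
    return val / K


def triage_roc(
    r2: float,
    prev1: float = 0.45,
    control_dist: str = "population",
    K: float = 0.005,
    n_points: int = 201,
    window: float | None = None,
) -> RocCurve:
    """Sweep score thresholds to build the triage ROC curve.

    ``prev1`` (epilepsy prevalence among single-seizure individuals) does
    not enter the curve itself — mixture weights affect only PPV-style
    quantities — but is carried for interface symmetry.
    """
    _check_r2(r2)
    r = np.sqrt(r2)
    T = norm.isf(K)
    ts = np.linspace(-6.0, 8.0, n_points)[::-1]
    if r2 == 0.0:
        fpr = tpr = norm.sf(ts)
    else:
        tpr = np.array([_case_score_sf(t, r, T, K) for t in ts])
        fpr = np.array([_ctrl_score_sf(t, r, T, control_dist, window) for t in ts])
    auc = triage_auc(r2, control_dist, K, window=window)
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


def triage_topq(
    r2: float,
    prev1: float = 0.45,
    control_dist: str = "population",
    q: float = 0.10,
    K: float = 0.005,
    window: float | None = None,
) -> tuple[float, float]:
    """(PPV, sensitivity) when flagging the top-``q`` fraction of scores.

    The threshold ``t`` solves
    ``prev1 P(G_case > t) + (1 - prev1) P(G_ctrl > t) = q``; then
    PPV = prev1 P(G_case > t) / q and sensitivity = P(G_case > t).
    """
    _check_r2(r2)
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if r2 == 0.0:
        return prev1, q
    r = np.sqrt(r2)
    T = norm.isf(K)

    def top_fraction(t: float) -> float:
        return (
            prev1 * _case_score_sf(t, r, T, K)
            + (1.0 - prev1) * _ctrl_score_sf(t, r, T, control_dist, window)
            - q
        )

    t = brentq(top_fraction, -8.0, 8.0, xtol=1e-10)
    sens = _case_score_sf(t, r, T, K)
    return prev1 * sens / q, sens


def required_r2(
    target_auc: float,
    scenario: str = "best",
    K: float = 0.005,
    tol: float = 1e-4,
    window: float | None = None,
) -> float:
    """Score quality needed to reach a target AUC (bisection on ``r2``).

    ``scenario`` is one of ``screening``, ``best`` (triage, population
    controls) or ``worst`` (triage, at-threshold controls).  The worst
    case has a bounded AUC; an unreachable target raises with the
    supremum reported in the message.
    """
    if not (0.5 < target_auc < 1.0):
        raise ValueError("target AUC must lie in (0.5, 1)")
    if scenario == "screening":
        auc = lambda r2: screening_auc(r2, K)
    elif scenario == "best":
        auc = lambda r2: triage_auc(r2, "population", K)
    elif scenario == "worst":
        auc = lambda r2: triage_auc(r2, "at_threshold", K, window=window)
    else:
        raise ValueError("scenario must be 'screening', 'best' or 'worst'")
    hi = auc(1.0 - 1e-9)
    if hi <= target_auc:
        raise ValueError(
            f"target AUC {target_auc} unreachable in scenario {scenario!r}; "
            f"supremum ~ {hi:.4f}"
        )
    return brentq(lambda r2: auc(r2) - target_auc, 1e-8, 1.0 - 1e-9, xtol=tol)


def mc_screening_auc(r2: float, K: float, n_draws: int = 10**7, seed: int = 0) -> float:
    """Monte-Carlo cross-check of :func:`screening_auc`."""
    _check_r2(r2)
    rng = np.random.default_rng(seed)
    r = np.sqrt(r2)
    T = norm.isf(K)
    L = rng.standard_normal(n_draws)
    G = r * L + np.sqrt(1.0 - r2) * rng.standard_normal(n_draws)
    case = L > T
    g_case, g_ctrl = G[case], G[~case]
    if g_case.size == 0:
        raise RuntimeError("no cases drawn; increase n_draws")
    reps = 50
    idx = rng.integers(0, g_ctrl.size, size=g_case.size * reps)
    return float((np.repeat(g_case, reps) > g_ctrl[idx]).mean())


def mc_triage_auc(
    r2: float,
    control_dist: str = "population",
    K: float = 0.005,
    n_case: int = 10**5,
    seed: int = 0,
    window: float | None = None,
) -> float:
    """Monte-Carlo cross-check of :func:`triage_auc` (direct truncated sampling)."""
    _check_r2(r2)
    rng = np.random.default_rng(seed)
    r = np.sqrt(r2)
    T = norm.isf(K)
    # case liabilities: inverse-CDF sampling of the upper tail
    u = rng.random(n_case)
    l_case = norm.isf(u * K)
    g_case = r * l_case + np.sqrt(1.0 - r2) * rng.standard_normal(n_case)
    if control_dist == "population":
        l_ctrl = norm.ppf(rng.random(n_case) * (1.0 - K))
    elif window is None:
        l_ctrl = np.full(n_case, T)
    else:
        lo_u, hi_u = norm.cdf(T - window), norm.cdf(T)
        l_ctrl = norm.ppf(lo_u + rng.random(n_case) * (hi_u - lo_u))
    g_ctrl = r * l_ctrl + np.sqrt(1.0 - r2) * rng.standard_normal(n_case)
    return float((g_case[rng.integers(0, n_case, 4 * n_case)] >
                  g_ctrl[rng.integers(0, n_case, 4 * n_case)]).mean())
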