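"""REML variance-component estimation and the marginal association scan.

The univariate model is the standard GREML linear mixed model on the
observed scale (for a binary trait, cases coded 1 and controls 0):

    y = X b + g + e,   g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with ``K`` the allelic-correlation kinship.  With a single kinship the
restricted likelihood can be maximised exactly: project the model onto
the orthogonal complement of the covariates, eigendecompose the
projected kinship once, and optimise the single heritability ratio
``h = sigma_g^2 / (sigma_g^2 + sigma_e^2)`` on [0, 1] (the total
variance profiles out in closed form).  This is exact, deterministic,
and needs no iterative AI/EM updates; an AI-REML iteration is provided
as an independent cross-check.

The bivariate model couples two traits measured on *disjoint* sample
sets through the cross-block kinship, estimating per-trait genetic and
residual variances and the genetic correlation ``rho_g`` (the
correlation of SNP effect sizes between the traits) by direct
maximisation of the joint restricted likelihood.  Likelihood-ratio tests
of ``rho = 0`` and ``rho = 1`` are reported (the latter halved for the
boundary).

The association scan offers a fast linear score test (equivalent to the
squared marginal z-statistic after residualising phenotype and genotype
on the covariates) and per-SNP additive logistic regression; both report
the genomic inflation factor ``lambda_GC = median(chi2) / 0.4549``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .grm import KinshipMatrix

__all__ = [
    "RemlFit",
    "BivariateFit",
    "ScanResult",
    "GREML",
    "BivariateGREML",
    "AssociationScan",
    "reml_univariate",
    "reml_bivariate",
    "association_scan",
]

CHI2_NULL_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class RemlFit:
    h_obs: float
    se_obs: float
    sigma_g: float
    sigma_e: float
    loglik: float
    n_iter: int
    converged: bool
    fixed_effects: np.ndarray


@dataclass
class BivariateFit:
    h1: float
    h2: float
    rho_g: float
    se_rho: float
    loglik: float
    lrt_rho0_p: float
    lrt_rho1_p: float


@dataclass
class ScanResult:
    table: pd.DataFrame
    lambda_gc: float
    min_p: float


def _as_kinship_values(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _design(X, n: int) -> np.ndarray:
    """Covariate matrix with an intercept guaranteed."""
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("covariate matrix does not match sample count")
    ones = np.ones((n, 1))
    # add intercept unless the span already contains it
    resid = ones - X @ np.linalg.lstsq(X, ones, rcond=None)[0]
    if np.max(np.abs(resid)) > 1e-8:
        X = np.hstack([ones, X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariates are rank-deficient")
    return X


class GREML(BaseEstimator):
    """Exact single-kinship REML of variance explained on the observed scale.

    Parameters
    ----------
    compute_se : bool
        Report a standard error from the curvature (observed information)
        of the profile restricted log-likelihood at the optimum.
    xatol : float
        Tolerance of the 1-D heritability optimisation.

    Fitted attributes (trailing underscore): ``h2_``, ``se_``,
    ``sigma_g_``, ``sigma_e_``, ``loglik_``, ``beta_``, ``n_iter_``,
    ``converged_``, ``n_samples_``.
    """

    def __init__(self, compute_se: bool = True, xatol: float = 1e-9):
        self.compute_se = compute_se
        self.xatol = xatol

    def fit(self, K, y, X=None):
        Kv = _as_kinship_values(K)
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if Kv.shape != (n, n):
            raise ValueError("kinship and phenotype dimensions disagree")
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype contains non-finite values")
        Xd = _design(X, n)
        q = Xd.shape[1]

        # orthonormal basis of the complement of the covariate span
        Q, _ = np.linalg.qr(Xd, mode="complete")
        A = Q[:, q:]
        S = A.T @ Kv @ A
        lam, U = np.linalg.eigh((S + S.T) / 2.0)
        if lam.min() < -1e-6 * max(1.0, lam.max()):
            raise FloatingPointError(
                f"projected kinship has negative eigenvalue {lam.min():.3g}"
            )
        lam = np.maximum(lam, 0.0)
        w2 = (U.T @ (A.T @ y)) ** 2
        df = n - q
        n_eval = 0

        def negll(h: float) -> float:
            nonlocal n_eval
            n_eval += 1
            v = h * lam + (1.0 - h)
            if np.any(v <= 0):
                return np.inf
            s2 = np.sum(w2 / v) / df
            return 0.5 * (df * np.log(s2) + np.sum(np.log(v)) + df * (1.0 + np.log(2 * np.pi)))

        res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": self.xatol})
        # the bounded optimiser never lands exactly on the ends; check them
        cands = [(negll(0.0), 0.0), (negll(1.0 - 1e-12), 1.0), (res.fun, float(res.x))]
        nll, h = min(cands, key=lambda t: t[0])
        v = h * lam + (1.0 - h)
        s2 = np.sum(w2 / v) / df

        se = np.nan
        if self.compute_se:
            eps = 1e-4
            hm, hp = max(h - eps, 0.0), min(h + eps, 1.0)
            d2 = (negll(hm) - 2 * negll((hm + hp) / 2) + negll(hp)) / ((hp - hm) / 2) ** 2
            se = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan

        V = s2 * (h * Kv + (1.0 - h) * np.eye(n))
        cf = cho_factor(V, lower=True)
        XtVi = cho_solve(cf, Xd).T
        self.beta_ = np.linalg.solve(XtVi @ Xd, XtVi @ y)
        self.h2_ = float(h)
        self.se_ = se
        self.sigma_g_ = float(h * s2)
        self.sigma_e_ = float((1.0 - h) * s2)
        self.loglik_ = float(-nll)
        self.n_iter_ = n_eval
        self.converged_ = True
        self.n_samples_ = n
        self._eig = (lam, w2, df)  # kept for profile cross-checks
        return self

    def profile_loglik(self, h_grid) -> np.ndarray:
        """Restricted log-likelihood along a heritability grid (after fit)."""
        lam, w2, df = self._eig
        out = []
        for h in np.asarray(h_grid, dtype=float):
            v = h * lam + (1.0 - h)
            s2 = np.sum(w2 / v) / df
            out.append(-0.5 * (df * np.log(s2) + np.sum(np.log(v))
                               + df * (1.0 + np.log(2 * np.pi))))
        return np.asarray(out)


def reml_univariate(K, y, X=None) -> RemlFit:
    """Functional wrapper over :class:`GREML`."""
    est = GREML().fit(K, y, X)
    return RemlFit(
        h_obs=est.h2_, se_obs=est.se_, sigma_g=est.sigma_g_, sigma_e=est.sigma_e_,
        loglik=est.loglik_, n_iter=est.n_iter_, converged=est.converged_,
        fixed_effects=est.beta_,
    )


def ai_reml_univariate(K, y, X=None, max_iter: int = 100, tol: float = 1e-8):
    """Average-information REML iteration — an independent cross-check engine.

    Returns (sigma_g, sigma_e, loglik).  Same model as :class:`GREML`;
    used in tests to confirm the eigendecomposition solution is the
    fixpoint of the iterative algorithm.
    """
    Kv = _as_kinship_values(K)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    Xd = _design(X, n)
    vc = np.array([0.5, 0.5]) * np.var(y)
    ll_old = -np.inf
    for _ in range(max_iter):
        V = vc[0] * Kv + vc[1] * np.eye(n)
        cf = cho_factor(V, lower=True)
        Vi_X = cho_solve(cf, Xd)
        XtViX = Xd.T @ Vi_X
        Py = cho_solve(cf, y) - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ y)
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (logdetV + np.linalg.slogdet(XtViX)[1] + y @ Py)
        KPy = Kv @ Py
        PKPy = cho_solve(cf, KPy) - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ KPy)
        PPy = cho_solve(cf, Py) - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ Py)
        # score: dl/dsigma_i = -0.5 (tr(P A_i) - y'P A_i P y)
        ViK = cho_solve(cf, Kv)
        trPK = np.trace(ViK) - np.einsum("ij,ji->", np.linalg.solve(XtViX, Vi_X.T @ Kv), Vi_X)
        trP = np.trace(cho_solve(cf, np.eye(n))) - np.einsum(
            "ij,ji->", np.linalg.solve(XtViX, Vi_X.T), Vi_X)
        score = -0.5 * np.array([trPK - Py @ KPy, trP - Py @ Py])
        AI = 0.5 * np.array([
            [KPy @ PKPy, KPy @ PPy],
            [KPy @ PPy, Py @ PPy],
        ])
        step = np.linalg.solve(AI, score)
        vc_new = np.maximum(vc + step, 1e-8 * np.var(y))
        if abs(ll - ll_old) < tol and np.max(np.abs(vc_new - vc)) < tol:
            vc = vc_new
            break
        vc, ll_old = vc_new, ll
    return float(vc[0]), float(vc[1]), float(ll)


class BivariateGREML(BaseEstimator):
    """Bivariate REML for two traits on disjoint sample sets.

    ``fit(K, y1, y2)`` takes length-n phenotype vectors aligned with the
    kinship, with NaN marking samples not measured for that trait; the
    two measured sets must be disjoint.  Estimates
    (sigma_g1, sigma_g2, rho, sigma_e1, sigma_e2) by L-BFGS-B on the
    joint restricted likelihood, plus constrained fits at rho = 0 and
    rho = 1 for likelihood-ratio tests.
    """

    def __init__(self, compute_se: bool = True, gtol: float = 1e-7):
        self.compute_se = compute_se
        self.gtol = gtol

    # -- likelihood machinery -------------------------------------------
    @staticmethod
    def _negll(theta, K11, K22, K12, y, Xd, fixed_rho=None):
        if fixed_rho is None:
            sg1, sg2, rho, se1, se2 = theta
        else:
            sg1, sg2, se1, se2 = theta
            rho = fixed_rho
        n1, n2 = K11.shape[0], K22.shape[0]
        c = rho * np.sqrt(sg1 * sg2)
        V = np.empty((n1 + n2, n1 + n2))
        V[:n1, :n1] = sg1 * K11 + se1 * np.eye(n1)
        V[n1:, n1:] = sg2 * K22 + se2 * np.eye(n2)
        V[:n1, n1:] = c * K12
        V[n1:, :n1] = c * K12.T
        try:
            cf = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e10
        Vi_X = cho_solve(cf, Xd)
        XtViX = Xd.T @ Vi_X
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e10
        Py = cho_solve(cf, y) - Vi_X @ np.linalg.solve(XtViX, Vi_X.T @ y)
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return 0.5 * (logdetV + logdetXtViX + y @ Py)

    def _optimise(self, args, rho0, fixed_rho=None):
        bounds_var = (1e-6, 10.0)
        if fixed_rho is None:
            x0 = np.array([0.3, 0.3, rho0, 0.7, 0.7])
            bounds = [bounds_var, bounds_var, (-0.99999, 0.99999), bounds_var, bounds_var]
        else:
            x0 = np.array([0.3, 0.3, 0.7, 0.7])
            bounds = [bounds_var, bounds_var, bounds_var, bounds_var]
        res = minimize(self._negll, x0, args=args + (fixed_rho,), method="L-BFGS-B",
                       bounds=bounds, options={"gtol": self.gtol, "maxiter": 500})
        return res

    def fit(self, K, y1, y2, X1=None, X2=None):
        Kv = _as_kinship_values(K)
        y1 = np.asarray(y1, dtype=float).ravel()
        y2 = np.asarray(y2, dtype=float).ravel()
        idx1 = np.flatnonzero(np.isfinite(y1))
        idx2 = np.flatnonzero(np.isfinite(y2))
        if np.intersect1d(idx1, idx2).size:
            raise ValueError("trait sample sets overlap; shared-sample covariance "
                             "is not modelled")
        K11 = Kv[np.ix_(idx1, idx1)]
        K22 = Kv[np.ix_(idx2, idx2)]
        K12 = Kv[np.ix_(idx1, idx2)]
        # standardise each trait so variance parameters are comparable
        s1, s2 = np.std(y1[idx1]), np.std(y2[idx2])
        yy = np.concatenate([y1[idx1] / s1, y2[idx2] / s2])
        X1d = _design(X1, idx1.size)
        X2d = _design(X2, idx2.size)
        Xd = np.zeros((idx1.size + idx2.size, X1d.shape[1] + X2d.shape[1]))
        Xd[: idx1.size, : X1d.shape[1]] = X1d
        Xd[idx1.size:, X1d.shape[1]:] = X2d
        args = (K11, K22, K12, yy, Xd)

        res = self._optimise(args, rho0=0.2)
        sg1, sg2, rho, se1, se2 = res.x
        ll = -res.fun
        res0 = self._optimise(args, rho0=0.0, fixed_rho=0.0)
        res1 = self._optimise(args, rho0=1.0, fixed_rho=0.99999)
        lrt0 = max(0.0, 2.0 * (ll - (-res0.fun)))
        lrt1 = max(0.0, 2.0 * (ll - (-res1.fun)))
        self.h1_ = float(sg1 / (sg1 + se1))
        self.h2trait_ = float(sg2 / (sg2 + se2))
        self.rho_g_ = float(rho)
        self.loglik_ = float(ll)
        self.lrt_rho0_p_ = float(chi2.sf(lrt0, 1))
        # rho = 1 sits on the parameter boundary: halved chi-square(1)
        self.lrt_rho1_p_ = float(0.5 * chi2.sf(lrt1, 1)) if lrt1 > 0 else 1.0
        self.converged_ = bool(res.success)
        se_rho = np.nan
        if self.compute_se:
            eps = 5e-3
            f = lambda r: self._negll(
                np.array([sg1, sg2, se1, se2]), *args, fixed_rho=np.clip(r, -0.99999, 0.99999))
            r0 = np.clip(rho, -0.99 + eps, 0.99 - eps)
            d2 = (f(r0 - eps) - 2 * f(r0) + f(r0 + eps)) / eps**2
            se_rho = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
        self.se_rho_ = se_rho
        self.sigma_ = {"g1": sg1 * s1**2, "g2": sg2 * s2**2,
                       "e1": se1 * s1**2, "e2": se2 * s2**2}
        return self


def reml_bivariate(K, y1, y2, X1=None, X2=None) -> BivariateFit:
    """Functional wrapper over :class:`BivariateGREML`."""
    est = BivariateGREML().fit(K, y1, y2, X1, X2)
    return BivariateFit(
        h1=est.h1_, h2=est.h2trait_, rho_g=est.rho_g_, se_rho=est.se_rho_,
        loglik=est.loglik_, lrt_rho0_p=est.lrt_rho0_p_, lrt_rho1_p=est.lrt_rho1_p_,
    )


class AssociationScan(BaseEstimator):
    """Marginal per-SNP 1-df association tests.

    ``model='linear-score'`` residualises phenotype and genotypes on the
    covariates and computes the squared marginal correlation statistic
    ``chi2_j = (n - q) r_j^2 / (1 - r_j^2)`` — the score test of the
    linear model, which closely tracks logistic regression for balanced
    designs and modest effects.  ``model='logistic'`` fits per-SNP
    additive logistic regressions (statsmodels); SNPs with separation
    fall back to the score test and are flagged.
    """

    def __init__(self, model: str = "linear-score"):
        self.model = model

    def fit(self, G, y, X=None):
        from .simulate import GenotypeMatrix

        dos = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)
        snp_ids = (G.snp_ids if isinstance(G, GenotypeMatrix)
                   else np.array([f"snp{j}" for j in range(dos.shape[1])], dtype=object))
        y = np.asarray(y, dtype=float).ravel()
        n, m = dos.shape
        Xd = _design(X, n)
        q = Xd.shape[1]
        if self.model not in ("linear-score", "logistic"):
            raise ValueError("model must be 'linear-score' or 'logistic'")

        Xpinv = np.linalg.pinv(Xd)
        ry = y - Xd @ (Xpinv @ y)
        Gf = np.asarray(dos, dtype=float)
        rG = Gf - Xd @ (Xpinv @ Gf)
        gss = np.einsum("ij,ij->j", rG, rG)
        gss = np.where(gss <= 0, np.nan, gss)
        gty = rG.T @ ry
        yss = ry @ ry
        r2 = gty**2 / (gss * yss)
        chisq = (n - q) * r2 / (1.0 - r2)
        beta = gty / gss
        flagged = np.zeros(m, dtype=bool)

        if self.model == "logistic":
            import statsmodels.api as sm

            for j in range(m):
                Xj = np.column_stack([Xd, Gf[:, j]])
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = sm.Logit(y, Xj).fit(disp=0, maxiter=100)
                    if not np.isfinite(fit.bse[-1]) or fit.bse[-1] > 100:
                        raise np.linalg.LinAlgError
                    zstat = fit.params[-1] / fit.bse[-1]
                    chisq[j] = zstat**2
                    beta[j] = fit.params[-1]
                except Exception:
                    flagged[j] = True  # separation/no convergence: keep score test

        pvals = chi2.sf(chisq, 1)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        self.table_ = pd.DataFrame({
            "SNP": snp_ids, "BETA": beta, "CHISQ": chisq, "P": pvals,
            "FALLBACK": flagged,
        })
        valid = np.isfinite(chisq)
        self.lambda_gc_ = float(np.median(chisq[valid]) / CHI2_NULL_MEDIAN)
        self.min_p_ = float(np.nanmin(pvals))
        return self


def association_scan(G, y, X=None, model: str = "linear-score") -> ScanResult:
    """Functional wrapper over :class:`AssociationScan`."""
    est = AssociationScan(model=model).fit(G, y, X)
    return ScanResult(table=est.table_, lambda_gc=est.lambda_gc_, min_p=est.min_p_)
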