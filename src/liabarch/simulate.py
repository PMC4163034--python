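"""Synthetic genotype/phenotype generation under the liability model.

The generators emulate the statistical structure the downstream analysis
assumes: Hardy-Weinberg genotypes at given allele frequencies (SNPs
independent, no LD), an additive liability with a chosen total
heritability and per-variant heritability spectrum, case-control
ascertainment at a low prevalence with oversampled cases, cohort-specific
genotyping errors (two control cohorts genotyped on different platforms),
and pairs of traits whose causal effect sizes correlate.

Effect sizes act on standardized genotypes, so a causal variant's
liability heritability is simply ``beta_j^2`` regardless of its allele
frequency — matching the centred-and-scaled allelic-correlation kinship
used by the heritability analysis.  Liabilities are ``N(0, 1)`` in the
generating population, with genetic share ``h2``.

Every generator is deterministic under its ``seed`` and records its
parameters as provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .liability import LiabilityDesign

__all__ = [
    "GenotypeMatrix",
    "TraitModel",
    "simulate_genotypes",
    "simulate_liability_trait",
    "ascertain_case_control",
    "simulate_ascertained_cohort",
    "inject_genotype_errors",
    "simulate_correlated_traits",
]

SPECTRUM_FAMILIES = ("equal", "uniform", "exponential", "chi2")


@dataclass
class GenotypeMatrix:
    """Additive dosages (n_samples x n_snps) with SNP metadata.

    ``allele_freq`` holds the generating (population) allele frequency of
    the counted allele; ``cohort_label`` tags each sample (e.g. "case",
    "ctrlA", "ctrlB").  ``meta`` carries generator provenance.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray
    allele_freq: np.ndarray
    cohort_label: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def standardized(self, freq: np.ndarray | None = None) -> np.ndarray:
        """Centred/scaled dosage matrix ``(x - 2f) / sqrt(2 f (1-f))``."""
        f = self.allele_freq if freq is None else np.asarray(freq)
        return (self.dosages - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_samples) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(rows, cols)],
            sample_ids=self.sample_ids[rows],
            snp_ids=self.snp_ids[cols],
            allele_freq=self.allele_freq[cols],
            cohort_label=None if self.cohort_label is None else self.cohort_label[rows],
            meta=dict(self.meta),
        )


@dataclass
class TraitModel:
    """Causal architecture of a simulated trait.

    ``beta`` are effects on standardized genotypes of the SNPs in
    ``causal_idx``; per-variant liability heritability is ``beta**2`` and
    sums to ``h2``.
    """

    causal_idx: np.ndarray
    beta: np.ndarray
    h2: float
    family: str
    rho: float | None = None
    meta: dict = field(default_factory=dict)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int | np.random.Generator = 0,
    cohort_label: str | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: frequencies uniform on ``maf_range``, dosages Binomial(2, f)."""
    if n <= 0 or m <= 0:
        raise ValueError("n and m must be positive")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = _rng(seed)
    f = rng.uniform(lo, hi, size=m) if lo < hi else np.full(m, lo)
    dosages = rng.binomial(2, f, size=(n, m)).astype(np.int8)
    labels = None if cohort_label is None else np.full(n, cohort_label, dtype=object)
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        allele_freq=f,
        cohort_label=labels,
        meta={"generator": "simulate_genotypes", "n": n, "m": m, "maf_range": maf_range},
    )


def _draw_variant_heritabilities(n_causal: int, h2: float, family: str, rng) -> np.ndarray:
    if family not in SPECTRUM_FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {SPECTRUM_FAMILIES}")
    if family == "equal":
        raw = np.ones(n_causal)
    elif family == "uniform":
        raw = rng.random(n_causal)
    elif family == "exponential":
        raw = rng.exponential(1.0, n_causal)
    else:  # chi2: gamma with shape 0.5, i.e. squared Gaussian effects
        raw = rng.gamma(0.5, 1.0, n_causal)
    raw = np.maximum(raw, 1e-12)
    return raw * (h2 / raw.sum())


def simulate_liability_trait(
    G: GenotypeMatrix,
    n_causal: int,
    h2: float,
    family: str = "equal",
    seed: int | np.random.Generator = 0,
) -> tuple[TraitModel, np.ndarray]:
    """Draw a causal architecture and liabilities for an existing genotype matrix.

    Per-variant heritabilities are drawn from the family and rescaled to
    sum to ``h2``; effects are ``±sqrt(v_j)`` with random sign on
    standardized genotypes; liability adds ``N(0, 1 - h2)`` noise.
    """
    if not (0.0 <= h2 < 1.0):
        raise ValueError("h2 must lie in [0, 1)")
    if n_causal > G.n_snps:
        raise ValueError("n_causal exceeds number of SNPs")
    rng = _rng(seed)
    causal = np.sort(rng.choice(G.n_snps, size=n_causal, replace=False))
    v = _draw_variant_heritabilities(n_causal, h2, family, rng) if h2 > 0 else np.zeros(n_causal)
    beta = np.sqrt(v) * rng.choice([-1.0, 1.0], size=n_causal)
    genetic = G.standardized()[:, causal] @ beta
    liab = genetic + rng.normal(0.0, np.sqrt(1.0 - h2), size=G.n_samples)
    model = TraitModel(
        causal_idx=causal, beta=beta, h2=h2, family=family,
        meta={"generator": "simulate_liability_trait", "n_causal": n_causal, "h2": h2},
    )
    return model, liab


def ascertain_case_control(
    liabilities: np.ndarray,
    design: LiabilityDesign,
    n_case: int,
    n_ctrl: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample cases from {L > T} and controls from {L <= T} of one population.

    Returns (selected indices, 0/1 phenotype).  Raises if the population
    does not contain enough individuals on either side of the threshold
    (the caller should oversample; see :func:`simulate_ascertained_cohort`).
    """
    rng = _rng(seed)
    liabilities = np.asarray(liabilities)
    above = np.flatnonzero(liabilities > design.T)
    below = np.flatnonzero(liabilities <= design.T)
    if above.size < n_case or below.size < n_ctrl:
        raise RuntimeError(
            f"population of {liabilities.size} holds {above.size} cases / "
            f"{below.size} controls; need {n_case} / {n_ctrl}"
        )
    cases = rng.choice(above, size=n_case, replace=False)
    ctrls = rng.choice(below, size=n_ctrl, replace=False)
    idx = np.concatenate([cases, ctrls])
    y = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])
    return idx, y


def simulate_ascertained_cohort(
    n_case: int,
    n_ctrl: int,
    K: float,
    m: int,
    n_causal: int,
    h2: float,
    family: str = "equal",
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int | np.random.Generator = 0,
    batch_size: int = 50_000,
    max_batches: int = 400,
    control_cohorts: tuple[str, ...] = ("ctrlA",),
) -> tuple[GenotypeMatrix, np.ndarray, TraitModel, np.ndarray]:
    """Case-control cohort ascertained at prevalence ``K`` from a large population.

    Because cases are rare (1/K individuals per case on average), the
    population is simulated in batches: only causal genotypes are drawn
    for screening, and the non-causal SNPs are filled in afterwards for
    the selected individuals only — statistically identical to screening
    full genomes since SNPs are independent.

    Controls are split evenly across ``control_cohorts`` labels; cases are
    labelled "case".  Returns (genotypes, phenotype 0/1, trait model,
    liabilities), samples ordered cases first.
    """
    if not (0.0 <= h2 < 1.0):
        raise ValueError("h2 must lie in [0, 1)")
    if n_causal > m:
        raise ValueError("n_causal exceeds m")
    rng = _rng(seed)
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    from scipy.stats import norm

    T = norm.isf(K)
    f = rng.uniform(lo, hi, size=m) if lo < hi else np.full(m, lo)
    causal = np.sort(rng.choice(m, size=n_causal, replace=False))
    v = _draw_variant_heritabilities(n_causal, h2, family, rng) if h2 > 0 else np.zeros(n_causal)
    beta = np.sqrt(v) * rng.choice([-1.0, 1.0], size=n_causal)
    f_c = f[causal]
    scale = np.sqrt(2.0 * f_c * (1.0 - f_c))
    sd_e = np.sqrt(1.0 - h2)

    case_geno, ctrl_geno = [], []
    case_liab, ctrl_liab = [], []
    n_case_found = n_ctrl_found = 0
    for _ in range(max_batches):
        if n_case_found >= n_case and n_ctrl_found >= n_ctrl:
            break
        x = rng.binomial(2, f_c, size=(batch_size, n_causal)).astype(np.int8)
        liab = ((x - 2.0 * f_c) / scale) @ beta + rng.normal(0.0, sd_e, size=batch_size)
        is_case = liab > T
        if n_case_found < n_case:
            take = np.flatnonzero(is_case)[: n_case - n_case_found]
            case_geno.append(x[take])
            case_liab.append(liab[take])
            n_case_found += take.size
        if n_ctrl_found < n_ctrl:
            take = np.flatnonzero(~is_case)[: n_ctrl - n_ctrl_found]
            ctrl_geno.append(x[take])
            ctrl_liab.append(liab[take])
            n_ctrl_found += take.size
    if n_case_found < n_case or n_ctrl_found < n_ctrl:
        raise RuntimeError(
            f"could not ascertain {n_case} cases / {n_ctrl} controls within "
            f"{max_batches} batches of {batch_size}"
        )

    n = n_case + n_ctrl
    dosages = np.empty((n, m), dtype=np.int8)
    dosages[:, causal] = np.vstack(case_geno + ctrl_geno)
    noncausal = np.setdiff1d(np.arange(m), causal)
    dosages[:, noncausal] = rng.binomial(2, f[noncausal], size=(n, noncausal.size))
    liabilities = np.concatenate(case_liab + ctrl_liab)
    y = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)])

    labels = np.empty(n, dtype=object)
    labels[:n_case] = "case"
    splits = np.array_split(np.arange(n_case, n), len(control_cohorts))
    for lab, part in zip(control_cohorts, splits):
        labels[part] = lab

    G = GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"S{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        allele_freq=f,
        cohort_label=labels,
        meta={
            "generator": "simulate_ascertained_cohort",
            "n_case": n_case, "n_ctrl": n_ctrl, "K": K, "m": m,
            "n_causal": n_causal, "h2": h2, "family": family,
        },
    )
    model = TraitModel(causal_idx=causal, beta=beta, h2=h2, family=family,
                       meta={"generator": "simulate_ascertained_cohort"})
    return G, y, model, liabilities


def inject_genotype_errors(
    G: GenotypeMatrix,
    rate: float,
    cohort: str,
    seed: int | np.random.Generator = 0,
    freq_shift: float = 0.01,
) -> GenotypeMatrix:
    """Cohort-specific genotyping errors by frequency-perturbed regeneration.

    For samples of the named cohort only, each dosage is independently
    replaced with probability ``rate`` by a Binomial(2, f') draw, with
    ``f'`` the SNP frequency shifted by ``freq_shift`` (clipped to
    (0.001, 0.999)).  Other cohorts are untouched; the input is not
    modified.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("error rate must lie in [0, 1]")
    if G.cohort_label is None:
        raise KeyError("genotype matrix carries no cohort labels")
    rows = np.flatnonzero(G.cohort_label == cohort)
    if rows.size == 0:
        raise KeyError(f"unknown cohort label {cohort!r}")
    out = replace(G, dosages=G.dosages.copy(), meta=dict(G.meta))
    if rate == 0.0:
        return out
    rng = _rng(seed)
    f_err = np.clip(G.allele_freq + freq_shift, 0.001, 0.999)
    block = out.dosages[rows]
    mask = rng.random(block.shape) < rate
    redraw = rng.binomial(2, np.broadcast_to(f_err, block.shape)).astype(np.int8)
    out.dosages[rows] = np.where(mask, redraw, block)
    out.meta.update(error_cohort=cohort, error_rate=rate, error_freq_shift=freq_shift)
    return out


def simulate_correlated_traits(
    G: GenotypeMatrix,
    n_causal: int,
    h2_1: float,
    h2_2: float,
    rho: float,
    seed: int | np.random.Generator = 0,
) -> tuple[TraitModel, TraitModel, np.ndarray, np.ndarray]:
    """Two traits with correlated causal effects over a shared causal set.

    Effects are drawn bivariate normal with correlation ``rho``, then each
    column is rescaled so its squared effects sum to the trait's ``h2``.
    Returns the two trait models and the two liability vectors (evaluated
    on all samples of ``G``).
    """
    if abs(rho) > 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    for h2 in (h2_1, h2_2):
        if not (0.0 <= h2 < 1.0):
            raise ValueError("h2 must lie in [0, 1)")
    if n_causal > G.n_snps:
        raise ValueError("n_causal exceeds number of SNPs")
    rng = _rng(seed)
    causal = np.sort(rng.choice(G.n_snps, size=n_causal, replace=False))
    e1 = rng.standard_normal(n_causal)
    e2 = rho * e1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n_causal)
    b1 = e1 * np.sqrt(h2_1 / np.sum(e1**2)) if h2_1 > 0 else np.zeros(n_causal)
    b2 = e2 * np.sqrt(h2_2 / np.sum(e2**2)) if h2_2 > 0 else np.zeros(n_causal)
    if abs(rho) == 1.0 and h2_1 == h2_2:
        b2 = np.sign(rho) * b1  # exact identity/mirror, not just in distribution
    Z = G.standardized()[:, causal]
    l1 = Z @ b1 + rng.normal(0.0, np.sqrt(1.0 - h2_1), size=G.n_samples)
    l2 = Z @ b2 + rng.normal(0.0, np.sqrt(1.0 - h2_2), size=G.n_samples)
    meta = {"generator": "simulate_correlated_traits", "rho": rho}
    m1 = TraitModel(causal_idx=causal, beta=b1, h2=h2_1, family="gaussian", rho=rho, meta=meta)
    m2 = TraitModel(causal_idx=causal, beta=b2, h2=h2_2, family="gaussian", rho=rho, meta=meta)
    return m1, m2, l1, l2
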