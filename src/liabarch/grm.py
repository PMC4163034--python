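"""Allelic-correlation kinship (GRM), relatedness filtering, principal axes.

The kinship between individuals j and k is the average over SNPs of the
product of their centred, scaled genotypes:

    K_jk = (1/W) sum_i w_i (x_ij - 2 f_i)(x_ik - 2 f_i) / (2 f_i (1 - f_i))

with ``W = sum_i w_i`` and unit weights by default.  Allele frequencies
are estimated from the full analysis sample (cases and controls pooled).
The ``weights`` argument is an injection point for externally computed
tagging weights (e.g. LD-adjusted); the unweighted form is the default.

I/O follows the GCTA binary triple convention (``.grm.bin`` float32
lower triangle, ``.grm.N.bin``, ``.grm.id``) with a plain-text
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simulate import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "compute_grm",
    "filter_relatedness",
    "principal_axes",
    "write_grm_text",
    "read_grm_text",
    "write_grm_bin",
    "read_grm_bin",
]


@dataclass
class KinshipMatrix:
    """Symmetric n x n kinship with sample ids and provenance."""

    values: np.ndarray
    sample_ids: np.ndarray
    n_snps_used: int
    weights_applied: bool = False

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix(
            values=self.values[np.ix_(idx, idx)],
            sample_ids=self.sample_ids[idx],
            n_snps_used=self.n_snps_used,
            weights_applied=self.weights_applied,
        )


def compute_grm(G: GenotypeMatrix, weights: np.ndarray | None = None) -> KinshipMatrix:
    """Allelic-correlation kinship from dosages.

    Monomorphic SNPs (in-sample frequency 0 or 1) are excluded with a
    warning reporting the count.  Frequencies are the pooled in-sample
    estimates, not the generating values.
    """
    X = np.asarray(G.dosages, dtype=np.float64)
    f = X.mean(axis=0) / 2.0
    poly = (f > 0.0) & (f < 1.0)
    n_dropped = int((~poly).sum())
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} monomorphic SNPs from the kinship matrix")
        X, f = X[:, poly], f[poly]
    if weights is None:
        w = np.ones(X.shape[1])
        applied = False
    else:
        w = np.asarray(weights, dtype=np.float64)
        if weights is not None and n_dropped:
            w = w[poly]
        if w.shape[0] != X.shape[1]:
            raise ValueError("weights length does not match SNP count")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        applied = True
    Z = (X - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    Zw = Z * np.sqrt(w / w.sum())
    K = Zw @ Zw.T
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, sample_ids=np.asarray(G.sample_ids),
                         n_snps_used=X.shape[1], weights_applied=applied)


def filter_relatedness(K: KinshipMatrix, threshold: float = 0.026) -> np.ndarray:
    """Greedy relatedness filtering: retained sample ids with no pair above threshold.

    Repeatedly drops the sample participating in the most over-threshold
    pairs (ties broken toward the larger sample index) until no pair
    exceeds ``threshold``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    A = np.triu(K.values, k=1) > threshold
    A = A | A.T
    alive = np.ones(K.n_samples, dtype=bool)
    deg = A.sum(axis=1).astype(int)
    while True:
        if not np.any(deg[alive] > 0):
            break
        cand = np.flatnonzero(alive & (deg == deg[alive].max()))
        drop = cand[-1]  # largest index among maximal-degree samples
        alive[drop] = False
        deg[A[drop]] -= 1
        deg[drop] = 0
    return K.sample_ids[alive]


def principal_axes(K: KinshipMatrix, n_axes: int) -> np.ndarray:
    """Top eigenvectors of the kinship, by descending eigenvalue.

    Columns are unit-norm with a deterministic sign convention: the
    largest-magnitude loading of each axis is positive.
    """
    n = K.n_samples
    if not (0 < n_axes < n):
        raise ValueError(f"n_axes must lie in (0, {n})")
    vals, vecs = np.linalg.eigh(K.values)
    order = np.argsort(vals)[::-1][:n_axes]
    V = vecs[:, order]
    for j in range(V.shape[1]):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return V


# ---------------------------------------------------------------------------
# I/O: GCTA-compatible binary triple and a plain-text form

def _p(prefix, ext: str):
    return Path(str(prefix) + ext)


def _tri_indices(n: int):
    return np.tril_indices(n)


def write_grm_bin(K: KinshipMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    n = K.n_samples
    i, j = _tri_indices(n)
    K.values[i, j].astype("<f4").tofile(_p(prefix, ".grm.bin"))
    np.full(i.size, K.n_snps_used, dtype="<f4").tofile(_p(prefix, ".grm.N.bin"))
    with open(_p(prefix, ".grm.id"), "w") as fh:
        for sid in K.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_bin(prefix: str | Path) -> KinshipMatrix:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(_p(prefix, ".grm.id"))]
    n = len(ids)
    tri = np.fromfile(_p(prefix, ".grm.bin"), dtype="<f4")
    i, j = _tri_indices(n)
    if tri.size != i.size:
        raise ValueError("grm.bin size does not match grm.id sample count")
    V = np.zeros((n, n))
    V[i, j] = tri
    V = V + np.tril(V, k=-1).T
    nsnp = np.fromfile(_p(prefix, ".grm.N.bin"), dtype="<f4")
    return KinshipMatrix(values=V, sample_ids=np.array(ids, dtype=object),
                         n_snps_used=int(nsnp[0]) if nsnp.size else 0)


def write_grm_text(K: KinshipMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    np.savetxt(_p(prefix, ".grm.txt"), K.values, fmt="%.8g", delimiter="\t")
    with open(_p(prefix, ".grm.id"), "w") as fh:
        for sid in K.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_text(prefix: str | Path) -> KinshipMatrix:
    prefix = Path(prefix)
    V = np.loadtxt(_p(prefix, ".grm.txt"), delimiter="\t", ndmin=2)
    ids = [line.split()[1] for line in open(_p(prefix, ".grm.id"))]
    if V.shape[0] != len(ids):
        raise ValueError("grm.txt dimensions do not match grm.id sample count")
    return KinshipMatrix(values=V, sample_ids=np.array(ids, dtype=object), n_snps_used=0)
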