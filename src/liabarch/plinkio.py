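"""PLINK .bed/.bim/.fam reading and writing for hard-call dosages.

SNP-major .bed layout: magic bytes 0x6c 0x1b, mode byte 0x01, then for
each SNP the samples packed four per byte, two bits each, least
significant pair first.  Two-bit codes (counting A1): 00 -> 2 copies,
10 -> 1, 11 -> 0, 01 -> missing.  Missing genotypes are rejected on read
with a count (the synthetic generators never emit them).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = ["read_plink", "write_plink", "write_phenotype_tsv", "PlinkFormatError"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# dosage -> 2-bit code and back
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, -9, 1, 0], dtype=np.int8)  # index by 2-bit code


class PlinkFormatError(ValueError):
    pass


def _p(prefix, ext):
    return Path(str(prefix) + ext)


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write hard-call dosages as a .bed/.bim/.fam triple (SNP-major)."""
    dos = np.asarray(G.dosages)
    if not np.all(np.isin(dos, (0, 1, 2))):
        raise PlinkFormatError(".bed stores hard calls; dosages must be 0/1/2")
    n, m = dos.shape
    codes = np.empty((m, n), dtype=np.uint8)
    dt = dos.T
    codes[dt == 2] = 0b00
    codes[dt == 1] = 0b10
    codes[dt == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(_p(prefix, ".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
    with open(_p(prefix, ".bim"), "w") as fh:
        for j, sid in enumerate(G.snp_ids):
            fh.write(f"1\t{sid}\t0\t{j + 1}\tA\tB\n")
    with open(_p(prefix, ".fam"), "w") as fh:
        labels = G.cohort_label
        for i, s in enumerate(G.sample_ids):
            pheno = 2 if labels is not None and labels[i] == "case" else 1
            fh.write(f"{s}\t{s}\t0\t0\t0\t{pheno}\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triple back into a :class:`GenotypeMatrix`.

    Allele frequencies are re-estimated from the sample.  Raises
    :class:`PlinkFormatError` on a bad magic/mode byte, dimension
    mismatch, or any missing genotype (with the missing count).
    """
    fam = pd.read_csv(_p(prefix, ".fam"), sep=r"\s+", header=None,
                      names=["FID", "IID", "PID", "MID", "SEX", "PHENO"])
    bim = pd.read_csv(_p(prefix, ".bim"), sep=r"\s+", header=None,
                      names=["CHR", "SNP", "CM", "BP", "A1", "A2"])
    n, m = len(fam), len(bim)
    raw = open(_p(prefix, ".bed"), "rb").read()
    if raw[:3] != _MAGIC:
        raise PlinkFormatError(
            "bad .bed header: expected magic 6c 1b with SNP-major mode 01, "
            f"got {raw[:3].hex(' ')}"
        )
    bps = (n + 3) // 4  # bytes per SNP
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * bps:
        raise PlinkFormatError(
            f".bed payload of {body.size} bytes does not match "
            f"{m} SNPs x {bps} bytes ({n} samples)"
        )
    body = body.reshape(m, bps)
    codes = np.empty((m, bps * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    codes = codes[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()
    n_missing = int((dosages == -9).sum())
    if n_missing:
        raise PlinkFormatError(f".bed contains {n_missing} missing genotypes")
    f = dosages.mean(axis=0) / 2.0
    labels = np.where(fam["PHENO"].to_numpy() == 2, "case", "ctrl").astype(object)
    return GenotypeMatrix(
        dosages=dosages.astype(np.int8),
        sample_ids=fam["IID"].to_numpy(dtype=object),
        snp_ids=bim["SNP"].to_numpy(dtype=object),
        allele_freq=f,
        cohort_label=labels,
        meta={"source": str(prefix)},
    )


def write_phenotype_tsv(path, sample_ids, phenotype, covariates: dict | None = None,
                        cohort_label=None) -> None:
    """FID/IID-keyed phenotype + covariate TSV companion to the PLINK triple."""
    df = pd.DataFrame({"FID": sample_ids, "IID": sample_ids,
                       "PHENO": np.asarray(phenotype)})
    if cohort_label is not None:
        df["COHORT"] = np.asarray(cohort_label)
    for name, vals in (covariates or {}).items():
        df[name] = np.asarray(vals)
    df.to_csv(path, sep="\t", index=False)
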