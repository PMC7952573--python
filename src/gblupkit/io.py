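"""Genotype, phenotype and GRM input/output.

Implements the three on-disk formats the pipeline touches:

* PLINK bed/bim/fam (bed: magic ``0x6C 0x1B``, mode ``0x01`` SNP-major,
  two bits per genotype, four samples per byte packed low-bits-first),
* the GCTA binary GRM triplet (``.grm.bin`` float32 lower triangle
  including the diagonal, ``.grm.N.bin`` per-pair SNP counts,
  ``.grm.id`` two-column text),
* tab-separated phenotype/covariate tables with ``NA`` for missing.

The in-memory genotype container is :class:`GenotypeMatrix`: allele
counts 0/1/2 (copies of allele1) with ``-1`` for a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> allele1 dosage: 00 -> 2, 01 -> missing, 10 -> 1, 11 -> 0
_CODE_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
# call (indexed as call & 3, so -1 -> 3) -> 2-bit code
_CALL_TO_CODE = np.array([0b11, 0b10, 0b00, 0b01], dtype=np.uint8)

_DECODE = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _s in range(4):
        _DECODE[_b, _s] = _CODE_TO_CALL[(_b >> (2 * _s)) & 0b11]

_SEX_TO_CODE = {"male": 1, "female": 2, "unknown": 0}
_CODE_TO_SEX = {1: "male", 2: "female"}


class BedFormatError(ValueError):
    """Raised when a .bed file has bad magic bytes or mode."""


class BedLengthError(ValueError):
    """Raised when a .bed payload size disagrees with bim/fam counts."""


class GrmLengthError(ValueError):
    """Raised when a GRM binary size disagrees with the id count."""


class SNPRecord(NamedTuple):
    snp_id: str
    chrom: str
    pos_bp: int
    allele1: str
    allele2: str


class SampleRecord(NamedTuple):
    sample_id: str
    family_id: str
    sex: str  # "male" | "female" | "unknown"


@dataclass
class GenotypeMatrix:
    """Allele-count genotypes for n samples x k SNPs.

    ``samples``: DataFrame with columns family_id, sample_id, sex.
    ``snps``: DataFrame with columns snp_id, chrom, pos_bp, allele1, allele2.
    ``calls``: int8 array of shape (n, k); entries in {0, 1, 2, -1},
    counting copies of allele1 (-1 = missing).
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.samples)}, {len(self.snps)}) samples x snps"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        ok = (self.calls >= -1) & (self.calls <= 2)
        if not ok.all():
            raise ValueError("genotype calls outside {0,1,2,missing}")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in panel")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        same = self.snps["allele1"].astype(str) == self.snps["allele2"].astype(str)
        if same.any():
            raise ValueError("allele1 == allele2 for some SNPs")
        if (self.snps["pos_bp"] < 1).any():
            raise ValueError("pos_bp must be >= 1")

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Row/column subset by positional index arrays (copies)."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        sj = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=self.samples.iloc[si].reset_index(drop=True),
            snps=self.snps.iloc[sj].reset_index(drop=True),
            calls=self.calls[np.ix_(si, sj)].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.calls, other.calls)
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
        )


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam fileset (SNP-major bed only)."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["family_id", "sample_id", "father", "mother", "sex_code", "phenotype"],
        dtype={"family_id": str, "sample_id": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    n, k = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise BedFormatError(
            f"{prefix}.bed: bad magic/mode bytes {raw[:3].tobytes()!r} "
            "(expected 6c 1b 01, SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + k * bytes_per_snp
    if raw.size != expected:
        raise BedLengthError(
            f"{prefix}.bed: payload is {raw.size} bytes, expected {expected} "
            f"(3 + {k} SNPs x ceil({n}/4))"
        )
    if k and n:
        calls = _DECODE[raw[3:]].reshape(k, bytes_per_snp * 4)[:, :n].T
    else:
        calls = np.zeros((n, k), dtype=np.int8)
    samples = pd.DataFrame(
        {
            "family_id": fam["family_id"],
            "sample_id": fam["sample_id"],
            "sex": fam["sex_code"].map(_CODE_TO_SEX).fillna("unknown"),
        }
    )
    snps = bim[["snp_id", "chrom", "pos_bp", "allele1", "allele2"]].copy()
    return GenotypeMatrix(samples=samples, snps=snps, calls=np.ascontiguousarray(calls))


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK bed/bim/fam fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, k = g.n_samples, g.n_snps
    sex_code = g.samples["sex"].map(_SEX_TO_CODE).fillna(0).astype(int)
    fam = pd.DataFrame(
        {
            "family_id": g.samples["family_id"],
            "sample_id": g.samples["sample_id"],
            "father": 0,
            "mother": 0,
            "sex_code": sex_code,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": g.snps["chrom"],
            "snp_id": g.snps["snp_id"],
            "cm": 0,
            "pos_bp": g.snps["pos_bp"],
            "allele1": g.snps["allele1"],
            "allele2": g.snps["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((k, bytes_per_snp * 4), dtype=np.uint8)  # pad bits are code 00
    if n and k:
        padded[:, :n] = _CALL_TO_CODE[g.calls.T & 0b11]
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated phenotype/covariate table (NA = missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table must have a sample_id column")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_grm_gcta(a: np.ndarray, k_snps: int, sample_ids, prefix: str | Path) -> None:
    """Write a GRM in the GCTA binary triplet (float32, lossy on disk)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    a = np.asarray(a, dtype=np.float64)
    n = a.shape[0]
    tri = a[np.tril_indices(n)].astype(np.float32)
    tri.tofile(str(prefix) + ".grm.bin")
    np.full(tri.shape, float(k_snps), dtype=np.float32).tofile(str(prefix) + ".grm.N.bin")
    ids = pd.DataFrame({"family_id": [str(s) for s in sample_ids], "sample_id": [str(s) for s in sample_ids]})
    ids.to_csv(str(prefix) + ".grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(prefix: str | Path):
    """Read a GCTA binary GRM triplet; returns a :class:`gblupkit.grm.GRM`."""
    from .grm import GRM  # local import to avoid a cycle

    prefix = str(Path(prefix))
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None, dtype=str)
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype=np.float32)
    n_pairs = n * (n + 1) // 2
    if tri.size != n_pairs:
        raise GrmLengthError(
            f"{prefix}.grm.bin holds {tri.size} float32 values; "
            f"{n} ids require {n_pairs}"
        )
    a = np.zeros((n, n), dtype=np.float64)
    a[np.tril_indices(n)] = tri
    a = a + np.tril(a, -1).T
    counts = np.fromfile(prefix + ".grm.N.bin", dtype=np.float32)
    k_snps = int(round(float(counts[0]))) if counts.size else 0
    return GRM(a=a, k_snps=k_snps, sample_ids=list(ids.iloc[:, 1]))
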