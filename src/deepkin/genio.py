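"""PLINK 1 binary genotype I/O, QC, and genotype standardization.

Genotypes are stored as counts of the A1 ("counted") allele in {0, 1, 2}
with ``-1`` marking a missing call.  All downstream relatedness statistics
are provably invariant to which allele is counted at each locus (flipping
A1/A2 maps a standardized column to its negative, and every statistic is
quadratic in the standardized genotypes), so no allele harmonization is
performed or needed.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "StandardizedMatrix",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "allele_frequencies",
    "qc_filter",
    "standardize",
]

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK BED codes -> A1 allele count (missing = -1).
# 00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)

_BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
_FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """Raised for malformed or mutually inconsistent BED/BIM/FAM files."""


@dataclass
class GenotypeMatrix:
    """n x m genotype matrix with sample and variant metadata.

    Attributes
    ----------
    samples : list of str
        Individual IDs, in file order.
    variants : pandas.DataFrame
        One row per locus with columns chrom, snp, cm, pos, a1, a2.
    G : numpy.ndarray
        ``(n, m)`` int8 matrix of A1-allele counts; ``-1`` is missing.
    """

    samples: list[str]
    variants: pd.DataFrame
    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-D array")
        n, m = self.G.shape
        if n != len(self.samples):
            raise ValueError(
                f"G has {n} rows but {len(self.samples)} sample IDs"
            )
        if m != len(self.variants):
            raise ValueError(
                f"G has {m} columns but {len(self.variants)} variant records"
            )

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @property
    def p_hat(self) -> np.ndarray:
        """In-sample counted-allele frequency per locus."""
        return allele_frequencies(self)


@dataclass
class StandardizedMatrix:
    """Column-standardized genotypes x~ = (x - 2p)/sqrt(2pq).

    Columns have zero mean when the frequencies were estimated from the
    same samples, and (approximately) unit variance under Hardy-Weinberg
    proportions.
    """

    X: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


def _decode_bed_bytes(payload: np.ndarray, n: int, m: int) -> np.ndarray:
    """Unpack SNP-major BED payload into an (n, m) int8 genotype matrix."""
    bytes_per_snp = (n + 3) // 4
    payload = payload.reshape(m, bytes_per_snp)
    # expand each byte into 4 two-bit codes, little-endian within the byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (payload >> (2 * k)) & 0b11
    return _BED_DECODE[codes[:, :n]].T.copy()


def _encode_bed_bytes(G: np.ndarray) -> bytes:
    """Pack an (n, m) genotype matrix into SNP-major BED payload bytes."""
    n, m = G.shape
    # A1 count -> 2-bit code
    code_of = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    codes = np.zeros((m, n), dtype=np.uint8)
    for g, c in code_of.items():
        codes[G.T == g] = c
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    out = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    return out.tobytes()


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary trio (``prefix.bed/.bim/.fam``).

    The BED file must be in SNP-major mode (the only mode PLINK 1.9+
    writes).  Sample and variant order is preserved.

    Raises
    ------
    PlinkFormatError
        On bad magic bytes or a BED payload whose size does not match
        ``ceil(n/4) * m``.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=_FAM_COLUMNS, dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=_BIM_COLUMNS,
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: individual-major BED is not supported"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    expected = ((n + 3) // 4) * m
    if payload.size != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: payload is {payload.size} bytes, expected "
            f"{expected} for {n} samples x {m} variants"
        )
    G = _decode_bed_bytes(payload, n, m)
    return GenotypeMatrix(samples=list(fam["iid"]), variants=bim, G=G)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix.bed/.bim/.fam`` in the PLINK 1 SNP-major dialect."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + struct.pack("B", _SNP_MAJOR))
        fh.write(_encode_bed_bytes(gm.G))
    fam = pd.DataFrame(
        {
            "fid": gm.samples, "iid": gm.samples,
            "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    gm.variants.to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False
    )


def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per locus, ignoring missing genotypes.

    p_hat[l] = (sum of non-missing A1 counts at l) / (2 * non-missing n).

    Raises
    ------
    ValueError
        If some locus has no non-missing genotype (names the locus).
    """
    G = gm.G
    observed = G != MISSING
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        bad = np.flatnonzero(n_obs == 0)
        names = ", ".join(gm.variants["snp"].iloc[bad[:5]])
        raise ValueError(f"locus entirely missing: {names}")
    counts = np.where(observed, G, 0).sum(axis=0)
    return counts / (2.0 * n_obs)


def qc_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    allow_missing: bool = False,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop loci failing MAF and missingness criteria.

    A locus is retained when min(p, 1-p) is *strictly* greater than
    ``maf_min`` (a boundary MAF exactly equal to the threshold is
    dropped), and — unless ``allow_missing`` — when no genotype at the
    locus is missing.

    Returns the filtered matrix together with a report of the number of
    loci dropped per rule.

    Raises
    ------
    ValueError
        If no locus survives (advises relaxing thresholds).
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    p = allele_frequencies(gm)
    maf = np.minimum(p, 1 - p)
    keep = maf > maf_min
    n_maf = int((~keep).sum())
    n_miss = 0
    if not allow_missing:
        has_missing = (gm.G == MISSING).any(axis=0)
        n_miss = int((keep & has_missing).sum())
        keep &= ~has_missing
    if not keep.any():
        raise ValueError(
            "no locus passes QC; relax maf_min or allow missing genotypes"
        )
    report = {
        "n_input": gm.m,
        "dropped_maf": n_maf,
        "dropped_missing": n_miss,
        "n_retained": int(keep.sum()),
    }
    out = GenotypeMatrix(
        samples=gm.samples,
        variants=gm.variants.loc[keep].reset_index(drop=True),
        G=gm.G[:, keep],
    )
    return out, report


def standardize(
    gm: GenotypeMatrix, impute_missing: bool = False
) -> StandardizedMatrix:
    """Center and scale each locus: x~ = (x - 2p)/sqrt(2p(1-p)).

    Frequencies are always estimated in-sample from the provided cohort.
    Missing genotypes are rejected unless ``impute_missing`` is set, in
    which case they are mean-imputed (x~ = 0) with a warning — intended
    for exploratory runs only.

    Raises
    ------
    ValueError
        On a monomorphic locus (division by zero; names the locus) or
        on unexpected missing genotypes.
    """
    p = allele_frequencies(gm)
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        names = ", ".join(gm.variants["snp"].iloc[np.flatnonzero(mono)[:5]])
        raise ValueError(f"monomorphic locus (2pq = 0): {names}")
    missing = gm.G == MISSING
    if missing.any() and not impute_missing:
        raise ValueError(
            "missing genotypes present; run qc_filter(allow_missing=False) "
            "or pass impute_missing=True"
        )
    scale = np.sqrt(2.0 * p * (1.0 - p))
    X = (gm.G.astype(np.float64) - 2.0 * p) / scale
    if missing.any():
        import warnings

        warnings.warn(
            "mean-imputing missing genotypes (x~ = 0); estimates at "
            "imputed loci are shrunk toward unrelatedness",
            stacklevel=2,
        )
        X[missing] = 0.0
    return StandardizedMatrix(X=X, source=f"n={gm.n}, m={gm.m}")
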