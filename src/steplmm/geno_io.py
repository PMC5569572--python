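"""Genotype and phenotype I/O.

Supported genotype formats:

* PLINK 1 binary trio (``.bed``/``.bim``/``.fam``), SNP-major.
* VCF v4.x (biallelic SNPs; multiallelic records are skipped).
* Plain dosage TSV: header row of SNP ids, first column of sample ids,
  entries in {0, 1, 2} (``NA`` for missing).

Dosages count copies of the ALT (second) allele. MAF is ``min(p, 1-p)``
with ``p = mean(dosage)/2``; the model downstream is invariant to which
allele is counted, up to the sign of the estimated substitution effect.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -9  # internal code for a missing genotype

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "impute_missing",
    "filter_maf",
    "align_samples",
]


@dataclass
class GenotypeMatrix:
    """n_individuals x n_snps allele-dosage matrix plus per-SNP metadata.

    ``dosages`` holds ALT-allele counts in {0, 1, 2}; missing entries are
    coded :data:`MISSING` until :func:`impute_missing` runs. SNPs are kept
    sorted by (chrom, pos_bp) from load time onward.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: list[tuple[str, str]]
    sample_ids: list[str]
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if not (len(self.snp_ids) == len(self.pos_bp) == len(self.alleles) == m):
            raise ValueError("per-SNP metadata length does not match dosage columns")
        if self.maf is None:
            self.maf = compute_maf(self.dosages)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING).any())

    def alt_freq(self) -> np.ndarray:
        """Per-SNP ALT allele frequency p = mean(dosage)/2 (missing excluded)."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            alleles=[self.alleles[i] for i in idx],
            sample_ids=list(self.sample_ids),
            maf=self.maf[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        sub = GenotypeMatrix(
            dosages=self.dosages[idx, :],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos_bp=self.pos_bp,
            alleles=list(self.alleles),
            sample_ids=[self.sample_ids[i] for i in idx],
        )
        return sub

    def centered_dosages(self, snp_idx=None) -> np.ndarray:
        """Dosages centered by twice the ALT frequency (mean-zero coding)."""
        if snp_idx is None:
            snp_idx = np.arange(self.n_snps)
        snp_idx = np.atleast_1d(np.asarray(snp_idx))
        d = self.dosages[:, snp_idx].astype(float)
        p = d.mean(axis=0) / 2.0
        return d - 2.0 * p


@dataclass
class PhenotypeTable:
    """Phenotypes and fixed covariates, row-aligned to a GenotypeMatrix.

    ``X`` always carries an all-ones intercept as its first column.
    """

    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("y and X row counts differ")
        if not np.isfinite(self.y).all() or not np.isfinite(self.X).all():
            raise ValueError("missing or non-finite values in phenotypes/covariates")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate design X is rank deficient")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_beta(self) -> int:
        return self.X.shape[1]


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP, ignoring missing entries."""
    d = np.ma.masked_equal(dosages, MISSING)
    p = np.asarray(d.mean(axis=0) / 2.0)
    return np.minimum(p, 1.0 - p)


def _sort_by_position(G: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((G.pos_bp, np.asarray([str(c) for c in G.chrom])))
    if np.array_equal(order, np.arange(G.n_snps)):
        return G
    return G.take_snps(order)


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from PLINK bed / VCF / dosage TSV into a GenotypeMatrix.

    ``format`` is one of ``plink-bed``, ``vcf``, ``dosage-tsv``; when omitted
    it is inferred from the file suffix. Multiallelic VCF records are skipped
    with a logged count. The result is sorted by (chrom, pos_bp).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            format = "plink-bed"
        elif suffix in (".vcf", ".gz", ".bgz"):
            format = "vcf"
        else:
            format = "dosage-tsv"
    if format == "plink-bed":
        G = _read_plink_bed(path)
    elif format == "vcf":
        G = _read_vcf(path)
    elif format == "dosage-tsv":
        G = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    if G.n_snps == 0:
        raise ValueError(f"no biallelic SNPs parsed from {path}")
    return _sort_by_position(G)


def _read_plink_bed(path: Path) -> GenotypeMatrix:
    stem = path.with_suffix("")
    bim = pd.read_csv(
        stem.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        stem.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(path, dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise IOError(f"{path} is not a SNP-major PLINK .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size < m * bytes_per_snp:
        raise IOError(f"{path} truncated: expected {m * bytes_per_snp} body bytes")
    body = body[: m * bytes_per_snp].reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    # 00 -> 2 copies of A1 (alt), 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    dosages = lut[codes].T.astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=bim["snp_id"].tolist(),
        chrom=bim["chrom"].to_numpy(dtype=object),
        pos_bp=bim["pos"].to_numpy(),
        alleles=list(zip(bim["a2"], bim["a1"])),  # (ref, alt)
        sample_ids=fam["iid"].tolist(),
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosage_cols, snp_ids, chroms, poss, alleles = [], [], [], [], []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        gt = var.gt_types.astype(np.int8)  # 0/1/2 alt copies, 3 = missing
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        alleles.append((var.REF, var.ALT[0]))
    vcf.close()
    if n_multiallelic:
        logger.info("skipped %d multiallelic records in %s", n_multiallelic, path)
    if not dosage_cols:
        return GenotypeMatrix(
            np.empty((len(samples), 0), dtype=np.int8), [], np.array([], dtype=object),
            np.array([], dtype=np.int64), [], samples,
        )
    return GenotypeMatrix(
        dosages=np.column_stack(dosage_cols),
        snp_ids=snp_ids,
        chrom=np.asarray(chroms, dtype=object),
        pos_bp=np.asarray(poss, dtype=np.int64),
        alleles=alleles,
        sample_ids=samples,
    )


_ID_POS_RE = re.compile(r"^(?P<chrom>[\w.]+)[:_](?P<pos>\d+)$")


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    dosages = df.to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    snp_ids = [str(c) for c in df.columns]
    chroms, poss = [], []
    for i, sid in enumerate(snp_ids):
        m = _ID_POS_RE.match(sid)
        if m:
            chroms.append(m.group("chrom"))
            poss.append(int(m.group("pos")))
        else:
            chroms.append("1")
            poss.append(i + 1)
    return GenotypeMatrix(
        dosages=dosages,
        snp_ids=snp_ids,
        chrom=np.asarray(chroms, dtype=object),
        pos_bp=np.asarray(poss, dtype=np.int64),
        alleles=[("A", "B")] * len(snp_ids),
        sample_ids=[str(s) for s in df.index],
    )


# ---------------------------------------------------------------------------
# writers


def write_genotypes(G: GenotypeMatrix, prefix, format: str = "plink-bed") -> Path:
    """Write a GenotypeMatrix as a PLINK trio or dosage TSV; returns main path."""
    prefix = Path(prefix)
    if format == "plink-bed":
        return _write_plink_bed(G, prefix)
    if format == "dosage-tsv":
        path = prefix.with_suffix(".dosage.tsv")
        df = pd.DataFrame(
            np.where(G.dosages == MISSING, np.nan, G.dosages),
            index=pd.Index(G.sample_ids, name="sample_id"),
            columns=G.snp_ids,
        )
        df.to_csv(path, sep="\t", float_format="%.0f", na_rep="NA")
        return path
    raise ValueError(f"unsupported write format: {format!r}")


def _write_plink_bed(G: GenotypeMatrix, prefix: Path) -> Path:
    n, m = G.n_individuals, G.n_snps
    bim = pd.DataFrame(
        {
            "chrom": [str(c) for c in G.chrom],
            "snp_id": G.snp_ids,
            "cm": 0,
            "pos": G.pos_bp,
            "a1": [alt for _, alt in G.alleles],
            "a2": [ref for ref, _ in G.alleles],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": G.sample_ids, "iid": G.sample_ids, "f": 0, "m": 0, "sex": 0, "ph": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    # dosage -> 2-bit code: 2 -> 00, 1 -> 10, 0 -> 11, missing -> 01
    code = np.full((m, n), 3, dtype=np.uint8)
    d = G.dosages.T
    code[d == 2] = 0
    code[d == 1] = 2
    code[d == MISSING] = 1
    pad = (-n) % 4
    if pad:
        code = np.concatenate([code, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    code = code.reshape(m, -1, 4)
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (code << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    bed_path = prefix.with_suffix(".bed")
    with open(bed_path, "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.tobytes())
    return bed_path


# ---------------------------------------------------------------------------
# phenotype reading and alignment


def read_phenotypes(
    path,
    trait: str,
    covariates: list[str] | None = None,
    sample_col: str = "sample_id",
) -> PhenotypeTable:
    """Read a delimited phenotype/covariate table.

    Builds the fixed design X = [1 | covariates]; rows with a missing trait
    or covariate value are dropped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if sample_col not in df.columns:
        raise ValueError(f"column {sample_col!r} missing from {path}")
    if trait not in df.columns:
        raise ValueError(f"trait column {trait!r} missing from {path}")
    covariates = list(covariates or [])
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate column {c!r} missing from {path}")
    keep = df[[trait] + covariates].notna().all(axis=1)
    if (~keep).any():
        logger.warning("dropped %d samples with missing phenotype/covariates", int((~keep).sum()))
    df = df.loc[keep]
    n = len(df)
    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(dtype=float) for c in covariates])
    return PhenotypeTable(
        y=df[trait].to_numpy(dtype=float),
        X=X,
        covariate_names=["intercept"] + covariates,
        sample_ids=[str(s) for s in df[sample_col]],
    )


def align_samples(G: GenotypeMatrix, pheno: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Align genotypes and phenotypes on shared sample ids.

    Genotyped samples without a phenotype are dropped with a warning;
    a phenotyped sample without genotypes is an error.
    """
    geno_pos = {s: i for i, s in enumerate(G.sample_ids)}
    missing = [s for s in pheno.sample_ids if s not in geno_pos]
    if missing:
        raise ValueError(f"{len(missing)} phenotyped samples lack genotypes, e.g. {missing[:3]}")
    pheno_set = set(pheno.sample_ids)
    n_dropped = sum(1 for s in G.sample_ids if s not in pheno_set)
    if n_dropped:
        logger.warning("dropped %d genotyped samples without phenotypes", n_dropped)
    idx = np.array([geno_pos[s] for s in pheno.sample_ids])
    return G.take_samples(idx), pheno


# ---------------------------------------------------------------------------
# filters


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean rounded into {0, 1, 2}."""
    if not G.has_missing:
        return G
    d = G.dosages.astype(float)
    miss = d == MISSING
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = G.snp_ids[int(np.argmax(all_missing))]
        raise ValueError(f"SNP {bad!r} has no observed genotypes")
    masked = np.ma.masked_array(d, mask=miss)
    fill = np.clip(np.rint(masked.mean(axis=0)), 0, 2)
    d = np.where(miss, np.broadcast_to(fill, d.shape), d)
    return GenotypeMatrix(
        dosages=d.astype(np.int8),
        snp_ids=list(G.snp_ids),
        chrom=G.chrom,
        pos_bp=G.pos_bp,
        alleles=list(G.alleles),
        sample_ids=list(G.sample_ids),
    )


def filter_maf(G: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with MAF >= threshold (order preserved)."""
    keep = np.flatnonzero(G.maf >= threshold)
    if keep.size == 0:
        raise ValueError(f"no SNPs remain at MAF >= {threshold}")
    if keep.size == G.n_snps:
        return G
    return G.take_snps(keep)
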