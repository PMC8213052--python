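"""Genotype/phenotype input and quality control.

Genotypes are held as dosages of a designated reference allele Q
(0/1/2 copies, NaN for missing).  Two text dialects are supported:

* ``snp_major_tsv`` — header ``snp_id chrom pos alleleQ alleleq`` followed by
  one column per subject holding codes ``0/1/2/NA``;
* ``ped_map`` — PLINK text .ped/.map pair (alleles as letters, ``0 0`` missing).

QC follows a two-stage scheme: SNP filters on minor-allele frequency and
call rate, then phenotype outlier removal first by quartile fences and
second by standardized residuals from a full-model fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

COHORT_COLUMNS = ["subject_id", "sex", "ethnicity", "bsa", "walk", "exer", "read", "smoke", "trans"]
COFACTORS = ["walk", "exer", "read", "smoke", "trans"]


@dataclass
class SnpMeta:
    """Per-SNP metadata; ``maf``/``call_rate`` are computed from the calls."""

    snp_id: str
    chrom: int
    pos: int
    allele_Q: str
    allele_q: str
    maf: float = np.nan
    call_rate: float = np.nan

    @property
    def label(self) -> str:
        # "Chromosome-SNP-Alleles" identity format
        return f"{self.chrom}_{self.snp_id}_{self.allele_Q}/{self.allele_q}"


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix counting copies of the Q allele."""

    subjects: list[str]
    snps: list[SnpMeta]
    calls: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} snps"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0)) | (
            (self.calls >= 0) & (self.calls <= 2)
        )
        if not ok.all():
            raise ValueError("calls outside [0, 2]")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return [s.snp_id for s in self.snps].index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def subset_subjects(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        out = GenotypeMatrix(
            [s for s, keep in zip(self.subjects, mask) if keep],
            [replace(s) for s in self.snps],
            self.calls[mask],
        )
        _annotate_freq(out)
        return out


@dataclass
class QCReport:
    """Tally of rows/columns dropped by each QC rule.

    Conservation holds on both axes: in = out + sum of drops.
    """

    n_snps_in: int = 0
    n_snps_out: int = 0
    snps_dropped_maf: int = 0
    snps_dropped_callrate: int = 0
    n_subjects_in: int = 0
    n_subjects_out: int = 0
    subjects_dropped_iqr: int = 0
    subjects_dropped_residual: int = 0

    def validate(self) -> None:
        assert self.n_snps_in == self.n_snps_out + self.snps_dropped_maf + self.snps_dropped_callrate
        assert (
            self.n_subjects_in
            == self.n_subjects_out + self.subjects_dropped_iqr + self.subjects_dropped_residual
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _annotate_freq(g: GenotypeMatrix) -> None:
    """Recompute maf and call_rate in place from the call matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq_q = np.nanmean(g.calls, axis=0) / 2.0
    call_rate = 1.0 - np.isnan(g.calls).mean(axis=0)
    for j, s in enumerate(g.snps):
        fq = freq_q[j]
        s.maf = float(min(fq, 1.0 - fq)) if np.isfinite(fq) else np.nan
        s.call_rate = float(call_rate[j])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "snp_major_tsv") -> GenotypeMatrix:
    """Read a genotype file; ``dialect`` is ``snp_major_tsv`` or ``ped_map``.

    For ``ped_map``, ``path`` is the .ped file; the .map file with the same
    stem must sit next to it.  The first-listed allele of each SNP becomes Q.
    """
    if dialect == "snp_major_tsv":
        return _read_snp_major_tsv(path)
    if dialect == "ped_map":
        return _read_ped_map(path)
    raise ValueError(f"unknown dialect: {dialect}")


def _read_snp_major_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "chrom", "pos", "alleleQ", "alleleq"]
    if list(df.columns[:5]) != required:
        raise ValueError(f"{path}: header must start with {required}")
    subjects = list(df.columns[5:])
    snps, rows = [], []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        vals = rec[5:]
        row = np.full(len(subjects), np.nan)
        for k, v in enumerate(vals):
            if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("NA", "nan", ""):
                continue
            try:
                row[k] = float(v)
            except ValueError:
                raise ValueError(f"{path}: line {i}: bad genotype code {v!r}") from None
        try:
            snps.append(SnpMeta(rec.snp_id, int(rec.chrom), int(rec.pos), rec.alleleQ, rec.alleleq))
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {i}: malformed SNP metadata") from None
        rows.append(row)
    g = GenotypeMatrix(subjects, snps, np.array(rows).T if rows else np.empty((len(subjects), 0)))
    _annotate_freq(g)
    return g


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write ``snp_major_tsv``; integral dosages round-trip exactly."""
    data = {
        "snp_id": [s.snp_id for s in g.snps],
        "chrom": [s.chrom for s in g.snps],
        "pos": [s.pos for s in g.snps],
        "alleleQ": [s.allele_Q for s in g.snps],
        "alleleq": [s.allele_q for s in g.snps],
    }
    def fmt(v):
        if np.isnan(v):
            return "NA"
        return str(int(v)) if v == int(v) else repr(v)

    subj_cols = {
        subj: [fmt(v) for v in g.calls[k]] for k, subj in enumerate(g.subjects)
    }
    df = pd.concat([pd.DataFrame(data), pd.DataFrame(subj_cols)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def _read_ped_map(ped_path) -> GenotypeMatrix:
    import os

    map_path = os.path.splitext(str(ped_path))[0] + ".map"
    snps = []
    with open(map_path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}: line {i}: expected 4 fields")
            chrom, snp_id, _cm, pos = parts[:4]
            snps.append(SnpMeta(snp_id, int(chrom), int(pos), "", ""))
    subjects, geno_rows = [], []
    with open(ped_path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(snps):
                raise ValueError(f"{ped_path}: line {i}: expected {6 + 2 * len(snps)} fields")
            subjects.append(parts[1])  # within-family id
            geno_rows.append(parts[6:])
    calls = np.full((len(subjects), len(snps)), np.nan)
    for j, meta in enumerate(snps):
        # first non-missing allele encountered defines Q
        alleles: list[str] = []
        for row in geno_rows:
            for a in (row[2 * j], row[2 * j + 1]):
                if a != "0" and a not in alleles:
                    alleles.append(a)
        if len(alleles) > 2:
            raise ValueError(f"{ped_path}: SNP {meta.snp_id} has >2 alleles")
        q_allele = alleles[0] if alleles else "?"
        meta.allele_Q = q_allele
        meta.allele_q = alleles[1] if len(alleles) > 1 else "?"
        for k, row in enumerate(geno_rows):
            a1, a2 = row[2 * j], row[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue
            calls[k, j] = (a1 == q_allele) + (a2 == q_allele)
    g = GenotypeMatrix(subjects, snps, calls)
    _annotate_freq(g)
    return g


def read_cohort(path) -> pd.DataFrame:
    """Read the phenotype/covariate CSV (subject_id, sex, ethnicity, bsa, 5 cofactors)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    eth = df["ethnicity"].to_numpy()
    if not np.isin(eth, (1, 2, 3, 4)).all():
        raise ValueError(f"{path}: ethnicity codes must be in 1..4")
    return df


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_snps(
    g: GenotypeMatrix, maf_min: float = 0.05, call_rate_min: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with MAF below ``maf_min`` or call rate below ``call_rate_min``.

    A SNP failing both rules is tallied once, under MAF.
    """
    if not (0 <= maf_min <= 0.5 and 0 <= call_rate_min <= 1):
        raise ValueError("thresholds out of range")
    maf = np.array([s.maf for s in g.snps])
    cr = np.array([s.call_rate for s in g.snps])
    bad_maf = ~(maf >= maf_min)  # NaN maf (all-missing SNP) fails too
    bad_cr = (cr < call_rate_min) & ~bad_maf
    keep = ~(bad_maf | bad_cr)
    rep = QCReport(
        n_snps_in=g.n_snps,
        n_snps_out=int(keep.sum()),
        snps_dropped_maf=int(bad_maf.sum()),
        snps_dropped_callrate=int(bad_cr.sum()),
    )
    if rep.n_snps_out == 0:
        warnings.warn("all SNPs removed by QC filters")
    out = GenotypeMatrix(
        list(g.subjects), [replace(s) for s, k in zip(g.snps, keep) if k], g.calls[:, keep]
    )
    _annotate_freq(out)
    return out, rep


def filter_phenotype_outliers_iqr(y, upper_anchor: str = "q2") -> np.ndarray:
    """Quartile-fence outlier mask: keep Q1 − 1.5·IQR ≤ y ≤ anchor + 1.5·IQR.

    The upper fence is anchored at the median (Q2) by default, matching the
    source procedure as printed; pass ``upper_anchor="q3"`` for the
    conventional Tukey fence.  Quantiles use linear (type-7) interpolation.
    Missing values are retained by the mask (they carry no outlier evidence).
    """
    y = np.asarray(y, dtype=float)
    obs = y[~np.isnan(y)]
    if obs.size == 0:
        raise ValueError("all phenotype values missing")
    if obs.size < 4:
        raise ValueError("need at least 4 non-missing values for quartiles")
    q1, q2, q3 = np.quantile(obs, [0.25, 0.50, 0.75])
    iqr = q3 - q1
    anchor = {"q2": q2, "q3": q3}[upper_anchor]
    lo, hi = q1 - 1.5 * iqr, anchor + 1.5 * iqr
    with np.errstate(invalid="ignore"):
        out = (y > hi) | (y < lo)
    return ~out


def filter_residual_outliers(y, design, cutoff: float = 3.0) -> np.ndarray:
    """Standardized-residual mask: fit the full model once, drop |ε − μ|/σ > cutoff.

    ``design`` is a DesignBundle (its fixed and random columns are both used
    in the fit).  Runs exactly once; a zero residual spread keeps everyone.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("residual filter requires a complete phenotype vector")
    W = design.full_matrix()
    beta, *_ = np.linalg.lstsq(W, y, rcond=None)
    eps = y - W @ beta
    sd = eps.std()
    if sd <= 1e-10 * (np.abs(y).mean() + 1.0):  # exact fit up to round-off
        warnings.warn("degenerate residual spread; no subjects masked")
        return np.ones_like(y, dtype=bool)
    z = np.abs(eps - eps.mean()) / sd
    return z <= cutoff


def impute_missing(g: GenotypeMatrix, ethnicity: np.ndarray | None = None) -> GenotypeMatrix:
    """Mean-impute missing dosages per SNP (within ethnic group when given)."""
    calls = g.calls.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nanmean(calls, axis=0)
        if ethnicity is None:
            fill = np.broadcast_to(overall, calls.shape)
        else:
            ethnicity = np.asarray(ethnicity)
            fill = np.empty_like(calls)
            for h in np.unique(ethnicity):
                rows = ethnicity == h
                gmean = np.nanmean(calls[rows], axis=0)
                gmean = np.where(np.isnan(gmean), overall, gmean)
                fill[rows] = gmean
    calls = np.where(np.isnan(calls), fill, calls)
    out = GenotypeMatrix(list(g.subjects), [replace(s) for s in g.snps], calls)
    _annotate_freq(out)
    return out
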