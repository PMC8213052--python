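"""Genome scan with permutation-derived experiment-wise significance.

Single-locus scan: each SNP is tested jointly over its additive and
dominance effects plus their ethnicity interactions.  Pairwise scan: each
candidate pair is tested jointly over the four digenic epistasis codings and
their sixteen group incidences, with both loci's marginal terms in the
background model.

Experiment-wise control follows the permutation scheme: the phenotype is
shuffled within sex x ethnicity strata, the scan maximum F is recorded per
permutation, and the critical F is the empirical (1 - alpha) quantile.
P_EW uses the add-one estimator (1 + #{draws >= f}) / (n_perm + 1).

The heavy lifting is a shared engine: per scan unit an orthonormal extension
of the background basis and an orthonormal basis of the tested block are
precomputed once, after which each (possibly permuted) phenotype costs one
matrix product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .encoding import (
    ETHNIC_GROUPS,
    LocusCoding,
    code_locus,
    code_pair,
    locus_term_labels,
    pair_term_labels,
)
from .io_qc import GenotypeMatrix
from .mixed_model import FResult, orthonormal_basis

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 2000
DEFAULT_ALPHA = 0.05


@dataclass
class ScanResult:
    unit: str                      # snp_id or "snp_i:snp_j"
    f: FResult
    neg_log10_p_ew: float | None = None
    selected: bool = False


@dataclass
class PermutationNull:
    n_perm: int
    max_stat_draws: np.ndarray
    alpha: float
    seed: int

    @property
    def critical_f(self) -> float:
        return float(np.quantile(self.max_stat_draws, 1.0 - self.alpha))

    def p_ew(self, f: float) -> float:
        return (1.0 + int(np.sum(self.max_stat_draws >= f))) / (self.n_perm + 1.0)

    def neg_log10_p_ew(self, f: float) -> float:
        return float(-np.log10(self.p_ew(f)))


@dataclass
class _ScanUnit:
    unit: str
    term_set: list[str]
    bg_ext: np.ndarray   # orthonormal extension of the shared background
    tested: np.ndarray   # orthonormal tested block, orthogonal to background+ext


def _shared_background(cohort, cofactor: str | None) -> np.ndarray:
    cols = [np.ones(len(cohort)), cohort["sex"].to_numpy(dtype=float)]
    if cofactor is not None:
        c = cohort[cofactor].to_numpy(dtype=float)
        if np.isnan(c).any():
            raise ValueError(f"cofactor {cofactor!r} has missing values")
        cols.append(c)
    eth = cohort["ethnicity"].to_numpy()
    for h in ETHNIC_GROUPS:
        cols.append((eth == h).astype(float))
    return orthonormal_basis(np.column_stack(cols))


def _locus_block(coding: LocusCoding, eth: np.ndarray) -> np.ndarray:
    cols = [coding.xA, coding.xD]
    for base in (coding.xA, coding.xD):
        for h in ETHNIC_GROUPS:
            cols.append(base * (eth == h))
    return np.column_stack(cols)


def _pair_blocks(ci: LocusCoding, cj: LocusCoding, eth: np.ndarray):
    """(marginal background block, tested epistasis block) for a pair."""
    marg = np.hstack([_locus_block(ci, eth), _locus_block(cj, eth)])
    pc = code_pair(ci, cj)
    cols = [pc.xAA, pc.xAD, pc.xDA, pc.xDD]
    for base in (pc.xAA, pc.xAD, pc.xDA, pc.xDD):
        for h in ETHNIC_GROUPS:
            cols.append(base * (eth == h))
    return marg, np.column_stack(cols)


def _units_1d(g: GenotypeMatrix, cohort, QB: np.ndarray) -> list[_ScanUnit]:
    eth = cohort["ethnicity"].to_numpy()
    n = len(cohort)
    units = []
    for meta in g.snps:
        coding = code_locus(g, meta.snp_id)
        tested = orthonormal_basis(_locus_block(coding, eth), against=QB)
        if tested.shape[1] == 0:
            log.info("skipping monomorphic/aliased SNP %s", meta.snp_id)
            continue
        units.append(
            _ScanUnit(meta.snp_id, locus_term_labels(meta.snp_id), np.empty((n, 0)), tested)
        )
    return units


def _units_2d(g: GenotypeMatrix, cohort, candidates, QB: np.ndarray) -> list[_ScanUnit]:
    eth = cohort["ethnicity"].to_numpy()
    codings = {s: code_locus(g, s) for s in candidates}
    units = []
    for si, sj in combinations(sorted(candidates, key=g.snp_index), 2):
        marg, epi = _pair_blocks(codings[si], codings[sj], eth)
        M = orthonormal_basis(marg, against=QB)
        QBM = np.hstack([QB, M])
        tested = orthonormal_basis(epi, against=QBM)
        if tested.shape[1] == 0:
            log.info("skipping pair %s:%s (epistasis aliased with marginals)", si, sj)
            continue
        units.append(_ScanUnit(f"{si}:{sj}", pair_term_labels(f"{si}:{sj}"), M, tested))
    return units


def _engine(QB: np.ndarray, units: list[_ScanUnit], Y: np.ndarray):
    """Joint F per unit (rows) per phenotype column of ``Y`` (columns)."""
    n = Y.shape[0]
    yty = np.einsum("ij,ij->j", Y, Y)
    rb = np.einsum("ij,ij->j", QB.T @ Y, QB.T @ Y) if QB.shape[1] else np.zeros(Y.shape[1])
    n_units = len(units)
    F = np.empty((n_units, Y.shape[1]))
    df1 = np.empty(n_units, dtype=int)
    df2 = np.empty(n_units, dtype=int)
    if n_units == 0:
        return F, df1, df2
    # stack all per-unit blocks for one GEMM each
    ext_stack = np.hstack([u.bg_ext for u in units]) if any(u.bg_ext.shape[1] for u in units) else None
    tst_stack = np.hstack([u.tested for u in units])
    PT = tst_stack.T @ Y
    PT2 = PT * PT
    if ext_stack is not None:
        PE = ext_stack.T @ Y
        PE2 = PE * PE
    t_off = e_off = 0
    for i, u in enumerate(units):
        r_t = u.tested.shape[1]
        r_e = u.bg_ext.shape[1]
        extra = PT2[t_off : t_off + r_t].sum(axis=0)
        ext_ss = PE2[e_off : e_off + r_e].sum(axis=0) if r_e else 0.0
        rank_full = QB.shape[1] + r_e + r_t
        sse = yty - rb - ext_ss - extra
        df1[i] = r_t
        df2[i] = n - rank_full
        with np.errstate(divide="ignore", invalid="ignore"):
            F[i] = (extra / r_t) / (sse / df2[i])
        t_off += r_t
        e_off += r_e
    return F, df1, df2


def _results_from_engine(units, F, df1, df2) -> list[ScanResult]:
    out = []
    for i, u in enumerate(units):
        f = float(F[i, 0])
        p = float(stats.f.sf(f, int(df1[i]), int(df2[i])))
        out.append(ScanResult(u.unit, FResult(f, int(df1[i]), int(df2[i]), p, u.term_set)))
    return out


def scan_1d(g: GenotypeMatrix, cohort, cofactor: str | None = None, y=None) -> list[ScanResult]:
    """Joint single-locus scan over all SNPs in ``g``."""
    if g.n_snps == 0:
        return []
    y = cohort["bsa"].to_numpy(dtype=float) if y is None else np.asarray(y, dtype=float)
    QB = _shared_background(cohort, cofactor)
    units = _units_1d(g, cohort, QB)
    F, df1, df2 = _engine(QB, units, y[:, None])
    return _results_from_engine(units, F, df1, df2)


def scan_2d(
    g: GenotypeMatrix, cohort, candidates, cofactor: str | None = None, y=None
) -> list[ScanResult]:
    """Joint epistasis scan over all unordered pairs of ``candidates``."""
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate SNPs for the pairwise scan")
    y = cohort["bsa"].to_numpy(dtype=float) if y is None else np.asarray(y, dtype=float)
    QB = _shared_background(cohort, cofactor)
    units = _units_2d(g, cohort, candidates, QB)
    F, df1, df2 = _engine(QB, units, y[:, None])
    return _results_from_engine(units, F, df1, df2)


def preselect_candidates(
    results: list[ScanResult], liberal_alpha: float = 1e-3, max_candidates: int = 200
) -> list[str]:
    """Liberal pointwise preselection for the pairwise stage: smallest-p SNPs."""
    if not results:
        raise ValueError("empty scan results")
    passing = [r for r in results if r.f.p_nominal <= liberal_alpha]
    passing.sort(key=lambda r: -r.f.f_value)
    return [r.unit for r in passing[:max_candidates]]


def stratified_permutations(cohort, n_perm: int, rng) -> np.ndarray:
    """(n, n_perm) index matrix permuting subjects within sex x ethnicity strata."""
    sex = cohort["sex"].to_numpy()
    eth = cohort["ethnicity"].to_numpy()
    n = len(cohort)
    idx = np.empty((n, n_perm), dtype=np.intp)
    for s in np.unique(sex):
        for h in np.unique(eth):
            rows = np.flatnonzero((sex == s) & (eth == h))
            if rows.size == 0:
                continue
            order = np.argsort(rng.random((rows.size, n_perm)), axis=0)
            idx[rows] = rows[order]
    return idx


def permutation_threshold(
    g: GenotypeMatrix,
    cohort,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    cofactor: str | None = None,
    mode: str = "1d",
    candidates=None,
    y=None,
    batch: int = 256,
) -> PermutationNull:
    """Permutation null of the scan maximum F.

    ``mode`` selects the scan statistic: ``"1d"`` (all SNPs) or ``"2d"``
    (pairs of ``candidates``).  Phenotypes are shuffled within
    sex x ethnicity strata so the block/random structure of the null model
    is preserved.
    """
    if n_perm < 100:
        raise ValueError("n_perm below 100 makes the critical quantile unstable")
    y = cohort["bsa"].to_numpy(dtype=float) if y is None else np.asarray(y, dtype=float)
    QB = _shared_background(cohort, cofactor)
    if mode == "1d":
        units = _units_1d(g, cohort, QB)
    elif mode == "2d":
        units = _units_2d(g, cohort, list(candidates), QB)
    else:
        raise ValueError(f"unknown mode: {mode}")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        idx = stratified_permutations(cohort, m, rng)
        F, _, _ = _engine(QB, units, y[idx])
        draws[done : done + m] = F.max(axis=0)
        done += m
    return PermutationNull(n_perm=n_perm, max_stat_draws=draws, alpha=alpha, seed=seed)


def assign_experimentwise(
    results: list[ScanResult], null: PermutationNull, threshold: float | None = None
) -> list[ScanResult]:
    """Attach -log10 P_EW to each result and mark selections.

    ``threshold`` is on the -log10 P_EW scale; defaults to the alpha of the
    permutation null (selected iff P_EW < alpha, i.e. F > critical F).
    """
    for r in results:
        r.neg_log10_p_ew = null.neg_log10_p_ew(r.f.f_value)
        if threshold is None:
            r.selected = null.p_ew(r.f.f_value) < null.alpha
        else:
            r.selected = r.neg_log10_p_ew > threshold
    return results
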