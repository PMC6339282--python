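"""Pairwise linkage disequilibrium from unphased diploid genotypes.

Two-locus haplotype frequencies are estimated by expectation-maximization:
every genotype class except the double heterozygote contributes gametes of
known phase; the double heterozygote splits its two gametes between the
coupling (AB/ab) and repulsion (Ab/aB) configurations in proportion to the
current frequency estimates.  The log-likelihood is non-decreasing across
iterations.  From the haplotype frequencies the standard statistics follow:

    D   = f_AB - p_A p_B
    D'  = |D| / Dmax,  Dmax = min(p_A q_B, q_A p_B) if D > 0
                              else min(p_A p_B, q_A q_B)
    R^2 = D^2 / (p_A q_A p_B q_B)

and a goodness-of-fit chi-square X^2 = R^2 * n over n chromosomes, tested at
one degree of freedom (the LDpair convention).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_model import CohortGenotypes, MISSING, VariantDef

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class MonomorphicLocusError(ValueError):
    """LD statistics are undefined when a locus is fixed."""


@dataclass(frozen=True)
class TwoLocusHaplotypeFreqs:
    """Frequencies of the four two-locus gametes (A/a = ref/alt at locus 1)."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    source: str = "observed-phased"      # or "em-estimated"
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = float("nan")

    def __post_init__(self):
        vals = (self.f_AB, self.f_Ab, self.f_aB, self.f_ab)
        if min(vals) < -1e-12:
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def p_A(self) -> float:
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        return self.f_AB + self.f_aB


@dataclass(frozen=True)
class LDStats:
    D: float
    D_prime: float
    R2: float
    chi2: float
    p_value: float
    n_chromosomes: int


def ld_from_haplotypes(freqs: TwoLocusHaplotypeFreqs, n_chromosomes: int) -> LDStats:
    """LD statistics from two-locus haplotype frequencies."""
    pA, pB = freqs.p_A, freqs.p_B
    qA, qB = 1.0 - pA, 1.0 - pB
    if min(pA, qA, pB, qB) <= 0:
        raise MonomorphicLocusError("LD undefined: a locus is monomorphic")
    D = freqs.f_AB - pA * pB
    dmax = min(pA * qB, qA * pB) if D > 0 else min(pA * pB, qA * qB)
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * qA * pB * qB)
    chi2 = r2 * n_chromosomes
    return LDStats(D, d_prime, r2, chi2, float(stats.chi2.sf(chi2, df=1)),
                   n_chromosomes)


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype table under haplotype
    frequencies f = (f_AB, f_Ab, f_aB, f_ab) with random gamete union."""
    fAB, fAb, faB, fab = f
    # P(genotype class) at (row = alt dose at locus 1, col = alt dose at locus 2)
    probs = np.array([
        [fAB * fAB, 2 * fAB * fAb, fAb * fAb],
        [2 * fAB * faB, 2 * (fAB * fab + fAb * faB), 2 * fAb * fab],
        [faB * faB, 2 * faB * fab, fab * fab],
    ])
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float((counts * logp).sum())


def em_haplotype_freqs(
    counts: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> TwoLocusHaplotypeFreqs:
    """EM estimate of two-locus haplotype frequencies from a 3x3 genotype
    table (rows: alt dose at locus 1; columns: alt dose at locus 2).

    EM is restarted from three deterministic initial conditions — linkage
    equilibrium at the observed allele frequencies, all double heterozygotes
    in coupling phase, and all in repulsion phase — and the run with the
    highest log-likelihood wins (ties go to the equilibrium start).  The
    likelihood of this model can have two local maxima, and on small tables
    the equilibrium point is occasionally itself a stationary saddle, so a
    single start can stall.  Non-convergence at ``max_iter`` is flagged on
    the result, not raised.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3) or counts.min() < 0:
        raise ValueError("counts must be a non-negative 3x3 table")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty genotype table")

    n_chrom = 2.0 * total
    alt1 = (counts * np.array([0, 1, 2])[:, None]).sum() / n_chrom
    alt2 = (counts * np.array([0, 1, 2])[None, :]).sum() / n_chrom
    pA, pB = 1.0 - alt1, 1.0 - alt2   # ref-allele frequencies

    # phase-known haplotype counts per genotype cell: cell (i,j) contributes
    # gametes (A or a at locus1 per dose, B or b at locus2), except (1,1)
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            if c == 0:
                continue
            # with at most one heterozygous locus the gamete pairing is unique
            if i == 1:      # A a with locus2 homozygous
                base[0 if j == 0 else 1] += c       # A with B or b
                base[2 if j == 0 else 3] += c       # a with B or b
            elif j == 1:    # B b with locus1 homozygous
                base[0 if i == 0 else 2] += c
                base[1 if i == 0 else 3] += c
            else:
                idx = (0 if i == 0 else 2) + (0 if j == 0 else 1)
                base[idx] += 2 * c

    dh = counts[1, 1]

    def run(f0: np.ndarray) -> tuple[np.ndarray, float, bool, int]:
        f = f0
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # E-step: split double heterozygotes between coupling/repulsion
            num_coupling = f[0] * f[3]
            num_repulsion = f[1] * f[2]
            denom = num_coupling + num_repulsion
            w = 0.5 if denom <= 0 else num_coupling / denom
            expect = base.copy()
            expect[0] += dh * w
            expect[3] += dh * w
            expect[1] += dh * (1 - w)
            expect[2] += dh * (1 - w)
            # M-step
            f = expect / n_chrom
            ll = _loglik(counts, f)
            if abs(ll - prev_ll) < tol:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        return f, prev_ll, converged, it

    equilibrium = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB,
                            (1 - pA) * (1 - pB)])
    equilibrium = np.maximum(equilibrium, 0.0)
    equilibrium /= equilibrium.sum()
    starts = [equilibrium]
    if dh > 0:
        for w0 in (1.0, 0.0):
            f0 = base.copy()
            f0[0] += dh * w0
            f0[3] += dh * w0
            f0[1] += dh * (1 - w0)
            f0[2] += dh * (1 - w0)
            starts.append(f0 / n_chrom)

    best = None
    for f0 in starts:
        result = run(f0)
        if best is None or result[1] > best[1] + 1e-12:
            best = result
    f, ll, converged, it = best
    return TwoLocusHaplotypeFreqs(*[float(x) for x in f], source="em-estimated",
                                  converged=converged, n_iter=it,
                                  log_likelihood=ll)


def two_locus_genotype_table(
    cohort: CohortGenotypes, v1: VariantDef, v2: VariantDef
) -> tuple[np.ndarray, int]:
    """3x3 genotype table over samples non-missing at both loci; returns the
    table and the number of complete samples."""
    c1, c2 = cohort.column(v1), cohort.column(v2)
    keep = (c1 != MISSING) & (c2 != MISSING)
    table = np.zeros((3, 3), dtype=int)
    for i, j in zip(c1[keep], c2[keep]):
        table[i, j] += 1
    return table, int(keep.sum())


def ld_pair(cohort: CohortGenotypes, v1: VariantDef, v2: VariantDef) -> LDStats:
    """EM-phased LD statistics for one variant pair."""
    table, n = two_locus_genotype_table(cohort, v1, v2)
    freqs = em_haplotype_freqs(table)
    return ld_from_haplotypes(freqs, 2 * n)


def ld_matrix(cohort: CohortGenotypes, gene: str) -> pd.DataFrame:
    """All pairwise LD statistics for a gene's polymorphic variants.

    Returns a long-format symmetric table with columns variant1, variant2,
    D, Dprime, R2, chi2, p, n_chrom.
    """
    variants = []
    for v in cohort.variants_for_gene(gene):
        col = cohort.column(v)
        col = col[col != MISSING]
        if col.size and 0 < col.sum() < 2 * col.size:
            variants.append(v)
    if len(variants) < 2:
        raise ValueError(f"{gene}: need >= 2 polymorphic variants for LD")
    rows = []
    for v1, v2 in itertools.combinations(variants, 2):
        s = ld_pair(cohort, v1, v2)
        for a, b in ((v1, v2), (v2, v1)):
            rows.append({
                "variant1": a.label or a.variant_id,
                "variant2": b.label or b.variant_id,
                "D": s.D, "Dprime": s.D_prime, "R2": s.R2,
                "chi2": s.chi2, "p": s.p_value, "n_chrom": s.n_chromosomes,
            })
    for v in variants:
        rows.append({"variant1": v.label or v.variant_id,
                     "variant2": v.label or v.variant_id,
                     "D": 0.0, "Dprime": 1.0, "R2": 1.0,
                     "chi2": float("nan"), "p": float("nan"),
                     "n_chrom": 0})
    return pd.DataFrame(rows)
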