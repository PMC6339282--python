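"""Independent reference implementations used to check the package.

Everything here is deliberately naive (enumeration, direct counting,
closed forms) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support:
    sum point probabilities of every table with the observed margins that is
    no more probable than the observed one."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(x: int) -> float:
        # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = point(a)
    return sum(p for x in range(lo, hi + 1)
               if (p := point(x)) <= p_obs * (1 + 1e-12))


def chi2_cellwise(a: int, b: int, c: int, d: int) -> float:
    """Pearson statistic computed cell by cell from expected counts."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(((obs - exp) ** 2 / exp).sum())


def hwe_chi2_algebraic(n_rr: int, n_ra: int, n_aa: int) -> float:
    """HWE chi-square via the homozygote-excess closed form
    X^2 = n D^2 / (p q)^2 with D = n_rr/n - p^2."""
    n = n_rr + n_ra + n_aa
    p = (2 * n_rr + n_ra) / (2 * n)
    q = 1 - p
    dev = n_rr / n - p * p
    return n * dev * dev / (p * q) ** 2


def two_locus_loglik(table: np.ndarray, f_ab_ref: float, p_a: float, p_b: float) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table given the
    ref-ref haplotype frequency and the two ref-allele frequencies."""
    f = np.array([
        f_ab_ref,
        p_a - f_ab_ref,
        p_b - f_ab_ref,
        1 - p_a - p_b + f_ab_ref,
    ])
    if f.min() < -1e-12:
        return -np.inf
    f = np.maximum(f, 1e-300)
    fAB, fAb, faB, fab = f
    # rows: alt dose at locus 1 (A/a = ref/alt); cols: alt dose at locus 2
    probs = np.array([
        [fAB ** 2, 2 * fAB * fAb, fAb ** 2],
        [2 * fAB * faB, 2 * (fAB * fab + fAb * faB), 2 * fAb * fab],
        [faB ** 2, 2 * faB * fab, fab ** 2],
    ])
    t = np.asarray(table, dtype=float)
    return float((t * np.log(np.maximum(probs, 1e-300))).sum())


def grid_mle_f_ab(table: np.ndarray, resolution: float = 1e-3) -> float:
    """Exhaustive grid search for the MLE ref-ref haplotype frequency."""
    t = np.asarray(table, dtype=float)
    two_n = 2 * t.sum()
    alt1 = (t * np.array([0, 1, 2])[:, None]).sum() / two_n
    alt2 = (t * np.array([0, 1, 2])[None, :]).sum() / two_n
    p_a, p_b = 1 - alt1, 1 - alt2
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.arange(lo, hi + resolution / 2, resolution)
    lls = [two_locus_loglik(t, f, p_a, p_b) for f in grid]
    return float(grid[int(np.argmax(lls))])
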