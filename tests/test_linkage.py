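"""Two-locus LD statistics and EM haplotype-frequency estimation."""

import numpy as np
import pytest

from a3pop import synthetic_data as sd
from a3pop.linkage import (
    MonomorphicLocusError, TwoLocusHaplotypeFreqs, em_haplotype_freqs,
    ld_from_haplotypes, ld_matrix, ld_pair, two_locus_genotype_table,
)

from .oracles import grid_mle_f_ab


# ---------------------------------------------------------------------------
# ld_from_haplotypes
# ---------------------------------------------------------------------------

def test_independence_gives_zero_ld():
    f = TwoLocusHaplotypeFreqs(0.25, 0.25, 0.25, 0.25)
    s = ld_from_haplotypes(f, 200)
    assert s.D == pytest.approx(0.0)
    assert s.R2 == pytest.approx(0.0)
    assert s.chi2 == pytest.approx(0.0)


def test_perfect_coupling():
    f = TwoLocusHaplotypeFreqs(0.5, 0.0, 0.0, 0.5)
    s = ld_from_haplotypes(f, 100)
    assert s.D_prime == pytest.approx(1.0)
    assert s.R2 == pytest.approx(1.0)
    assert s.chi2 == pytest.approx(100.0)


def test_dprime_one_with_partial_r2():
    # one missing gamete class: D' = 1 but R^2 < 1
    f = TwoLocusHaplotypeFreqs(0.7, 0.0, 0.2, 0.1)
    s = ld_from_haplotypes(f, 100)
    assert s.D_prime == pytest.approx(1.0)
    assert 0 < s.R2 < 1


def test_monomorphic_locus_rejected():
    f = TwoLocusHaplotypeFreqs(0.5, 0.5, 0.0, 0.0)
    with pytest.raises(MonomorphicLocusError):
        ld_from_haplotypes(f, 100)


def test_r2_is_indicator_correlation():
    """R^2 equals the squared correlation of allele indicators, checked by a
    sampling oracle at large n."""
    rng = np.random.default_rng(19)
    for _ in range(5):
        f = rng.dirichlet([2, 2, 2, 2])
        freqs = TwoLocusHaplotypeFreqs(*f)
        if min(freqs.p_A, 1 - freqs.p_A, freqs.p_B, 1 - freqs.p_B) < 0.05:
            continue
        s = ld_from_haplotypes(freqs, 1000)
        haps = rng.choice(4, size=400_000, p=f)
        x = np.isin(haps, (0, 1)).astype(float)   # A allele at locus 1
        y = np.isin(haps, (0, 2)).astype(float)   # B allele at locus 2
        r2_mc = np.corrcoef(x, y)[0, 1] ** 2
        assert s.R2 == pytest.approx(r2_mc, abs=1e-2)


def test_ld_invariant_under_allele_relabeling():
    f = TwoLocusHaplotypeFreqs(0.5, 0.2, 0.1, 0.2)
    s = ld_from_haplotypes(f, 100)
    # swap alleles at locus 1: (AB, Ab, aB, ab) -> (aB, ab, AB, Ab)
    s1 = ld_from_haplotypes(TwoLocusHaplotypeFreqs(0.1, 0.2, 0.5, 0.2), 100)
    # swap alleles at locus 2
    s2 = ld_from_haplotypes(TwoLocusHaplotypeFreqs(0.2, 0.5, 0.2, 0.1), 100)
    for other in (s1, s2):
        assert other.D_prime == pytest.approx(s.D_prime)
        assert other.R2 == pytest.approx(s.R2)


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------

def test_em_without_double_hets_is_direct_counting():
    table = np.array([[12, 3, 0], [4, 0, 1], [0, 2, 8]])
    f = em_haplotype_freqs(table)
    # count gametes directly: every cell except (1,1) has known phase
    n_chrom = 2 * table.sum()
    counts = np.zeros(4)
    for i in range(3):
        for j in range(3):
            c = table[i, j]
            if i == 1:
                counts[0 if j == 0 else 1] += c
                counts[2 if j == 0 else 3] += c
            elif j == 1:
                counts[0 if i == 0 else 2] += c
                counts[1 if i == 0 else 3] += c
            else:
                counts[(0 if i == 0 else 2) + (0 if j == 0 else 1)] += 2 * c
    expected = counts / n_chrom
    assert np.allclose([f.f_AB, f.f_Ab, f.f_aB, f.f_ab], expected, atol=1e-9)
    assert f.converged


def test_em_symmetric_double_hets_resolved_deterministically():
    """An all-double-heterozygote table has two exactly tied maximum-
    likelihood families (full coupling and full repulsion), each with higher
    likelihood than the linkage-equilibrium stationary point; the
    deterministic multistart always returns the coupling family."""
    table = np.zeros((3, 3), dtype=int)
    table[1, 1] = 10
    f = em_haplotype_freqs(table)
    assert f.f_AB == pytest.approx(0.5)
    assert f.f_ab == pytest.approx(0.5)
    assert f.f_Ab == pytest.approx(0.0)
    # equal margins: the result is a valid frequency vector with 0.5/0.5 alleles
    assert f.p_A == pytest.approx(0.5) and f.p_B == pytest.approx(0.5)
    # rerunning gives the identical tie-break
    g = em_haplotype_freqs(table)
    assert (g.f_AB, g.f_Ab, g.f_aB, g.f_ab) == (f.f_AB, f.f_Ab, f.f_aB, f.f_ab)


def test_em_loglikelihood_nondecreasing():
    table = np.array([[5, 2, 1], [3, 6, 2], [0, 3, 4]])
    lls = [em_haplotype_freqs(table, tol=0.0, max_iter=k).log_likelihood
           for k in range(1, 25)]
    assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))


def test_em_matches_grid_search_on_small_tables():
    """On tables with <= 8 individuals the EM solution attains the same
    likelihood as an exhaustive 1e-3 grid over the free haplotype frequency.
    (Tiny tables can have two exactly tied optima, so the comparison is on
    the achieved likelihood, not the parameter.)"""
    from .oracles import two_locus_loglik

    rng = np.random.default_rng(23)
    checked = 0
    while checked < 15:
        table = rng.multinomial(rng.integers(2, 9), np.ones(9) / 9).reshape(3, 3)
        two_n = 2 * table.sum()
        alt1 = (table * np.array([0, 1, 2])[:, None]).sum() / two_n
        alt2 = (table * np.array([0, 1, 2])[None, :]).sum() / two_n
        if min(alt1, 1 - alt1, alt2, 1 - alt2) == 0:
            continue
        est = em_haplotype_freqs(table)
        p_a, p_b = 1 - alt1, 1 - alt2
        ll_em = two_locus_loglik(table, est.f_AB, p_a, p_b)
        ll_grid = two_locus_loglik(table, grid_mle_f_ab(table), p_a, p_b)
        assert ll_em >= ll_grid - 1e-3
        checked += 1


def test_em_recovers_simulated_truth_within_3_se():
    n = 2000
    p_a, p_b, d = 0.6, 0.7, 0.08
    table, hap_counts = sd.simulate_two_locus(p_a, p_b, d, n, seed=101)
    est = em_haplotype_freqs(table)
    true_f = p_a * p_b + d
    se = np.sqrt(true_f * (1 - true_f) / (2 * n))
    assert abs(est.f_AB - true_f) <= 3 * se


def test_em_null_r2_small():
    """With D = 0, EM-estimated R^2 stays below 0.01 in >= 95% of replicates
    at n = 2000."""
    ok = 0
    for rep in range(100):
        table, _ = sd.simulate_two_locus(0.6, 0.4, 0.0, 2000, seed=500 + rep)
        f = em_haplotype_freqs(table)
        s = ld_from_haplotypes(f, 2 * table.sum())
        ok += s.R2 < 0.01
    assert ok >= 95


def test_em_rejects_bad_tables():
    with pytest.raises(ValueError):
        em_haplotype_freqs(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        em_haplotype_freqs(np.ones((2, 2)))


def test_em_r2_close_to_true_phase_r2():
    """EM-phased R^2 tracks the true-phase R^2 within 0.02 at n = 2000 and
    MAF >= 0.1 (100 replicates)."""
    worst = 0.0
    for rep in range(100):
        table, hap_counts = sd.simulate_two_locus(0.7, 0.6, 0.05, 2000, seed=900 + rep)
        n_chrom = hap_counts.sum()
        f_true = hap_counts / n_chrom
        if min(f_true[0] + f_true[1], f_true[2] + f_true[3],
               f_true[0] + f_true[2], f_true[1] + f_true[3]) < 0.1:
            continue
        s_true = ld_from_haplotypes(TwoLocusHaplotypeFreqs(*f_true, source="observed-phased"), n_chrom)
        s_em = ld_from_haplotypes(em_haplotype_freqs(table), n_chrom)
        worst = max(worst, abs(s_true.R2 - s_em.R2))
    assert worst <= 0.02


# ---------------------------------------------------------------------------
# Cohort-level LD matrix
# ---------------------------------------------------------------------------

def _perfectly_correlated_cohort(n=200):
    """Two A3G variants in complete coupling."""
    from a3pop.variant_model import CohortGenotypes
    defs = [v for v in sd.variant_defs("A3G") if v.cds_pos in (557, 823)]
    rng = np.random.default_rng(3)
    doses = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25]).astype(np.int8)
    return CohortGenotypes([f"S{i}" for i in range(n)], defs,
                           np.column_stack([doses, doses]))


def test_ld_matrix_perfect_correlation():
    m = ld_matrix(_perfectly_correlated_cohort(), "A3G")
    off = m[m.variant1 != m.variant2]
    assert np.allclose(off.Dprime, 1.0)
    assert np.allclose(off.R2, 1.0, atol=1e-9)


def test_ld_matrix_symmetric_unit_diagonal():
    cohort, _ = sd.simulate_cohort(sd.SimulationConfig(n_samples=150, seed=8))
    m = ld_matrix(cohort, "A3H").set_index(["variant1", "variant2"])
    for (v1, v2), row in m.iterrows():
        if v1 == v2:
            assert row.R2 == 1.0 and row.Dprime == 1.0
        else:
            assert m.loc[(v2, v1)].R2 == pytest.approx(row.R2)


def test_ld_matrix_independent_variants_r2_near_null():
    """For independently simulated variants the mean off-diagonal R^2 is of
    order 1/n_chromosomes."""
    from a3pop.variant_model import CohortGenotypes
    rng = np.random.default_rng(17)
    n = 500
    defs = sd.variant_defs("A3G")[:4]
    doses = rng.choice([0, 1, 2], size=(n, 4), p=[0.36, 0.48, 0.16]).astype(np.int8)
    cohort = CohortGenotypes([f"S{i}" for i in range(n)], defs, doses)
    m = ld_matrix(cohort, "A3G")
    off = m[m.variant1 != m.variant2]
    mean_r2 = off.R2.mean()
    assert 0.1 / (2 * n) < mean_r2 < 5.0 / (2 * n)


def test_ld_pair_uses_complete_samples_only():
    cohort, _ = sd.simulate_cohort(sd.SimulationConfig(seed=4))
    v1, v2 = cohort.variants_for_gene("A3H")[:2]
    table, n = two_locus_genotype_table(cohort, v1, v2)
    assert table.sum() == n
    s = ld_pair(cohort, v1, v2)
    assert s.n_chromosomes == 2 * n
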