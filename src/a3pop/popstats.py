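"""Allele frequencies, MAF filtering and Hardy-Weinberg chi-squared testing.

The HWE test is the classical 1-degree-of-freedom goodness-of-fit chi-square
on the three genotype classes against (p^2, 2pq, q^2) expectations, without
continuity correction and without class pooling: that is the convention under
which the published A3D/A3F/A3G statistics reproduce exactly (e.g. counts
(54, 84, 16) give X^2 = 4.02).  Monomorphic sites are reported as such with
X^2 = 0 and p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .variant_model import GenotypeCounts, VariantDef
from ._util import round_half_away


@dataclass(frozen=True)
class AlleleFrequencies:
    ref_count: int
    alt_count: int

    @property
    def two_n(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def ref_pct(self) -> float:
        return 100.0 * self.ref_count / self.two_n

    @property
    def alt_pct(self) -> float:
        return 100.0 * self.alt_count / self.two_n

    @property
    def maf_pct(self) -> float:
        return min(self.ref_pct, self.alt_pct)


@dataclass(frozen=True)
class HweResult:
    expected: tuple[float, float, float]
    chi2: float
    p_value: float
    df: int = 1
    monomorphic: bool = False

    @property
    def deviates(self) -> bool:
        """Non-consistency with HWE at the 0.05 level."""
        return self.p_value < 0.05


def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencies:
    """Allele tallies and percentages from genotype counts."""
    if counts.n == 0:
        raise ValueError("allele frequencies undefined for n = 0")
    return AlleleFrequencies(
        ref_count=2 * counts.n_rr + counts.n_ra,
        alt_count=counts.n_ra + 2 * counts.n_aa,
    )


def hwe_chisq(counts: GenotypeCounts, yates: bool = False) -> HweResult:
    """Hardy-Weinberg chi-squared goodness-of-fit test (df = 1).

    ``yates`` applies the continuity correction |obs-exp| - 0.5 per class;
    it defaults off, matching the published statistics.
    """
    n = counts.n
    if n == 0:
        raise ValueError("HWE test undefined for n = 0")
    freqs = allele_frequencies(counts)
    p = freqs.ref_count / freqs.two_n
    q = 1.0 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    if freqs.ref_count == 0 or freqs.alt_count == 0:
        return HweResult(expected, 0.0, 1.0, monomorphic=True)
    chi2 = 0.0
    for obs, exp in zip((counts.n_rr, counts.n_ra, counts.n_aa), expected):
        dev = abs(obs - exp)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / exp
    return HweResult(expected, chi2, float(stats.chi2.sf(chi2, df=1)))


def maf_filter(
    variants: Sequence[tuple[VariantDef, GenotypeCounts]],
    threshold_pct: float = 5.0,
) -> tuple[list[tuple[VariantDef, GenotypeCounts]], list[tuple[VariantDef, GenotypeCounts]]]:
    """Partition variants into (major, minor) by minor-allele frequency.

    A variant is "major" iff its MAF is >= ``threshold_pct``; strictly lower
    frequencies are excluded, matching the "MAF < 5% were excluded" rule.
    """
    if not (0 < threshold_pct <= 50):
        raise ValueError("threshold must be in (0, 50]")
    major, minor = [], []
    for v, c in variants:
        (major if allele_frequencies(c).maf_pct >= threshold_pct else minor).append((v, c))
    return major, minor


def hwe_report_row(variant: VariantDef, counts: GenotypeCounts) -> dict:
    """One per-variant report row: counts, frequencies, HWE statistics."""
    freqs = allele_frequencies(counts)
    hwe = hwe_chisq(counts)
    return {
        "gene": variant.gene,
        "variant": variant.label or variant.variant_id,
        "variant_id": variant.variant_id,
        "cds_pos": variant.cds_pos,
        "n": counts.n,
        "n_homref": counts.n_rr,
        "n_het": counts.n_ra,
        "n_homalt": counts.n_aa,
        "ref_pct": round_half_away(freqs.ref_pct, 1),
        "alt_pct": round_half_away(freqs.alt_pct, 1),
        "maf_pct": round_half_away(freqs.maf_pct, 1),
        "hwe_chi2": round_half_away(hwe.chi2, 3),
        "hwe_p": hwe.p_value,
        "hwe_deviates": bool(hwe.deviates and not hwe.monomorphic),
        "monomorphic": hwe.monomorphic,
    }
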