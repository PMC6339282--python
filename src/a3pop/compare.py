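"""Cross-population allele-frequency comparison.

Cohort allele counts are compared against published reference-population
frequencies in 2x2 tables: a two-sided Fisher's exact test for
1000-Genomes-sized panels and a Pearson chi-squared test for very large
(ExAC-sized) panels.  The two-sided Fisher p-value is the point-probability
("sum of all tables as or less likely") convention.

Reference panels usually publish only percentages and chromosome counts, so
allele counts are reconstructed by rounding; the reconstruction is reported
alongside each p-value and exact counts can be supplied to override it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
from scipy import stats

from .popstats import allele_frequencies
from .variant_model import GenotypeCounts
from ._util import round_half_away

#: Panels larger than this use the chi-squared test instead of Fisher.
CHI2_SIZE_CUTOFF = 10_000


@dataclass(frozen=True)
class ReferencePopulation:
    """One published reference panel for one variant."""

    code: str
    two_n: int
    alt_pct: float | None           # None encodes NI/ND entries
    ref_count: int | None = None    # exact counts, when known
    alt_count: int | None = None

    def __post_init__(self):
        if self.two_n <= 0:
            raise ValueError(f"{self.code}: two_n must be positive")

    @property
    def known(self) -> bool:
        return self.alt_pct is not None or self.alt_count is not None


@dataclass(frozen=True)
class ComparisonResult:
    population: str
    table: tuple[tuple[int, int], tuple[int, int]]   # [(cohort ref, alt), (pop ref, alt)]
    method: str                                      # fisher | chi2 | skipped
    p_value: float | None
    chi2: float | None = None
    reason: str | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.p_value is None else self.p_value <= 0.05


def reconstruct_counts(pop: ReferencePopulation) -> tuple[int, int]:
    """(ref, alt) allele counts from published percentage and 2n.

    Rounds half away from zero; exact counts stored on the population take
    precedence.
    """
    if pop.ref_count is not None and pop.alt_count is not None:
        return pop.ref_count, pop.alt_count
    if pop.alt_pct is None:
        raise ValueError(f"{pop.code}: no published frequency to reconstruct from")
    alt = int(round_half_away(pop.alt_pct / 100.0 * pop.two_n))
    if not (0 <= alt <= pop.two_n):
        raise ValueError(f"{pop.code}: reconstructed alt count {alt} outside [0, {pop.two_n}]")
    return pop.two_n - alt, alt


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities of all tables with the observed
    margins that are no more probable than the observed table.  Degenerate
    margins (an empty row or column) give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chi2_two_by_two(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared (df = 1) for the 2x2 table [[a, b], [c, d]].

    No continuity correction by default.  Zero margins are rejected with a
    pointer to the exact test.
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: use fisher_exact_two_sided instead")
    n = r1 + r2
    delta = abs(a * d - b * c)
    if yates:
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta * delta / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def default_method_rule(pop: ReferencePopulation) -> str:
    return "chi2" if pop.two_n > CHI2_SIZE_CUTOFF else "fisher"


def compare_populations(
    cohort_counts: GenotypeCounts,
    pops: Sequence[ReferencePopulation],
    method_rule: Callable[[ReferencePopulation], str] = default_method_rule,
) -> list[ComparisonResult]:
    """Compare cohort allele frequencies against each reference panel."""
    freqs = allele_frequencies(cohort_counts)
    a, b = freqs.ref_count, freqs.alt_count
    out = []
    for pop in pops:
        if not pop.known:
            out.append(ComparisonResult(pop.code, ((a, b), (0, 0)), "skipped",
                                        None, reason="no published frequency (NI/ND)"))
            continue
        c, d = reconstruct_counts(pop)
        method = method_rule(pop)
        if method == "chi2":
            try:
                chi2, p = chi2_two_by_two(a, b, c, d)
            except ValueError:
                # zero margin (e.g. both populations monomorphic): fall back
                method, chi2, p = "fisher", None, fisher_exact_two_sided(a, b, c, d)
        else:
            chi2, p = None, fisher_exact_two_sided(a, b, c, d)
        out.append(ComparisonResult(pop.code, ((a, b), (c, d)), method, p, chi2))
    return out


def comparison_frame(variant_label: str, results: Iterable[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "variant": variant_label,
            "population": r.population,
            "cohort_ref": r.table[0][0], "cohort_alt": r.table[0][1],
            "pop_ref": r.table[1][0], "pop_alt": r.table[1][1],
            "method": r.method,
            "p_value": r.p_value,
            "significant": r.significant,
            "note": r.reason or "",
        })
    return pd.DataFrame(rows)
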