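"""Haplotype assignment, A3H stability classification and cohort summaries.

Short unphased reads cannot resolve phase when a sample is heterozygous at
two or more of the sites used for assignment, so diplotypes are classified
as *confirmed* (0 or 1 heterozygous site: the haplotype pair is uniquely
determined) or *unconfirmed* (>= 2 heterozygous sites: phase ambiguous, no
pair reported).  Samples whose only non-reference calls lie at excluded
sites (minor, synonymous or novel variants) are reported as *other*; samples
missing a call at any assignment site are *no_call*.

For A3H, each haplotype is stable (II, V, VII: long protein half-life, able
to restrict HIV-1), unstable (I, III, IV, VI, and anything carrying the N15
deletion) or of unknown stability.  Per-sample stability is resolved by
enumerating all phase configurations consistent with the genotypes; when
every configuration yields the same number of stable haplotypes that number
is reported (e.g. a 15del homozygote has 0 stable haplotypes regardless of
phase), otherwise "unknown".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import _tables
from .popstats import allele_frequencies
from .variant_model import CohortGenotypes, GenotypeCounts, MISSING, VariantDef
from ._util import round_half_away

CONFIRMED = "confirmed"
UNCONFIRMED = "unconfirmed"
OTHER = "other"
NO_CALL = "no_call"

STABLE = "stable"
UNSTABLE = "unstable"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class HaplotypeDef:
    gene: str
    label: str
    alleles: tuple[int, ...]        # alt dose (0/1) per assignment site
    stability: str = UNKNOWN


class HaplotypeTable:
    """Named multi-site allele combinations for one gene.

    Unknown confirmed combinations mint deterministic labels from their
    allele pattern in site order (``novel-0101``), so labelling never depends
    on the order samples are processed.
    """

    def __init__(self, gene: str, sites: Sequence[int],
                 named: Mapping[str, Mapping[int, int]] | None = None):
        self.gene = gene
        self.sites = tuple(sites)
        self._by_alleles: dict[tuple[int, ...], str] = {}
        self._by_label: dict[str, HaplotypeDef] = {}
        for label, allele_map in (named or {}).items():
            unknown_sites = set(allele_map) - set(self.sites)
            if unknown_sites:
                raise ValueError(
                    f"{gene}/{label}: alleles given for non-assignment sites {sorted(unknown_sites)}")
            doses = tuple(int(allele_map.get(s, 0)) for s in self.sites)
            self.add(label, doses)

    def add(self, label: str, doses: tuple[int, ...]) -> HaplotypeDef:
        if label in self._by_label:
            raise ValueError(f"duplicate haplotype label {label!r}")
        hap = HaplotypeDef(self.gene, label, doses, self._stability(label, doses))
        self._by_label[label] = hap
        self._by_alleles.setdefault(doses, label)
        return hap

    def _stability(self, label: str, doses: tuple[int, ...]) -> str:
        if self.gene != "A3H":
            return UNKNOWN
        if _tables.A3H_DELETION_SITE in self.sites:
            if doses[self.sites.index(_tables.A3H_DELETION_SITE)]:
                return UNSTABLE
        if label in _tables.A3H_STABLE:
            return STABLE
        if label in _tables.A3H_UNSTABLE:
            return UNSTABLE
        return UNKNOWN

    def label_for(self, doses: tuple[int, ...]) -> str:
        label = self._by_alleles.get(doses)
        if label is None:
            label = "novel-" + "".join(str(d) for d in doses)
            if label not in self._by_label:
                self.add(label, doses)
        return label

    def stability_of(self, doses: tuple[int, ...]) -> str:
        return self._stability(self._by_alleles.get(doses, ""), doses)

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> HaplotypeDef:
        return self._by_label[label]

    @property
    def labels(self) -> list[str]:
        return list(self._by_label)


def default_haplotype_table(gene: str) -> HaplotypeTable:
    """The shipped named-haplotype table for one of the four genes."""
    sites = default_considered_site_positions(gene)
    return HaplotypeTable(gene, sites, _tables.HAPLOTYPE_TABLE[gene])


def default_considered_site_positions(gene: str) -> tuple[int, ...]:
    """Assignment sites for a gene: the forced configuration when present,
    otherwise the plain nonsynonymous-MAF rule applied to the published
    genotype counts."""
    if _tables.FORCED_SITES.get(gene):
        return tuple(sorted(_tables.FORCED_SITES[gene]))
    pairs = []
    for (g, label, vid, tx, pos, exon, ref, alt, _codon, counts, _syn) in _tables.VARIANT_TABLE:
        if g != gene:
            continue
        v = VariantDef(gene=g, variant_id=vid, cds_pos=pos, ref_allele=ref,
                       alt_allele=alt, exon=exon, transcript_id=tx, label=label)
        pairs.append((v, GenotypeCounts(*counts)))
    return tuple(v.cds_pos for v in considered_sites(gene, pairs))


@dataclass(frozen=True)
class DiplotypeCall:
    sample: str
    gene: str
    status: str
    het_count: int
    pair: tuple[str, str] | None = None           # sorted labels when confirmed
    genotypes: tuple[int, ...] = ()               # alt dose per assignment site
    sites: tuple[int, ...] = ()


def considered_sites(
    gene: str,
    variants: Sequence[tuple[VariantDef, GenotypeCounts]],
    maf_threshold_pct: float = 5.0,
    effects: Mapping[str, str] | None = None,
) -> list[VariantDef]:
    """Sites used for haplotype assignment, ordered by CDS position.

    Nonsynonymous variants with MAF >= threshold are considered; per-gene
    forced-site and excluded-site configuration overrides the plain rule to
    reproduce the published site choices (A3H always uses the five canonical
    sites and never 140; novel variants are never considered).  ``effects``
    optionally maps variant_id to "synonymous"/"nonsynonymous"; without it,
    the built-in annotation flag is used for known variants.
    """
    forced = set(_tables.FORCED_SITES.get(gene, ()))
    excluded = set(_tables.EXCLUDED_SITES.get(gene, ()))
    syn_by_id = {row[2]: row[10] for row in _tables.VARIANT_TABLE if row[0] == gene}

    chosen = []
    for v, counts in variants:
        if v.cds_pos in excluded:
            continue
        if v.variant_id.startswith("NI"):
            continue
        if forced:
            if v.cds_pos in forced:
                chosen.append(v)
            continue
        if effects is not None:
            synonymous = effects.get(v.variant_id) == "synonymous"
        else:
            synonymous = syn_by_id.get(v.variant_id, False)
        if synonymous:
            continue
        if counts.n and allele_frequencies(counts).maf_pct >= maf_threshold_pct:
            chosen.append(v)
    return sorted(chosen, key=lambda v: v.cds_pos)


def assign_diplotype(
    sample: str,
    gene: str,
    genotypes: Mapping[int, int],
    table: HaplotypeTable,
    has_excluded_nonref: bool = False,
) -> DiplotypeCall:
    """Assign a diplotype from genotypes at the assignment sites.

    ``genotypes`` maps CDS position to alt dose; genotypes at positions not
    in the table's site list are ignored, never an error.  Missing calls
    (absent site or dose -1) give ``no_call``.
    """
    doses = []
    for s in table.sites:
        d = genotypes.get(s, MISSING)
        if d == MISSING:
            return DiplotypeCall(sample, gene, NO_CALL, 0, sites=table.sites)
        doses.append(int(d))
    doses = tuple(doses)
    het = sum(1 for d in doses if d == 1)

    if het >= 2:
        return DiplotypeCall(sample, gene, UNCONFIRMED, het,
                             genotypes=doses, sites=table.sites)
    if all(d == 0 for d in doses) and has_excluded_nonref:
        return DiplotypeCall(sample, gene, OTHER, 0,
                             genotypes=doses, sites=table.sites)
    # phase is unambiguous: split each dose across the two haplotypes
    h1 = tuple(1 if d == 2 else 0 for d in doses)
    h2 = tuple(1 if d >= 1 else 0 for d in doses)
    pair = tuple(sorted((table.label_for(h1), table.label_for(h2))))
    return DiplotypeCall(sample, gene, CONFIRMED, het, pair=pair,
                         genotypes=doses, sites=table.sites)


def _phasings(doses: Sequence[int]):
    """All haplotype pairs consistent with the genotypes (het sites split
    both ways; the first het site is pinned to haplotype 1 to halve the
    symmetric enumeration)."""
    het_idx = [i for i, d in enumerate(doses) if d == 1]
    hom = [1 if d == 2 else 0 for d in doses]
    if not het_idx:
        yield tuple(hom), tuple(hom)
        return
    for bits in itertools.product((0, 1), repeat=len(het_idx) - 1):
        assign = (1,) + bits
        h1, h2 = list(hom), list(hom)
        for i, b in zip(het_idx, assign):
            (h1 if b else h2)[i] = 1
        yield tuple(h1), tuple(h2)


def classify_a3h_stability(call: DiplotypeCall, table: HaplotypeTable) -> int | str:
    """Number of stable haplotypes (0/1/2) carried by a sample, or "unknown".

    Resolved whenever the answer is invariant across all phase
    configurations consistent with the genotypes; a haplotype of unknown
    stability makes the count unknown unless it cannot change the answer.
    """
    if call.gene != "A3H" or table.gene != "A3H":
        raise ValueError("stability classification applies to A3H only")
    if call.status == NO_CALL:
        return UNKNOWN
    outcomes = set()
    for h1, h2 in _phasings(call.genotypes):
        stabs = (table.stability_of(h1), table.stability_of(h2))
        if UNKNOWN in stabs:
            # bracket the possible counts for this phasing
            lo = sum(s == STABLE for s in stabs)
            hi = lo + sum(s == UNKNOWN for s in stabs)
            outcomes.update(range(lo, hi + 1))
        else:
            outcomes.add(sum(s == STABLE for s in stabs))
        if len(outcomes) > 1:
            return UNKNOWN
    return outcomes.pop()


@dataclass
class CohortHaplotypeSummary:
    gene: str
    n: int                                   # samples with calls
    n_no_call: int
    categories: dict[str, int]               # "ii/iii" / "unconfirmed" / "other"
    zero_stable: int | None = None           # A3H only
    stability_counts: dict | None = None

    def pct(self, category: str) -> float:
        return round_half_away(100.0 * self.categories.get(category, 0) / self.n, 1)

    @property
    def zero_stable_pct(self) -> float | None:
        if self.zero_stable is None:
            return None
        return round_half_away(100.0 * self.zero_stable / self.n, 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": self.gene, "category": k, "count": c,
                 "pct": self.pct(k)} for k, c in self.categories.items()]
        if self.zero_stable is not None:
            rows.append({"gene": self.gene, "category": "zero_stable_haplotypes",
                         "count": self.zero_stable, "pct": self.zero_stable_pct})
        return pd.DataFrame(rows)


def summarize_cohort(
    calls: Sequence[DiplotypeCall],
    table: HaplotypeTable | None = None,
) -> CohortHaplotypeSummary:
    """Per-category counts and percentages over samples with calls.

    For A3H (``table`` given) the summary additionally counts samples with
    zero stable haplotypes.
    """
    if not calls:
        raise ValueError("no diplotype calls to summarize")
    gene = calls[0].gene
    with_calls = [c for c in calls if c.status != NO_CALL]
    categories: dict[str, int] = {}
    for c in with_calls:
        key = "/".join(c.pair) if c.status == CONFIRMED else c.status
        categories[key] = categories.get(key, 0) + 1

    zero_stable = None
    stab_counts = None
    if gene == "A3H" and table is not None:
        stab_counts = {0: 0, 1: 0, 2: 0, UNKNOWN: 0}
        for c in with_calls:
            stab_counts[classify_a3h_stability(c, table)] += 1
        zero_stable = stab_counts[0]
    return CohortHaplotypeSummary(gene, len(with_calls),
                                  len(calls) - len(with_calls),
                                  categories, zero_stable, stab_counts)


def assign_gene(
    cohort: CohortGenotypes,
    gene: str,
    table: HaplotypeTable | None = None,
    maf_threshold_pct: float = 5.0,
) -> tuple[list[DiplotypeCall], HaplotypeTable]:
    """Run diplotype assignment for every sample of a cohort at one gene."""
    gene_variants = cohort.variants_for_gene(gene)
    if table is None:
        if gene in _tables.HAPLOTYPE_TABLE:
            # study genes: fixed published site configuration
            table = default_haplotype_table(gene)
        else:
            from .variant_model import count_genotypes
            pairs = [(v, count_genotypes(cohort, v)) for v in gene_variants]
            sites = [v.cds_pos for v in considered_sites(gene, pairs, maf_threshold_pct)]
            table = HaplotypeTable(gene, sorted(sites), {"i": {}})

    site_variants = {v.cds_pos: v for v in gene_variants}
    excluded_variants = [v for v in gene_variants if v.cds_pos not in table.sites]
    calls = []
    for i, sample in enumerate(cohort.samples):
        genotypes = {}
        for s in table.sites:
            v = site_variants.get(s)
            genotypes[s] = int(cohort.column(v)[i]) if v is not None else MISSING
        has_excl = any(cohort.column(v)[i] > 0 for v in excluded_variants)
        calls.append(assign_diplotype(sample, gene, genotypes, table, has_excl))
    return calls, table
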