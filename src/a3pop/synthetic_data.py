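"""Cohort simulators and deterministic fixtures built from the study tables.

Two fixture families are provided:

* :func:`tally_cohorts` — per-gene cohorts whose per-variant genotype
  counts equal the published tallies exactly.  The multi-site layout is a
  deterministic block arrangement; for A3H it is curated so that every rare
  genotype falls inside the N15-deletion-homozygote block, which makes the
  zero-stable-haplotype count equal the number of deletion homozygotes (the
  published genotype tallies and per-individual haplotype categories are
  mutually inconsistent for A3H, so no single cohort can reproduce both).
* :func:`category_cohorts` — per-gene cohorts expanded sample-by-sample from
  the published per-individual haplotype categories, used for
  diplotype-level summaries.

The statistical generator :func:`simulate_cohort` draws diploid genotypes
from per-gene haplotype frequencies under Hardy-Weinberg equilibrium, with
an inbreeding coefficient F as the single deviation knob (with probability F
the two haplotypes are identical by descent) and per-gene whole-gene
missingness emulating amplification failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _tables
from .haplotypes import HaplotypeTable, default_haplotype_table
from .variant_model import CohortGenotypes, MISSING, VariantDef

NEUTRAL_CODON = "GCT"      # alanine padding for synthetic CDS fixtures

#: Codons that must be spelled explicitly in the synthetic CDS (the A3H N15
#: deletion needs an AAC-AAC context so that removing "CAA" at CDS 45-47
#: deletes one asparagine in frame).
_SPECIAL_CODONS = {"ENST00000442487": {15: "AAC", 16: "AAC"}}

#: Default per-gene haplotype frequencies for simulation, composed from the
#: cohort allele frequencies (A3H chosen so the deletion-carrying haplotypes
#: sum to 0.598, the cohort's deletion-allele frequency).
DEFAULT_HAPLOTYPE_FREQS: dict[str, dict[str, float]] = {
    "A3D": {"i": 0.786, "ii": 0.062, "iii": 0.042, "iv": 0.110},
    "A3F": {"i": 0.574, "iii": 0.176, "iv": 0.049, "vi": 0.201},
    "A3G": {"i": 0.399, "ii": 0.370, "iii": 0.179, "iv": 0.052},
    "A3H": {"i": 0.050, "ii": 0.352, "iii": 0.300, "iv": 0.060, "x": 0.238},
}

#: Whole-gene failure rates reproducing 168/154/165/133 successes of 192.
DEFAULT_MISSING_GENE_RATE = {
    gene: 1.0 - n / _tables.N_RECRUITED for gene, n in _tables.GENE_N.items()
}


def variant_defs(gene: str | None = None) -> list[VariantDef]:
    """VariantDef objects for the study's variant table."""
    defs = []
    for (g, label, vid, tx, pos, exon, ref, alt, _codon, _counts, _syn) in _tables.VARIANT_TABLE:
        if gene is not None and g != gene:
            continue
        defs.append(VariantDef(gene=g, variant_id=vid, cds_pos=pos,
                               ref_allele=ref, alt_allele=alt, exon=exon,
                               transcript_id=tx, label=label))
    return defs


def published_genotype_counts(gene: str) -> dict[str, tuple[int, int, int]]:
    """label -> (hom-ref, het, hom-alt) tallies as published."""
    return {row[1]: row[9] for row in _tables.VARIANT_TABLE if row[0] == gene}


def build_cds(transcript_id: str) -> str:
    """Synthetic CDS carrying the study's reference codons at the correct
    codon numbers, padded elsewhere with a neutral alanine codon.

    The real Ensembl transcripts are not redistributed; only the codons the
    annotation exercises are faithful, which is all the coding-effect
    machinery needs.
    """
    aa_len = _tables.TRANSCRIPT_AA_LEN[transcript_id]
    codons = [NEUTRAL_CODON] * aa_len + ["TAA"]
    for num, codon in _SPECIAL_CODONS.get(transcript_id, {}).items():
        codons[num - 1] = codon
    for (_g, label, _vid, tx, pos, _exon, ref, _alt, ref_codon, _c, _s) in _tables.VARIANT_TABLE:
        if tx != transcript_id or ref_codon is None:
            continue
        num = -(-pos // 3)                  # ceil
        if codons[num - 1] not in (NEUTRAL_CODON, ref_codon):
            raise ValueError(f"{transcript_id} codon {num}: conflicting codons "
                             f"{codons[num - 1]} vs {ref_codon} ({label})")
        codons[num - 1] = ref_codon
    cds = "".join(codons)
    for (_g, label, _vid, tx, pos, _exon, ref, _alt, _rc, _c, _s) in _tables.VARIANT_TABLE:
        if tx != transcript_id:
            continue
        found = cds[pos - 1: pos - 1 + len(ref)]
        if found != ref:
            raise ValueError(f"{transcript_id}/{label}: CDS has {found!r} at "
                             f"{pos}, expected {ref!r}")
    return cds


def cds_fixtures() -> dict[str, str]:
    """transcript_id -> synthetic CDS for all study transcripts."""
    return {tx: build_cds(tx) for tx in _tables.TRANSCRIPT_AA_LEN}


def write_cds_fasta(path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    records = [SeqRecord(Seq(s), id=tx, description="synthetic CDS fixture")
               for tx, s in cds_fixtures().items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Deterministic fixtures from the printed tables
# ---------------------------------------------------------------------------

def _block_doses(n: int, counts: tuple[int, int, int], offset: int) -> np.ndarray:
    """Deterministic genotype layout: hom-alt, then het, then hom-ref, over a
    rotated sample order (the rotation decorrelates variants)."""
    rr, ra, aa = counts
    if rr + ra + aa != n:
        raise ValueError(f"counts {counts} do not sum to {n}")
    doses = np.array([2] * aa + [1] * ra + [0] * rr, dtype=np.int8)
    return np.roll(doses, offset % n)


#: Curated A3H layout: samples 0-54 are deletion homozygotes and absorb every
#: rare genotype at the other sites; 55-103 are deletion heterozygotes;
#: 104-132 are deletion-free.  (cds_pos -> list of (dose, index range)).
_A3H_LAYOUT = {
    45: [(2, 0, 55), (1, 55, 104), (0, 104, 133)],
    53: [(2, 0, 6), (1, 6, 21), (0, 21, 133)],
    313: [(0, 0, 1), (1, 1, 5), (2, 5, 133)],
    361: [(0, 5, 6), (1, 6, 12), (2, 0, 5), (2, 12, 133)],
    418: [(2, 0, 133)],
    534: [(0, 0, 3), (1, 3, 14), (2, 14, 133)],
    129: [(0, 14, 20), (1, 20, 27), (2, 0, 14), (2, 27, 133)],
}


def tally_cohort(gene: str) -> CohortGenotypes:
    """Cohort whose per-variant genotype counts equal the published tallies
    exactly (deterministic layout; see module docstring for the A3H case)."""
    defs = variant_defs(gene)
    n = _tables.GENE_N[gene]
    samples = [f"{gene}.T{i:03d}" for i in range(n)]
    doses = np.full((n, len(defs)), MISSING, dtype=np.int8)
    if gene == "A3H":
        for j, v in enumerate(defs):
            col = np.full(n, MISSING, dtype=np.int8)
            for dose, lo, hi in _A3H_LAYOUT[v.cds_pos]:
                col[lo:hi] = dose
            if (col == MISSING).any():
                raise ValueError(f"A3H layout leaves gaps at {v.cds_pos}")
            doses[:, j] = col
    else:
        counts = published_genotype_counts(gene)
        for j, v in enumerate(defs):
            doses[:, j] = _block_doses(n, counts[v.label], offset=7 * j)
    cohort = CohortGenotypes(samples, defs, doses)
    _check_counts(cohort, gene)
    return cohort


def _check_counts(cohort: CohortGenotypes, gene: str) -> None:
    from .variant_model import count_genotypes
    expected = published_genotype_counts(gene)
    for v in cohort.variants_for_gene(gene):
        c = count_genotypes(cohort, v)
        if (c.n_rr, c.n_ra, c.n_aa) != expected[v.label]:
            raise ValueError(
                f"fixture self-check failed: {gene}/{v.label} counts "
                f"{(c.n_rr, c.n_ra, c.n_aa)} != published {expected[v.label]}")


def category_cohort(gene: str) -> CohortGenotypes:
    """Cohort expanded sample-by-sample from the published per-individual
    haplotype categories (each printed category repeated its printed count)."""
    defs = variant_defs(gene)
    pos_idx = {v.cds_pos: j for j, v in enumerate(defs)}
    categories = _tables.HAPLOTYPE_CATEGORIES[gene]
    n = sum(c[0] for c in categories)
    if n != _tables.GENE_N[gene]:
        raise ValueError(f"{gene}: categories sum to {n}, expected {_tables.GENE_N[gene]}")
    samples = [f"{gene}.C{i:03d}" for i in range(n)]
    doses = np.zeros((n, len(defs)), dtype=np.int8)
    i = 0
    for count, considered, _label, extras in categories:
        for site_map in (considered, extras):
            for pos, dose in site_map.items():
                doses[i:i + count, pos_idx[pos]] = dose
        i += count
    return CohortGenotypes(samples, defs, doses)


def tally_cohorts() -> dict[str, CohortGenotypes]:
    return {g: tally_cohort(g) for g in _tables.GENES}


def category_cohorts() -> dict[str, CohortGenotypes]:
    return {g: category_cohort(g) for g in _tables.GENES}


def fixture_from_printed_tables() -> dict[str, CohortGenotypes]:
    """Per-gene cohorts with genotype counts exactly equal to the published
    tallies (alias of :func:`tally_cohorts`)."""
    return tally_cohorts()


# ---------------------------------------------------------------------------
# Statistical simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Cohort-simulation parameters.

    ``haplotype_freqs`` maps gene -> {haplotype label: frequency}; labels
    must exist in the gene's haplotype table.  ``inbreeding_f`` is Wright's
    F: with probability F a sample's two haplotypes are identical by
    descent, producing a heterozygote deficit without changing allele
    frequencies.  ``missing_gene_rate`` is the per-gene probability that a
    sample fails for the whole gene.
    """

    n_samples: int = _tables.N_RECRUITED
    haplotype_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(f) for g, f in DEFAULT_HAPLOTYPE_FREQS.items()})
    inbreeding_f: float = 0.0
    missing_gene_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_GENE_RATE))
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.inbreeding_f <= 1):
            raise ValueError("inbreeding_f must be in [0, 1]")
        for gene, freqs in self.haplotype_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{gene}: haplotype frequencies sum to {total}, not 1")
            if min(freqs.values()) < 0:
                raise ValueError(f"{gene}: negative haplotype frequency")
        for gene, rate in self.missing_gene_rate.items():
            if not (0 <= rate <= 1):
                raise ValueError(f"{gene}: missing rate {rate} outside [0, 1]")


def simulate_cohort(
    config: SimulationConfig,
    tables: Mapping[str, HaplotypeTable] | None = None,
) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Draw a diploid cohort from per-gene haplotype frequencies.

    Returns the unphased cohort plus a truth table (sample, gene, hap1,
    hap2; whole-gene failures have empty labels) for oracle tests.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.haplotype_freqs)
    tables = tables or {g: default_haplotype_table(g) for g in genes}

    samples = [f"SIM{i:04d}" for i in range(config.n_samples)]
    all_defs: list[VariantDef] = []
    gene_cols: dict[str, list[int]] = {}
    for g in genes:
        site_set = set(tables[g].sites)
        defs = [v for v in variant_defs(g) if v.cds_pos in site_set]
        if {v.cds_pos for v in defs} != site_set:
            raise ValueError(f"{g}: haplotype table sites missing from variant table")
        gene_cols[g] = list(range(len(all_defs), len(all_defs) + len(defs)))
        all_defs.extend(defs)

    doses = np.full((config.n_samples, len(all_defs)), MISSING, dtype=np.int8)
    truth_rows = []
    for g in genes:
        table = tables[g]
        labels = list(config.haplotype_freqs[g])
        probs = np.array([config.haplotype_freqs[g][lab] for lab in labels])
        probs = probs / probs.sum()
        hap_doses = np.array([table[lab].alleles for lab in labels], dtype=np.int8)
        site_order = {s: k for k, s in enumerate(table.sites)}
        defs = [all_defs[j] for j in gene_cols[g]]
        col_site = [site_order[v.cds_pos] for v in defs]

        fail = rng.random(config.n_samples) < config.missing_gene_rate.get(g, 0.0)
        h1 = rng.choice(len(labels), size=config.n_samples, p=probs)
        h2 = rng.choice(len(labels), size=config.n_samples, p=probs)
        ibd = rng.random(config.n_samples) < config.inbreeding_f
        h2 = np.where(ibd, h1, h2)
        for i in range(config.n_samples):
            if fail[i]:
                truth_rows.append((samples[i], g, "", ""))
                continue
            d = hap_doses[h1[i]] + hap_doses[h2[i]]
            for jj, j in enumerate(gene_cols[g]):
                doses[i, j] = d[col_site[jj]]
            truth_rows.append((samples[i], g, labels[h1[i]], labels[h2[i]]))

    truth = pd.DataFrame(truth_rows, columns=["sample_id", "gene", "hap1", "hap2"])
    return CohortGenotypes(samples, all_defs, doses), truth


def simulate_two_locus(
    p_A: float, p_B: float, D: float, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` diploid samples from two-locus haplotype frequencies
    (p_A p_B + D, p_A q_B - D, q_A p_B - D, q_A q_B + D).

    ``p_A``/``p_B`` are ref-allele frequencies.  Returns the 3x3 genotype
    table (alt dose at locus 1 x alt dose at locus 2) and the true haplotype
    counts (AB, Ab, aB, ab).  Raises for inadmissible D with the admissible
    interval.
    """
    qA, qB = 1.0 - p_A, 1.0 - p_B
    freqs = np.array([p_A * p_B + D, p_A * qB - D, qA * p_B - D, qA * qB + D])
    if freqs.min() < -1e-12:
        lo = -min(p_A * p_B, qA * qB)
        hi = min(p_A * qB, qA * p_B)
        raise ValueError(f"inadmissible D={D}; admissible interval is [{lo:.6g}, {hi:.6g}]")
    freqs = np.maximum(freqs, 0.0)
    freqs /= freqs.sum()
    rng = np.random.default_rng(seed)
    haps = rng.choice(4, size=2 * n, p=freqs)
    hap_counts = np.bincount(haps, minlength=4)
    alt1 = np.isin(haps, (2, 3)).astype(int)    # a-allele gametes
    alt2 = np.isin(haps, (1, 3)).astype(int)    # b-allele gametes
    d1 = alt1[0::2] + alt1[1::2]
    d2 = alt2[0::2] + alt2[1::2]
    table = np.zeros((3, 3), dtype=int)
    for i, j in zip(d1, d2):
        table[i, j] += 1
    return table, hap_counts


# ---------------------------------------------------------------------------
# Minimal VCF writer (round-trip fixture support)
# ---------------------------------------------------------------------------

def write_vcf(cohort: CohortGenotypes, path,
              cds_by_transcript: Mapping[str, str] | None = None) -> None:
    """Write a cohort as a CDS-space VCF (CHROM = gene, POS = CDS position).

    Deletions are written in anchored form (REF includes the preceding base)
    when the transcript CDS is supplied, otherwise with an ``N`` anchor.
    """
    genes = sorted({v.gene for v in cohort.variants})
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines += [f"##contig=<ID={g}>" for g in genes]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.samples))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, v in enumerate(cohort.variants):
        if v.alt_allele == "-":
            cds = (cds_by_transcript or {}).get(v.transcript_id)
            anchor = cds[v.cds_pos - 2] if cds and v.cds_pos >= 2 else "N"
            pos, ref, alt = v.cds_pos - 1, anchor + v.ref_allele, anchor
        else:
            pos, ref, alt = v.cds_pos, v.ref_allele, v.alt_allele
        gts = "\t".join(gt_map[int(d)] for d in cohort.doses[:, j])
        vid = v.variant_id if v.variant_id != "NI" else f"NI:{v.cds_pos}"
        lines.append(f"{v.gene}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
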