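"""Genotype ingest, tallies and coding-effect annotation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from a3pop import (
    CohortGenotypes, GenotypeCounts, MISSING, VariantDef,
    annotate_coding_effect, count_genotypes, read_genotype_table,
    read_vcf_minimal,
)
from a3pop import synthetic_data as sd
from a3pop.variant_model import (
    CdsConsistencyError, GenotypeParseError, VariantLookupError,
    substitution_class,
)


# ---------------------------------------------------------------------------
# Coding-effect annotation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gene, label, codon, pos_in_codon, ref_codon, alt_codon, ref_aa, alt_aa, effect, klass",
    [
        ("A3D", "R97C", 97, 1, "CGC", "TGC", "R", "C", "nonsynonymous", "transition"),
        ("A3D", "R248K", 248, 2, "AGG", "AAG", "R", "K", "nonsynonymous", "transition"),
        ("A3D", "L221L", 221, 3, "CTG", "CTC", "L", "L", "synonymous", "transversion"),
        ("A3F", "A108S", 108, 1, "GCT", "TCT", "A", "S", "nonsynonymous", "transversion"),
        ("A3F", "Q87L", 87, 2, "CAG", "CTG", "Q", "L", "nonsynonymous", "transversion"),
        ("A3G", "H186R", 186, 2, "CAC", "CGC", "H", "R", "nonsynonymous", "transition"),
        ("A3H", "E178D", 178, 3, "GAG", "GAC", "E", "D", "nonsynonymous", "transversion"),
        ("A3H", "T43T", 43, 3, "ACG", "ACC", "T", "T", "synonymous", "transversion"),
    ],
)
def test_snv_annotation(cds, defs_by_label, gene, label, codon, pos_in_codon,
                        ref_codon, alt_codon, ref_aa, alt_aa, effect, klass):
    v = defs_by_label[(gene, label)]
    eff = annotate_coding_effect(cds[v.transcript_id], v)
    assert (eff.codon_number, eff.codon_position) == (codon, pos_in_codon)
    assert (eff.ref_codon, eff.alt_codon) == (ref_codon, alt_codon)
    assert (eff.ref_aa, eff.alt_aa) == (ref_aa, alt_aa)
    assert eff.effect_class == effect
    assert eff.substitution_class == klass
    assert eff.is_synonymous == (ref_aa == alt_aa)


def test_inframe_deletion_annotation(cds, defs_by_label):
    v = defs_by_label[("A3H", "N15del")]
    eff = annotate_coding_effect(cds[v.transcript_id], v)
    assert eff.codon_number == 15
    assert eff.effect_class == "inframe_deletion"
    assert eff.substitution_class == "indel"
    assert eff.ref_aa == "N"        # one asparagine removed


def test_frameshift_deletion():
    cds = "ATGAAACCCGGGTAA"
    v = VariantDef(gene="X", variant_id="fs1", cds_pos=4, ref_allele="AA",
                   alt_allele="-")
    eff = annotate_coding_effect(cds, v)
    assert eff.effect_class == "frameshift"


def test_ref_mismatch_reports_expected_and_found(cds, defs_by_label):
    v = defs_by_label[("A3D", "R97C")]
    bad = VariantDef(gene="A3D", variant_id="bad", cds_pos=v.cds_pos,
                     ref_allele="A", alt_allele="G", transcript_id=v.transcript_id)
    with pytest.raises(CdsConsistencyError, match="expected ref 'A', found 'C'"):
        annotate_coding_effect(cds[v.transcript_id], bad)


def test_allele_swap_symmetry(cds, defs_by_label):
    """Reversing ref/alt keeps codon number and substitution class and swaps
    the amino acids (annotating against the mutated CDS)."""
    for (gene, label), v in defs_by_label.items():
        if not v.is_snv:
            continue
        seq = cds[v.transcript_id]
        fwd = annotate_coding_effect(seq, v)
        mutated = seq[:v.cds_pos - 1] + v.alt_allele + seq[v.cds_pos:]
        rev = annotate_coding_effect(mutated, VariantDef(
            gene=gene, variant_id="rev", cds_pos=v.cds_pos,
            ref_allele=v.alt_allele, alt_allele=v.ref_allele))
        assert rev.codon_number == fwd.codon_number
        assert (rev.ref_aa, rev.alt_aa) == (fwd.alt_aa, fwd.ref_aa)
        assert rev.substitution_class == fwd.substitution_class


def test_transition_transversion_partition(defs_by_label):
    """Every SNV is exactly one of transition/transversion."""
    for v in defs_by_label.values():
        if v.is_snv:
            assert substitution_class(v.ref_allele, v.alt_allele) in (
                "transition", "transversion")
        else:
            assert substitution_class(v.ref_allele, v.alt_allele) == "indel"


# ---------------------------------------------------------------------------
# Genotype tables and counting
# ---------------------------------------------------------------------------

def _write_tsv(path, rows):
    header = "sample_id\tgene\tvariant_id\tallele1\tallele2\n"
    path.write_text(header + "".join("\t".join(r) + "\n" for r in rows))


def test_read_genotype_table_het_and_missing(tmp_path, defs_by_label):
    p = tmp_path / "g.tsv"
    _write_tsv(p, [
        ("S001", "A3D", "rs61748819", "G", "A"),
        ("S002", "A3D", "rs61748819", ".", "."),
    ])
    cohort = read_genotype_table(p, sd.variant_defs("A3D"))
    v = defs_by_label[("A3D", "R248K")]
    assert list(cohort.column(v)) == [1, MISSING]


def test_read_genotype_table_empty_cohort(tmp_path):
    p = tmp_path / "empty.tsv"
    _write_tsv(p, [])
    cohort = read_genotype_table(p, sd.variant_defs("A3D"))
    assert cohort.samples == []


@pytest.mark.parametrize("row, msg", [
    (("S001", "A3D", "rs0000", "G", "A"), "unknown variant"),
    (("S001", "A3D", "rs61748819", "G", "T"), "neither ref"),
])
def test_read_genotype_table_rejects_bad_rows(tmp_path, row, msg):
    p = tmp_path / "bad.tsv"
    _write_tsv(p, [row])
    with pytest.raises(GenotypeParseError, match=msg):
        read_genotype_table(p, sd.variant_defs("A3D"))


def test_genotype_tsv_round_trip(tmp_path, tally_fixture):
    cohort = tally_fixture["A3D"]
    p = tmp_path / "rt.tsv"
    cohort.to_tsv(p)
    back = read_genotype_table(p, cohort.variants)
    assert back.samples == cohort.samples
    assert np.array_equal(back.doses, cohort.doses)


def test_count_genotypes_all_homref():
    v = VariantDef(gene="X", variant_id="v1", cds_pos=1, ref_allele="A", alt_allele="G")
    cohort = CohortGenotypes([f"S{i}" for i in range(5)], [v],
                             np.zeros((5, 1), dtype=np.int8))
    c = count_genotypes(cohort, v)
    assert (c.n_rr, c.n_ra, c.n_aa) == (5, 0, 0)


@pytest.mark.parametrize("gene, label, expected", [
    ("A3D", "R248K", (133, 33, 2)),
    ("A3G", "H186R", (63, 82, 20)),
    ("A3H", "N15del", (29, 49, 55)),
])
def test_count_genotypes_study_fixture(tally_fixture, defs_by_label, gene, label, expected):
    c = count_genotypes(tally_fixture[gene], defs_by_label[(gene, label)])
    assert (c.n_rr, c.n_ra, c.n_aa) == expected


def test_count_genotypes_matches_loop_oracle():
    cohort, _ = sd.simulate_cohort(sd.SimulationConfig(n_samples=80, seed=11))
    for v in cohort.variants:
        c = count_genotypes(cohort, v)
        tally = [0, 0, 0]
        n_missing = 0
        for i in range(len(cohort.samples)):
            d = int(cohort.column(v)[i])
            if d == MISSING:
                n_missing += 1
            else:
                tally[d] += 1
        assert (c.n_rr, c.n_ra, c.n_aa) == tuple(tally)
        assert c.n + n_missing == len(cohort.samples)


def test_count_genotypes_unknown_variant_raises(tally_fixture):
    v = VariantDef(gene="A3D", variant_id="rs999", cds_pos=5, ref_allele="A",
                   alt_allele="C")
    with pytest.raises(VariantLookupError):
        count_genotypes(tally_fixture["A3D"], v)


def test_gene_n_matches_study(tally_fixture):
    for gene, n in {"A3D": 168, "A3F": 154, "A3G": 165, "A3H": 133}.items():
        assert tally_fixture[gene].gene_n(gene) == n


# ---------------------------------------------------------------------------
# VCF ingest
# ---------------------------------------------------------------------------

def test_vcf_round_trip(tmp_path, tally_fixture, cds):
    cohort = tally_fixture["A3H"]
    p = tmp_path / "a3h.vcf"
    sd.write_vcf(cohort, p, cds)
    back = read_vcf_minimal(p, cohort.variants)
    assert back.samples == cohort.samples
    assert np.array_equal(back.doses, cohort.doses)


def test_vcf_gt_parsing(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text("\n".join([
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=G1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
        "G1\t10\trsX\tA\tG\t.\t.\t.\tGT\t0/1\t1|1\t./.",
    ]) + "\n")
    cohort = read_vcf_minimal(p)
    assert cohort.samples == ["S1", "S2", "S3"]
    assert list(cohort.doses[:, 0]) == [1, 2, MISSING]   # phase ignored


def test_vcf_rejects_multiallelic(tmp_path):
    p = tmp_path / "multi.vcf"
    p.write_text("\n".join([
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=G1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
        "G1\t10\trsX\tA\tG,T\t.\t.\t.\tGT\t1/2",
    ]) + "\n")
    with pytest.raises(GenotypeParseError, match="non-biallelic"):
        read_vcf_minimal(p)


# ---------------------------------------------------------------------------
# Domain-type invariants
# ---------------------------------------------------------------------------

def test_variantdef_validation():
    with pytest.raises(ValueError):
        VariantDef(gene="X", variant_id="v", cds_pos=0, ref_allele="A", alt_allele="G")
    with pytest.raises(ValueError):
        VariantDef(gene="X", variant_id="v", cds_pos=1, ref_allele="A", alt_allele="A")


@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_genotype_counts_allele_conservation(rr, ra, aa):
    c = GenotypeCounts(rr, ra, aa)
    assert c.two_n == 2 * (rr + ra + aa)
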