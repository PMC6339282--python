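"""Domain types, genotype ingest and coding-effect annotation.

Genotypes live in CDS coordinate space (1-based nucleotide positions within a
transcript's coding sequence), which keeps all four APOBEC3 genes strand-free.
Calls are unordered ref/alt allele pairs stored as alt-allele dose
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing); phase from VCF input is
deliberately discarded, matching short-read unphased genotype calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

MISSING = -1

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class GenotypeParseError(ValueError):
    """Malformed genotype input (names the offending line or record)."""


class VariantLookupError(KeyError):
    """A requested variant is not present in the cohort."""


class CdsConsistencyError(ValueError):
    """A variant's declared ref allele disagrees with the CDS sequence."""


@dataclass(frozen=True)
class VariantDef:
    """One biallelic coding variant.

    ``ref_allele``/``alt_allele`` of unequal length encode indels; the alt
    symbol ``-`` denotes a pure deletion of the ref bases.
    """

    gene: str
    variant_id: str
    cds_pos: int
    ref_allele: str
    alt_allele: str
    exon: int = 0
    transcript_id: str = ""
    label: str = ""

    def __post_init__(self):
        if self.cds_pos < 1:
            raise ValueError(f"{self.variant_id}: cds_pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if not self.ref_allele:
            raise ValueError(f"{self.variant_id}: empty ref allele")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1 and self.alt_allele != "-"

    @property
    def is_deletion(self) -> bool:
        return self.alt_allele == "-" or len(self.alt_allele) < len(self.ref_allele)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.variant_id if self.variant_id != "NI" else f"NI:{self.cds_pos}")


@dataclass(frozen=True)
class CodingEffect:
    """Consequence of a variant on the encoded protein."""

    codon_number: int
    codon_position: int | None      # 1..3 for SNVs, None for indels
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str
    alt_aa: str
    effect_class: str               # synonymous | nonsynonymous | inframe_deletion | frameshift
    substitution_class: str         # transition | transversion | indel

    @property
    def is_synonymous(self) -> bool:
        return self.effect_class == "synonymous"


@dataclass(frozen=True)
class GenotypeCounts:
    """(hom-ref, het, hom-alt) tallies over non-missing samples."""

    n_rr: int
    n_ra: int
    n_aa: int

    def __post_init__(self):
        if min(self.n_rr, self.n_ra, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_rr + self.n_ra + self.n_aa

    @property
    def two_n(self) -> int:
        return 2 * self.n


@dataclass
class CohortGenotypes:
    """Sample x variant diploid calls with missingness.

    ``doses`` is an ``(n_samples, n_variants)`` int8 array of alt-allele
    doses with :data:`MISSING` for no-calls.
    """

    samples: list[str]
    variants: list[VariantDef]
    doses: np.ndarray

    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=np.int8)
        if self.doses.shape != (len(self.samples), len(self.variants)):
            raise ValueError("doses shape does not match samples x variants")
        bad = ~np.isin(self.doses, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("doses must be in {-1, 0, 1, 2}")
        self._index = {v.key: j for j, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate variants in cohort")

    # -- lookup -----------------------------------------------------------
    def column(self, variant: VariantDef) -> np.ndarray:
        try:
            return self.doses[:, self._index[variant.key]]
        except KeyError:
            raise VariantLookupError(
                f"variant {variant.gene}/{variant.variant_id} not in cohort"
            ) from None

    def variants_for_gene(self, gene: str) -> list[VariantDef]:
        return [v for v in self.variants if v.gene == gene]

    def gene_n(self, gene: str) -> int:
        """Samples with at least one non-missing call in ``gene``."""
        cols = [j for j, v in enumerate(self.variants) if v.gene == gene]
        if not cols:
            return 0
        return int((self.doses[:, cols] != MISSING).any(axis=1).sum())

    def subset_complete(self, variants: Sequence[VariantDef]) -> "CohortGenotypes":
        """Restrict to samples non-missing at every listed variant."""
        cols = [self._index[v.key] for v in variants]
        keep = (self.doses[:, cols] != MISSING).all(axis=1)
        return CohortGenotypes(
            [s for s, k in zip(self.samples, keep) if k],
            list(variants),
            self.doses[np.ix_(keep, cols)],
        )

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sample_id, gene, variant_id, allele1, allele2."""
        rows = []
        for i, s in enumerate(self.samples):
            for j, v in enumerate(self.variants):
                d = self.doses[i, j]
                if d == MISSING:
                    a1 = a2 = "."
                else:
                    a1 = v.ref_allele if d < 2 else v.alt_allele
                    a2 = v.alt_allele if d > 0 else v.ref_allele
                vid = v.variant_id if v.variant_id != "NI" else f"NI:{v.cds_pos}"
                rows.append((s, v.gene, vid, a1, a2))
        return pd.DataFrame(rows, columns=["sample_id", "gene", "variant_id", "allele1", "allele2"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ingest
# ---------------------------------------------------------------------------

def read_variant_table(path) -> list[VariantDef]:
    """Read a variant-definition TSV: gene, variant_id, transcript_id,
    cds_pos, ref, alt, exon."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "variant_id", "cds_pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeParseError(f"variant table missing columns: {sorted(missing)}")
    defs = []
    for _, row in df.iterrows():
        defs.append(VariantDef(
            gene=row["gene"],
            variant_id=row["variant_id"],
            cds_pos=int(row["cds_pos"]),
            ref_allele=row["ref"],
            alt_allele=row["alt"],
            exon=int(row.get("exon", 0) or 0),
            transcript_id=str(row.get("transcript_id", "") or ""),
            label=str(row.get("label", "") or row["variant_id"]),
        ))
    return defs


def _dose_from_alleles(a1: str, a2: str, v: VariantDef, where: str) -> int:
    pair = {a1, a2}
    if pair == {"."}:
        return MISSING
    dose = 0
    for a in (a1, a2):
        if a == v.alt_allele:
            dose += 1
        elif a != v.ref_allele:
            raise GenotypeParseError(
                f"{where}: allele {a!r} is neither ref ({v.ref_allele!r}) nor "
                f"alt ({v.alt_allele!r}) for {v.gene}/{v.variant_id}"
            )
    return dose


def read_genotype_table(path, variant_defs: Sequence[VariantDef]) -> CohortGenotypes:
    """Read a long-format genotype TSV into a cohort.

    Expected header: ``sample_id  gene  variant_id  allele1  allele2``.
    A pair of ``.`` alleles denotes a missing call; variants a sample has no
    row for are missing too.  Unknown variant ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "gene", "variant_id", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeParseError(f"genotype table missing columns: {sorted(missing)}")

    by_key: dict[tuple[str, str], VariantDef] = {}
    for v in variant_defs:
        # novel variants all share id "NI"; they are addressed positionally
        if v.variant_id != "NI":
            by_key[(v.gene, v.variant_id)] = v
        by_key[(v.gene, f"NI:{v.cds_pos}")] = v

    samples: list[str] = []
    sample_idx: dict[str, int] = {}
    vlist = list(variant_defs)
    vidx = {v.key: j for j, v in enumerate(vlist)}
    records: list[tuple[int, int, int]] = []

    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.gene, row.variant_id)
        if key not in by_key:
            raise GenotypeParseError(
                f"line {line_no}: unknown variant {row.gene}/{row.variant_id}"
            )
        v = by_key[key]
        dose = _dose_from_alleles(row.allele1, row.allele2, v, f"line {line_no}")
        if row.sample_id not in sample_idx:
            sample_idx[row.sample_id] = len(samples)
            samples.append(row.sample_id)
        records.append((sample_idx[row.sample_id], vidx[v.key], dose))

    doses = np.full((len(samples), len(vlist)), MISSING, dtype=np.int8)
    for i, j, d in records:
        doses[i, j] = d
    return CohortGenotypes(samples, vlist, doses)


def read_vcf_minimal(path, variant_defs: Sequence[VariantDef] | None = None) -> CohortGenotypes:
    """Read a minimal biallelic VCF with GT fields into a cohort.

    The convention for CDS-space VCFs written by this package: CHROM is the
    gene name, POS the 1-based CDS position, ID the variant id.  Phase
    separators (``/`` or ``|``) are both accepted and phase is ignored.
    Multi-allelic records are rejected with an instruction to split them.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise GenotypeParseError(f"{path}: VCF has no GT FORMAT definition")
    samples = list(vf.header.samples)

    by_id = {}
    if variant_defs is not None:
        for v in variant_defs:
            if v.variant_id != "NI":
                by_id[v.variant_id] = v
            by_id[f"NI:{v.cds_pos}"] = v
            by_id[f"{v.gene}:{v.cds_pos}"] = v

    vlist: list[VariantDef] = []
    columns: list[np.ndarray] = []
    offending = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            offending.append(f"{rec.chrom}:{rec.pos}")
            continue
        if variant_defs is not None:
            v = by_id.get(rec.id) or by_id.get(f"{rec.chrom}:{rec.pos}")
            if v is None:
                raise GenotypeParseError(
                    f"{path}: record {rec.chrom}:{rec.pos} ({rec.id}) matches no "
                    "declared variant"
                )
        else:
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) > 1 and len(alt) == 1 and ref.startswith(alt):
                # anchored deletion, e.g. ACAA>A: strip the anchor base
                ref, alt = ref[1:], "-"
            v = VariantDef(
                gene=rec.chrom,
                variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                cds_pos=rec.pos,
                ref_allele=ref,
                alt_allele=alt,
            )
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            col[i] = sum(1 for a in gt if a == 1)
        vlist.append(v)
        columns.append(col)
    if offending:
        raise GenotypeParseError(
            f"{path}: non-biallelic records {offending}; split multi-allelic "
            "sites (e.g. `bcftools norm -m-`) before ingest"
        )
    doses = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0), dtype=np.int8))
    return CohortGenotypes(samples, vlist, doses)


# ---------------------------------------------------------------------------
# Tallies and annotation
# ---------------------------------------------------------------------------

def count_genotypes(cohort: CohortGenotypes, variant: VariantDef) -> GenotypeCounts:
    """Tally (hom-ref, het, hom-alt) for one variant, excluding missing calls."""
    col = cohort.column(variant)
    return GenotypeCounts(
        int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
    )


def substitution_class(ref: str, alt: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    if len(ref) != 1 or len(alt) != 1:
        return "indel"
    same_family = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return "transition" if same_family else "transversion"


def annotate_coding_effect(cds: str, variant: VariantDef) -> CodingEffect:
    """Annotate a variant against a CDS sequence.

    SNVs report codon number ``ceil(pos/3)``, the within-codon position, both
    codons and amino acids, synonymous/nonsynonymous status and the
    transition/transversion class.  Deletions report in-frame vs frameshift
    by length and the first affected codon.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    pos = variant.cds_pos
    if not (1 <= pos <= len(cds)):
        raise ValueError(f"{variant.variant_id}: cds_pos {pos} outside CDS")
    found = cds[pos - 1: pos - 1 + len(variant.ref_allele)]
    if found != variant.ref_allele:
        raise CdsConsistencyError(
            f"{variant.gene}/{variant.variant_id} at CDS {pos}: expected ref "
            f"{variant.ref_allele!r}, found {found!r}"
        )

    codon_number = math.ceil(pos / 3)
    if variant.is_snv:
        codon_position = (pos - 1) % 3 + 1
        start = (codon_number - 1) * 3
        ref_codon = cds[start:start + 3]
        alt_codon = (ref_codon[:codon_position - 1] + variant.alt_allele
                     + ref_codon[codon_position:])
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
        return CodingEffect(codon_number, codon_position, ref_codon, alt_codon,
                            ref_aa, alt_aa, effect,
                            substitution_class(variant.ref_allele, variant.alt_allele))

    # deletion
    del_len = len(variant.ref_allele) - (0 if variant.alt_allele == "-" else len(variant.alt_allele))
    if del_len <= 0:
        raise ValueError(f"{variant.variant_id}: unsupported allele pair "
                         f"{variant.ref_allele}>{variant.alt_allele}")
    if del_len % 3 == 0:
        # translate the spanned region before/after deletion to name the lost aa
        first = (codon_number - 1) * 3
        last_codon = math.ceil((pos + len(variant.ref_allele) - 1) / 3)
        region = cds[first:last_codon * 3]
        mut_start = pos - 1 - first
        mutated = region[:mut_start] + region[mut_start + del_len:]
        ref_aa = str(Seq(region).translate())
        alt_aa = str(Seq(mutated).translate()) if mutated else "-"
        lost = _deleted_aa(ref_aa, alt_aa)
        return CodingEffect(codon_number, None, None, None, lost, "-",
                            "inframe_deletion", "indel")
    return CodingEffect(codon_number, None, None, None, "?", "?",
                        "frameshift", "indel")


def _deleted_aa(ref_aa: str, alt_aa: str) -> str:
    """Name the residues removed by an in-frame deletion (left-aligned)."""
    i = 0
    while i < len(alt_aa) and ref_aa[i] == alt_aa[i]:
        i += 1
    return ref_aa[i:i + (len(ref_aa) - len(alt_aa))] or ref_aa
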