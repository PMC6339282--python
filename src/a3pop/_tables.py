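"""Built-in study tables for the APOBEC3 South-African cohort analysis.

These are the published per-variant descriptors, genotype tallies, haplotype
category counts and reference-population allele frequencies that the fixture
generators and the default CLI run consume.  Everything downstream treats
them as ordinary input tables; user-supplied TSVs with the same schema can
replace any of them.

Conventions
-----------
* Coordinates are 1-based nucleotide positions within the coding sequence
  (CDS) of the per-gene transcript listed in ``TRANSCRIPTS``.
* Genotypes are stored as alt-allele dose: 0 = hom-ref, 1 = het, 2 = hom-alt.
* The A3H N15 deletion is a biallelic indel: ref allele ``CAA`` (asparagine
  retained), alt allele ``-`` (3-bp deletion).
"""

from __future__ import annotations

GENES = ("A3D", "A3F", "A3G", "A3H")

TRANSCRIPTS = {
    "A3D": "ENST00000216099",
    "A3F": "ENST00000308521",   # isoform 201; Q87L is numbered on isoform 202
    "A3F-202": "ENST00000381565",
    "A3G": "ENST00000407997",
    "A3H": "ENST00000442487",
}

#: CDS length in amino acids per transcript (stop codon added separately).
TRANSCRIPT_AA_LEN = {
    "ENST00000216099": 386,
    "ENST00000308521": 373,
    "ENST00000381565": 101,
    "ENST00000407997": 384,
    "ENST00000442487": 183,
}

#: gene, label, variant_id, transcript, cds_pos, exon, ref, alt, ref_codon,
#: (n_homref, n_het, n_homalt), synonymous?
#: ref_codon is the reference codon containing the variant (None for indels).
VARIANT_TABLE = [
    # --- A3D (n = 168) ---
    ("A3D", "R6K",   "NI",          "ENST00000216099",   17, 1, "G", "A", "AGA", (151, 17, 0), False),
    ("A3D", "R97C",  "rs75858538",  "ENST00000216099",  289, 1, "C", "T", "CGC", (148, 19, 1), False),
    ("A3D", "L221R", "NI",          "ENST00000216099",  662, 5, "T", "G", "CTG", (165, 3, 0),  False),
    ("A3D", "C224Y", "rs772893975", "ENST00000216099",  671, 5, "G", "A", "TGT", (161, 7, 0),  False),
    ("A3D", "T238A", "rs201709403", "ENST00000216099",  712, 5, "A", "G", "ACA", (154, 14, 0), False),
    ("A3D", "T238I", "NI",          "ENST00000216099",  713, 5, "C", "T", "ACA", (160, 8, 0),  False),
    ("A3D", "R248K", "rs61748819",  "ENST00000216099",  743, 5, "G", "A", "AGG", (133, 33, 2), False),
    ("A3D", "C320Y", "rs61999342",  "ENST00000216099",  959, 6, "G", "A", "TGC", (167, 1, 0),  False),
    ("A3D", "L221L", "rs769426665", "ENST00000216099",  663, 5, "G", "C", "CTG", (165, 3, 0),  True),
    ("A3D", "T316T", "rs184448269", "ENST00000216099",  948, 6, "C", "T", "ACC", (161, 7, 0),  True),
    # --- A3F (n = 154) ---
    ("A3F", "R48P",  "rs35053197",  "ENST00000308521",  143, 2, "G", "C", "CGT", (142, 12, 0), False),
    ("A3F", "A78V",  "rs5750728",   "ENST00000308521",  233, 4, "C", "T", "GCC", (95, 56, 3),  False),
    ("A3F", "I87L",  "rs146543452", "ENST00000308521",  259, 4, "A", "C", "ATC", (153, 1, 0),  False),
    ("A3F", "Q87L",  "rs114704208", "ENST00000381565",  260, 3, "A", "T", "CAG", (145, 9, 0),  False),
    ("A3F", "A108S", "rs2020390",   "ENST00000308521",  322, 4, "G", "T", "GCT", (54, 84, 16), False),
    ("A3F", "V231I", "rs2076101",   "ENST00000308521",  691, 5, "G", "A", "GTC", (122, 30, 2), False),
    ("A3F", "Y307C", "rs12157816",  "ENST00000308521",  920, 6, "A", "G", "TAC", (139, 15, 0), False),
    ("A3F", "I117I", "NI",          "ENST00000308521",  351, 4, "C", "T", "ATC", (152, 2, 0),  True),
    ("A3F", "S118S", "rs35928287",  "ENST00000308521",  354, 4, "C", "T", "TCC", (113, 41, 0), True),
    ("A3F", "R143R", "rs4821862",   "ENST00000308521",  429, 4, "C", "T", "CGC", (19, 91, 44), True),
    ("A3F", "Y196Y", "rs765418322", "ENST00000308521",  588, 4, "T", "C", "TAT", (126, 24, 4), True),
    ("A3F", "S229S", "rs549550231", "ENST00000308521",  687, 5, "A", "G", "TCA", (152, 2, 0),  True),
    ("A3F", "E245E", "rs113109079", "ENST00000308521",  735, 5, "G", "A", "GAG", (146, 7, 1),  True),
    ("A3F", "S327S", "rs35895636",  "ENST00000308521",  981, 5, "C", "T", "TCC", (128, 23, 3), True),
    # --- A3G (n = 165) ---
    ("A3G", "H186R", "rs8177832",   "ENST00000407997",  557, 4, "A", "G", "CAC", (63, 82, 20), False),
    ("A3G", "R256H", "rs17000736",  "ENST00000407997",  767, 6, "G", "A", "CGC", (161, 4, 0),  False),
    ("A3G", "Q275E", "rs17496046",  "ENST00000407997",  823, 6, "C", "G", "CAG", (111, 49, 5), False),
    ("A3G", "G363R", "rs148267053", "ENST00000407997", 1087, 7, "G", "A", "GGA", (148, 17, 0), False),
    ("A3G", "S60S",  "rs112603901", "ENST00000407997",  180, 3, "C", "T", "TCC", (147, 18, 0), True),
    ("A3G", "A109A", "rs375760983", "ENST00000407997",  327, 3, "C", "T", "GCC", (164, 1, 0),  True),
    ("A3G", "F119F", "rs5757465",   "ENST00000407997",  357, 3, "T", "C", "TTT", (164, 1, 0),  True),
    ("A3G", "L371L", "rs11545130",  "ENST00000407997", 1111, 7, "C", "T", "CTG", (158, 7, 0),  True),
    # --- A3H (n = 133) ---
    ("A3H", "N15del","rs140936762", "ENST00000442487",   45, 1, "CAA", "-", None, (29, 49, 55), False),
    ("A3H", "R18L",  "rs139293",    "ENST00000442487",   53, 1, "G", "T", "CGC", (112, 15, 6), False),
    ("A3H", "G105R", "rs139297",    "ENST00000442487",  313, 2, "G", "C", "GGC", (1, 4, 128),  False),
    ("A3H", "K121E", "rs139298",    "ENST00000442487",  361, 2, "A", "G", "AAG", (1, 6, 126),  False),
    ("A3H", "K140E", "rs139300",    "ENST00000442487",  418, 3, "A", "G", "AAG", (0, 0, 133),  False),
    ("A3H", "E178D", "rs139302",    "ENST00000442487",  534, 4, "G", "C", "GAG", (3, 11, 119), False),
    ("A3H", "T43T",  "rs139294",    "ENST00000442487",  129, 1, "G", "C", "ACG", (6, 7, 120),  True),
]

#: Number of successfully sequenced subjects per gene (out of 192 recruited).
GENE_N = {"A3D": 168, "A3F": 154, "A3G": 165, "A3H": 133}
N_RECRUITED = 192

# ---------------------------------------------------------------------------
# Haplotype machinery configuration
# ---------------------------------------------------------------------------

#: Sites (CDS positions) used for haplotype assignment per gene.  These
#: reproduce the published site choices, which follow the MAF >= 5% rule with
#: documented exceptions (T238A at 4.2% is kept for A3D; A3F keeps the full
#: printed site list; A3H always uses the five canonical sites and never 140).
FORCED_SITES = {
    "A3D": (289, 712, 743),
    "A3F": (143, 233, 259, 322, 691, 920),
    "A3G": (),                      # plain MAF rule suffices
    "A3H": (45, 53, 313, 361, 534),
}

#: Variants never used for assignment even when common: novel (no rsID) sites
#: and the A3H K140E site (fixed hom-alt everywhere; suspected reference-
#: genome error).
EXCLUDED_SITES = {
    "A3D": (17, 662, 713),
    "A3F": (351,),
    "A3G": (),
    "A3H": (418,),
}

#: Named haplotypes: gene -> label -> {cds_pos: per-haplotype alt dose (0/1)}.
#: Sites absent from a mapping carry the reference allele.  Label "i" is the
#: reference combination for every gene.
HAPLOTYPE_TABLE = {
    "A3D": {
        "i": {}, "ii": {289: 1}, "iii": {712: 1}, "iv": {743: 1},
    },
    "A3F": {
        "i": {}, "iii": {322: 1}, "iv": {920: 1}, "vi": {233: 1, 322: 1},
    },
    "A3G": {
        "i": {}, "ii": {557: 1}, "iii": {823: 1}, "iv": {1087: 1},
    },
    "A3H": {
        "i": {},
        "ii": {313: 1, 361: 1, 534: 1},
        "iii": {45: 1, 313: 1, 361: 1, 534: 1},
        "iv": {45: 1, 53: 1, 313: 1, 361: 1, 534: 1},
        "x": {45: 1, 313: 1, 361: 1},
    },
}

#: A3H protein-stability classes.  Haplotypes II, V and VII encode proteins
#: with long half-lives able to restrict HIV-1; I, III, IV and VI are
#: degraded rapidly; any haplotype carrying the N15 deletion is unstable.
#: Everything else is of unknown stability.
A3H_STABLE = frozenset({"ii", "v", "vii"})
A3H_UNSTABLE = frozenset({"i", "iii", "iv", "vi"})
A3H_DELETION_SITE = 45

# ---------------------------------------------------------------------------
# Published per-individual haplotype categories (Table-3-style), per gene:
# (count, {cds_pos: alt dose at assignment sites}, expected diplotype or None,
#  {cds_pos: dose} extras at excluded/minor sites carried by these samples)
# ---------------------------------------------------------------------------

HAPLOTYPE_CATEGORIES = {
    "A3D": [
        (88, {}, "i/i", {}),
        (1, {289: 2}, "ii/ii", {}),
        (18, {289: 1}, "i/ii", {}),
        (10, {712: 1}, "i/iii", {}),
        (1, {743: 2}, "iv/iv", {}),
        (27, {743: 1}, "i/iv", {}),
        (7, {}, None, {671: 1}),    # minor-variant carriers (C224Y het)
        (16, {}, None, {17: 1}),    # others: novel R6K het
    ],
    "A3F": [
        (5, {}, "i/i", {}),
        (2, {322: 2}, "iii/iii", {}),
        (32, {322: 1}, "i/iii", {}),
        (5, {920: 1}, "i/iv", {}),
        (1, {233: 2, 322: 2}, "vi/vi", {}),
        (2, {233: 1, 322: 2}, "iii/vi", {}),
        (5, {}, None, {260: 1}),    # minor-variant carriers (Q87L het)
        (51, {}, None, {429: 1}),   # others: synonymous R143R het
        (21, {233: 1, 322: 1}, None, {}),            # unconfirmed (2 het)
        (14, {233: 1, 322: 1, 691: 1}, None, {}),    # unconfirmed (3 het)
        (8, {233: 1, 322: 2, 691: 1}, None, {}),     # unconfirmed (2 het)
        (2, {233: 1, 322: 1, 691: 2}, None, {}),     # unconfirmed (2 het)
        (6, {143: 1, 322: 1}, None, {}),             # unconfirmed (2 het)
    ],
    "A3G": [
        (5, {}, "i/i", {}),
        (20, {557: 2}, "ii/ii", {}),
        (43, {557: 1}, "i/ii", {}),
        (3, {823: 2}, "iii/iii", {}),
        (22, {823: 1}, "i/iii", {}),
        # printed as "iv/iv" but the 363R heterozygote implies i/iv
        (9, {1087: 1}, "i/iv", {}),
        (11, {}, None, {767: 1}),   # minor-variant carriers (R256H het)
        (52, {}, None, {180: 1}),   # others: synonymous S60S het
    ],
    "A3H": [
        (38, {313: 2, 361: 2, 534: 2}, "ii/ii", {418: 2}),
        (25, {45: 2, 313: 2, 361: 2}, "x/x", {418: 2}),
        (36, {45: 1, 313: 2, 361: 2, 534: 2}, "ii/iii", {418: 2}),
        (6, {45: 2, 53: 2, 313: 2, 361: 2, 534: 2}, "iv/iv", {418: 2}),
        (7, {45: 2, 53: 1, 313: 2, 361: 2, 534: 2}, "iii/iv", {418: 2}),
        # others: synonymous T43T carriers on a iii/iii background
        (10, {45: 2, 313: 2, 361: 2, 534: 2}, "iii/iii", {418: 2, 129: 1}),
        (4, {45: 1, 313: 2, 361: 1, 534: 2}, None, {418: 2}),   # unconfirmed
        (7, {45: 1, 53: 1, 313: 2, 361: 2, 534: 2}, None, {418: 2}),
    ],
}

# ---------------------------------------------------------------------------
# Reference-population allele frequencies (alt %, as published; None = not
# identified / not determined in the reference panel).
# ---------------------------------------------------------------------------

SUPERPOPULATION_2N = {
    "EAS": 1008, "EUR": 1006, "AFR": 1322, "AMR": 694, "SAS": 978,
    "ExAC": 121412,
}

#: label -> (EAS, EUR, AFR, AMR, SAS, ExAC) alt-allele percentages.
REFERENCE_ALT_PCT = {
    "R6K":   (None, None, None, None, None, None),
    "R97C":  (0, 0, 3.4, 0, 0, 0.3),
    "L221R": (None, None, None, None, None, None),
    "C224Y": (None, None, None, None, None, 0),
    "T238A": (0, 0, 0, 0, 0, 0),
    "T238I": (None, None, None, None, None, None),
    "R248K": (0, 0, 11.0, 1.0, 0, 1.0),
    "C320Y": (None, None, None, None, None, 0),
    "L221L": (None, None, None, None, None, 0),
    "T316T": (0, 0, 1.2, 0.4, 0, 0.1),
    "R48P":  (0, 0, 3.1, 0.6, 0.6, 0.3),
    "A78V":  (71, 49, 20, 62, 61, 47.8),
    "I87L":  (0, 0, 1.0, 0, 0, 0),
    "Q87L":  (0, 0, 5.5, 0.4, 0, 0.3),
    "A108S": (71.0, 49.0, 32.0, 63.0, 60.0, 47.6),
    "V231I": (71.0, 49.0, 19.0, 62.0, 61.0, 51.6),
    "Y307C": (0, 2.0, 3.0, 2.0, 0, 1.3),
    "I117I": (None, None, None, None, None, None),
    "S118S": (None, None, None, None, None, 0.3),
    "R143R": (71.0, 49.0, 55.0, 64.0, 61.0, 54.6),
    "Y196Y": (None, None, None, None, None, 0),
    "S229S": (None, None, None, None, None, 0),
    "E245E": (0, 0, 1.0, 0, 0, 0),
    "S327S": (0, 0, 1.7, 0, 0, 0.2),
    "H186R": (7.2, 3.0, 43.0, 7.5, 0.8, 6.4),
    "R256H": (0, 0, 1.4, 0, 0, 0),
    "Q275E": (2.7, 5.4, 12.5, 4.0, 1.3, 5.7),
    "G363R": (0, 0, 1.4, 0.1, 0, 0),
    "S60S":  (0, 0, 0.3, 0, 0, 0),
    "A109A": (None, None, None, None, None, 0),
    "F119F": (22.4, 44.7, 2.9, 39.8, 44.5, 37.2),
    "L371L": (0, 0, 3.0, 0.4, 0, 0.3),
    "N15del": (26, 34, 31, 28, 40, 34.3),
    "R18L":  (15.9, 29.3, 7.0, 24.2, 30.6, 26.8),
    "G105R": (31.5, 46.4, 87.5, 38.3, 42.9, 48.1),
    "K121E": (31.5, 47.7, 87.5, 38.8, 43.9, 48.5),
    "K140E": (100, 100, 100, 100, 100, 100),
    "E178D": (33.0, 45.4, 84.7, 34.6, 43.9, 47.7),
    "T43T":  (33.3, 45.4, 82.8, 38.0, 44.0, 47.6),
}

POP_ORDER = ("EAS", "EUR", "AFR", "AMR", "SAS", "ExAC")
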