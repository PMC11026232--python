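"""Variant definitions for the five candidate loci.

Four biallelic SNPs genotyped by TaqMan qPCR (rs1024905, rs6724624, rs5443,
rs2651899) and the tri-allelic 5-HTTLPR/rs25531 promoter system of the
serotonin transporter gene, genotyped by PCR-RFLP.  The 5-HTTLPR long (L)
allele carries a 43 bp insertion absent from the short (S) allele; rs25531
splits L into L_A and L_G, with L_G transcriptionally similar to S.

``REFERENCE_ALLELE_COUNTS`` holds the published user/non-user allele counts
of the source cohort (545 genotyped cluster headache patients; 409 triptan
users, 109 non-users after excluding tablet-only users).  They seed the
synthetic-cohort generator's default allele frequencies and serve as a
cross-check fixture for the counting and odds-ratio arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class VariantDef:
    """Identity and genotype space of one analysed variant.

    Parameters
    ----------
    variant_id : str
        rs identifier, or ``"5-HTTLPR"`` for the promoter indel system.
    alleles : tuple of str
        Allele symbols in descending default (pooled) frequency order.
    chrom, pos : str, int
        Nominal coordinates used for VCF export.  Positions are placeholder
        coordinates that preserve ordering, not genome-build positions.
    triallelic : bool
        True only for the 5-HTTLPR/rs25531 system.
    """

    variant_id: str
    alleles: tuple[str, ...]
    chrom: str = "."
    pos: int = 0
    triallelic: bool = False

    def genotype_space(self) -> list[tuple[str, str]]:
        """All unordered diploid genotypes over the allele set."""
        out = []
        for i, a in enumerate(self.alleles):
            for b in self.alleles[i:]:
                out.append((a, b))
        return out


SNP_IDS = ("rs1024905", "rs6724624", "rs5443", "rs2651899")
HTTLPR = "5-HTTLPR"
VARIANT_IDS = SNP_IDS + (HTTLPR,)

VARIANTS: dict[str, VariantDef] = {
    "rs1024905": VariantDef("rs1024905", ("G", "C"), chrom="12", pos=2000),
    "rs6724624": VariantDef("rs6724624", ("C", "G"), chrom="2", pos=1000),
    "rs5443": VariantDef("rs5443", ("C", "T"), chrom="12", pos=1000),
    "rs2651899": VariantDef("rs2651899", ("T", "C"), chrom="1", pos=1000),
    HTTLPR: VariantDef(HTTLPR, ("L_A", "S", "L_G"), triallelic=True),
}

# Published allele counts, (triptan users, triptan non-users) per allele.
REFERENCE_ALLELE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "rs1024905": {"G": (435, 89), "C": (379, 125)},
    "rs6724624": {"C": (634, 179), "G": (170, 35)},
    "rs5443": {"C": (577, 152), "T": (235, 62)},
    "rs2651899": {"T": (475, 128), "C": (331, 88)},
    # bi-allelic recoding: presence (L) / absence (S) of the 43 bp insertion
    "5-HTTLPR:biallelic": {"L": (465, 110), "S": (329, 106)},
    # collapsed tri-allelic recoding: L_A vs (L_G grouped with S)
    "5-HTTLPR:collapsed": {"L_A": (415, 101), "S*": (379, 115)},
}

# Published sex-adjusted additive odds ratios (effect allele = pooled minor),
# used only as cross-check values in tests and reports.
REFERENCE_ADJUSTED_OR: dict[str, float] = {
    "rs1024905": 1.609,
    "rs6724624": 0.733,
    "rs5443": 1.014,
    "rs2651899": 0.986,
    "5-HTTLPR:biallelic": 1.342,
    "5-HTTLPR:collapsed": 1.240,
}


def pooled_frequencies() -> dict[str, dict[str, float]]:
    """Default allele frequencies: pooled user+non-user proportions.

    For the tri-allelic system the L_A and S frequencies come from the
    collapsed and bi-allelic tables respectively and the L_G frequency is the
    only derivable remainder, (bi-allelic L) − (tri-allelic L_A).
    """
    freqs: dict[str, dict[str, float]] = {}
    for vid in SNP_IDS:
        counts = {a: u + n for a, (u, n) in REFERENCE_ALLELE_COUNTS[vid].items()}
        tot = sum(counts.values())
        freqs[vid] = {a: c / tot for a, c in counts.items()}
    la = sum(REFERENCE_ALLELE_COUNTS["5-HTTLPR:collapsed"]["L_A"])
    l_bi = sum(REFERENCE_ALLELE_COUNTS["5-HTTLPR:biallelic"]["L"])
    s = sum(REFERENCE_ALLELE_COUNTS["5-HTTLPR:biallelic"]["S"])
    tot = l_bi + s
    freqs[HTTLPR] = {"L_A": la / tot, "L_G": (l_bi - la) / tot, "S": s / tot}
    return freqs
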