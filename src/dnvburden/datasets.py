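"""Small bundled example datasets.

The worked example used throughout the documentation and tests is the set
of five de novo *TRIO* variants reported in a congenital
ventriculomegaly / hydrocephalus cohort of 2,697 proband–parent trios
(GRCh37 coordinates, transcript NM_003074.4, protein NP_003065.3), together
with the UniProt (O75962) domain architecture of the 3,097-residue TRIO
protein that the variants are mapped onto.
"""

from __future__ import annotations

from .mutmap import DomainAnnotation
from .variants import AnnotatedDNV, parse_protein_position

__all__ = [
    "trio_cv_dnvs",
    "TRIO_PROTEIN_LENGTH",
    "TRIO_DH1_DOMAIN",
    "TRIO_COHORT_N",
]

#: Number of proband-parent trios in the cohort the example variants come from.
TRIO_COHORT_N = 2697

#: Length of the human TRIO protein (UniProt O75962).
TRIO_PROTEIN_LENGTH = 3097

#: The DH1 subdomain of TRIO's Ras-GEF1 catalytic region (closed residue
#: interval), where protein-damaging de novo variants cluster.
TRIO_DH1_DOMAIN: "DomainAnnotation"

_TRIO_CV_ROWS = [
    # proband_id, chrom, pos, ref, alt, protein_change, cadd, mpc, pop_maf
    ("9407016", "5", 14388735, "G", "A", "p.(Glu1299Lys)", 34.0, 2.0711495, None),
    ("6755562", "5", 14388736, "A", "G", "p.(Glu1299Gly)", 33.0, 2.1058088, None),
    ("2053950", "5", 14390392, "C", "A", "p.(His1371Asn)", 33.0, 2.0407752, None),
    ("8449411", "5", 14394220, "A", "T", "p.(Lys1431Met)", 32.0, 2.2356751, None),
    ("4149673", "5", 14482773, "G", "T", "p.(Cys2183Phe)", 16.78, 0.4605982, 4.09e-06),
]


def trio_cv_dnvs() -> list[AnnotatedDNV]:
    """The five de novo *TRIO* missense variants from the CV/CH cohort.

    All five are missense; their damaging/non-damaging split is *not*
    stored here — it is recomputed by :func:`dnvburden.classify.classify_variant`
    from the MPC scores.
    """
    return [
        AnnotatedDNV(
            proband_id=pid,
            gene="TRIO",
            consequence="missense",
            transcript="NM_003074.4",
            protein_change=pchange,
            protein_pos=parse_protein_position(pchange),
            mpc=mpc,
            cadd=cadd,
            pop_maf=maf,
            chrom=chrom,
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
        )
        for pid, chrom, pos, ref, alt, pchange, cadd, mpc, maf in _TRIO_CV_ROWS
    ]


TRIO_DH1_DOMAIN = DomainAnnotation(
    name="Ras-GEF1 DH1",
    start=1292,
    end=1467,
    source="UniProt O75962",
)
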