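"""Core data model for trio-based de novo variant (DNV) analysis.

A *trio* is a proband sequenced together with both biological parents.  A
candidate DNV is a variant called in the proband and absent from both
parents; whether a candidate survives depends on the sequencing evidence
carried here (read depths, allele fractions, genotype qualities, and
site-level quality annotations such as VQSLOD and strand-bias FS).

This module defines the shared in-memory types:

* :class:`TrioSiteRecord` — one decomposed ALT allele at one site with the
  per-member evidence the filter cascades gate on;
* :class:`AnnotatedDNV` — a candidate joined to functional annotation
  (gene, consequence, MetaSVM/MPC/CADD, population frequency, protein
  position);
* :class:`VariantClass` — the damaging-variant classification label;
* :class:`MutationRateTable` — per-gene, per-class de novo mutation
  probabilities p_{g,c} (probability of a de novo event per chromosome per
  generation), the basis of all expected-count arithmetic;

plus readers/writers for the standard carriers: VCF 4.2 via :mod:`pysam`
and tab-separated rate/annotation tables via :mod:`pandas`.

Conventions: VCF coordinates are 1-based; protein positions are 1-based;
absent annotations are represented as ``None``, never as sentinel numbers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ConfigurationError",
    "ParseError",
    "ValidationError",
    "MemberEvidence",
    "TrioSiteRecord",
    "AnnotatedDNV",
    "VariantClass",
    "MutationRateTable",
    "TRIO_MEMBERS",
    "ATOMIC_CLASSES",
    "CLASS_GROUPS",
    "LOF_CONSEQUENCES",
    "normalize_chrom",
    "is_autosome",
    "parse_protein_position",
    "read_trio_vcf",
    "write_trio_vcf",
    "read_trio_genotypes",
    "read_rate_table",
    "write_rate_table",
    "read_annotation_table",
    "write_annotation_table",
]


class ConfigurationError(ValueError):
    """Raised when inputs are wired together inconsistently (e.g. a sample
    name missing from a VCF header)."""


class ParseError(ValueError):
    """Raised when a record in an input file cannot be interpreted."""


class ValidationError(ValueError):
    """Raised when a value violates a documented invariant."""


TRIO_MEMBERS = ("proband", "mother", "father")

#: Atomic consequence classes used throughout: predicted loss-of-function,
#: damaging missense, other missense, synonymous.
ATOMIC_CLASSES = ("lof", "misD", "mis", "synonymous")

#: Composite class groups, expressed in terms of atomic classes.  A
#: class-resolved rate table composes additively over these.
CLASS_GROUPS: dict[str, tuple[str, ...]] = {
    "lof": ("lof",),
    "misD": ("misD",),
    "mis": ("mis",),
    "synonymous": ("synonymous",),
    "protein_altering": ("lof", "misD", "mis"),
    "protein_damaging": ("lof", "misD"),
}

#: Consequences treated as predicted loss-of-function.
LOF_CONSEQUENCES = frozenset(
    {"stop-gain", "stop-loss", "frameshift", "canonical-splice", "start-loss"}
)

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so that ``chr5`` and ``5`` compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOMES


@dataclass(frozen=True)
class MemberEvidence:
    """Sequencing evidence for one trio member at one site.

    ``None`` means the field was absent from the call, which downstream
    filters treat conservatively (an absent value fails any threshold that
    gates on it).
    """

    total_depth: int | None = None
    alt_depth: int | None = None
    genotype_quality: float | None = None

    def __post_init__(self) -> None:
        if self.total_depth is not None and self.total_depth < 0:
            raise ValidationError(f"negative total_depth: {self.total_depth}")
        if self.alt_depth is not None:
            if self.alt_depth < 0:
                raise ValidationError(f"negative alt_depth: {self.alt_depth}")
            if self.total_depth is not None and self.alt_depth > self.total_depth:
                raise ValidationError(
                    f"alt_depth {self.alt_depth} exceeds total_depth {self.total_depth}"
                )

    @property
    def alt_fraction(self) -> float | None:
        """Alternate allele fraction; defined only when total_depth > 0."""
        if self.total_depth is None or self.alt_depth is None or self.total_depth == 0:
            return None
        return self.alt_depth / self.total_depth


@dataclass(frozen=True)
class TrioSiteRecord:
    """One candidate variant site, decomposed to a single ALT allele."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    proband: MemberEvidence = field(default_factory=MemberEvidence)
    mother: MemberEvidence = field(default_factory=MemberEvidence)
    father: MemberEvidence = field(default_factory=MemberEvidence)
    vqslod: float | None = None
    fisher_strand: float | None = None
    region_class: str | None = None  # "exonic" | "splice-site" | "other"
    cohort_recurrence: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"ref == alt ({self.ref_allele}) at {self.chrom}:{self.pos}")

    def member(self, name: str) -> MemberEvidence:
        if name not in TRIO_MEMBERS:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def is_autosomal(self) -> bool:
        return is_autosome(self.chrom)

    @property
    def is_length_change(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Join key used to look up annotations: (chrom, pos, ref, alt)."""
        return (normalize_chrom(self.chrom), self.pos, self.ref_allele, self.alt_allele)


_PROTEIN_POS_RE = re.compile(r"(\d+)")


def parse_protein_position(protein_change: str | None) -> int | None:
    """Extract the residue index from an HGVS-style protein change.

    ``p.(Glu1299Lys)`` -> 1299.  Returns ``None`` when no residue number is
    present.
    """
    if not protein_change:
        return None
    m = _PROTEIN_POS_RE.search(protein_change)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class AnnotatedDNV:
    """A candidate DNV joined to its functional annotation."""

    proband_id: str
    gene: str
    consequence: str  # missense, stop-gain, ..., synonymous, other
    transcript: str | None = None
    cdna_change: str | None = None
    protein_change: str | None = None
    protein_pos: int | None = None
    metasvm: str | None = None  # "deleterious" | "tolerated" | None
    mpc: float | None = None
    cadd: float | None = None
    pop_maf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValidationError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if self.mpc is not None and self.mpc < 0:
            raise ValidationError(f"mpc must be >= 0, got {self.mpc}")
        if self.pop_maf is not None and not (0.0 <= self.pop_maf <= 1.0):
            raise ValidationError(f"pop_maf outside [0, 1]: {self.pop_maf}")
        if self.metasvm is not None and self.metasvm not in ("deleterious", "tolerated"):
            raise ValidationError(f"unknown metasvm call: {self.metasvm!r}")

    @property
    def key(self) -> tuple[str, int, str, str] | None:
        if self.chrom is None or self.pos is None or self.ref_allele is None or self.alt_allele is None:
            return None
        return (normalize_chrom(self.chrom), self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class VariantClass:
    """Damaging-variant classification of a single DNV.

    ``protein_altering`` is true for LoF and any missense;
    ``protein_damaging`` is true for LoF and damaging missense (misD).
    """

    label: str  # one of ATOMIC_CLASSES or "other"

    def __post_init__(self) -> None:
        if self.label not in ATOMIC_CLASSES and self.label != "other":
            raise ValidationError(f"unknown class label: {self.label!r}")

    @property
    def protein_altering(self) -> bool:
        return self.label in ("lof", "misD", "mis")

    @property
    def protein_damaging(self) -> bool:
        return self.label in ("lof", "misD")


class MutationRateTable:
    """Per-gene, per-class de novo mutation probabilities.

    Each row gives p_{g,c}: the probability of a de novo event of class *c*
    in gene *g* per chromosome per generation.  The expected count of DNVs
    of class *c* in gene *g* across a cohort of N probands is 2·N·p_{g,c}
    (two transmitted haplotypes per proband).

    The *gene universe size* G (used for multiple-testing correction)
    defaults to the number of distinct genes in the table but can be
    overridden, e.g. to the 19,347-gene universe of genome-wide rate
    models, when the table at hand is a subset.
    """

    def __init__(
        self,
        probabilities: Mapping[tuple[str, str], float],
        n_genes: int | None = None,
    ) -> None:
        probs: dict[tuple[str, str], float] = {}
        per_gene: dict[str, float] = {}
        for (gene, cls), p in probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability outside [0, 1] for {(gene, cls)}: {p}")
            if (gene, cls) in probs:
                raise ValidationError(f"duplicate (gene, class) row: {(gene, cls)}")
            probs[(gene, cls)] = float(p)
            per_gene[gene] = per_gene.get(gene, 0.0) + p
        if not probs:
            raise ValidationError("empty mutation rate table")
        for gene, total in per_gene.items():
            if total > 1.0 + 1e-12:
                raise ValidationError(f"class probabilities for {gene} sum to {total} > 1")
        self._probs = probs
        self._genes = frozenset(g for g, _ in probs)
        if n_genes is None:
            n_genes = len(self._genes)
        if n_genes <= 0:
            raise ValidationError(f"gene universe size must be > 0, got {n_genes}")
        self.n_genes = int(n_genes)

    @property
    def genes(self) -> frozenset[str]:
        return self._genes

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def probability(self, gene: str, class_group: str, missing: str = "error") -> float:
        """p_{g, class_group}; composite groups sum their atomic components.

        ``missing`` controls behaviour for genes absent from the table:
        ``"error"`` raises, ``"zero"`` returns 0.0.
        """
        if class_group not in CLASS_GROUPS:
            raise ValidationError(f"unknown class group: {class_group!r}")
        if gene not in self._genes:
            if missing == "zero":
                return 0.0
            raise KeyError(f"gene not in rate table: {gene!r}")
        # A direct row for the composite label wins when present.
        if (gene, class_group) in self._probs:
            return self._probs[(gene, class_group)]
        return sum(self._probs.get((gene, c), 0.0) for c in CLASS_GROUPS[class_group])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "class": c, "probability": p}
            for (g, c), p in sorted(self._probs.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "class", "probability"])


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

_INFO_REGION = "REGION"
_INFO_RECURRENCE = "RECUR"


def _none_if_missing(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


def _member_evidence(sample, alt_index: int) -> MemberEvidence:
    ad = sample.get("AD")
    alt_depth = None
    if ad is not None and len(ad) > alt_index + 1:
        alt_depth = _none_if_missing(ad[alt_index + 1])
    dp = _none_if_missing(sample.get("DP"))
    if dp is None and ad is not None and all(a is not None for a in ad):
        dp = int(sum(ad))
    gq = _none_if_missing(sample.get("GQ"))
    # Guard against callers emitting AD entries exceeding DP (can happen with
    # split multi-allelics); cap rather than reject.
    if dp is not None and alt_depth is not None and alt_depth > dp:
        dp = int(alt_depth)
    return MemberEvidence(
        total_depth=int(dp) if dp is not None else None,
        alt_depth=int(alt_depth) if alt_depth is not None else None,
        genotype_quality=float(gq) if gq is not None else None,
    )


def read_trio_vcf(
    path: str | Path,
    sample_map: Mapping[str, str],
) -> Iterator[TrioSiteRecord]:
    """Stream :class:`TrioSiteRecord` from a multi-sample VCF.

    ``sample_map`` maps the roles ``proband``/``mother``/``father`` to
    sample names in the VCF header.  Multi-allelic sites are decomposed:
    one record is yielded per ALT allele, each carrying that allele's own
    alt depth.  Missing FORMAT/INFO fields map to ``None``.
    """
    missing_roles = [m for m in TRIO_MEMBERS if m not in sample_map]
    if missing_roles:
        raise ConfigurationError(f"sample_map lacks roles: {missing_roles}")
    with pysam.VariantFile(str(path)) as vf:
        header_samples = set(vf.header.samples)
        for role in TRIO_MEMBERS:
            if sample_map[role] not in header_samples:
                raise ConfigurationError(
                    f"sample {sample_map[role]!r} (role {role}) not in VCF header"
                )
        for n, rec in enumerate(vf, start=1):
            try:
                yield from _decompose_record(rec, sample_map)
            except (ValidationError, ValueError, KeyError) as exc:
                raise ParseError(f"malformed VCF record #{n} at {rec.chrom}:{rec.pos}: {exc}") from exc


def _info_get(info, key):
    # pysam raises for INFO keys that the header does not declare
    try:
        return _none_if_missing(info.get(key))
    except (KeyError, ValueError):
        return None


def _decompose_record(rec, sample_map) -> Iterator[TrioSiteRecord]:
    info = rec.info
    vqslod = _info_get(info, "VQSLOD")
    fs = _info_get(info, "FS")
    region = _info_get(info, _INFO_REGION)
    recur = _info_get(info, _INFO_RECURRENCE)
    for i, alt in enumerate(rec.alts or ()):
        evidence = {
            role: _member_evidence(rec.samples[sample_map[role]], i)
            for role in TRIO_MEMBERS
        }
        yield TrioSiteRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref_allele=rec.ref,
            alt_allele=alt,
            vqslod=float(vqslod) if vqslod is not None else None,
            fisher_strand=float(fs) if fs is not None else None,
            region_class=str(region) if region is not None else None,
            cohort_recurrence=int(recur) if recur is not None else None,
            **evidence,
        )


def _vcf_header(sample_names: Iterable[str], contigs: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig, length=260_000_000)
    header.info.add("VQSLOD", 1, "Float", "Variant quality score log-odds")
    header.info.add("FS", 1, "Float", "Phred-scaled Fisher strand bias p-value")
    header.info.add("AF", "A", "Float", "Population alternate allele frequency")
    header.info.add(_INFO_REGION, 1, "String", "Region class (exonic/splice-site/other)")
    header.info.add(_INFO_RECURRENCE, 1, "Integer", "Unrelated carriers of this variant in the cohort")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for name in sample_names:
        header.add_sample(name)
    return header


def write_trio_vcf(
    path: str | Path,
    records: Iterable[TrioSiteRecord],
    sample_map: Mapping[str, str],
    genotypes: Mapping[tuple[str, int, str, str], Mapping[str, tuple[int, int]]] | None = None,
) -> None:
    """Write decomposed trio records to a VCF 4.2 file.

    Unless overridden via ``genotypes`` (keyed by record ``key``), the
    written genotype is 0/1 for the proband and 0/0 for the parents — the
    de novo configuration.
    """
    records = sorted(records, key=lambda r: (normalize_chrom(r.chrom), r.pos, r.alt_allele))
    contigs = sorted({r.chrom for r in records}, key=lambda c: (len(c), c))
    names = [sample_map[m] for m in TRIO_MEMBERS]
    header = _vcf_header(names, contigs)
    default_gt = {"proband": (0, 1), "mother": (0, 0), "father": (0, 0)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            site = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref_allele, rec.alt_allele),
            )
            if rec.vqslod is not None:
                site.info["VQSLOD"] = rec.vqslod
            if rec.fisher_strand is not None:
                site.info["FS"] = rec.fisher_strand
            if rec.region_class is not None:
                site.info[_INFO_REGION] = rec.region_class
            if rec.cohort_recurrence is not None:
                site.info[_INFO_RECURRENCE] = rec.cohort_recurrence
            gts = default_gt if genotypes is None else genotypes.get(rec.key, default_gt)
            for role in TRIO_MEMBERS:
                ev = rec.member(role)
                sample = site.samples[sample_map[role]]
                sample["GT"] = gts[role]
                if ev.total_depth is not None:
                    sample["DP"] = ev.total_depth
                    if ev.alt_depth is not None:
                        sample["AD"] = (ev.total_depth - ev.alt_depth, ev.alt_depth)
                if ev.genotype_quality is not None:
                    sample["GQ"] = int(round(ev.genotype_quality))
            out.write(site)


def read_trio_genotypes(
    path: str | Path,
    sample_map: Mapping[str, str],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Read biallelic genotype vectors (alt-allele dosage 0/1/2, -1 missing)
    for the three trio members, plus the per-site population allele
    frequency from INFO/AF (NaN when absent).

    Multi-allelic sites are skipped: dosage coding is only meaningful for
    biallelic SNPs, which is what kinship estimation uses.
    """
    missing_roles = [m for m in TRIO_MEMBERS if m not in sample_map]
    if missing_roles:
        raise ConfigurationError(f"sample_map lacks roles: {missing_roles}")
    dosages: dict[str, list[int]] = {m: [] for m in TRIO_MEMBERS}
    freqs: list[float] = []
    with pysam.VariantFile(str(path)) as vf:
        header_samples = set(vf.header.samples)
        for role in TRIO_MEMBERS:
            if sample_map[role] not in header_samples:
                raise ConfigurationError(
                    f"sample {sample_map[role]!r} (role {role}) not in VCF header"
                )
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0] if af else None
            freqs.append(float(af) if af is not None else np.nan)
            for role in TRIO_MEMBERS:
                gt = rec.samples[sample_map[role]].get("GT")
                if gt is None or any(a is None for a in gt):
                    dosages[role].append(-1)
                else:
                    dosages[role].append(int(sum(gt)))
    return (
        {m: np.asarray(v, dtype=np.int8) for m, v in dosages.items()},
        np.asarray(freqs, dtype=float),
    )


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------


def read_rate_table(path: str | Path, n_genes: int | None = None) -> MutationRateTable:
    """Read a tab-separated per-gene, per-class mutation probability table.

    Expected header: ``gene  class  probability``.  Duplicate (gene, class)
    rows and probabilities outside [0, 1] raise :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty rate table: {path}") from exc
    required = {"gene", "class", "probability"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"rate table {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise ValidationError(f"rate table has no rows: {path}")
    dupes = df.duplicated(subset=["gene", "class"])
    if dupes.any():
        first = df.loc[dupes.idxmax()]
        raise ValidationError(f"duplicate (gene, class) row: ({first['gene']}, {first['class']})")
    probs = {
        (str(r["gene"]), str(r["class"])): float(r["probability"])
        for r in df.to_dict(orient="records")
    }
    return MutationRateTable(probs, n_genes=n_genes)


def write_rate_table(table: MutationRateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


_ANNOTATION_COLUMNS = [
    "proband_id", "chrom", "pos", "ref_allele", "alt_allele", "gene",
    "transcript", "cdna_change", "protein_change", "protein_pos",
    "consequence", "metasvm", "mpc", "cadd", "pop_maf",
]


def read_annotation_table(path: str | Path) -> list[AnnotatedDNV]:
    """Read an annotated-variant table (tab-separated, canonical columns).

    Columns outside :data:`_ANNOTATION_COLUMNS` are ignored; ``protein_pos``
    is recovered from ``protein_change`` when not given explicitly.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"proband_id": str, "chrom": str})
    if "gene" not in df.columns or "consequence" not in df.columns:
        raise ValidationError(f"annotation table {path} needs at least gene and consequence columns")
    out = []
    for row in df.to_dict(orient="records"):
        kwargs = {}
        for col in _ANNOTATION_COLUMNS:
            val = row.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
                val = None
            kwargs[col] = val
        for col in ("pos", "protein_pos"):
            if kwargs[col] is not None:
                kwargs[col] = int(kwargs[col])
        for col in ("mpc", "cadd", "pop_maf"):
            if kwargs[col] is not None:
                kwargs[col] = float(kwargs[col])
        if kwargs["protein_pos"] is None:
            kwargs["protein_pos"] = parse_protein_position(kwargs["protein_change"])
        if kwargs["proband_id"] is None:
            kwargs["proband_id"] = "unknown"
        out.append(AnnotatedDNV(**kwargs))
    return out


def write_annotation_table(dnvs: Iterable[AnnotatedDNV], path: str | Path) -> None:
    rows = []
    for d in dnvs:
        rows.append({c: getattr(d, c) for c in _ANNOTATION_COLUMNS})
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def annotation_lookup(dnvs: Iterable[AnnotatedDNV]) -> dict[tuple[str, int, str, str], AnnotatedDNV]:
    """Build the (chrom, pos, ref, alt) -> annotation join map."""
    table = {}
    for d in dnvs:
        if d.key is not None:
            table[d.key] = d
    return table
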