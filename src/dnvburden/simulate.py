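"""Synthetic trio cohorts with the statistical structure the analysis assumes.

The generative model mirrors the analysis model in reverse:

* per trio, the number of de novo events in gene *g* is
  Poisson(2 * p_g * multiplier_g), where p_g comes from a (real or
  synthesized) mutation-probability table and multiplier_g is a
  risk-gene enrichment fold-change (1 under the null);
* each event draws a consequence class from a class mix, an annotation
  consistent with that class (misD events receive MPC >= 2 or a
  deleterious MetaSVM call), and sequencing evidence from a noise model
  (negative-binomial depths, beta-distributed heterozygous allele
  fractions, discretized genotype qualities, rare low-level parental
  contamination, and site-quality scores typical of true calls);
* spurious candidate sites ("artifacts") are spiked in at a configurable
  rate with evidence drawn from distributions typical of sequencing
  artifacts (low VQSLOD, skewed allele fractions, lower GQ, elevated
  strand bias, occasional cohort recurrence), so the filter cascades face
  a non-degenerate classification problem;
* pedigree genotype panels (Hardy-Weinberg parents, one transmitted
  allele per parent) exercise the kinship QC.

Everything is deterministic given the config seed, and every simulated
site carries a truth label so filter sensitivity/specificity can be
scored.

The noise distributions themselves are modelling choices of this package
(the analysis thresholds constrain only what *passes*); their defaults
are chosen to resemble well-behaved exome trio data and are fully exposed
on :class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .variants import (
    ATOMIC_CLASSES,
    AnnotatedDNV,
    MemberEvidence,
    MutationRateTable,
    TrioSiteRecord,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimulatedCohort",
    "simulate_rate_table",
    "simulate_cohort",
    "simulate_trio_genotypes",
    "simulate_related_pair",
    "simulate_gene_counts",
    "write_cohort",
    "DEFAULT_CLASS_MIX",
]

#: Default consequence-class mix for coding de novo events: mostly
#: missense, with roughly a quarter synonymous and a modest LoF fraction.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "lof": 0.08,
    "misD": 0.17,
    "mis": 0.50,
    "synonymous": 0.25,
}

_LOF_CHOICES = ("stop-gain", "frameshift", "canonical-splice", "start-loss", "stop-loss")
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort generator.  ``seed`` is mandatory."""

    seed: int
    n_trios: int = 100
    # rate table: either supplied or synthesized from (n_genes, p_range)
    rate_table: MutationRateTable | None = None
    n_genes: int = 500
    p_range: tuple[float, float] = (1e-6, 1e-4)
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    enrichment: Mapping[str, float] = field(default_factory=dict)  # gene -> fold multiplier

    # evidence noise model: true de novo calls
    depth_mean: float = 60.0
    depth_dispersion: float = 8.0       # negative-binomial size parameter
    het_beta: tuple[float, float] = (25.0, 25.0)  # alt fraction of a true het
    gq_mean: float = 85.0
    gq_sd: float = 12.0
    parent_contamination_prob: float = 0.02
    parent_contamination_fraction: float = 0.01
    vqslod_true: tuple[float, float] = (12.0, 4.0)   # normal (mean, sd)
    fs_true_scale: float = 3.0                        # exponential scale
    true_recurrence_lambda: float = 0.05

    # artifact model: spurious candidate sites
    artifact_rate: float = 1.0          # expected artifact sites per trio
    artifact_depth_mean: float = 30.0
    artifact_alt_beta: tuple[float, float] = (2.0, 8.0)
    artifact_gq: tuple[float, float] = (45.0, 20.0)
    vqslod_artifact: tuple[float, float] = (-5.0, 6.0)
    fs_artifact_scale: float = 20.0
    artifact_recurrence_lambda: float = 1.5

    protein_length: int = 3097

    def __post_init__(self) -> None:
        if self.n_trios < 0:
            raise ValidationError("n_trios must be >= 0")
        lo, hi = self.p_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError(f"p_range must lie in (0, 1), got {self.p_range}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_mix must sum to 1, sums to {total}")
        if any(m <= 0 for m in self.enrichment.values()):
            raise ValidationError("enrichment multipliers must be > 0")


@dataclass
class TruthSet:
    """Truth labels for simulated candidate sites, keyed by
    (trio_id, chrom, pos, ref, alt)."""

    true_dnvs: set = field(default_factory=set)
    artifacts: set = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.true_dnvs & self.artifacts
        if overlap:
            raise ValidationError(f"sites labelled both true and artifact: {sorted(overlap)[:3]}")

    def score(self, passing_keys: Iterable) -> dict:
        """Sensitivity/specificity of a filter given the keys it passed."""
        passed = set(passing_keys)
        tp = len(passed & self.true_dnvs)
        fp = len(passed & self.artifacts)
        sens = tp / len(self.true_dnvs) if self.true_dnvs else float("nan")
        spec = (len(self.artifacts) - fp) / len(self.artifacts) if self.artifacts else float("nan")
        return {
            "n_true": len(self.true_dnvs),
            "n_artifact": len(self.artifacts),
            "true_passed": tp,
            "artifact_passed": fp,
            "sensitivity": sens,
            "specificity": spec,
        }


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    rate_table: MutationRateTable
    #: (trio_id, TrioSiteRecord) in generation order
    records: list
    annotations: dict
    truth: TruthSet

    @property
    def trio_ids(self) -> list[str]:
        return [f"T{i:05d}" for i in range(self.config.n_trios)]


def simulate_rate_table(
    n_genes: int,
    p_range: tuple[float, float] = (1e-6, 1e-4),
    seed: int = 0,
    class_mix: Mapping[str, float] | None = None,
) -> MutationRateTable:
    """Synthesize a class-resolved rate table with log-uniform total
    per-gene probabilities split across classes by ``class_mix``."""
    lo, hi = p_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValidationError(f"p_range must lie in (0, 1), got {p_range}")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    rng = np.random.default_rng(seed)
    if lo == hi:
        totals = np.full(n_genes, lo)
    else:
        totals = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    probs: dict[tuple[str, str], float] = {}
    for i, total in enumerate(totals):
        gene = f"G{i:05d}"
        for cls in ATOMIC_CLASSES:
            probs[(gene, cls)] = float(total * mix.get(cls, 0.0))
    return MutationRateTable(probs)


def _consequence_for(label: str, rng: np.random.Generator) -> str:
    if label == "lof":
        return _LOF_CHOICES[rng.integers(len(_LOF_CHOICES))]
    if label in ("misD", "mis"):
        return "missense"
    return "synonymous"


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _nb_depth(rng: np.random.Generator, mean: float, size_param: float) -> int:
    p = size_param / (size_param + mean)
    return max(int(rng.negative_binomial(size_param, p)), 1)


def _gene_locus(gene_index: int) -> tuple[str, int]:
    chrom = str(gene_index % 22 + 1)
    start = 1_000_000 + (gene_index // 22) * 100_000
    return chrom, start


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort: candidate records, annotations, truth."""
    rng = np.random.default_rng(cfg.seed)
    table = cfg.rate_table or simulate_rate_table(
        cfg.n_genes, cfg.p_range, seed=int(rng.integers(2**31)), class_mix=cfg.class_mix
    )
    genes = sorted(table.genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    p_total = np.array([table.probability(g, "protein_altering") +
                        table.probability(g, "synonymous") for g in genes])
    mult = np.array([cfg.enrichment.get(g, 1.0) for g in genes])
    lam = 2.0 * p_total * mult

    mix_labels = list(cfg.class_mix)
    mix_probs = np.array([cfg.class_mix[c] for c in mix_labels])

    records: list[tuple[str, TrioSiteRecord]] = []
    annotations: dict = {}
    truth = TruthSet()
    position_offset: dict[str, int] = {}

    def next_pos(gene: str) -> tuple[str, int]:
        chrom, start = _gene_locus(gene_index[gene])
        offset = position_offset.get(gene, 0)
        position_offset[gene] = offset + 1 + int(rng.integers(1, 50))
        return chrom, start + position_offset[gene]

    for t in range(cfg.n_trios):
        trio_id = f"T{t:05d}"
        counts = rng.poisson(lam)
        for gi in np.flatnonzero(counts):
            for _ in range(int(counts[gi])):
                gene = genes[gi]
                label = mix_labels[rng.choice(len(mix_labels), p=mix_probs)]
                rec, ann = _draw_true_site(rng, cfg, trio_id, gene, label, next_pos)
                records.append((trio_id, rec))
                annotations[rec.key] = ann
                truth.true_dnvs.add((trio_id,) + rec.key)
        n_art = rng.poisson(cfg.artifact_rate)
        for _ in range(int(n_art)):
            gene = genes[int(rng.integers(len(genes)))]
            rec, ann = _draw_artifact_site(rng, cfg, trio_id, gene, next_pos)
            records.append((trio_id, rec))
            annotations[rec.key] = ann
            truth.artifacts.add((trio_id,) + rec.key)

    return SimulatedCohort(
        config=cfg, rate_table=table, records=records,
        annotations=annotations, truth=truth,
    )


def _draw_true_site(rng, cfg, trio_id, gene, label, next_pos):
    chrom, pos = next_pos(gene)
    ref, alt_allele = _snv_alleles(rng)
    members = {}
    for role in ("proband", "mother", "father"):
        depth = _nb_depth(rng, cfg.depth_mean, cfg.depth_dispersion)
        if role == "proband":
            frac = rng.beta(*cfg.het_beta)
            alt = int(rng.binomial(depth, frac))
        elif rng.random() < cfg.parent_contamination_prob:
            alt = int(rng.binomial(depth, cfg.parent_contamination_fraction))
        else:
            alt = 0
        gq = float(np.clip(rng.normal(cfg.gq_mean, cfg.gq_sd), 1, 99))
        members[role] = MemberEvidence(total_depth=depth, alt_depth=alt,
                                       genotype_quality=round(gq))
    rec = TrioSiteRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt_allele,
        vqslod=float(rng.normal(*cfg.vqslod_true)),
        fisher_strand=float(rng.exponential(cfg.fs_true_scale)),
        region_class="splice-site" if label == "lof" and rng.random() < 0.2 else "exonic",
        cohort_recurrence=int(rng.poisson(cfg.true_recurrence_lambda)),
        **members,
    )
    ann = _annotation_for(rng, cfg, trio_id, gene, label, rec)
    return rec, ann


def _draw_artifact_site(rng, cfg, trio_id, gene, next_pos):
    chrom, pos = next_pos(gene)
    ref, alt_allele = _snv_alleles(rng)
    members = {}
    for role in ("proband", "mother", "father"):
        depth = _nb_depth(rng, cfg.artifact_depth_mean, cfg.depth_dispersion)
        if role == "proband":
            alt = int(rng.binomial(depth, rng.beta(*cfg.artifact_alt_beta)))
        else:
            alt = int(rng.binomial(depth, 0.02))
        gq = float(np.clip(rng.normal(*cfg.artifact_gq), 1, 99))
        members[role] = MemberEvidence(total_depth=depth, alt_depth=alt,
                                       genotype_quality=round(gq))
    rec = TrioSiteRecord(
        chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt_allele,
        vqslod=float(rng.normal(*cfg.vqslod_artifact)),
        fisher_strand=float(rng.exponential(cfg.fs_artifact_scale)),
        region_class="exonic" if rng.random() < 0.8 else "other",
        cohort_recurrence=int(rng.poisson(cfg.artifact_recurrence_lambda)),
        **members,
    )
    label = "mis" if rng.random() < 0.8 else "synonymous"
    ann = _annotation_for(rng, cfg, trio_id, gene, label, rec)
    return rec, ann


def _annotation_for(rng, cfg, trio_id, gene, label, rec) -> AnnotatedDNV:
    consequence = _consequence_for(label, rng)
    mpc = None
    metasvm = None
    if label == "misD":
        if rng.random() < 0.5:
            mpc = float(rng.uniform(2.0, 3.5))
            metasvm = "deleterious" if rng.random() < 0.5 else None
        else:
            metasvm = "deleterious"
            mpc = float(rng.uniform(0.5, 3.0))
    elif label == "mis":
        mpc = float(rng.uniform(0.0, 1.9)) if rng.random() < 0.8 else None
        metasvm = "tolerated" if rng.random() < 0.7 else None
    protein_pos = int(rng.integers(1, cfg.protein_length + 1))
    pop_maf = None if rng.random() < 0.9 else float(rng.uniform(0.0, 3e-4))
    return AnnotatedDNV(
        proband_id=trio_id,
        gene=gene,
        consequence=consequence,
        protein_pos=protein_pos,
        metasvm=metasvm,
        mpc=mpc,
        cadd=float(rng.uniform(5, 40)),
        pop_maf=pop_maf,
        chrom=rec.chrom,
        pos=rec.pos,
        ref_allele=rec.ref_allele,
        alt_allele=rec.alt_allele,
    )


# ---------------------------------------------------------------------------
# Gene-count simulation (for calibration and power studies)
# ---------------------------------------------------------------------------


def simulate_gene_counts(
    p_per_gene: np.ndarray,
    n_probands: int,
    multipliers: np.ndarray | float = 1.0,
    n_replicates: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Cohort-level per-gene DNV counts ~ Poisson(2 * N * p_g * multiplier_g).

    Returns an (n_replicates, n_genes) integer array.  This is the
    generative twin of the burden test's null model and is what
    calibration and power studies draw from.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.asarray(p_per_gene, dtype=float)
    lam = 2.0 * n_probands * p * np.asarray(multipliers, dtype=float)
    return rng.poisson(lam, size=(n_replicates, p.size))


# ---------------------------------------------------------------------------
# Pedigree genotype simulation
# ---------------------------------------------------------------------------


def _hardy_weinberg(rng, freqs) -> np.ndarray:
    return (rng.random(freqs.size) < freqs).astype(np.int8) + (
        rng.random(freqs.size) < freqs
    ).astype(np.int8)


def _transmit(rng, parent: np.ndarray, freqs) -> np.ndarray:
    """One allele drawn from a parent: 0/1/2 transmit alt with prob g/2."""
    return (rng.random(parent.size) < parent / 2.0).astype(np.int8)


def _inject_errors(rng, geno: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return geno
    out = geno.copy()
    hit = rng.random(geno.size) < rate
    out[hit] = rng.integers(0, 3, size=int(hit.sum()), dtype=np.int8)
    return out


def simulate_trio_genotypes(
    n_sites: int,
    freqs,
    pedigree: str = "parent_offspring",
    seed: int = 0,
    genotype_error_rate: float = 0.0,
) -> dict[str, np.ndarray]:
    """Aligned dosage vectors for a trio.

    ``pedigree`` is ``"parent_offspring"`` (proband inherits one allele
    per parent per site) or ``"unrelated"`` (all three drawn independently
    from Hardy-Weinberg at the site frequencies).  Genotyping noise
    replaces each call with a uniform random dosage at
    ``genotype_error_rate`` per call.
    """
    rng = np.random.default_rng(seed)
    freqs = np.broadcast_to(np.asarray(freqs, dtype=float), (n_sites,))
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValidationError("freqs must lie strictly inside (0, 1)")
    mother = _hardy_weinberg(rng, freqs)
    father = _hardy_weinberg(rng, freqs)
    if pedigree == "parent_offspring":
        proband = _transmit(rng, mother, freqs) + _transmit(rng, father, freqs)
    elif pedigree == "unrelated":
        proband = _hardy_weinberg(rng, freqs)
    else:
        raise ValidationError(f"unknown pedigree: {pedigree!r}")
    out = {"proband": proband, "mother": mother, "father": father}
    return {k: _inject_errors(rng, v, genotype_error_rate) for k, v in out.items()}


def simulate_related_pair(
    n_sites: int,
    freqs,
    relationship: str,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A genotype pair under a named relationship, for kinship validation.

    ``relationship``: ``"parent_offspring"``, ``"unrelated"``,
    ``"duplicate"``, or ``"full_siblings"``.
    """
    rng = np.random.default_rng(seed)
    freqs = np.broadcast_to(np.asarray(freqs, dtype=float), (n_sites,))
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValidationError("freqs must lie strictly inside (0, 1)")
    mother = _hardy_weinberg(rng, freqs)
    father = _hardy_weinberg(rng, freqs)
    if relationship == "parent_offspring":
        child = _transmit(rng, mother, freqs) + _transmit(rng, father, freqs)
        return child, mother
    if relationship == "unrelated":
        return _hardy_weinberg(rng, freqs), _hardy_weinberg(rng, freqs)
    if relationship == "duplicate":
        sample = _hardy_weinberg(rng, freqs)
        return sample, sample.copy()
    if relationship == "full_siblings":
        sib1 = _transmit(rng, mother, freqs) + _transmit(rng, father, freqs)
        sib2 = _transmit(rng, mother, freqs) + _transmit(rng, father, freqs)
        return sib1, sib2
    raise ValidationError(f"unknown relationship: {relationship!r}")


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort to disk: one VCF per trio, the annotation
    and rate tables, and the truth set.  Returns the paths written."""
    from .variants import write_annotation_table, write_rate_table, write_trio_vcf

    out = Path(out_dir)
    trio_dir = out / "trios"
    trio_dir.mkdir(parents=True, exist_ok=True)
    by_trio: dict[str, list[TrioSiteRecord]] = {t: [] for t in cohort.trio_ids}
    for trio_id, rec in cohort.records:
        by_trio.setdefault(trio_id, []).append(rec)
    paths: dict[str, Path] = {}
    for trio_id, recs in by_trio.items():
        path = trio_dir / f"{trio_id}.vcf"
        sample_map = {
            "proband": f"{trio_id}-01",
            "mother": f"{trio_id}-02",
            "father": f"{trio_id}-03",
        }
        write_trio_vcf(path, recs, sample_map)
        paths[trio_id] = path
    ann_path = out / "annotations.tsv"
    write_annotation_table(list(cohort.annotations.values()), ann_path)
    rate_path = out / "rate_table.tsv"
    write_rate_table(cohort.rate_table, rate_path)
    truth_path = out / "truth.tsv"
    rows = [
        {"trio_id": k[0], "chrom": k[1], "pos": k[2], "ref_allele": k[3],
         "alt_allele": k[4], "label": label}
        for label, keys in (("true", cohort.truth.true_dnvs), ("artifact", cohort.truth.artifacts))
        for k in sorted(keys)
    ]
    pd.DataFrame(rows, columns=["trio_id", "chrom", "pos", "ref_allele", "alt_allele", "label"]
                 ).to_csv(truth_path, sep="\t", index=False)
    paths.update(annotations=ann_path, rate_table=rate_path, truth=truth_path)
    return paths
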