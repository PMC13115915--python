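"""De novo variant filter cascades.

Two filter dialects are implemented, reflecting the two pipelines that
produced the cohort's DNV calls:

* the **yale** dialect — location/depth/frequency filters plus proband
  alternate-read support, proband allele-balance, and parental
  contamination thresholds;
* the **genedx** dialect — location/depth/frequency filters plus eleven
  site- and genotype-quality criteria (GQ, VQSLOD, Fisher strand bias,
  alternate-allele ratios by allele-length class, indel length, a joint
  VQSLOD/allele-ratio exclusion, and cohort recurrence).

Every record receives a :class:`FilterVerdict` naming each failed
criterion, so that a filter report can account for every rejection.

Missing-value policy (conservative): a record lacking a value that a
criterion gates on *fails* that criterion, with one deliberate exception —
an absent population allele frequency passes the frequency filter, because
genuinely novel variants have no frequency entry.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .variants import AnnotatedDNV, TrioSiteRecord, TRIO_MEMBERS

__all__ = [
    "FilterConfig",
    "FilterVerdict",
    "FilterReport",
    "FilterEvaluationError",
    "apply_common_filters",
    "apply_yale_filters",
    "apply_genedx_filters",
    "evaluate_record",
    "filter_cohort",
]


class FilterEvaluationError(ValueError):
    """Raised when a criterion is undefined for a record (e.g. an allele
    fraction with zero proband depth)."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for both filter dialects.

    Defaults are the published values; inequality strictness follows the
    published criteria exactly and is documented per field.
    """

    dialect: str = "genedx"  # "yale" | "genedx"

    # --- common to both dialects ---
    min_member_depth: int = 10          # depth >= 10 in all trio members
    max_pop_maf: float = 4e-4           # keep if MAF <= 4e-4 (absent passes)
    allowed_regions: tuple[str, ...] = ("exonic", "splice-site")

    # --- yale dialect ---
    min_proband_alt_reads: int = 5      # alt depth >= 5
    min_alt_fraction_low: float = 0.28  # fraction >= 0.28 when alt reads < 10
    min_alt_fraction_high: float = 0.20 # fraction >= 0.20 when alt reads >= 10
    max_parent_alt_fraction: float = 0.035  # each parent <= 3.5%
    #: The published high-support clause reads "<= 20%", which would reject
    #: every confident heterozygote; by default it is interpreted as the
    #: *minimum* allele fraction at >= 10 alt reads.  Set False for the
    #: literal reading.
    high_support_fraction_is_minimum: bool = True

    # --- genedx dialect (criteria i-xi) ---
    min_gq: float = 40.0                # i: GQ > 40, all members (strict)
    min_vqslod: float = -10.0           # ii: VQSLOD > -10 (strict)
    max_fs: float = 30.0                # iii: FS < 30 (strict)
    genedx_min_proband_alt_reads: int = 4  # iv: alt count > 4 (strict)
    min_alt_ratio: float = 0.1          # v: ratio > 0.1 (strict)
    min_alt_ratio_equal_len: float = 0.15  # vi: ratio > 0.15, len(ref)==len(alt)
    min_alt_ratio_diff_len: float = 0.25   # vii: ratio > 0.25, lengths differ
    max_alt_ratio_autosomal: float = 0.9   # viii: ratio < 0.9 on autosomes
    max_allele_len: int = 100           # ix: len(ref) < 100 and len(alt) < 100
    joint_vqslod: float = 7.0           # x: reject VQSLOD < 7 AND ratio < 0.3
    joint_alt_ratio: float = 0.3
    max_cohort_recurrence: int = 2      # xi: carriers in <= 2 unrelated individuals

    #: Drop sex-chromosome records entirely instead of merely skipping the
    #: autosome-only ratio ceiling (criterion viii).
    exclude_sex_chromosomes: bool = False

    def __post_init__(self) -> None:
        if self.dialect not in ("yale", "genedx"):
            raise ValueError(f"unknown dialect: {self.dialect!r}")
        for name in ("min_alt_fraction_low", "min_alt_fraction_high",
                     "max_parent_alt_fraction", "min_alt_ratio",
                     "min_alt_ratio_equal_len", "min_alt_ratio_diff_len",
                     "max_alt_ratio_autosomal", "joint_alt_ratio", "max_pop_maf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_member_depth", "min_proband_alt_reads",
                     "genedx_min_proband_alt_reads", "max_allele_len",
                     "max_cohort_recurrence"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of evaluating one record: pass/fail plus the named criteria
    that failed (empty iff passed)."""

    record: TrioSiteRecord
    failed_criteria: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failed_criteria

    def merged(self, other: "FilterVerdict") -> "FilterVerdict":
        return FilterVerdict(self.record, self.failed_criteria + other.failed_criteria)


def _proband_ratio(rec: TrioSiteRecord) -> float | None:
    """Proband alternate-allele fraction; raises when depth is zero."""
    ev = rec.proband
    if ev.total_depth == 0:
        raise FilterEvaluationError(
            f"proband depth is zero at {rec.chrom}:{rec.pos}; allele fraction undefined"
        )
    return ev.alt_fraction


def apply_common_filters(
    rec: TrioSiteRecord,
    ann: AnnotatedDNV | None,
    cfg: FilterConfig,
) -> FilterVerdict:
    """Location, trio read-depth, and population-frequency filters shared by
    both dialects."""
    failed: list[str] = []
    if rec.region_class not in cfg.allowed_regions:
        failed.append("common.location")
    for member in TRIO_MEMBERS:
        dp = rec.member(member).total_depth
        if dp is None or dp < cfg.min_member_depth:
            failed.append("common.depth")
            break
    maf = ann.pop_maf if ann is not None else None
    if maf is not None and maf > cfg.max_pop_maf:
        failed.append("common.maf")
    return FilterVerdict(rec, tuple(failed))


def apply_yale_filters(rec: TrioSiteRecord, cfg: FilterConfig) -> FilterVerdict:
    failed: list[str] = []
    alt = rec.proband.alt_depth
    if alt is None or alt < cfg.min_proband_alt_reads:
        failed.append("yale.i")
    frac = _proband_ratio(rec)
    if frac is None or alt is None:
        failed.append("yale.ii")
    elif alt < 10:
        if frac < cfg.min_alt_fraction_low:
            failed.append("yale.ii")
    elif cfg.high_support_fraction_is_minimum:
        if frac < cfg.min_alt_fraction_high:
            failed.append("yale.ii")
    else:  # literal reading of the published "<=" clause
        if frac > cfg.min_alt_fraction_high:
            failed.append("yale.ii")
    for parent in ("mother", "father"):
        pfrac = rec.member(parent).alt_fraction
        if pfrac is None or pfrac > cfg.max_parent_alt_fraction:
            failed.append("yale.iii")
            break
    return FilterVerdict(rec, tuple(failed))


def apply_genedx_filters(rec: TrioSiteRecord, cfg: FilterConfig) -> FilterVerdict:
    failed: list[str] = []
    # i: GQ strictly above threshold in all members
    for member in TRIO_MEMBERS:
        gq = rec.member(member).genotype_quality
        if gq is None or not gq > cfg.min_gq:
            failed.append("genedx.i")
            break
    # ii: VQSLOD strictly above floor
    if rec.vqslod is None or not rec.vqslod > cfg.min_vqslod:
        failed.append("genedx.ii")
    # iii: Fisher strand bias strictly below ceiling
    if rec.fisher_strand is None or not rec.fisher_strand < cfg.max_fs:
        failed.append("genedx.iii")
    # iv: proband alternate read count strictly above threshold
    alt = rec.proband.alt_depth
    if alt is None or not alt > cfg.genedx_min_proband_alt_reads:
        failed.append("genedx.iv")
    ratio = _proband_ratio(rec)
    # v: overall ratio floor
    if ratio is None or not ratio > cfg.min_alt_ratio:
        failed.append("genedx.v")
    # vi/vii: ratio floors by allele-length class
    if not rec.is_length_change:
        if ratio is None or not ratio > cfg.min_alt_ratio_equal_len:
            failed.append("genedx.vi")
    else:
        if ratio is None or not ratio > cfg.min_alt_ratio_diff_len:
            failed.append("genedx.vii")
    # viii: ratio ceiling, autosomes only
    if rec.is_autosomal:
        if ratio is None or not ratio < cfg.max_alt_ratio_autosomal:
            failed.append("genedx.viii")
    # ix: allele length ceiling
    if not (len(rec.ref_allele) < cfg.max_allele_len and len(rec.alt_allele) < cfg.max_allele_len):
        failed.append("genedx.ix")
    # x: joint exclusion of low-VQSLOD, low-ratio calls
    if (rec.vqslod is None or ratio is None
            or (rec.vqslod < cfg.joint_vqslod and ratio < cfg.joint_alt_ratio)):
        failed.append("genedx.x")
    # xi: cohort recurrence cap
    if rec.cohort_recurrence is None or rec.cohort_recurrence > cfg.max_cohort_recurrence:
        failed.append("genedx.xi")
    return FilterVerdict(rec, tuple(failed))


def evaluate_record(
    rec: TrioSiteRecord,
    ann: AnnotatedDNV | None,
    cfg: FilterConfig,
) -> FilterVerdict:
    """Full verdict under the configured dialect (common block + dialect block)."""
    if cfg.exclude_sex_chromosomes and not rec.is_autosomal:
        return FilterVerdict(rec, ("common.non_autosomal",))
    verdict = apply_common_filters(rec, ann, cfg)
    if cfg.dialect == "yale":
        return verdict.merged(apply_yale_filters(rec, cfg))
    return verdict.merged(apply_genedx_filters(rec, cfg))


@dataclass
class FilterReport:
    """Cohort-level accounting: every input record is passed, failed (with
    named criteria), unjoinable, or unevaluable."""

    n_input: int = 0
    n_passed: int = 0
    n_failed: int = 0
    n_unjoinable: int = 0
    n_unevaluable: int = 0
    failures: Counter = field(default_factory=Counter)

    def reconciles(self) -> bool:
        return self.n_input == self.n_passed + self.n_failed + self.n_unjoinable + self.n_unevaluable


def filter_cohort(
    records: Iterable[TrioSiteRecord],
    annotations: Mapping[tuple[str, int, str, str], AnnotatedDNV],
    cfg: FilterConfig,
) -> tuple[list[AnnotatedDNV], FilterReport]:
    """Apply the configured cascade across a cohort's candidate records.

    Records are joined to annotations by (chrom, pos, ref, alt); unjoinable
    records are excluded and counted.  Returns the passing annotated DNVs
    and a :class:`FilterReport` whose per-criterion counts account for
    every rejection.
    """
    passing: list[AnnotatedDNV] = []
    report = FilterReport()
    for rec in records:
        report.n_input += 1
        ann = annotations.get(rec.key)
        if ann is None:
            report.n_unjoinable += 1
            continue
        try:
            verdict = evaluate_record(rec, ann, cfg)
        except FilterEvaluationError:
            report.n_unevaluable += 1
            continue
        if verdict.passed:
            report.n_passed += 1
            passing.append(ann)
        else:
            report.n_failed += 1
            report.failures.update(verdict.failed_criteria)
    return passing, report
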