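"""Filter cascade tests: boundary behaviour on every published threshold,
agreement with an independent per-criterion brute-force evaluator, and the
cascade's structural properties (idempotence, monotonicity, provenance)."""

import dataclasses

import numpy as np
import pytest

from dnvburden.filters import (
    FilterConfig,
    FilterEvaluationError,
    apply_common_filters,
    apply_genedx_filters,
    apply_yale_filters,
    evaluate_record,
    filter_cohort,
)
from dnvburden.variants import AnnotatedDNV, MemberEvidence, TrioSiteRecord, is_autosome

from conftest import random_record


# ---------------------------------------------------------------------------
# Independent brute-force oracle: each criterion restated in isolation,
# sharing nothing with the implementation but the record fields.
# ---------------------------------------------------------------------------


def oracle_failures(rec: TrioSiteRecord, dialect: str, maf=None) -> set:
    """Evaluate every criterion independently.  Missing values fail the
    criteria that need them, except an absent population frequency, which
    passes the frequency filter."""
    failed = set()

    if rec.region_class not in ("exonic", "splice-site"):
        failed.add("common.location")
    depths = [rec.proband.total_depth, rec.mother.total_depth, rec.father.total_depth]
    if any(d is None or d < 10 for d in depths):
        failed.add("common.depth")
    if maf is not None and maf > 4e-4:
        failed.add("common.maf")

    def frac(ev):
        if ev.total_depth in (None, 0) or ev.alt_depth is None:
            return None
        return ev.alt_depth / ev.total_depth

    ratio = frac(rec.proband)

    if dialect == "yale":
        if rec.proband.alt_depth is None or rec.proband.alt_depth < 5:
            failed.add("yale.i")
        if ratio is None:
            failed.add("yale.ii")
        elif rec.proband.alt_depth < 10:
            if ratio < 0.28:
                failed.add("yale.ii")
        else:
            if ratio < 0.20:
                failed.add("yale.ii")
        for parent in (rec.mother, rec.father):
            f = frac(parent)
            if f is None or f > 0.035:
                failed.add("yale.iii")
        return failed

    gqs = [rec.proband.genotype_quality, rec.mother.genotype_quality,
           rec.father.genotype_quality]
    if any(g is None or g <= 40 for g in gqs):
        failed.add("genedx.i")
    if rec.vqslod is None or rec.vqslod <= -10:
        failed.add("genedx.ii")
    if rec.fisher_strand is None or rec.fisher_strand >= 30:
        failed.add("genedx.iii")
    if rec.proband.alt_depth is None or rec.proband.alt_depth <= 4:
        failed.add("genedx.iv")
    if ratio is None or ratio <= 0.1:
        failed.add("genedx.v")
    if len(rec.ref_allele) == len(rec.alt_allele):
        if ratio is None or ratio <= 0.15:
            failed.add("genedx.vi")
    else:
        if ratio is None or ratio <= 0.25:
            failed.add("genedx.vii")
    if is_autosome(rec.chrom) and (ratio is None or ratio >= 0.9):
        failed.add("genedx.viii")
    if len(rec.ref_allele) >= 100 or len(rec.alt_allele) >= 100:
        failed.add("genedx.ix")
    if rec.vqslod is None or ratio is None or (rec.vqslod < 7 and ratio < 0.3):
        failed.add("genedx.x")
    if rec.cohort_recurrence is None or rec.cohort_recurrence > 2:
        failed.add("genedx.xi")
    return failed


def _full_failures(rec, cfg, maf=None):
    ann = AnnotatedDNV(proband_id="p", gene="G", consequence="missense", pop_maf=maf)
    return set(evaluate_record(rec, ann, cfg).failed_criteria)


@pytest.mark.parametrize("dialect", ["yale", "genedx"])
def test_cascade_matches_brute_force_oracle(dialect):
    """Verdicts agree with independent per-criterion evaluation on 1,000
    randomized records spanning both sides of every threshold."""
    rng = np.random.default_rng(20240917)
    cfg = FilterConfig(dialect=dialect)
    for _ in range(1000):
        rec = random_record(rng)
        maf = None if rng.random() < 0.5 else float(rng.uniform(0, 1e-3))
        if rec.proband.total_depth == 0:
            continue
        assert _full_failures(rec, cfg, maf) == oracle_failures(rec, dialect, maf), rec


# ---------------------------------------------------------------------------
# Boundary tests on both sides of every published threshold
# ---------------------------------------------------------------------------


def test_depth_boundary(make_record):
    cfg = FilterConfig()
    ann = AnnotatedDNV(proband_id="p", gene="G", consequence="missense")
    ok = apply_common_filters(make_record(father=(10, 0, 90)), ann, cfg)
    assert "common.depth" not in ok.failed_criteria
    bad = apply_common_filters(make_record(father=(9, 0, 90)), ann, cfg)
    assert "common.depth" in bad.failed_criteria


def test_maf_boundary(make_record):
    cfg = FilterConfig()
    rec = make_record()
    at = AnnotatedDNV(proband_id="p", gene="G", consequence="missense", pop_maf=4e-4)
    over = AnnotatedDNV(proband_id="p", gene="G", consequence="missense", pop_maf=5e-4)
    absent = AnnotatedDNV(proband_id="p", gene="G", consequence="missense", pop_maf=None)
    assert "common.maf" not in apply_common_filters(rec, at, cfg).failed_criteria
    assert "common.maf" in apply_common_filters(rec, over, cfg).failed_criteria
    assert "common.maf" not in apply_common_filters(rec, absent, cfg).failed_criteria


def test_location_filter(make_record):
    cfg = FilterConfig()
    ann = AnnotatedDNV(proband_id="p", gene="G", consequence="missense")
    assert "common.location" in apply_common_filters(make_record(region="other"), ann, cfg).failed_criteria
    for region in ("exonic", "splice-site"):
        assert apply_common_filters(make_record(region=region), ann, cfg).passed


@pytest.mark.parametrize(
    "proband,expect_fail",
    [
        ((16, 5, 90), False),   # alt reads exactly 5 pass criterion i; 5/16 = 0.31
        ((16, 4, 90), True),
        ((25, 7, 90), False),   # 7/25 = 0.28 exactly at the low-support floor
        ((100, 9, 90), True),   # 9/100 = 0.09 < 0.28 with < 10 alt reads
        ((50, 10, 90), False),  # 10/50 = 0.20 exactly at the high-support floor
        ((70, 12, 90), True),   # 12/70 = 0.171 < 0.20 with >= 10 alt reads
    ],
)
def test_yale_proband_support_boundaries(make_record, proband, expect_fail):
    verdict = apply_yale_filters(make_record(proband=proband), FilterConfig(dialect="yale"))
    assert bool(verdict.failed_criteria) == expect_fail


def test_yale_parent_fraction_boundary(make_record):
    cfg = FilterConfig(dialect="yale")
    at = make_record(mother=(200, 7, 90))   # 0.035 exactly
    over = make_record(mother=(200, 8, 90))  # 0.04
    assert "yale.iii" not in apply_yale_filters(at, cfg).failed_criteria
    assert "yale.iii" in apply_yale_filters(over, cfg).failed_criteria


def test_yale_literal_high_support_reading(make_record):
    """Under the literal published clause, a 50% allele fraction with >= 10
    alt reads is rejected; the default interpretation keeps it."""
    rec = make_record(proband=(40, 20, 90))
    assert apply_yale_filters(rec, FilterConfig(dialect="yale")).passed
    literal = FilterConfig(dialect="yale", high_support_fraction_is_minimum=False)
    assert "yale.ii" in apply_yale_filters(rec, literal).failed_criteria


GENEDX_BOUNDARY_CASES = [
    # (record overrides, criterion, expect_fail)
    ({"proband": (40, 20, 41), "mother": (40, 0, 41), "father": (40, 0, 41)}, "genedx.i", False),
    ({"mother": (40, 0, 40)}, "genedx.i", True),
    ({"vqslod": -9.9}, "genedx.ii", False),
    ({"vqslod": -10.0}, "genedx.ii", True),
    ({"fs": 29.9}, "genedx.iii", False),
    ({"fs": 30.0}, "genedx.iii", True),
    ({"proband": (40, 5, 90)}, "genedx.iv", False),
    ({"proband": (40, 4, 90)}, "genedx.iv", True),
    ({"proband": (100, 10, 90)}, "genedx.v", True),   # 0.10 exactly fails the strict floor
    ({"proband": (100, 11, 90)}, "genedx.v", False),
    ({"proband": (100, 15, 90)}, "genedx.vi", True),  # 0.15 exactly, equal-length alleles
    ({"proband": (100, 16, 90)}, "genedx.vi", False),
    ({"ref": "AT", "proband": (100, 25, 90)}, "genedx.vii", True),   # 0.25 exactly
    ({"ref": "AT", "proband": (100, 26, 90)}, "genedx.vii", False),
    ({"proband": (100, 89, 90)}, "genedx.viii", False),
    ({"proband": (100, 90, 90)}, "genedx.viii", True),  # 0.90 exactly hits the ceiling
    ({"proband": (100, 95, 90), "chrom": "X"}, "genedx.viii", False),  # skipped off-autosome
    ({"ref": "A" * 99}, "genedx.ix", False),
    ({"ref": "A" * 100}, "genedx.ix", True),
    ({"vqslod": 6.9, "proband": (100, 29, 90)}, "genedx.x", True),   # both joint conditions met
    ({"vqslod": 7.0, "proband": (100, 29, 90)}, "genedx.x", False),  # VQSLOD at 7 escapes
    ({"vqslod": 6.9, "proband": (100, 30, 90)}, "genedx.x", False),  # ratio at 0.3 escapes
    ({"recurrence": 2}, "genedx.xi", False),
    ({"recurrence": 3}, "genedx.xi", True),
]


@pytest.mark.parametrize("overrides,criterion,expect_fail", GENEDX_BOUNDARY_CASES)
def test_genedx_boundaries(make_record, overrides, criterion, expect_fail):
    verdict = apply_genedx_filters(make_record(**overrides), FilterConfig())
    assert (criterion in verdict.failed_criteria) == expect_fail


def test_genedx_ratio_boundary_case_4_of_40(make_record):
    # 4/40 = 0.10 exactly: fails v (strict >) even though iv is the headline
    verdict = apply_genedx_filters(make_record(proband=(40, 4, 90)), FilterConfig())
    assert "genedx.v" in verdict.failed_criteria


# ---------------------------------------------------------------------------
# Structural properties
# ---------------------------------------------------------------------------


def test_zero_proband_depth_is_an_evaluation_error(make_record):
    rec = make_record(proband=(0, 0, 90))
    with pytest.raises(FilterEvaluationError):
        apply_yale_filters(rec, FilterConfig(dialect="yale"))
    with pytest.raises(FilterEvaluationError):
        apply_genedx_filters(rec, FilterConfig())


def test_verdict_provenance(make_record):
    """Every rejected record names at least one failed criterion, and
    passed <=> no failed criteria."""
    rng = np.random.default_rng(5)
    cfg = FilterConfig()
    for _ in range(200):
        rec = random_record(rng)
        if rec.proband.total_depth == 0:
            continue
        verdict = apply_genedx_filters(rec, cfg)
        assert verdict.passed == (len(verdict.failed_criteria) == 0)


def _cohort(rng, n):
    records, anns = [], {}
    for _ in range(n):
        rec = random_record(rng)
        if rec.proband.total_depth == 0 or rec.key in anns:
            continue
        records.append(rec)
        anns[rec.key] = AnnotatedDNV(
            proband_id="p", gene="G", consequence="missense",
            chrom=rec.chrom, pos=rec.pos, ref_allele=rec.ref_allele,
            alt_allele=rec.alt_allele,
        )
    return records, anns


@pytest.mark.parametrize("dialect", ["yale", "genedx"])
def test_filter_cohort_idempotent(dialect):
    rng = np.random.default_rng(99)
    records, anns = _cohort(rng, 400)
    cfg = FilterConfig(dialect=dialect)
    passing, report = filter_cohort(records, anns, cfg)
    assert report.reconciles()
    passed_keys = {d.key for d in passing}
    again, report2 = filter_cohort(
        [r for r in records if r.key in passed_keys], anns, cfg
    )
    assert {d.key for d in again} == passed_keys
    assert report2.n_failed == 0


def test_filter_cohort_counts_unjoinable():
    rng = np.random.default_rng(11)
    records, anns = _cohort(rng, 100)
    # drop half the annotations
    keys = sorted(anns)[::2]
    thinned = {k: anns[k] for k in keys}
    _, report = filter_cohort(records, thinned, FilterConfig())
    assert report.n_unjoinable == len(records) - len(keys)
    assert report.reconciles()


def test_relaxing_a_threshold_never_shrinks_the_passing_set():
    rng = np.random.default_rng(21)
    records, anns = _cohort(rng, 600)
    strict = FilterConfig()
    for relaxed in [
        dataclasses.replace(strict, min_gq=20.0),
        dataclasses.replace(strict, min_vqslod=-30.0),
        dataclasses.replace(strict, max_fs=60.0),
        dataclasses.replace(strict, min_alt_ratio=0.01),
        dataclasses.replace(strict, max_cohort_recurrence=10),
    ]:
        pass_strict, _ = filter_cohort(records, anns, strict)
        pass_relaxed, _ = filter_cohort(records, anns, relaxed)
        assert {d.key for d in pass_strict} <= {d.key for d in pass_relaxed}


def test_exclude_sex_chromosomes_flag(make_record):
    rec = make_record(chrom="X")
    cfg = FilterConfig(exclude_sex_chromosomes=True)
    ann = AnnotatedDNV(proband_id="p", gene="G", consequence="missense")
    verdict = evaluate_record(rec, ann, cfg)
    assert verdict.failed_criteria == ("common.non_autosomal",)
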