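import numpy as np
import pytest

from dnvburden.datasets import trio_cv_dnvs
from dnvburden.variants import MemberEvidence, TrioSiteRecord


@pytest.fixture
def trio_table():
    """The five published de novo TRIO variants (the worked example)."""
    return trio_cv_dnvs()


@pytest.fixture
def make_record():
    """Factory for TrioSiteRecords with sensible passing defaults, so tests
    perturb exactly one quantity at a time."""

    def _make(
        chrom="1",
        pos=1000,
        ref="A",
        alt="G",
        proband=(40, 20, 90),   # (total_depth, alt_depth, GQ)
        mother=(40, 0, 90),
        father=(40, 0, 90),
        vqslod=10.0,
        fs=2.0,
        region="exonic",
        recurrence=0,
    ):
        def ev(spec):
            if spec is None:
                return MemberEvidence()
            dp, ad, gq = spec
            return MemberEvidence(total_depth=dp, alt_depth=ad, genotype_quality=gq)

        return TrioSiteRecord(
            chrom=chrom,
            pos=pos,
            ref_allele=ref,
            alt_allele=alt,
            proband=ev(proband),
            mother=ev(mother),
            father=ev(father),
            vqslod=vqslod,
            fisher_strand=fs,
            region_class=region,
            cohort_recurrence=recurrence,
        )

    return _make


def random_record(rng: np.random.Generator) -> TrioSiteRecord:
    """A randomized trio record spanning both sides of every filter
    threshold, with occasional absent fields.  Proband depth is kept
    positive so allele fractions are defined."""

    def maybe(value, p_absent=0.08):
        return None if rng.random() < p_absent else value

    def evidence(is_proband):
        dp = int(rng.integers(1 if is_proband else 0, 81))
        ad = int(rng.integers(0, dp + 1)) if dp else 0
        if not is_proband and rng.random() < 0.7:
            ad = min(ad, int(rng.integers(0, 4)))
        gq = float(rng.integers(0, 100))
        return MemberEvidence(
            total_depth=dp,
            alt_depth=maybe(ad),
            genotype_quality=maybe(gq),
        )

    ref_len = int(rng.choice([1, 1, 1, 2, 5, 99, 100, 120]))
    alt_len = int(rng.choice([1, 1, 1, 2, 5, 99, 100, 120]))
    bases = "ACGT"
    ref = "".join(rng.choice(list(bases), ref_len))
    alt = "".join(rng.choice(list(bases), alt_len))
    if ref == alt:
        alt = ref[:-1] + ("A" if ref[-1] != "A" else "C")
    return TrioSiteRecord(
        chrom=str(rng.choice(["1", "9", "22", "X", "chr5"])),
        pos=int(rng.integers(1, 10**6)),
        ref_allele=ref,
        alt_allele=alt,
        proband=evidence(True),
        mother=evidence(False),
        father=evidence(False),
        vqslod=maybe(float(rng.uniform(-20, 20))),
        fisher_strand=maybe(float(rng.uniform(0, 60))),
        region_class=str(rng.choice(["exonic", "splice-site", "other"])),
        cohort_recurrence=maybe(int(rng.integers(0, 6))),
    )
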