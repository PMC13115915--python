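"""Pedigree verification from genotypes.

Two complementary checks confirm that a nominal trio really is one:

* a method-of-moments identity-by-descent (IBD) estimate from pairwise
  identity-by-state (IBS) counts — for a true parent-offspring pair the
  estimated genome-wide IBD proportion pi-hat is ~0.5 (the accepted band
  is 45-55%); duplicates give ~1 and unrelated pairs ~0;
* the Mendelian-error rate — the fraction of sites at which the proband's
  genotype is impossible given the parental genotypes.  Genuine de novo
  variants are single-site "errors" by construction, so the genome-wide
  *rate*, not any individual site, is the QC signal.

Genotypes are alt-allele dosages (0/1/2) on shared biallelic sites;
missing calls are coded -1 and ignored.  The IBS-to-IBD moment estimator
follows the classical approach of genotype-based relatedness tools:
expected IBS-class probabilities under IBD states 0/1/2 are computed from
the site allele frequencies, negative moment estimates are clamped to
zero, and the state probabilities renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KinshipEstimate",
    "InsufficientDataError",
    "estimate_ibd",
    "mendelian_error_rate",
    "trio_qc",
    "PARENT_OFFSPRING_BAND",
]

#: Accepted pi-hat band for a parent-offspring pair.
PARENT_OFFSPRING_BAND = (0.45, 0.55)


class InsufficientDataError(ValueError):
    """Raised when too few informative sites remain for estimation."""


@dataclass(frozen=True)
class KinshipEstimate:
    pair: tuple[str, str]
    n_sites: int
    ibs_counts: tuple[int, int, int]  # sites sharing 0 / 1 / 2 alleles
    pi_hat: float

    def __post_init__(self) -> None:
        assert sum(self.ibs_counts) == self.n_sites
        assert 0.0 <= self.pi_hat <= 1.0


def _validate_genotypes(*vectors: np.ndarray) -> list[np.ndarray]:
    arrays = [np.asarray(v) for v in vectors]
    n = arrays[0].size
    for a in arrays:
        if a.ndim != 1 or a.size != n:
            raise ValueError("genotype vectors must be 1-D and aligned")
    return arrays


def estimate_ibd(
    geno_a,
    geno_b,
    freqs,
    pair: tuple[str, str] = ("A", "B"),
    min_sites: int = 100,
) -> KinshipEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    ``geno_a``/``geno_b`` are aligned dosage vectors; ``freqs`` are the alt
    allele frequencies of the same sites and must lie strictly inside
    (0, 1) to be informative.  pi_hat = P(IBD=1)/2 + P(IBD=2).
    """
    ga, gb = _validate_genotypes(geno_a, geno_b)
    p = np.asarray(freqs, dtype=float)
    if p.size != ga.size:
        raise ValueError("freqs must align with the genotype vectors")
    valid = (ga >= 0) & (gb >= 0) & (p > 0.0) & (p < 1.0)
    n = int(valid.sum())
    if n < min_sites:
        raise InsufficientDataError(
            f"only {n} informative sites; at least {min_sites} required"
        )
    ga, gb, p = ga[valid], gb[valid], p[valid]
    q = 1.0 - p

    ibs = 2 - np.abs(ga.astype(int) - gb.astype(int))
    n0 = int(np.sum(ibs == 0))
    n1 = int(np.sum(ibs == 1))
    n2 = int(np.sum(ibs == 2))

    # Expected IBS-class counts given each IBD state, summed over sites.
    e0_ibd0 = float(np.sum(2.0 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4.0 * p**3 * q + 4.0 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4.0 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2.0 * p**2 * q + 2.0 * p * q**2))
    e2_ibd1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))

    p0 = n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (n1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (n2 - p0 * e2_ibd0 - p1 * e2_ibd1) / n

    probs = np.clip([p0, p1, p2], 0.0, None)
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi_hat = float(np.clip(probs[1] / 2.0 + probs[2], 0.0, 1.0))
    return KinshipEstimate(pair=pair, n_sites=n, ibs_counts=(n0, n1, n2), pi_hat=pi_hat)


def mendelian_error_rate(proband, mother, father) -> float:
    """Fraction of sites at which the proband genotype cannot be produced
    by one transmitted allele from each parent.

    Given parental dosages, the set of possible child dosages is the
    contiguous range [min_m + min_f, max_m + max_f] where a parent with
    dosage 0/1/2 can transmit {0}/{0,1}/{1}.  Missing genotypes (-1) at a
    site exclude that site.
    """
    gp, gm, gf = _validate_genotypes(proband, mother, father)
    valid = (gp >= 0) & (gm >= 0) & (gf >= 0)
    if not valid.any():
        return 0.0
    gp, gm, gf = gp[valid], gm[valid], gf[valid]
    t_min = (gm == 2).astype(int) + (gf == 2).astype(int)
    t_max = (gm >= 1).astype(int) + (gf >= 1).astype(int)
    errors = (gp < t_min) | (gp > t_max)
    return float(errors.mean())


def trio_qc(
    genotypes: dict[str, np.ndarray],
    freqs,
    trio_id: str = "trio",
    band: tuple[float, float] = PARENT_OFFSPRING_BAND,
    min_sites: int = 100,
) -> dict:
    """Per-trio QC summary: pi-hat for both proband-parent pairs, the
    Mendelian-error rate, and a pass flag for pi-hat inside ``band``."""
    pm = estimate_ibd(genotypes["proband"], genotypes["mother"], freqs,
                      pair=("proband", "mother"), min_sites=min_sites)
    pf = estimate_ibd(genotypes["proband"], genotypes["father"], freqs,
                      pair=("proband", "father"), min_sites=min_sites)
    mendel = mendelian_error_rate(
        genotypes["proband"], genotypes["mother"], genotypes["father"]
    )
    lo, hi = band
    return {
        "trio_id": trio_id,
        "n_sites": pm.n_sites,
        "pi_hat_proband_mother": pm.pi_hat,
        "pi_hat_proband_father": pf.pi_hat,
        "mendel_error_rate": mendel,
        "kinship_pass": bool(lo <= pm.pi_hat <= hi and lo <= pf.pi_hat <= hi),
    }
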