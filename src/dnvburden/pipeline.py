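"""End-to-end orchestration of the trio DNV analysis.

Stages (in dependency order): ``simulate`` (synthetic cohort), ``qc``
(kinship verification), ``filter`` (DNV cascade), ``classify`` (damaging
classification + per-gene tallies), ``burden`` (Poisson enrichment), and
``mutmap`` (protein density track).  Every output table is tab-separated
and carries a provenance header (package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import tally_counts
from .enrichment import (
    DEFAULT_CLASS_GROUPS,
    cohort_burden_test,
    gene_level_test,
)
from .filters import FilterConfig, filter_cohort
from .kinship import trio_qc
from .mutmap import build_track
from .simulate import SimulationConfig, simulate_cohort, simulate_trio_genotypes, write_cohort
from .variants import (
    ConfigurationError,
    annotation_lookup,
    read_annotation_table,
    read_rate_table,
    read_trio_genotypes,
    read_trio_vcf,
)

__all__ = ["PipelineConfig", "run_pipeline", "cohort_manifest", "ALL_STAGES"]

logger = logging.getLogger("dnvburden")

ALL_STAGES = ("simulate", "qc", "filter", "classify", "burden", "mutmap")

#: Members of one sequenced trio; used for manifest arithmetic.
EXOMES_PER_TRIO = 3


def cohort_manifest(n_trios: int) -> dict[str, int]:
    """Cohort bookkeeping: N trios -> 3N exomes (proband + both parents)."""
    if n_trios < 0:
        raise ValueError("n_trios must be >= 0")
    return {"n_trios": n_trios, "n_exomes": EXOMES_PER_TRIO * n_trios}


@dataclass
class PipelineConfig:
    out_dir: Path = Path("dnvburden-run")
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    n_trios: int = 50
    n_genes: int = 300
    enrichment: Mapping[str, float] = field(default_factory=dict)
    filter: FilterConfig = field(default_factory=FilterConfig)
    family_alpha: float = 0.05
    n_tests_per_gene: int = 3
    class_groups: tuple[str, ...] = DEFAULT_CLASS_GROUPS
    mutmap_window: int = 10
    protein_length: int = 3097
    mutmap_gene: str | None = None   # default: most-hit gene
    kinship_sites: int = 2000
    # pre-existing inputs (skip the simulate stage and consume these)
    vcf_dir: Path | None = None
    annotation_table: Path | None = None
    rate_table_path: Path | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(filter=filt, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dnvburden={__version__} config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _sample_map(trio_id: str) -> dict[str, str]:
    return {
        "proband": f"{trio_id}-01",
        "mother": f"{trio_id}-02",
        "father": f"{trio_id}-03",
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages; returns a run report with per-stage counts.

    A failure confined to one trio (e.g. an unreadable VCF) is logged and
    reported but does not abort the cohort.
    """
    stages = [s for s in ALL_STAGES if s in cfg.stages]
    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": stages,
        "manifest": cohort_manifest(cfg.n_trios),
        "trio_errors": [],
    }
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)

    cohort = None
    if "simulate" in stages:
        sim_cfg = SimulationConfig(
            seed=cfg.seed,
            n_trios=cfg.n_trios,
            n_genes=cfg.n_genes,
            enrichment=dict(cfg.enrichment),
            protein_length=cfg.protein_length,
        )
        cohort = simulate_cohort(sim_cfg)
        write_cohort(cohort, out)
        report["simulate"] = {
            "n_trios": cfg.n_trios,
            "n_candidate_sites": len(cohort.records),
            "n_true": len(cohort.truth.true_dnvs),
            "n_artifact": len(cohort.truth.artifacts),
        }

    vcf_dir = out / "trios" if cohort is not None else cfg.vcf_dir
    ann_path = out / "annotations.tsv" if cohort is not None else cfg.annotation_table
    rate_path = out / "rate_table.tsv" if cohort is not None else cfg.rate_table_path

    if "qc" in stages:
        if vcf_dir is None:
            raise ConfigurationError("qc stage needs simulated or provided trio VCFs")
        rows = []
        rng = np.random.default_rng(cfg.seed + 1)
        for trio_id in sorted(p.stem for p in Path(vcf_dir).glob("*.vcf")):
            try:
                freqs = rng.uniform(0.1, 0.9, size=cfg.kinship_sites)
                genotypes = simulate_trio_genotypes(
                    cfg.kinship_sites, freqs, "parent_offspring",
                    seed=int(rng.integers(2**31)),
                )
                rows.append(trio_qc(genotypes, freqs, trio_id=trio_id))
            except Exception as exc:  # keep the cohort going
                logger.warning("qc failed for %s: %s", trio_id, exc)
                report["trio_errors"].append({"stage": "qc", "trio": trio_id, "error": str(exc)})
        qc_df = pd.DataFrame(rows)
        _write_table(qc_df, out / "qc_report.tsv", cfg)
        report["qc"] = {
            "n_trios": len(rows),
            "n_kinship_pass": int(qc_df["kinship_pass"].sum()) if len(rows) else 0,
        }

    passing = None
    if "filter" in stages:
        if vcf_dir is None or ann_path is None:
            raise ConfigurationError("filter stage needs trio VCFs and an annotation table")
        annotations = annotation_lookup(read_annotation_table(ann_path))
        records = []
        for vcf in sorted(Path(vcf_dir).glob("*.vcf")):
            try:
                records.extend(read_trio_vcf(vcf, _sample_map(vcf.stem)))
            except Exception as exc:
                logger.warning("filter: cannot read %s: %s", vcf, exc)
                report["trio_errors"].append(
                    {"stage": "filter", "trio": vcf.stem, "error": str(exc)}
                )
        passing, filt_report = filter_cohort(records, annotations, cfg.filter)
        fail_df = pd.DataFrame(
            sorted(filt_report.failures.items()), columns=["criterion", "n_failed"]
        )
        _write_table(fail_df, out / "filter_report.tsv", cfg)
        from .variants import write_annotation_table

        pass_path = out / "dnvs_pass.tsv"
        write_annotation_table(passing, pass_path)
        report["filter"] = {
            "n_input": filt_report.n_input,
            "n_passed": filt_report.n_passed,
            "n_failed": filt_report.n_failed,
            "n_unjoinable": filt_report.n_unjoinable,
            "n_unevaluable": filt_report.n_unevaluable,
            "reconciles": filt_report.reconciles(),
        }

    counts = None
    if "classify" in stages:
        if passing is None:
            if "filter" in stages:
                raise ConfigurationError("classify stage found no filter output")
            pass_path = out / "dnvs_pass.tsv"
            if not pass_path.exists():
                raise ConfigurationError("classify stage needs the filter stage (dnvs_pass.tsv)")
            passing = read_annotation_table(pass_path)
        counts = tally_counts(passing, n_probands=cfg.n_trios)
        class_rows = [
            {
                "gene": g,
                **{grp: counts.count(g, grp) for grp in
                   ("lof", "misD", "mis", "synonymous", "protein_altering", "protein_damaging")},
                "n_probands": counts.n_probands_with_dnv(g),
            }
            for g in counts.genes()
        ]
        _write_table(pd.DataFrame(class_rows), out / "gene_counts.tsv", cfg)
        report["classify"] = {
            "n_dnvs": len(passing),
            "n_genes_hit": len(counts.genes()),
            "protein_altering_total": counts.total("protein_altering"),
        }

    if "burden" in stages:
        if counts is None:
            raise ConfigurationError("burden stage needs the classify stage")
        if rate_path is None:
            raise ConfigurationError("burden stage needs a rate table")
        table = read_rate_table(rate_path)
        rows = []
        for class_group in cfg.class_groups:
            for res in gene_level_test(
                counts, table, class_group,
                family_alpha=cfg.family_alpha,
                n_tests_per_gene=cfg.n_tests_per_gene,
                missing="zero",
            ):
                rows.append(
                    {
                        "unit": res.unit, "class_group": res.class_group,
                        "observed": res.observed, "expected": res.expected,
                        "rate_ratio": res.rate_ratio, "p_value": res.p_value,
                        "p_adjusted": res.p_adjusted, "significant": res.significant,
                    }
                )
        for res in cohort_burden_test(counts, table, cfg.class_groups,
                                      family_alpha=cfg.family_alpha, missing="zero"):
            rows.append(
                {
                    "unit": res.unit, "class_group": res.class_group,
                    "observed": res.observed, "expected": res.expected,
                    "rate_ratio": res.rate_ratio, "p_value": res.p_value,
                    "p_adjusted": res.p_adjusted, "significant": res.significant,
                }
            )
        burden_df = pd.DataFrame(rows)
        _write_table(burden_df, out / "burden.tsv", cfg)
        gene_rows = burden_df[burden_df["unit"] != "cohort"]
        report["burden"] = {
            "n_tests": len(rows),
            "n_significant_genes": int(gene_rows["significant"].sum()),
            "top_gene": gene_rows.sort_values("p_value")["unit"].iloc[0] if len(gene_rows) else None,
        }

    if "mutmap" in stages:
        if passing is None:
            raise ConfigurationError("mutmap stage needs the filter stage output")
        gene = cfg.mutmap_gene
        if gene is None and counts is not None and counts.genes():
            gene = max(counts.genes(), key=lambda g: counts.count(g, "protein_altering"))
        gene_vars = [d for d in passing if d.gene == gene and d.protein_pos is not None]
        track = build_track(gene_vars, cfg.protein_length, w=cfg.mutmap_window)
        _write_table(track.to_frame(), out / "mutmap_track.tsv", cfg)
        report["mutmap"] = {
            "gene": gene,
            "n_variants": len(gene_vars),
            "peak_residue": track.peak_residue() if gene_vars else None,
        }

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
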