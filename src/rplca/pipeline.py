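"""End-to-end pipeline: coverage matrix -> CNVs -> variants -> verdicts.

``PipelineConfig`` collects every threshold of the analysis with its
panel default; ``run_pipeline`` executes the stages on files in the
dialects the library reads and writes a report bundle (TSV tables, a
cohort JSON, the resolved configuration, and a per-stage log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from . import cnv as cnv_mod
from . import variants as var_mod
from . import verdict as verdict_mod
from ._util import ValidationError
from .reads import CoverageMatrix, run_stats
from .panel import load_panel

logger = logging.getLogger("rplca")


@dataclass
class PipelineConfig:
    """All tunable thresholds, with the panel's defaults.

    Coverage classes: well >= 50 reads, moderate 11-49, poor <= 10.
    CNVs: runs of >= 6 consecutive probes at <= 0.65 (deletion) or
    >= 1.20 (duplication); mean <= 0.15 marks a full (hom/hemi) loss.
    Variants: MAF <= 0.5% (recessive/X-linked) or <= 0.1% (dominant) in
    every resource; alt fraction >= 80% hom / 35-80% het; >= 10 reads;
    recurrence < 10% of probands; missense thresholds PhyloP >= 2.7,
    CADD >= 15, Grantham >= 80; SpliceAI delta >= 0.2.
    """

    # CNV stage
    del_threshold: float = 0.65
    dup_threshold: float = 1.20
    min_consecutive_probes: int = 6
    hom_del_boundary: float = 0.15
    min_samples_for_normalization: int = 8
    # variant cascade
    ar_maf_cutoff: float = 0.005
    ad_maf_cutoff: float = 0.001
    hom_fraction: float = 0.80
    het_fraction: float = 0.35
    min_reads: int = 10
    run_frequency_fraction: float = 0.10
    phylop_min: float = 2.7
    cadd_min: float = 15.0
    grantham_min: float = 80.0
    spliceai_min: float = 0.2
    # coverage classes
    well_min_depth: int = 50
    moderate_min_depth: int = 11
    # inputs / outputs
    matrix_path: Optional[str] = None
    panel_path: Optional[str] = None
    variants_path: Optional[str] = None
    div_whitelist_path: Optional[str] = None
    out_dir: str = "rplca_out"
    phenotype: str = "RP"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineReport:
    """Paths and headline numbers produced by one pipeline run."""

    out_dir: Path
    n_samples: int = 0
    n_cnv_calls: int = 0
    n_variants_in: int = 0
    n_candidates: int = 0
    cohort: Optional[verdict_mod.CohortYield] = None
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute reads -> cnv -> variants -> verdict -> yield on file inputs.

    Requires ``matrix_path`` + ``panel_path`` (CNV stage) and/or
    ``variants_path`` (cascade + verdicts); any stage error aborts with
    the stage named.  Reports are byte-stable for identical inputs and
    configuration; timestamps appear only in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(out_dir=out)
    stage = "setup"
    try:
        (out / "resolved_config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")

        panel = None
        cnv_calls: list = []
        if config.matrix_path:
            stage = "reads"
            if not config.panel_path:
                raise ValidationError(
                    "matrix_path given without panel_path")
            matrix = CoverageMatrix.from_tsv(_existing(config.matrix_path))
            panel = load_panel(_existing(config.panel_path))
            report.n_samples = len(matrix.sample_ids)
            stats = run_stats(matrix)
            report.stage_counts["reads"] = {
                "samples": stats.n_samples, "probes": stats.n_probes,
                "total_read_pairs": stats.total_reads,
                "mean_per_sample": stats.mean_reads_per_sample,
                "mean_per_probe": stats.mean_reads_per_smmip,
            }
            stage = "cnv"
            norm = cnv_mod.normalize(
                matrix, min_samples=config.min_samples_for_normalization)
            cnv_calls = cnv_mod.call_cnvs(
                norm, panel,
                del_threshold=config.del_threshold,
                dup_threshold=config.dup_threshold,
                min_run=config.min_consecutive_probes,
                hom_del_boundary=config.hom_del_boundary)
            cnv_mod.write_calls(cnv_calls, out / "cnv_calls.tsv")
            report.n_cnv_calls = len(cnv_calls)
            report.stage_counts["cnv"] = {
                "calls": len(cnv_calls),
                "excluded_probes": len(norm.excluded_probes),
            }

        verdicts: list = []
        if config.variants_path:
            stage = "variants"
            records = var_mod.read_variants_tsv(
                _existing(config.variants_path))
            report.n_variants_in = len(records)
            whitelist = None
            if config.div_whitelist_path:
                whitelist = var_mod.load_div_whitelist(
                    _existing(config.div_whitelist_path))
            prioritized = var_mod.prioritize(
                records,
                div_whitelist=whitelist,
                ar_cutoff=config.ar_maf_cutoff,
                ad_cutoff=config.ad_maf_cutoff,
                run_fraction=config.run_frequency_fraction,
                min_reads=config.min_reads,
                spliceai_min=config.spliceai_min,
                phylop_min=config.phylop_min,
                cadd_min=config.cadd_min,
                grantham_min=config.grantham_min)
            var_mod.write_prioritized_tsv(prioritized,
                                          out / "prioritized_variants.tsv")
            survivors = var_mod.candidates(prioritized)
            report.n_candidates = len(survivors)
            report.stage_counts["variants"] = {
                "input": len(records), "candidates": len(survivors),
            }

            stage = "verdict"
            pairs_by_sample = verdict_mod.assemble_pairs(
                prioritized, cnv_calls)
            all_samples = sorted({v.sample_id for v in records})
            verdicts = [
                verdict_mod.proband_verdict(
                    s, pairs_by_sample.get(s, []),
                    phenotype=config.phenotype)
                for s in all_samples
            ]
            verdict_mod.write_verdicts(verdicts, out / "verdicts.tsv")
            stage = "yield"
            cohort = verdict_mod.cohort_yield(verdicts)
            report.cohort = cohort
            (out / "cohort_summary.json").write_text(
                json.dumps(asdict(cohort), indent=2) + "\n")
            report.stage_counts["verdict"] = {
                "probands": cohort.n,
                "very_likely_solved": cohort.n_very_likely,
                "possibly_solved": cohort.n_possibly,
            }

        (out / "pipeline_log.txt").write_text(
            "".join(f"{name}\t{json.dumps(counts, sort_keys=True)}\n"
                    for name, counts in report.stage_counts.items()))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def _existing(path: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p
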