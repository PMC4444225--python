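"""End-to-end orchestration: QC -> PPV selection -> gene variance ->
cohort statistics -> report files.

A run reads a variant table, gene panel and cohort manifest, applies the
quality filter, selects PPVs under all three modes (all nonsynonymous,
LoF, LoF-SNV), writes gene-variance and burden tables per mode plus a
detection report when diagnosed mutations are on the manifest, and
collects the headline numbers into one JSON summary.  Reports are
regenerated wholesale each run; given identical inputs and seed the
outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from . import fixtures
from .cohort_stats import (
    binomial_ci,
    detection_rate,
    ppv_burden,
    round_percent,
)
from .gene_variance import (
    VarianceConfig,
    gene_variance_table,
    percent_interpretable,
    write_gene_variance_table,
)
from .models import CohortManifest, GenePanel, ValidationError
from .ppv_classification import (
    PpvConfig,
    PpvMode,
    PpvSelection,
    confirm_clinical_mutation,
    select_ppvs,
    write_ppv_table,
)
from .qc_calibration import QcConfig, apply_quality_filter
from .variant_io import (
    VcfFieldMap,
    read_cohort_manifest,
    read_gene_panel,
    read_variant_table,
    write_cohort_manifest,
    write_gene_panel,
    write_variant_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "cancer_risk_summary",
           "build_fixtures"]

log = logging.getLogger("wgsinterp")


class PipelineError(RuntimeError):
    """A stage failed validation; the message names the stage."""


@dataclass
class RunConfig:
    variants: Union[str, Path] = ""
    panel: Union[str, Path] = ""
    manifest: Union[str, Path] = ""
    out_dir: Union[str, Path] = "wgsinterp-out"
    dialect: str = "tsv"
    field_map: VcfFieldMap = field(default_factory=VcfFieldMap)
    qc: QcConfig = field(default_factory=QcConfig)
    frequency_threshold: float = 0.01
    variance: VarianceConfig = field(default_factory=VarianceConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        """Load a run configuration from YAML or JSON.

        Nested sections ``field_map``, ``qc`` and ``variance`` map onto
        their config dataclasses; ``variance.exclude_genes`` may be a list.
        """
        path = Path(path)
        with open(path) as fh:
            payload = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") \
                else json.load(fh)
        kwargs = dict(payload)
        if "field_map" in kwargs:
            kwargs["field_map"] = VcfFieldMap.from_mapping(kwargs["field_map"])
        if "qc" in kwargs:
            kwargs["qc"] = QcConfig(**kwargs["qc"])
        if "variance" in kwargs:
            v = dict(kwargs["variance"])
            if "exclude_genes" in v:
                v["exclude_genes"] = frozenset(v["exclude_genes"])
            kwargs["variance"] = VarianceConfig(**v)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"config {path}: unknown key(s) {sorted(unknown)}")
        return cls(**kwargs)


def cancer_risk_summary(
    selection: PpvSelection,
    manifest: CohortManifest,
    panel: GenePanel,
    cohort_class: str = "test",
) -> dict:
    """Fraction of a cohort with >= 1 PPV in a cancer-associated gene,
    with its exact 95% confidence interval."""
    cancer_genes = {
        g for g, e in panel.entries.items()
        if e.cancer_associated and g not in panel.excluded_genes
    }
    ids = manifest.sample_ids(cohort_class=cohort_class)
    if not ids:
        raise PipelineError(f"manifest has no {cohort_class!r} samples")
    k = sum(
        1
        for s in ids
        if any(c.gene in cancer_genes for c in selection.per_sample.get(s, []))
    )
    lo, hi = binomial_ci(k, len(ids))
    return {
        "n_carriers": k,
        "n_samples": len(ids),
        "rate_percent": round_percent(k / len(ids)),
        "ci95_percent": [round_percent(lo), round_percent(hi)],
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the headline summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("reading inputs")
    try:
        result = read_variant_table(cfg.variants, cfg.dialect, cfg.field_map)
        panel = read_gene_panel(cfg.panel)
        manifest = read_cohort_manifest(cfg.manifest)
    except (ValidationError, FileNotFoundError) as exc:
        raise PipelineError(f"input stage: {exc}") from exc
    if len(manifest) == 0:
        raise PipelineError(f"input stage: manifest {cfg.manifest} lists no samples")
    if result.rejected:
        pd.DataFrame(result.rejected, columns=["line", "reason"]).to_csv(
            out / "rejected_rows.tsv", sep="\t", index=False
        )

    log.info("quality filter")
    retained, qc_summary = apply_quality_filter(result.calls, cfg.qc)

    summary: dict = {
        "n_input_calls": len(result.calls),
        "n_rejected_rows": len(result.rejected),
        "n_quality_pass": len(retained),
        "fraction_excluded": {
            cls: qc_summary.fraction_excluded(cls) for cls in qc_summary.n_input
        },
        "modes": {},
    }

    for mode in PpvMode:
        log.info("PPV selection, mode=%s", mode.value)
        sel = select_ppvs(
            retained, panel,
            PpvConfig(frequency_threshold=cfg.frequency_threshold, mode=mode),
        )
        results = gene_variance_table(sel, manifest, panel, cfg.variance)
        burden = ppv_burden(sel, manifest)
        write_ppv_table(sel, out / f"ppvs_{mode.value}.tsv")
        write_gene_variance_table(results, out / f"gene_variance_{mode.value}.tsv")
        hist_rows = [
            {"cohort": label, "n_ppvs": k, "n_samples": n}
            for label, hist in burden.per_cohort_histogram.items()
            for k, n in hist.items()
        ]
        pd.DataFrame(hist_rows).to_csv(
            out / f"burden_histogram_{mode.value}.tsv", sep="\t", index=False
        )
        summary["modes"][mode.value] = {
            "n_ppvs": sel.n_ppvs,
            "unique_variants": sel.unique_variant_count,
            "novel_fraction": sel.novel_fraction(),
            "mean_ppvs_per_individual": {
                label: burden.mean(label) for label in manifest.cohort_labels
            },
            "percent_interpretable": round_percent(
                percent_interpretable(results, panel, cfg.variance)
            ),
            "cancer_risk": cancer_risk_summary(sel, manifest, panel)
            if manifest.sample_ids(cohort_class="test")
            else None,
        }

    diagnosed = [s for s in manifest if s.clinical_mutation is not None]
    if diagnosed:
        log.info("clinical-mutation confirmation (%d samples)", len(diagnosed))
        statuses = [
            confirm_clinical_mutation(result.calls, s, cfg.qc) for s in diagnosed
        ]
        report = detection_rate(statuses)
        summary["detection"] = {
            "n_expected": report.n_expected,
            "n_high_quality": report.n_high_quality,
            "n_low_quality": report.n_low_quality,
            "rate_percent": round_percent(report.rate),
            "low_quality_categories": report.low_quality_categories,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def build_fixtures(out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the packaged worked-example fixtures as plain TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel_163.tsv",
        "table2_variants": out / "brca_cohort_lof_variants.tsv",
        "table3_variants": out / "nonbrca_cohort_lof_variants.tsv",
        "manifest": out / "cohort_manifest.tsv",
        "detection_manifest": out / "detection_manifest.tsv",
        "detection_variants": out / "detection_variants.tsv",
    }
    write_gene_panel(fixtures.clinical_panel(), paths["panel"])
    write_variant_table(fixtures.table2_calls(), paths["table2_variants"])
    write_variant_table(fixtures.table3_calls(), paths["table3_variants"])
    write_cohort_manifest(fixtures.cohort_manifest(), paths["manifest"])
    det_manifest, det_calls = fixtures.detection_scenario()
    write_cohort_manifest(det_manifest, paths["detection_manifest"])
    write_variant_table(det_calls, paths["detection_variants"])
    return paths
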