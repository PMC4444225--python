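"""Per-gene carrier statistics and the clinical-interpretability call.

For each panel gene and each cohort the analysis computes the *carrier
fraction* (fraction of the cohort's individuals with at least one PPV in
the gene) and the *carrier burden* (mean PPV count per individual).
Because PPVs are selected below 1% allele frequency, heterozygous
carriers of any single variant are expected in under 2% of individuals;
a gene whose carrier fraction in the control cohort stays below that 2%
bound is called *clinically interpretable* — PPVs reported in it are
unlikely to be recurrent false positives.  Genes with no PPVs in either
cohort are interpretable.  The comparison is strict: exactly 2% is not
interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .models import CohortManifest, GenePanel
from .ppv_classification import PpvConfig, PpvMode, PpvSelection, select_ppvs
from .qc_calibration import QcConfig

__all__ = [
    "VarianceConfig",
    "CohortGeneStats",
    "GeneVarianceResult",
    "carrier_stats",
    "gene_variance_table",
    "percent_interpretable",
    "coding_size_correlation",
    "frequency_threshold_sweep",
    "write_gene_variance_table",
]


@dataclass(frozen=True)
class VarianceConfig:
    """Interpretability settings.

    ``control_cohort`` selects the manifest cohort defining the background
    carrier fractions; ``None`` means every sample with
    ``cohort_class == "control"``.  ``exclude_genes`` are dropped from
    panel-percentage summaries only (the per-gene table still reports
    them): by default the genes that define the control cohort itself,
    whose carrier fraction is 100% by construction.
    """

    interpretability_threshold: float = 0.02
    control_cohort: Optional[str] = None
    exclude_genes: frozenset[str] = frozenset({"BRCA1", "BRCA2"})

    def __post_init__(self) -> None:
        if not (0.0 < self.interpretability_threshold < 1.0):
            raise ValueError(
                f"interpretability threshold must be in (0,1), got "
                f"{self.interpretability_threshold}"
            )


@dataclass(frozen=True)
class CohortGeneStats:
    cohort: str
    n_samples: int
    n_carriers: int
    n_ppvs: int

    @property
    def carrier_fraction(self) -> float:
        return self.n_carriers / self.n_samples

    @property
    def carrier_burden(self) -> float:
        return self.n_ppvs / self.n_samples


@dataclass
class GeneVarianceResult:
    gene: str
    mode: PpvMode
    per_cohort: dict[str, CohortGeneStats] = field(default_factory=dict)
    interpretable: bool = True

    def fraction(self, cohort: str) -> float:
        return self.per_cohort[cohort].carrier_fraction

    def burden(self, cohort: str) -> float:
        return self.per_cohort[cohort].carrier_burden


def _control_ids(manifest: CohortManifest, cfg: VarianceConfig) -> list[str]:
    if cfg.control_cohort is not None:
        ids = manifest.sample_ids(cohort_label=cfg.control_cohort)
    else:
        ids = manifest.sample_ids(cohort_class="control")
    if not ids:
        raise ValueError("control cohort is empty")
    return ids


def carrier_stats(
    selection: PpvSelection,
    manifest: CohortManifest,
    gene: str,
    cfg: VarianceConfig = VarianceConfig(),
) -> GeneVarianceResult:
    """Carrier fraction and burden for one gene, per cohort label.

    The interpretability call uses the control cohort only: carrier
    fraction strictly below the threshold (default 2%) is interpretable.
    """
    per_cohort: dict[str, CohortGeneStats] = {}
    for label in manifest.cohort_labels:
        ids = manifest.sample_ids(cohort_label=label)
        if not ids:
            raise ValueError(f"cohort {label!r} is empty")
        counts = [
            sum(1 for c in selection.per_sample.get(s, []) if c.gene == gene)
            for s in ids
        ]
        per_cohort[label] = CohortGeneStats(
            cohort=label,
            n_samples=len(ids),
            n_carriers=sum(1 for k in counts if k > 0),
            n_ppvs=sum(counts),
        )
    control = _control_ids(manifest, cfg)
    control_set = set(control)
    n_control_carriers = sum(
        1
        for s, calls in selection.per_sample.items()
        if s in control_set and any(c.gene == gene for c in calls)
    )
    control_fraction = n_control_carriers / len(control)
    return GeneVarianceResult(
        gene=gene,
        mode=selection.mode,
        per_cohort=per_cohort,
        interpretable=control_fraction < cfg.interpretability_threshold,
    )


def gene_variance_table(
    selection: PpvSelection,
    manifest: CohortManifest,
    panel: GenePanel,
    cfg: VarianceConfig = VarianceConfig(),
) -> list[GeneVarianceResult]:
    """One result per analysis-panel gene, genes with zero PPVs included."""
    return [
        carrier_stats(selection, manifest, gene, cfg) for gene in sorted(panel.genes)
    ]


def percent_interpretable(
    results: Sequence[GeneVarianceResult],
    panel: GenePanel,
    cfg: VarianceConfig = VarianceConfig(),
) -> float:
    """Fraction of panel genes called interpretable.

    Computed over the analysis panel minus ``cfg.exclude_genes``; a gene
    missing from ``results`` is treated as having no PPVs anywhere, hence
    interpretable.
    """
    universe = panel.genes - set(cfg.exclude_genes)
    if not universe:
        raise ValueError("no genes left after exclusions")
    by_gene = {r.gene: r for r in results}
    n_ok = sum(
        1 for g in universe if g not in by_gene or by_gene[g].interpretable
    )
    return n_ok / len(universe)


def coding_size_correlation(
    gene_counts: dict[str, float], panel: GenePanel
) -> Optional[float]:
    """Squared Pearson correlation of per-gene PPV count vs coding length.

    Returns ``None`` (absent, not 0) when fewer than three genes are
    available or either vector has zero variance.
    """
    genes = [g for g in sorted(panel.genes)]
    x = np.array([panel.entries[g].coding_length for g in genes], dtype=float)
    y = np.array([gene_counts.get(g, 0.0) for g in genes], dtype=float)
    if len(genes) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def frequency_threshold_sweep(
    calls: Iterable,
    panel: GenePanel,
    manifest: CohortManifest,
    thresholds: Sequence[float],
    mode: PpvMode = PpvMode.ALL,
    qc: Optional[QcConfig] = None,
    cfg: VarianceConfig = VarianceConfig(),
) -> pd.DataFrame:
    """Re-run PPV selection at alternative frequency thresholds.

    Returns a table (threshold, percent_interpretable, mean_ppvs_per_individual,
    n_ppvs); PPV counts are non-decreasing in threshold.
    """
    calls = list(calls)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    n_total = len(manifest)
    rows = []
    for t in thresholds:
        sel = select_ppvs(calls, panel, PpvConfig(frequency_threshold=t, mode=mode), qc)
        results = gene_variance_table(sel, manifest, panel, cfg)
        rows.append(
            {
                "threshold": t,
                "percent_interpretable": percent_interpretable(results, panel, cfg),
                "mean_ppvs_per_individual": sel.n_ppvs / n_total,
                "n_ppvs": sel.n_ppvs,
            }
        )
    return pd.DataFrame(rows)


def write_gene_variance_table(
    results: Sequence[GeneVarianceResult], path: Union[str, Path]
) -> None:
    """Long-format TSV: one row per gene per cohort, plot-ready."""
    rows = []
    for r in results:
        for label, s in r.per_cohort.items():
            rows.append(
                {
                    "gene": r.gene,
                    "cohort": label,
                    "n_samples": s.n_samples,
                    "n_carriers": s.n_carriers,
                    "n_ppvs": s.n_ppvs,
                    "carrier_fraction": s.carrier_fraction,
                    "carrier_burden": s.carrier_burden,
                    "interpretable": int(r.interpretable),
                    "mode": r.mode.value,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
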