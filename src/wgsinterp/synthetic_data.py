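"""Synthetic cohorts and replicate genome pairs.

The generator emulates the statistical structure the analysis assumes:

* per-gene background of rare missense calls, Poisson with mean
  proportional to coding length (``mu * L_g`` per individual), which is
  what makes per-gene PPV counts correlate with gene size;
* planted loss-of-function variants carried by a fixed fraction of one
  cohort, for parameter-recovery checks;
* a novel fraction of variants with absent reference-panel frequencies,
  the remainder drawn from a mixture with most mass below the 1%
  rare-variant threshold;
* replicate genome pairs sharing a true genotype vector, each call
  corrupted independently with a probability that strictly decreases
  with its simulated quality score — the structure replicate-concordance
  calibration relies on.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import (
    CohortManifest,
    Consequence,
    GenePanel,
    Genotype,
    PanelEntry,
    Inheritance,
    SampleRecord,
    VariantCall,
    VarType,
)

__all__ = [
    "ErrorModel",
    "PlantedLof",
    "SimulationConfig",
    "generate_panel",
    "generate_cohort",
    "generate_replicate_pair",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ErrorModel:
    """Quality law and quality-dependent genotype-error curve.

    Qualities are ``floor(Beta(a, b) * q_max)``; with the defaults the
    bulk of calls score well above the SNV threshold of 100, as on a
    production platform.  The error probability is logistic in quality,

        eps(q) = eps_max / (1 + exp((q - q_mid) / q_scale)),

    strictly decreasing in q.  ``eps_const`` overrides the curve with a
    constant (useful for closed-form checks); monotonicity is only
    guaranteed for the logistic form.
    """

    q_beta_a: float = 8.0
    q_beta_b: float = 2.0
    q_max: int = 300
    eps_max: float = 0.4
    q_mid: float = 100.0
    q_scale: float = 25.0
    eps_const: Optional[float] = None

    def sample_quality(self, rng: np.random.Generator, size: int) -> np.ndarray:
        q = np.floor(rng.beta(self.q_beta_a, self.q_beta_b, size=size) * self.q_max)
        return np.clip(q, 0, self.q_max).astype(int)

    def error_prob(self, q) -> np.ndarray:
        if self.eps_const is not None:
            return np.full_like(np.asarray(q, dtype=float), self.eps_const)
        q = np.asarray(q, dtype=float)
        return self.eps_max / (1.0 + np.exp((q - self.q_mid) / self.q_scale))


@dataclass(frozen=True)
class PlantedLof:
    """A loss-of-function variant carried by a fixed cohort fraction."""

    gene: str
    carrier_fraction: float
    cohort_label: str
    lof_class: str = "nonsense"  # or "frameshift"

    def __post_init__(self) -> None:
        if not (0.0 <= self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must be in [0,1]")
        if self.lof_class not in ("nonsense", "frameshift"):
            raise ValueError(f"unknown lof_class {self.lof_class!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the clinic setting the pipeline targets: a 163-gene
    panel, a 176-sample control cohort and an 82-sample test cohort, a
    background rare-missense rate tuned so individuals average a handful
    of panel PPVs, and a novel fraction just under half.
    """

    n_genes: int = 163
    coding_length_log_mean: float = 7.5  # log bp; median ~1.8 kb
    coding_length_log_sd: float = 0.8
    background_missense_rate: float = 2.2e-5  # calls per bp per individual
    planted_lof: tuple[PlantedLof, ...] = ()
    novel_fraction: float = 0.4633
    rare_mass: float = 0.9  # mass of non-novel frequencies below 1%
    n_samples: tuple[tuple[str, int], ...] = (("BRCA1/2", 176), ("nonBRCA", 82))
    control_label: str = "BRCA1/2"
    error_model: ErrorModel = field(default_factory=ErrorModel)
    hom_fraction: float = 0.05
    n_replicate_sites: int = 2000
    replicate_indel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("novel_fraction", "rare_mass", "hom_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.background_missense_rate < 0:
            raise ValueError("background_missense_rate must be non-negative")

    @property
    def cohorts(self) -> dict[str, int]:
        return dict(self.n_samples)


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def _gene_start(i: int) -> int:
    return (i + 1) * 1_000_000


def generate_panel(cfg: SimulationConfig) -> GenePanel:
    """The synthetic gene panel implied by a config (deterministic).

    Coding lengths are log-normal; inheritance is dominant throughout
    (the generator plants heterozygous carriers only).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    lengths = np.maximum(
        1,
        np.round(
            rng.lognormal(cfg.coding_length_log_mean, cfg.coding_length_log_sd,
                          size=cfg.n_genes)
        ).astype(int),
    )
    entries = {
        _gene_name(i): PanelEntry(
            gene=_gene_name(i),
            inheritance=Inheritance.DOMINANT,
            cancer_associated=False,
            coding_length=int(lengths[i]),
        )
        for i in range(cfg.n_genes)
    }
    return GenePanel(name="synthetic-panel", entries=entries)


def _draw_frequencies(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[Optional[float], Optional[float]]:
    if rng.random() < cfg.novel_fraction:
        return None, None
    if rng.random() < cfg.rare_mass:
        lo, hi = 1e-4, 0.0099
    else:
        lo, hi = 0.0101, 0.10
    fa = round(float(rng.uniform(lo, hi)), 6)
    fb = round(float(rng.uniform(lo, hi)), 6)
    return fa, fb


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i = rng.integers(4)
    j = (i + 1 + rng.integers(3)) % 4
    return str(_BASES[i]), str(_BASES[j])


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[CohortManifest, list[VariantCall]]:
    """Generate a cohort manifest and its per-sample variant calls.

    Background: per individual and gene g, ``Poisson(mu * L_g)`` rare
    missense SNVs at uniform positions.  Each planted LoF variant is
    carried (heterozygously) by exactly ``floor(pi * n)`` randomly chosen
    samples of its cohort at a fixed in-gene site.  Qualities come from
    the error model's quality law; frequencies follow the novel/rare
    mixture.  Output order and content are deterministic under the seed.
    """
    panel = generate_panel(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = sorted(panel.entries)
    lengths = {g: panel.entries[g].coding_length for g in genes}
    starts = {g: _gene_start(i) for i, g in enumerate(genes)}

    samples: list[SampleRecord] = []
    for label, n in cfg.n_samples:
        cls = "control" if label == cfg.control_label else "test"
        for j in range(n):
            samples.append(
                SampleRecord(
                    sample_id=f"{label}.{j + 1}", cohort_class=cls, cohort_label=label
                )
            )
    manifest = CohortManifest(samples=samples)

    calls: list[VariantCall] = []
    mu = cfg.background_missense_rate
    for s in samples:
        for g in genes:
            lam = mu * lengths[g]
            n_bg = int(rng.poisson(lam)) if lam > 0 else 0
            for _ in range(n_bg):
                pos = starts[g] + int(rng.integers(lengths[g]))
                ref, alt = _snv_alleles(rng)
                q = cfg.error_model.sample_quality(rng, 2)
                fa, fb = _draw_frequencies(rng, cfg)
                calls.append(
                    VariantCall(
                        sample_id=s.sample_id,
                        chrom="1",
                        pos=pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        var_type=VarType.SNV,
                        genotype=Genotype.HOM
                        if rng.random() < cfg.hom_fraction
                        else Genotype.HET,
                        allele_quality=(int(q[0]), int(q[1])),
                        consequence=Consequence.MISSENSE,
                        gene=g,
                        freq_panel_a=fa,
                        freq_panel_b=fb,
                        score=round(float(rng.uniform(0, 30)), 3),
                    )
                )

    for planted in cfg.planted_lof:
        if planted.gene not in lengths:
            raise ValueError(f"planted gene {planted.gene!r} not in synthetic panel")
        cohort_ids = manifest.sample_ids(cohort_label=planted.cohort_label)
        if not cohort_ids:
            raise ValueError(f"planted cohort {planted.cohort_label!r} is empty")
        n_carriers = math.floor(planted.carrier_fraction * len(cohort_ids))
        if planted.carrier_fraction > 0 and n_carriers < 1:
            warnings.warn(
                f"carrier fraction {planted.carrier_fraction} yields zero carriers "
                f"in cohort of {len(cohort_ids)}",
                stacklevel=2,
            )
        carriers = rng.choice(cohort_ids, size=n_carriers, replace=False)
        pos = starts[planted.gene] + lengths[planted.gene] // 2
        if planted.lof_class == "nonsense":
            ref, alt, vt, csq = "C", "A", VarType.SNV, Consequence.NONSENSE
        else:
            ref, alt, vt, csq = "AC", "A", VarType.DEL, Consequence.FRAMESHIFT
        for sid in sorted(carriers):
            q = cfg.error_model.sample_quality(rng, 2)
            calls.append(
                VariantCall(
                    sample_id=sid,
                    chrom="1",
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    var_type=vt,
                    genotype=Genotype.HET,
                    allele_quality=(int(q[0]), int(q[1])),
                    consequence=csq,
                    gene=planted.gene,
                    freq_panel_a=None,
                    freq_panel_b=None,
                    score=round(float(rng.uniform(20, 50)), 3),
                )
            )

    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.pos, c.alt_allele))
    return manifest, calls


def generate_replicate_pair(
    cfg: SimulationConfig,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Two variant tables for the same individual, sharing a truth vector.

    Each of ``cfg.n_replicate_sites`` sites has a true genotype (het or
    hom).  Per replicate and site, a quality q is drawn from the quality
    law and the genotype is flipped (het <-> hom) independently with
    probability ``eps(q)``.  Both allele-quality entries carry q.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = cfg.n_replicate_sites
    is_indel = rng.random(n) < cfg.replicate_indel_fraction
    true_hom = rng.random(n) < 0.3
    tables: list[list[VariantCall]] = []
    for _rep in range(2):
        q = cfg.error_model.sample_quality(rng, n)
        flip = rng.random(n) < cfg.error_model.error_prob(q)
        rep_calls = []
        for i in range(n):
            hom = bool(true_hom[i]) ^ bool(flip[i])
            if is_indel[i]:
                ref, alt, vt, csq = "AC", "A", VarType.DEL, Consequence.FRAMESHIFT
            else:
                ref, alt, vt, csq = "G", "T", VarType.SNV, Consequence.MISSENSE
            rep_calls.append(
                VariantCall(
                    sample_id="IND1",
                    chrom="R",
                    pos=100 * (i + 1),
                    ref_allele=ref,
                    alt_allele=alt,
                    var_type=vt,
                    genotype=Genotype.HOM if hom else Genotype.HET,
                    allele_quality=(int(q[i]), int(q[i])),
                    consequence=csq,
                    gene=None,
                )
            )
        tables.append(rep_calls)
    return tables[0], tables[1]
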