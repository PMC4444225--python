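"""Per-gene carrier statistics and interpretability."""

import numpy as np
import pytest

from conftest import make_call
from wgsinterp.gene_variance import (
    VarianceConfig,
    carrier_stats,
    coding_size_correlation,
    frequency_threshold_sweep,
    gene_variance_table,
    percent_interpretable,
)
from wgsinterp.models import CohortManifest, GenePanel, Inheritance, PanelEntry, \
    SampleRecord
from wgsinterp.ppv_classification import PpvConfig, PpvMode, PpvSelection, select_ppvs
from wgsinterp.synthetic_data import PlantedLof, SimulationConfig, generate_cohort, \
    generate_panel

NO_EXCL = VarianceConfig(exclude_genes=frozenset())


def small_panel(genes, lengths=None):
    lengths = lengths or {}
    return GenePanel(
        name="p",
        entries={
            g: PanelEntry(g, Inheritance.DOMINANT, False, lengths.get(g, 1000))
            for g in genes
        },
    )


def manifest_of(n_control, n_test):
    samples = [SampleRecord(f"C{i}", "control", "BRCA1/2") for i in range(n_control)]
    samples += [SampleRecord(f"T{i}", "test", "nonBRCA") for i in range(n_test)]
    return CohortManifest(samples=samples)


def selection_with(counts: dict[str, dict[str, int]]) -> PpvSelection:
    """counts: sample -> gene -> number of distinct PPVs."""
    per_sample = {}
    pos = 1
    for s, genes in counts.items():
        calls = []
        for g, k in genes.items():
            for _ in range(k):
                calls.append(make_call(sample_id=s, gene=g, pos=pos))
                pos += 1
        per_sample[s] = calls
    return PpvSelection(per_sample=per_sample, mode=PpvMode.ALL,
                        frequency_threshold=0.01)


def test_absent_gene_is_interpretable_with_zero_stats():
    m = manifest_of(10, 5)
    sel = selection_with({})
    r = carrier_stats(sel, m, "TP53", NO_EXCL)
    assert r.interpretable
    assert r.fraction("BRCA1/2") == 0.0 and r.burden("BRCA1/2") == 0.0


@pytest.mark.parametrize(
    "n_carriers,interpretable", [(3, True), (4, False)]
)
def test_two_percent_rule_on_176_controls(n_carriers, interpretable):
    """3/176 = 1.7% of controls is interpretable; 4/176 = 2.27% is not
    (strict < 2%)."""
    m = manifest_of(176, 10)
    sel = selection_with({f"C{i}": {"TP53": 1} for i in range(n_carriers)})
    r = carrier_stats(sel, m, "TP53", NO_EXCL)
    assert r.fraction("BRCA1/2") == pytest.approx(n_carriers / 176)
    assert r.interpretable is interpretable


def test_burden_counts_ppvs_not_carriers():
    m = manifest_of(4, 0)
    sel = selection_with({"C0": {"TP53": 2}, "C1": {"TP53": 1}})
    r = carrier_stats(sel, m, "TP53", NO_EXCL)
    assert r.per_cohort["BRCA1/2"].n_carriers == 2
    assert r.burden("BRCA1/2") == pytest.approx(3 / 4)
    assert r.fraction("BRCA1/2") <= r.burden("BRCA1/2") + 1e-12


def test_empty_cohort_is_an_error():
    m = manifest_of(0, 5)
    sel = selection_with({})
    with pytest.raises(ValueError, match="control"):
        carrier_stats(sel, m, "TP53", NO_EXCL)


def test_percent_interpretable_extremes():
    panel = small_panel([f"G{i}" for i in range(10)])
    m = manifest_of(100, 10)
    results = gene_variance_table(selection_with({}), m, panel, NO_EXCL)
    assert percent_interpretable(results, panel, NO_EXCL) == 1.0
    hot = selection_with(
        {f"C{i}": {g: 1 for g in panel.genes} for i in range(3)}  # 3% carriers
    )
    results = gene_variance_table(hot, m, panel, NO_EXCL)
    assert percent_interpretable(results, panel, NO_EXCL) == 0.0


def test_planted_artifacts_reduce_percent_interpretable_by_count():
    """Planting a high-frequency LoF artifact in k of G genes leaves exactly
    (G - k)/G interpretable."""
    k = 3
    cfg = SimulationConfig(
        seed=17,
        n_genes=20,
        background_missense_rate=0.0,
        planted_lof=tuple(
            PlantedLof(f"G{i + 1:04d}", 0.5, "BRCA1/2") for i in range(k)
        ),
        n_samples=(("BRCA1/2", 40), ("nonBRCA", 20)),
    )
    panel = generate_panel(cfg)
    manifest, calls = generate_cohort(cfg)
    sel = select_ppvs(calls, panel, PpvConfig(mode=PpvMode.LOF))
    results = gene_variance_table(sel, manifest, panel, NO_EXCL)
    assert percent_interpretable(results, panel, NO_EXCL) == pytest.approx(
        (20 - k) / 20
    )


def test_exclude_genes_only_affects_percentage_universe():
    panel = small_panel(["BRCA1", "BRCA2", "TP53", "ATM"])
    m = manifest_of(100, 10)
    sel = selection_with({f"C{i}": {"BRCA1": 1} for i in range(50)})
    results = gene_variance_table(sel, m, panel, NO_EXCL)
    assert percent_interpretable(results, panel, NO_EXCL) == pytest.approx(3 / 4)
    cfg = VarianceConfig(exclude_genes=frozenset({"BRCA1", "BRCA2"}))
    assert percent_interpretable(results, panel, cfg) == 1.0


# ---------------------------------------------------------------------------
# coding-size correlation


def test_counts_proportional_to_length_give_r2_one():
    lengths = {"A": 500, "B": 1500, "C": 3000, "D": 6000}
    panel = small_panel(lengths, lengths)
    counts = {g: L / 100 for g, L in lengths.items()}
    assert coding_size_correlation(counts, panel) == pytest.approx(1.0)


def test_permuted_counts_give_r2_near_zero():
    """Counts decoupled from length: mean r^2 over 100 permutations is small."""
    rng = np.random.default_rng(1)
    lengths = {f"G{i}": int(L) for i, L in enumerate(rng.lognormal(7.5, 0.8, 60))}
    panel = small_panel(lengths, lengths)
    base = np.array([lengths[g] / 50 for g in sorted(lengths)])
    r2s = []
    for _ in range(100):
        perm = rng.permutation(base)
        counts = {g: perm[i] for i, g in enumerate(sorted(lengths))}
        r2s.append(coding_size_correlation(counts, panel))
    assert np.mean(r2s) < 0.1


def test_degenerate_correlation_is_absent_not_zero():
    panel = small_panel(["A", "B", "C"], {"A": 1000, "B": 1000, "C": 1000})
    assert coding_size_correlation({"A": 1, "B": 2, "C": 3}, panel) is None
    panel2 = small_panel(["A", "B", "C"], {"A": 500, "B": 1000, "C": 2000})
    assert coding_size_correlation({"A": 2, "B": 2, "C": 2}, panel2) is None
    assert coding_size_correlation({"A": 1, "B": 2}, small_panel(["A", "B"])) is None


# ---------------------------------------------------------------------------
# frequency-threshold sweep


@pytest.fixture(scope="module")
def sweep_data():
    cfg = SimulationConfig(
        seed=23,
        n_genes=30,
        background_missense_rate=4e-5,
        n_samples=(("BRCA1/2", 30), ("nonBRCA", 15)),
    )
    manifest, calls = generate_cohort(cfg)
    return generate_panel(cfg), manifest, calls


def test_sweep_row_equals_direct_computation(sweep_data):
    panel, manifest, calls = sweep_data
    table = frequency_threshold_sweep(calls, panel, manifest, [0.01], cfg=NO_EXCL)
    sel = select_ppvs(calls, panel, PpvConfig(frequency_threshold=0.01))
    results = gene_variance_table(sel, manifest, panel, NO_EXCL)
    row = table.iloc[0]
    assert row["n_ppvs"] == sel.n_ppvs
    assert row["percent_interpretable"] == pytest.approx(
        percent_interpretable(results, panel, NO_EXCL)
    )
    assert row["mean_ppvs_per_individual"] == pytest.approx(
        sel.n_ppvs / len(manifest)
    )


def test_sweep_matches_brute_force_at_each_threshold(sweep_data):
    panel, manifest, calls = sweep_data
    thresholds = [0.001, 0.005, 0.01, 0.05]
    table = frequency_threshold_sweep(calls, panel, manifest, thresholds, cfg=NO_EXCL)
    counts = list(table["n_ppvs"])
    assert counts == sorted(counts)  # non-decreasing in threshold
    for t, n in zip(thresholds, counts):
        direct = select_ppvs(calls, panel, PpvConfig(frequency_threshold=t))
        assert n == direct.n_ppvs


def test_sweep_requires_sorted_thresholds(sweep_data):
    panel, manifest, calls = sweep_data
    with pytest.raises(ValueError, match="sorted"):
        frequency_threshold_sweep(calls, panel, manifest, [0.05, 0.01])
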