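"""Burden summaries, detection rates and the exact statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_call
from wgsinterp import fixtures as fx
from wgsinterp.cohort_stats import (
    binomial_ci,
    detection_rate,
    fisher_exact,
    ppv_burden,
    round_percent,
    summarize_scores_by_class,
)
from wgsinterp.models import CohortManifest, Consequence, SampleRecord
from wgsinterp.ppv_classification import (
    DetectionOutcome,
    DetectionStatus,
    PpvConfig,
    PpvMode,
    PpvSelection,
    confirm_clinical_mutation,
    select_ppvs,
)
from wgsinterp.synthetic_data import SimulationConfig, generate_cohort, generate_panel


def manifest_of(n, label="BRCA1/2", cls="control"):
    return CohortManifest(
        samples=[SampleRecord(f"S{i}", cls, label) for i in range(n)]
    )


def selection_counts(counts: list[int]) -> PpvSelection:
    per_sample = {
        f"S{i}": [make_call(sample_id=f"S{i}", pos=100 + j) for j in range(k)]
        for i, k in enumerate(counts)
    }
    return PpvSelection(per_sample=per_sample, mode=PpvMode.ALL,
                        frequency_threshold=0.01)


def test_burden_mean_and_histogram():
    burden = ppv_burden(selection_counts([2, 4]), manifest_of(2))
    assert burden.mean("BRCA1/2") == 3.0
    assert burden.per_cohort_histogram["BRCA1/2"] == {2: 1, 4: 1}
    zero = ppv_burden(selection_counts([]), manifest_of(3))
    assert zero.mean("BRCA1/2") == 0.0
    assert zero.per_cohort_histogram["BRCA1/2"] == {0: 3}


def test_synthetic_burden_matches_poisson_expectation():
    """Cohort mean PPVs per individual sits inside a 3-sigma band around the
    generator expectation mu * sum(L_g) (all background variants are PPVs
    before quality filtering: rare or novel by construction in 90% of
    non-novel draws; allow for the common-frequency leakage)."""
    cfg = SimulationConfig(
        seed=31,
        n_genes=80,
        background_missense_rate=3e-5,
        n_samples=(("BRCA1/2", 120), ("nonBRCA", 40)),
    )
    panel = generate_panel(cfg)
    manifest, calls = generate_cohort(cfg)
    sel = select_ppvs(calls, panel, PpvConfig())
    total_len = sum(e.coding_length for e in panel.entries.values())
    lam = cfg.background_missense_rate * total_len
    # a PPV requires rarity in both panels: novel, or non-novel rare draw
    p_rare = cfg.novel_fraction + (1 - cfg.novel_fraction) * cfg.rare_mass
    expected = lam * p_rare
    observed = ppv_burden(sel, manifest).mean("BRCA1/2")
    sigma = np.sqrt(lam / 120)
    assert abs(observed - expected) < 3 * sigma


# ---------------------------------------------------------------------------
# detection rate


def test_detection_rates_match_published_accounting():
    """75 expected carriers with 8 low-quality recoveries -> 89.3%; 88 with
    10 -> 88.6%; 16 of the 18 low-quality recoveries are indels."""
    manifest, calls = fx.detection_scenario()
    by_label = {}
    for label in ("BRCA1", "BRCA2"):
        statuses = [
            confirm_clinical_mutation(calls, s)
            for s in manifest
            if s.cohort_label == label
        ]
        by_label[label] = detection_rate(statuses)
    assert (by_label["BRCA1"].n_expected, by_label["BRCA1"].n_high_quality) == (75, 67)
    assert round_percent(by_label["BRCA1"].rate) == 89.3
    assert (by_label["BRCA2"].n_expected, by_label["BRCA2"].n_high_quality) == (88, 78)
    assert round_percent(by_label["BRCA2"].rate) == 88.6
    pooled = detection_rate(
        [confirm_clinical_mutation(calls, s) for s in manifest]
    )
    assert pooled.low_quality_categories["indel"] == 16
    assert pooled.n_low_quality == 18


def test_detection_rate_all_high_quality_is_one():
    statuses = [
        DetectionStatus(f"S{i}", DetectionOutcome.DETECTED_HIGH_QUALITY, "snv")
        for i in range(5)
    ]
    assert detection_rate(statuses).rate == 1.0


def test_detection_rate_without_expected_samples_is_an_error():
    statuses = [DetectionStatus("S1", DetectionOutcome.NOT_EXPECTED, "cnv")]
    with pytest.raises(ValueError, match="expected"):
        detection_rate(statuses)


# ---------------------------------------------------------------------------
# exact binomial CI


def _ci_bisection_oracle(k, n, level=0.95, tol=1e-10):
    """Invert the binomial tail probabilities by bisection."""
    alpha = 1 - level

    def solve(f, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if k == 0 else solve(
        lambda p: sps.binom.sf(k - 1, n, p) < alpha / 2, 0.0, 1.0
    )
    upper = 1.0 if k == n else solve(
        lambda p: sps.binom.cdf(k, n, p) >= alpha / 2, 0.0, 1.0
    )
    return lower, upper


def test_exact_ci_reproduces_printed_worked_example():
    """17 of 82 patients -> 20.7% with exact 95% CI 12.6-31.1%."""
    lo, hi = binomial_ci(17, 82)
    assert round_percent(17 / 82) == 20.7
    assert (round(lo, 3), round(hi, 3)) == (0.126, 0.311)
    assert (round_percent(lo), round_percent(hi)) == (12.6, 31.1)


@pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (5, 10), (1, 82), (17, 82)])
def test_exact_ci_matches_bisection_oracle(k, n):
    lo, hi = binomial_ci(k, n)
    olo, ohi = _ci_bisection_oracle(k, n)
    assert lo == pytest.approx(olo, abs=1e-8)
    assert hi == pytest.approx(ohi, abs=1e-8)
    if k == 0:
        assert lo == 0.0
    if k == n:
        assert hi == 1.0


def test_exact_ci_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        binomial_ci(5, 4)
    with pytest.raises(ValueError):
        binomial_ci(-1, 4)
    with pytest.raises(ValueError):
        binomial_ci(1, 4, level=1.0)


def test_exact_ci_coverage_at_nominal_level():
    """Over 1000 simulated Binomial(82, 0.2) draws the 95% interval covers
    the truth at least 93% of the time."""
    rng = np.random.default_rng(2024)
    draws = rng.binomial(82, 0.2, size=1000)
    covered = 0
    for k in draws:
        lo, hi = binomial_ci(int(k), 82)
        covered += lo <= 0.2 <= hi
    assert covered >= 930


# ---------------------------------------------------------------------------
# Fisher's exact test


def _fisher_enumeration_oracle(a, b, c, d):
    """Sum hypergeometric probabilities <= the observed table's, over all
    tables with the observed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: sps.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-10))


def test_fisher_identical_proportions_give_p_one():
    assert fisher_exact(1, 9, 1, 9) == pytest.approx(1.0)


def test_fisher_perfect_separation_small_table():
    # 2 of the 252 equiprobable-margin tables are at least as extreme
    assert fisher_exact(5, 0, 0, 5) == pytest.approx(2 / 252)


@pytest.mark.parametrize(
    "table",
    [(3, 7, 9, 1), (0, 12, 5, 5), (6, 6, 6, 6), (17, 65, 8, 67), (1, 0, 0, 1)],
)
def test_fisher_matches_enumeration_oracle(table):
    assert fisher_exact(*table) == pytest.approx(
        _fisher_enumeration_oracle(*table), abs=1e-12
    )


@pytest.mark.parametrize("table", [(3, 7, 9, 1), (0, 12, 5, 5), (2, 11, 4, 3)])
def test_fisher_symmetry_under_row_and_column_swap(table):
    a, b, c, d = table
    p = fisher_exact(a, b, c, d)
    assert fisher_exact(c, d, a, b) == pytest.approx(p)
    assert fisher_exact(b, a, d, c) == pytest.approx(p)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.integers(0, 25), b=st.integers(0, 25),
    c=st.integers(0, 25), d=st.integers(0, 25),
)
def test_fisher_invariants_hold_on_arbitrary_tables(a, b, c, d):
    """p is a probability, invariant under row/column swaps, and 1.0 for
    tables with a zero margin (no discriminating information)."""
    if a + b + c + d == 0:
        return
    p = fisher_exact(a, b, c, d)
    assert 0.0 <= p <= 1.0 + 1e-12
    assert fisher_exact(c, d, a, b) == pytest.approx(p)
    assert fisher_exact(b, a, d, c) == pytest.approx(p)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        assert p == pytest.approx(1.0)


def test_fisher_rejects_degenerate_tables():
    with pytest.raises(ValueError):
        fisher_exact(0, 0, 0, 0)
    with pytest.raises(ValueError):
        fisher_exact(-1, 1, 1, 1)


# ---------------------------------------------------------------------------
# score summaries


def test_scores_all_absent_yields_empty_summary_with_count():
    calls = [make_call(pos=p) for p in (100, 200)]
    df = summarize_scores_by_class(calls)
    assert df.empty
    assert df.attrs["n_absent_total"] == 2


def test_score_median_per_class():
    calls = [make_call(pos=p, score=s) for p, s in [(1, 10), (2, 20), (3, 30)]]
    df = summarize_scores_by_class(calls)
    assert df.loc[df.consequence == "missense", "median"].item() == 20


def test_score_quartiles_match_sort_based_oracle():
    rng = np.random.default_rng(3)
    scores = rng.uniform(0, 50, size=41)
    calls = [
        make_call(pos=100 + i, score=float(s)) for i, s in enumerate(scores)
    ] + [make_call(pos=900, consequence=Consequence.NONSENSE, score=44.0),
         make_call(pos=901)]  # one unscored call
    df = summarize_scores_by_class(calls).set_index("consequence")
    assert df.loc["missense", "median"] == pytest.approx(np.sort(scores)[20])
    assert df.loc["missense", "q1"] == pytest.approx(np.quantile(scores, 0.25))
    assert df.loc["missense", "n_absent"] == 1
    assert df.loc["nonsense", "n"] == 1
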