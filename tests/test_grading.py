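"""Grade mapping and agreement statistics, each checked against an
independent brute-force oracle where one exists."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stenokit.errors import StenokitError
from stenokit.grading import (
    average_reference,
    dichotomous_metrics,
    evaluate_rating_table,
    grade_from_percent,
    interpret_correlation,
    interpret_kappa,
    load_rating_table,
    spearman_with_band,
    weighted_kappa,
    wilcoxon_matched_pairs,
)

# ---------------------------------------------------------------- grade map


@pytest.mark.parametrize(
    "p,grade",
    [
        (0.0, 1),
        (0.10, 1),
        (0.24, 1),
        (0.245, 1),  # rounds to 24 %
        (0.25, 2),
        (0.30, 2),
        (0.50, 2),
        (0.51, 3),
        (0.60, 3),
        (0.75, 3),
        (0.76, 4),
        (0.85, 4),
        (0.99, 4),
        (1.0, 5),
    ],
)
def test_grade_bands(p, grade):
    assert grade_from_percent(p) == grade


@pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan")])
def test_grade_rejects_out_of_range(bad):
    with pytest.raises(StenokitError):
        grade_from_percent(bad)


@given(st.floats(min_value=0.0, max_value=1.0))
@settings(max_examples=200, deadline=None)
def test_grade_total_and_bounded(p):
    assert grade_from_percent(p) in {1, 2, 3, 4, 5}


def test_grade_monotone_and_surjective():
    grid = np.linspace(0.0, 1.0, 2001)
    grades = [grade_from_percent(float(p)) for p in grid]
    assert all(a <= b for a, b in zip(grades, grades[1:]))
    assert set(grades) == {1, 2, 3, 4, 5}


# ------------------------------------------------------------- kappa


def kappa_oracle(a, b, scheme):
    """Textbook double-sum weighted kappa on the 5x5 contingency table."""
    k = 5
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[x - 1, y - 1] += 1
    obs /= obs.sum()
    pa, pb = obs.sum(axis=1), obs.sum(axis=0)
    exp = np.outer(pa, pb)
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(i - j) / (k - 1) if scheme == "linear" else ((i - j) / (k - 1)) ** 2
    return 1.0 - (w * obs).sum() / (w * exp).sum()


def test_kappa_perfect_agreement():
    assert weighted_kappa([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]).value == pytest.approx(1.0)


@pytest.mark.parametrize("scheme", ["linear", "quadratic"])
def test_kappa_matches_bruteforce_on_enumerated_tables(scheme):
    """All grade-vector pairs of length 3 over {1,3,5}, plus random n<=8."""
    vecs = list(itertools.product([1, 3, 5], repeat=3))
    for a in vecs[::3]:
        for b in vecs[::3]:
            got = weighted_kappa(a, b, weights=scheme)
            if len(set(a) | set(b)) == 1:
                assert not got.defined
                continue
            want = kappa_oracle(a, b, scheme)
            if np.isfinite(want):
                assert got.value == pytest.approx(want, abs=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(2, 9))
        a = rng.integers(1, 6, n)
        b = rng.integers(1, 6, n)
        got = weighted_kappa(a, b, weights=scheme)
        want = kappa_oracle(a, b, scheme)
        if got.defined and np.isfinite(want):
            assert got.value == pytest.approx(want, abs=1e-12)


def test_kappa_symmetric_in_raters():
    rng = np.random.default_rng(1)
    a = rng.integers(1, 6, 30)
    b = rng.integers(1, 6, 30)
    assert weighted_kappa(a, b).value == pytest.approx(weighted_kappa(b, a).value)


def test_kappa_independent_uniform_ratings_near_zero():
    rng = np.random.default_rng(42)
    a = rng.integers(1, 6, 10_000)
    b = rng.integers(1, 6, 10_000)
    assert abs(weighted_kappa(a, b).value) < 0.05


def test_kappa_single_grade_flagged_not_nan():
    res = weighted_kappa([2, 2, 2], [2, 2, 2])
    assert res.value is None and "undefined" in res.flag


@pytest.mark.parametrize(
    "k,band",
    [(0.70, "good"), (0.95, "excellent"), (0.40, "poor"), (0.404, "poor"),
     (0.41, "moderate"), (0.60, "moderate"), (0.61, "good"), (0.80, "good"),
     (0.81, "excellent"), (1.0, "excellent"), (-0.2, "poor")],
)
def test_kappa_bands(k, band):
    assert interpret_kappa(k) == band


# ------------------------------------------------------------- spearman


def spearman_oracle(a, b):
    """Pearson correlation of midranks, computed from first principles."""

    def midranks(v):
        v = np.asarray(v, float)
        out = np.empty(len(v))
        for i, x in enumerate(v):
            less = np.sum(v < x)
            eq = np.sum(v == x)
            out[i] = less + (eq + 1) / 2.0
        return out

    ra, rb = midranks(a), midranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float(np.sum(ra * rb) / np.sqrt(np.sum(ra**2) * np.sum(rb**2)))


def test_spearman_identity_and_reversal():
    a = [1, 2, 3, 4, 5]
    r, band = spearman_with_band(a, a)
    assert r.value == pytest.approx(1.0) and band == "strong"
    r2, _ = spearman_with_band(a, [10, 8, 6, 4, 2])
    assert r2.value == pytest.approx(-1.0)


def test_spearman_ties_match_midrank_oracle():
    vecs = list(itertools.product([1, 2, 3], repeat=4))
    for a in vecs[::5]:
        for b in vecs[::7]:
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            r, _ = spearman_with_band(a, b)
            assert r.value == pytest.approx(spearman_oracle(a, b), abs=1e-12)


def test_spearman_zero_variance_flagged():
    r, band = spearman_with_band([2, 2, 2, 2], [1, 2, 3, 4])
    assert r.value is None and band is None


@pytest.mark.parametrize(
    "r,band",
    [(0.05, "negligible"), (0.2, "weak"), (-0.25, "weak"), (0.4, "moderate"),
     (0.5, "moderate"), (0.51, "strong"), (-0.9, "strong")],
)
def test_correlation_bands(r, band):
    assert interpret_correlation(r) == band


# ------------------------------------------------------- dichotomous metrics


def test_dichotomous_perfect():
    m = dichotomous_metrics([1, 2, 4, 5, 3], [1, 2, 4, 5, 3])
    assert m.sensitivity.value == m.specificity.value == m.ppv.value == m.npv.value == 1.0


def test_dichotomous_no_positives_in_truth():
    m = dichotomous_metrics([1, 2, 3], [1, 4, 3])
    assert m.sensitivity.value is None and "undefined" in m.sensitivity.flag
    assert m.specificity.value == pytest.approx(2 / 3)


def test_dichotomous_counts_arithmetic():
    # TP=5, FN=1, FP=0, TN=94
    truth = [4] * 6 + [1] * 94
    pred = [4] * 5 + [1] + [1] * 94
    m = dichotomous_metrics(truth, pred)
    assert (m.tp, m.fn, m.fp, m.tn) == (5, 1, 0, 94)
    assert m.sensitivity.value == pytest.approx(5 / 6)
    assert m.specificity.value == pytest.approx(1.0)


def test_dichotomous_rates_reproducible_from_counts():
    rng = np.random.default_rng(2)
    truth = rng.integers(1, 6, 60)
    pred = rng.integers(1, 6, 60)
    m = dichotomous_metrics(truth, pred)
    if m.sensitivity.defined:
        assert m.sensitivity.value == pytest.approx(m.tp / (m.tp + m.fn))
    if m.ppv.defined:
        assert m.ppv.value == pytest.approx(m.tp / (m.tp + m.fp))


# ------------------------------------------------------------- wilcoxon


def wilcoxon_exact_oracle(diffs):
    """Two-sided exact signed-rank p by full enumeration of sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    tobs = ranks[d > 0].sum()
    ts = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ts.append(sum(r for r, s in zip(ranks, signs) if s))
    ts = np.array(ts)
    return min(1.0, 2 * min((ts <= tobs).mean(), (ts >= tobs).mean()))


def test_wilcoxon_identical_flagged():
    res = wilcoxon_matched_pairs([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert res.value == 1.0 and "no nonzero" in res.flag


def test_wilcoxon_systematic_shift_significant():
    a = np.arange(20.0)
    assert wilcoxon_matched_pairs(a, a + 1).value < 0.05


def test_wilcoxon_exact_matches_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = int(rng.integers(5, 9))
        d = np.round(rng.normal(0, 1, n), 3)
        while len(set(np.abs(d))) < n or np.any(d == 0):
            d = np.round(rng.normal(0, 1, n), 3)
        a = np.zeros(n)
        got = wilcoxon_matched_pairs(d, a).value
        assert got == pytest.approx(wilcoxon_exact_oracle(d), abs=1e-12)


def test_wilcoxon_null_p_uniform():
    """Type-I behavior: p-values under a symmetric null are ~ Uniform(0,1)."""
    rng = np.random.default_rng(4)
    ps = []
    for _ in range(200):
        d = rng.normal(0, 1, 50)
        ps.append(wilcoxon_matched_pairs(d, np.zeros(50)).value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ------------------------------------------------------------ table I/O


def test_average_reference_rounding():
    a = [1, 2, 3]
    b = [2, 2, 4]  # averages 1.5, 2.0, 3.5
    assert list(average_reference(a, b)) == [2, 2, 4]
    assert list(average_reference(a, b, mode="floor")) == [1, 2, 3]
    assert list(average_reference(a, b, mode="ceil")) == [2, 2, 4]


def _write_csv(path, text):
    path.write_text(text)
    return path


def test_rating_table_roundtrip_and_stats(tmp_path):
    p = _write_csv(
        tmp_path / "r.csv",
        "case_id,segment,rater_a,rater_b\n"
        "1,AAI,1,1\n1,CIA_right,2,2\n2,AAI,3,4\n2,CIA_right,4,4\n3,AAI,1,2\n3,CIA_right,5,5\n",
    )
    df = load_rating_table(p)
    out = evaluate_rating_table(df)
    assert out["pooled"]["n"] == 6
    assert set(out["per_segment"]) == {"AAI", "CIA_right"}


def test_rating_table_missing_grade_names_row(tmp_path):
    p = _write_csv(tmp_path / "r.csv", "case_id,segment,rater_a,rater_b\n1,AAI,1,1\n2,AAI,,3\n")
    with pytest.raises(StenokitError, match="row 3"):
        load_rating_table(p)


def test_rating_table_duplicate_rejected(tmp_path):
    p = _write_csv(tmp_path / "r.csv", "case_id,segment,rater_a,rater_b\n1,AAI,1,1\n1,AAI,2,2\n")
    with pytest.raises(StenokitError, match="duplicate"):
        load_rating_table(p)
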