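"""Clinical grading of stenosis percentages and rater-agreement statistics.

The 5-point grading scale maps a fractional diameter reduction to:

====== =================================== ==============
Grade  Description                         Stenosis range
====== =================================== ==============
1      No / non-relevant stenosis          0-24 %
2      Mild stenosis                       25-50 %
3      Moderate stenosis                   51-75 %
4      Severe stenosis                     76-99 %
5      Occlusion                           100 %
====== =================================== ==============

Agreement between two raters (or a rater and an automated method) over
ordinal grades is quantified with weighted Cohen's kappa, Spearman rank
correlation, dichotomized (high-grade {4,5} vs {1,2,3}) confusion metrics,
and the Wilcoxon matched-pairs signed-rank test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .errors import StenokitError

GRADES = (1, 2, 3, 4, 5)
HIGH_GRADES = frozenset({4, 5})

VESSEL_SEGMENTS = ("AAI", "CIA_right", "CIA_left", "EIA_right", "EIA_left")


def grade_from_percent(p: float) -> int:
    """Map a stenosis fraction in [0, 1] to the 5-point grade.

    The fraction is first rounded to an integer percent (half-to-even, after
    snapping away float noise, so 0.245 reads as 24 %), then banded:
    0-24 -> 1, 25-50 -> 2, 51-75 -> 3, 76-99 -> 4, 100 -> 5.
    """
    if not np.isfinite(p) or p < 0.0 or p > 1.0:
        raise StenokitError(f"stenosis fraction must be in [0, 1], got {p!r}")
    pct = int(round(round(p * 100.0, 9)))
    if pct <= 24:
        return 1
    if pct <= 50:
        return 2
    if pct <= 75:
        return 3
    if pct <= 99:
        return 4
    return 5


def interpret_kappa(k: float) -> str:
    """Agreement band for a kappa value (rounded to 2 decimals first):
    <= 0.40 poor, 0.41-0.60 moderate, 0.61-0.80 good, 0.81-1.0 excellent."""
    if not -1.0 <= k <= 1.0:
        raise StenokitError(f"kappa must be in [-1, 1], got {k}")
    k2 = round(k, 2)
    if k2 <= 0.40:
        return "poor"
    if k2 <= 0.60:
        return "moderate"
    if k2 <= 0.80:
        return "good"
    return "excellent"


def interpret_correlation(r: float) -> str:
    """Strength band for a correlation coefficient: |r| <= 0.1 negligible,
    0.1 < |r| <= 0.3 weak, 0.3 < |r| <= 0.5 moderate, > 0.5 strong."""
    a = abs(r)
    if a > 1.0 + 1e-12:
        raise StenokitError(f"correlation must be in [-1, 1], got {r}")
    if a <= 0.1:
        return "negligible"
    if a <= 0.3:
        return "weak"
    if a <= 0.5:
        return "moderate"
    return "strong"


def _check_grades(v: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise StenokitError(f"{name} must be a 1-D grade vector")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise StenokitError(f"{name} contains non-integer grades")
        arr = arr.astype(int)
    if arr.size and (arr.min() < 1 or arr.max() > 5):
        raise StenokitError(f"{name} grades must be in 1..5")
    return arr


@dataclass
class FlaggedValue:
    """A statistic that may be undefined on degenerate input."""

    value: float | None
    flag: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


def weighted_kappa(rater_a: Sequence[int], rater_b: Sequence[int], weights: str = "linear") -> FlaggedValue:
    """Weighted Cohen's kappa over the 5x5 contingency of two graders.

    weights: ``"linear"`` (default) or ``"quadratic"``. Returns a flagged
    result (kappa undefined) when both raters use a single identical grade,
    where chance agreement equals observed agreement.
    """
    if weights not in ("linear", "quadratic"):
        raise StenokitError("weights must be 'linear' or 'quadratic'")
    a = _check_grades(rater_a, "rater_a")
    b = _check_grades(rater_b, "rater_b")
    if a.shape != b.shape:
        raise StenokitError("rating vectors must have equal length")
    if a.size < 2:
        raise StenokitError("need at least 2 paired ratings")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return FlaggedValue(None, "kappa undefined: a single grade used by both raters")
    k = cohen_kappa_score(a, b, weights=weights, labels=list(GRADES))
    return FlaggedValue(float(k))


def spearman_with_band(a: Sequence[float], b: Sequence[float]) -> tuple[FlaggedValue, str | None]:
    """Spearman rank correlation (average ranks for ties) with its strength band."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StenokitError("vectors must be 1-D and of equal length")
    if x.size < 3:
        raise StenokitError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return FlaggedValue(None, "correlation undefined: zero variance"), None
    r = float(stats.spearmanr(x, y).statistic)
    return FlaggedValue(r), interpret_correlation(r)


@dataclass
class DichotomousMetrics:
    """Confusion metrics for the high-grade {4,5} vs {1,2,3} dichotomy."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: FlaggedValue = field(init=False)
    specificity: FlaggedValue = field(init=False)
    ppv: FlaggedValue = field(init=False)
    npv: FlaggedValue = field(init=False)

    def __post_init__(self) -> None:
        self.sensitivity = self._rate(self.tp, self.tp + self.fn, "no positive cases in truth")
        self.specificity = self._rate(self.tn, self.tn + self.fp, "no negative cases in truth")
        self.ppv = self._rate(self.tp, self.tp + self.fp, "no positive predictions")
        self.npv = self._rate(self.tn, self.tn + self.fn, "no negative predictions")

    @staticmethod
    def _rate(num: int, den: int, reason: str) -> FlaggedValue:
        if den == 0:
            return FlaggedValue(None, f"undefined: {reason}")
        return FlaggedValue(num / den)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            fv: FlaggedValue = getattr(self, name)
            out[name] = fv.value
            if fv.flag:
                out[f"{name}_flag"] = fv.flag
        return out


def dichotomous_metrics(truth: Sequence[int], pred: Sequence[int]) -> DichotomousMetrics:
    """Sensitivity/specificity/PPV/NPV with positives = grade in {4, 5}."""
    t = _check_grades(truth, "truth")
    p = _check_grades(pred, "pred")
    if t.shape != p.shape:
        raise StenokitError("truth and pred must have equal length")
    tpos = np.isin(t, list(HIGH_GRADES))
    ppos = np.isin(p, list(HIGH_GRADES))
    return DichotomousMetrics(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def wilcoxon_matched_pairs(a: Sequence[float], b: Sequence[float]) -> FlaggedValue:
    """Two-sided Wilcoxon matched-pairs signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original treatment). The exact
    null distribution is used for n <= 25 without tied ranks, a normal
    approximation with continuity correction otherwise. All-zero differences
    yield p = 1.0 with a flag instead of an error.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StenokitError("vectors must be 1-D and of equal length")
    diffs = x - y
    n_nonzero = int(np.sum(diffs != 0))
    if n_nonzero == 0:
        return FlaggedValue(1.0, "no nonzero differences")
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=True, alternative="two-sided", method="auto"
    )
    flag = None
    if n_nonzero < 5:
        flag = f"only {n_nonzero} nonzero differences"
    return FlaggedValue(float(res.pvalue), flag)


def average_reference(rater_a: Sequence[int], rater_b: Sequence[int], mode: str = "half_up") -> np.ndarray:
    """Average two raters' grades into an integer reference standard.

    Half-integer averages are resolved by ``half_up`` (default), ``floor``
    or ``ceil``; kappa needs integer categories.
    """
    a = _check_grades(rater_a, "rater_a").astype(float)
    b = _check_grades(rater_b, "rater_b").astype(float)
    avg = (a + b) / 2.0
    if mode == "half_up":
        out = np.floor(avg + 0.5)
    elif mode == "floor":
        out = np.floor(avg)
    elif mode == "ceil":
        out = np.ceil(avg)
    else:
        raise StenokitError(f"unknown rounding mode {mode!r}")
    return out.astype(int)


@dataclass
class AgreementResult:
    """Bundle of the agreement statistics for one paired rating set."""

    n: int
    kappa: float | None
    kappa_flag: str | None
    kappa_band: str | None
    kappa_weights: str
    spearman_r: float | None
    spearman_flag: str | None
    r_band: str | None
    wilcoxon_p: float | None
    wilcoxon_flag: str | None
    dichotomous: DichotomousMetrics

    def to_dict(self) -> dict[str, Any]:
        return {
            "n": self.n,
            "kappa": self.kappa,
            "kappa_flag": self.kappa_flag,
            "kappa_band": self.kappa_band,
            "kappa_weights": self.kappa_weights,
            "spearman_r": self.spearman_r,
            "spearman_flag": self.spearman_flag,
            "r_band": self.r_band,
            "wilcoxon_p": self.wilcoxon_p,
            "wilcoxon_flag": self.wilcoxon_flag,
            "dichotomous": self.dichotomous.to_dict(),
        }


def agreement(
    rater_a: Sequence[int],
    rater_b: Sequence[int],
    weights: str = "linear",
    exclude_grade5: bool = False,
) -> AgreementResult:
    """All agreement statistics for one pair of grade vectors.

    With ``exclude_grade5=True``, pairs where the reference rater assigned
    grade 5 are dropped first — skeleton-based assessment cannot represent an
    occlusion, so such cases are excluded from method-vs-reference
    comparisons.
    """
    a = _check_grades(rater_a, "rater_a")
    b = _check_grades(rater_b, "rater_b")
    if a.shape != b.shape:
        raise StenokitError("rating vectors must have equal length")
    if exclude_grade5:
        keep = a != 5
        a, b = a[keep], b[keep]
    if a.size < 2:
        raise StenokitError("need at least 2 paired ratings after exclusions")
    kap = weighted_kappa(a, b, weights=weights)
    band = interpret_kappa(kap.value) if kap.defined else None
    rho, rband = spearman_with_band(a, b)
    wil = wilcoxon_matched_pairs(a, b)
    return AgreementResult(
        n=int(a.size),
        kappa=kap.value,
        kappa_flag=kap.flag,
        kappa_band=band,
        kappa_weights=weights,
        spearman_r=rho.value,
        spearman_flag=rho.flag,
        r_band=rband,
        wilcoxon_p=wil.value,
        wilcoxon_flag=wil.flag,
        dichotomous=dichotomous_metrics(a, b),
    )


def load_rating_table(path: str | Path) -> pd.DataFrame:
    """Read a paired rating CSV with header case_id,segment,rater_a,rater_b.

    Raises with the offending row number on missing or out-of-range grades
    and on duplicate (case_id, segment) pairs.
    """
    df = pd.read_csv(path)
    required = ["case_id", "segment", "rater_a", "rater_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StenokitError(f"rating CSV missing columns: {missing}")
    for col in ("rater_a", "rater_b"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise StenokitError(f"missing grade in column {col!r} at CSV row {bad[0] + 2}")
        vals = df[col].to_numpy()
        offgrid = df.index[(vals < 1) | (vals > 5) | (vals != np.floor(vals))]
        if len(offgrid):
            raise StenokitError(f"invalid grade in column {col!r} at CSV row {offgrid[0] + 2}")
        df[col] = df[col].astype(int)
    dup = df.duplicated(subset=["case_id", "segment"])
    if dup.any():
        raise StenokitError(f"duplicate case_id x segment at CSV row {df.index[dup][0] + 2}")
    return df


def evaluate_rating_table(df: pd.DataFrame, weights: str = "linear", exclude_grade5: bool = False) -> dict[str, Any]:
    """Per-segment and pooled agreement statistics for a rating table."""
    out: dict[str, Any] = {"weights": weights, "per_segment": {}, "pooled": None}
    for seg, grp in df.groupby("segment", sort=True):
        if len(grp) >= 2:
            out["per_segment"][str(seg)] = agreement(
                grp["rater_a"], grp["rater_b"], weights=weights, exclude_grade5=exclude_grade5
            ).to_dict()
    out["pooled"] = agreement(
        df["rater_a"], df["rater_b"], weights=weights, exclude_grade5=exclude_grade5
    ).to_dict()
    return out
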