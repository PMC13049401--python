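"""Evaluation battery for angle agreement and categorical performance.

Agreement between predicted and ground-truth Cobb angles is summarized by
the mean absolute error and its dispersion (sample SD, quartiles, IQR), an
ordinary least-squares R² (ground truth regressed on predictions, i.e.
predictions on the x-axis), and Bland–Altman bias with 95% limits of
agreement ``bias ± 1.96 × SD(differences)``. Two models scored on the same
images are compared with the classical paired t test on their absolute
errors.

Categorical performance (severity grades, curve types) is summarized by a
confusion matrix and one-vs-rest sensitivity, specificity, precision, NPV
and accuracy per class, each with a 95% Wilson score confidence interval
(Clopper–Pearson available via ``ci_method="clopper-pearson"``), plus
unweighted macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    DegenerateRegressionError,
    IncompatibilityError,
    InsufficientDataError,
    ValidationError,
    ZeroVarianceError,
)

LOA_MULTIPLIER = 1.96  # 95% limits of agreement

METRIC_NAMES = ("sensitivity", "specificity", "precision", "npv", "accuracy")


@dataclass
class PairedAngles:
    """Paired predicted/ground-truth angles, optionally tagged by group."""

    predicted: np.ndarray
    ground_truth: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.ground_truth = np.asarray(self.ground_truth, dtype=float)
        if self.predicted.shape != self.ground_truth.shape or self.predicted.ndim != 1:
            raise IncompatibilityError(
                f"predicted and ground_truth must be equal-length 1D, got "
                f"{self.predicted.shape} vs {self.ground_truth.shape}"
            )
        if self.predicted.size < 1:
            raise InsufficientDataError("need at least one pair")
        if not (np.isfinite(self.predicted).all() and np.isfinite(self.ground_truth).all()):
            raise ValidationError("angles must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.predicted.shape:
                raise IncompatibilityError("labels must match the angle arrays in length")

    def __len__(self) -> int:
        return self.predicted.size

    def by_group(self) -> dict[object, "PairedAngles"]:
        """Split into per-group PairedAngles using the labels."""
        if self.labels is None:
            return {None: self}
        return {
            g: PairedAngles(self.predicted[self.labels == g],
                            self.ground_truth[self.labels == g])
            for g in pd.unique(self.labels)
        }


@dataclass
class AgreementReport:
    """Residual, regression and Bland–Altman summary of one paired sample.

    ``t_stat``/``p_value`` are the one-sample paired t test of the signed
    differences against zero (the bias test); use :func:`paired_error_test`
    to compare two models.
    """

    n: int
    mae: float
    sd_abs_err: float
    q1: float
    median: float
    q3: float
    iqr: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float
    t_stat: float
    p_value: float
    quartiles_of: str = "absolute"

    def __post_init__(self) -> None:
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValidationError("limits of agreement must bracket the bias")
        if not self.q1 <= self.median <= self.q3:
            raise ValidationError("quartiles out of order")
        if abs(self.iqr - (self.q3 - self.q1)) > 1e-9:
            raise ValidationError("iqr != q3 - q1")

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n,
                "MAE (deg)": self.mae,
                "SD of |error| (deg)": self.sd_abs_err,
                "Q1 (deg)": self.q1,
                "median (deg)": self.median,
                "Q3 (deg)": self.q3,
                "IQR (deg)": self.iqr,
                "R^2": self.r_squared,
                "bias (deg)": self.bias,
                "95% LoA low (deg)": self.loa_low,
                "95% LoA high (deg)": self.loa_high,
                "t (bias vs 0)": self.t_stat,
                "p": self.p_value,
            }
        )


def agreement(p: PairedAngles, quartiles_of: str = "absolute") -> AgreementReport:
    """Full agreement analysis of predicted vs ground-truth angles.

    Quartiles use linear interpolation (the common "type 7" rule) and by
    default describe the absolute errors, matching the MAE framing; pass
    ``quartiles_of="signed"`` for the signed-difference distribution.
    Requires n >= 3 (sample SDs and the regression need it).
    """
    n = len(p)
    if n < 3:
        raise InsufficientDataError(f"agreement needs n >= 3, got {n}")
    if quartiles_of not in ("absolute", "signed"):
        raise ValidationError(f"quartiles_of must be 'absolute' or 'signed'")
    diff = p.predicted - p.ground_truth
    abs_err = np.abs(diff)
    if np.var(p.predicted) == 0:
        raise DegenerateRegressionError("predictions have zero variance; R^2 undefined")
    qsrc = abs_err if quartiles_of == "absolute" else diff
    q1, med, q3 = np.percentile(qsrc, [25, 50, 75])
    sd_diff = float(diff.std(ddof=1))
    bias = float(diff.mean())
    # GT regressed on predictions: predictions on the x-axis.
    lin = sps.linregress(p.predicted, p.ground_truth)
    if np.all(diff == diff[0]):
        t_stat, p_value = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
    else:
        t_res = sps.ttest_1samp(diff, 0.0)
        t_stat, p_value = float(t_res.statistic), float(t_res.pvalue)
    return AgreementReport(
        n=n,
        mae=float(abs_err.mean()),
        sd_abs_err=float(abs_err.std(ddof=1)),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(q3 - q1),
        r_squared=float(lin.rvalue**2),
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd_diff,
        loa_high=bias + LOA_MULTIPLIER * sd_diff,
        t_stat=t_stat,
        p_value=p_value,
        quartiles_of=quartiles_of,
    )


def paired_error_test(abs_err_a: Sequence[float],
                      abs_err_b: Sequence[float]) -> tuple[float, float]:
    """Paired t test comparing two models' absolute errors on the same images.

    Returns ``(t_stat, p_value)`` for the classical paired t statistic on
    ``a - b`` with n-1 degrees of freedom (two-sided).
    """
    a = np.asarray(abs_err_a, dtype=float)
    b = np.asarray(abs_err_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise IncompatibilityError("error lists must be equal-length 1D")
    if a.size < 2:
        raise InsufficientDataError(f"paired test needs n >= 2, got {a.size}")
    d = a - b
    if np.all(d == d[0]) and d.std(ddof=1) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ZeroVarianceError("all paired differences identical; p undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class MetricEstimate:
    """A binomial proportion with its 95% CI, or an undefined marker."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    successes: int = 0
    trials: int = 0
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass
class ClassificationReport:
    """Confusion matrix plus one-vs-rest metrics with CIs and macro averages."""

    classes: tuple
    confusion: np.ndarray  # rows = truth, cols = predicted
    per_class: dict = field(repr=False, default_factory=dict)
    macro: dict = field(repr=False, default_factory=dict)
    ci_method: str = "wilson"

    def summary(self) -> pd.DataFrame:
        rows = {}
        for cls in self.classes:
            rows[cls] = {
                m: (np.nan if not e.defined else e.value)
                for m, e in self.per_class[cls].items()
            }
        rows["macro"] = dict(self.macro)
        return pd.DataFrame(rows).T[list(METRIC_NAMES)]


def _proportion(successes: int, trials: int, name: str,
                ci_method: str) -> MetricEstimate:
    if trials == 0:
        return MetricEstimate(value=None, undefined_reason=f"{name}: empty denominator")
    method = {"wilson": "wilson", "clopper-pearson": "beta"}[ci_method]
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method=method)
    return MetricEstimate(value=successes / trials, ci_low=float(lo), ci_high=float(hi),
                          successes=successes, trials=trials)


def classification_report(truth: Sequence, pred: Sequence, classes: Sequence,
                          ci_method: str = "wilson") -> ClassificationReport:
    """One-vs-rest classification metrics with 95% CIs.

    For each class: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
    TP/(TP+FP), NPV TN/(TN+FN), accuracy (TP+TN)/n. Confidence intervals use
    the Wilson score interval by default. Metrics with an empty denominator
    are reported as undefined with a reason (never silently NaN); macro
    averages are the unweighted means over the classes where the metric is
    defined.
    """
    if ci_method not in ("wilson", "clopper-pearson"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise IncompatibilityError("truth and pred must have equal length")
    if len(truth) == 0:
        raise InsufficientDataError("need at least one sample")
    classes = tuple(classes)
    unknown = sorted({str(x) for x in list(truth) + list(pred) if x not in classes})
    if unknown:
        raise ValidationError(f"labels outside the class list: {unknown}")
    cm = _sk_confusion(truth, pred, labels=list(classes))
    n = int(cm.sum())
    per_class: dict = {}
    for k, cls in enumerate(classes):
        tp = int(cm[k, k])
        fn = int(cm[k, :].sum() - tp)
        fp = int(cm[:, k].sum() - tp)
        tn = n - tp - fn - fp
        per_class[cls] = {
            "sensitivity": _proportion(tp, tp + fn, "sensitivity", ci_method),
            "specificity": _proportion(tn, tn + fp, "specificity", ci_method),
            "precision": _proportion(tp, tp + fp, "precision", ci_method),
            "npv": _proportion(tn, tn + fn, "npv", ci_method),
            "accuracy": _proportion(tp + tn, n, "accuracy", ci_method),
        }
    macro = {}
    for m in METRIC_NAMES:
        vals = [per_class[c][m].value for c in classes if per_class[c][m].defined]
        macro[m] = float(np.mean(vals)) if vals else np.nan
    return ClassificationReport(classes=classes, confusion=cm, per_class=per_class,
                                macro=macro, ci_method=ci_method)


def plot_bland_altman(p: PairedAngles, ax=None):
    """Bland–Altman plot: paired differences against pair means, with the
    bias line and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    rep = agreement(p)
    if ax is None:
        _, ax = plt.subplots()
    means = (p.predicted + p.ground_truth) / 2.0
    diffs = p.predicted - p.ground_truth
    ax.scatter(means, diffs, s=12, alpha=0.6)
    ax.axhline(rep.bias, color="k", lw=1, label=f"bias {rep.bias:.2f}")
    for y in (rep.loa_low, rep.loa_high):
        ax.axhline(y, color="r", ls="--", lw=1)
    ax.set_xlabel("mean of predicted and ground truth (deg)")
    ax.set_ylabel("predicted - ground truth (deg)")
    ax.legend(loc="best")
    return ax
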