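"""Inter-rater agreement statistics for categorical and continuous outputs.

Covers everything the evaluation reports need: overall percent agreement
and Cohen's kappa on confusion tables (with the conventional interpretation
bands: slight / fair / moderate / substantial / almost perfect), per-class
sensitivity/specificity/PPV/NPV, the single-measurement two-way
absolute-agreement intraclass correlation (ICC(A,1)), Bland-Altman bias
with 1.96-SD limits of agreement, and mean per-pair absolute relative
error.  Formulas are written out explicitly from their ANOVA / contingency
definitions; the test-suite cross-checks them against independent
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


class AgreementError(ValueError):
    pass


def agreement_band(value: float) -> str:
    """Interpretation band for a kappa or ICC value (0-0.2 slight, ... )."""
    for upper, name in KAPPA_BANDS:
        if value <= upper:
            return name
    return "almost perfect"


@dataclass
class ConfusionTable:
    """k x k contingency counts: reference on rows, prediction on columns."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.labels = tuple(self.labels)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise AgreementError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if k < 2:
            raise AgreementError("need at least 2 categories")
        if (self.counts < 0).any():
            raise AgreementError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise AgreementError("confusion table is empty")

    @classmethod
    def from_pairs(cls, reference: Sequence, prediction: Sequence,
                   labels: Sequence | None = None) -> "ConfusionTable":
        reference = list(reference)
        prediction = list(prediction)
        if len(reference) != len(prediction):
            raise AgreementError("reference and prediction lengths differ")
        if labels is None:
            labels = sorted(set(reference) | set(prediction))
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)))
        for r, p in zip(reference, prediction):
            counts[index[r], index[p]] += 1
        return cls(counts, tuple(labels))

    def drop_label(self, label) -> "ConfusionTable":
        """Exclude cases where either rater used the given label.

        Mirrors the 'excluding cases where a fundal rating was used'
        analysis: the label's row and column are removed entirely.
        """
        if label not in self.labels:
            return self
        i = self.labels.index(label)
        keep = [j for j in range(len(self.labels)) if j != i]
        return ConfusionTable(self.counts[np.ix_(keep, keep)],
                              tuple(l for j, l in enumerate(self.labels) if j != i))

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def percent_agreement(table: ConfusionTable) -> float:
    """100 x trace / total."""
    return 100.0 * float(np.trace(table.counts)) / table.total


def cohens_kappa(table: ConfusionTable) -> dict:
    """Chance-corrected agreement with band and large-sample p-value.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products;
    exactly 1 for any perfect-diagonal table.  The p-value is the standard
    large-sample z-test of kappa = 0 (per-table); for a set of per-fold
    kappas use :func:`kappa_ttest`.  When both raters use a single category
    (p_e = 1) kappa is undefined and flagged.
    """
    n = table.total
    p = table.counts / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if np.isclose(pe, 1.0):
        if np.isclose(po, 1.0):
            return {"kappa": float("nan"), "band": None, "p_value": float("nan"),
                    "defined": False}
        pe = 1.0 - 1e-15
    if np.isclose(po, 1.0):
        kappa = 1.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    # large-sample variance under H0: kappa = 0 (Fleiss)
    var0 = (pe + pe ** 2 - float((row * col * (row + col)).sum())) / (n * (1 - pe) ** 2)
    if var0 > 0:
        z = kappa / np.sqrt(var0)
        p_value = float(2 * stats.norm.sf(abs(z)))
    else:
        p_value = float("nan")
    return {"kappa": float(kappa), "band": agreement_band(kappa),
            "p_value": p_value, "defined": True}


def kappa_ttest(kappas: Sequence[float]) -> dict:
    """One-sample t-test of a set of per-fold kappas against 0."""
    kappas = np.asarray(kappas, dtype=float)
    if kappas.size < 2:
        raise AgreementError("need >= 2 kappa values for a t-test")
    t, p = stats.ttest_1samp(kappas, 0.0)
    return {"mean_kappa": float(kappas.mean()), "t": float(t), "p_value": float(p)}


def binary_rates(table: ConfusionTable, positive_label) -> dict:
    """Sensitivity/specificity/PPV/NPV (%), collapsing to 2x2 vs the label."""
    if positive_label not in table.labels:
        raise AgreementError(f"label {positive_label!r} not in table")
    i = table.labels.index(positive_label)
    c = table.counts
    tp = c[i, i]
    fn = c[i].sum() - tp
    fp = c[:, i].sum() - tp
    tn = c.sum() - tp - fn - fp

    def _pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {"sensitivity": _pct(tp, tp + fn), "specificity": _pct(tn, tn + fp),
            "ppv": _pct(tp, tp + fp), "npv": _pct(tn, tn + fn),
            "defined": bool(tp + fn > 0)}


def icc_absolute(pred, ref, *, average_measures: bool = False) -> dict:
    """Two-way absolute-agreement intraclass correlation.

    Single-measurement ICC(A,1) by default (``average_measures=True`` gives
    ICC(A,k)), from the two-way ANOVA mean squares with n subjects and k = 2
    raters:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.column_stack([np.asarray(ref, float), np.asarray(pred, float)])
    n, k = x.shape
    if n < 3:
        raise AgreementError("need >= 3 paired measurements")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if np.isclose(msr, 0.0) and np.isclose(msc, 0.0) and np.isclose(mse, 0.0):
        return {"icc": float("nan"), "band": None, "defined": False}
    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(denom_single, 0.0):
        return {"icc": float("nan"), "band": None, "defined": False}
    if average_measures:
        icc = (msr - mse) / (msr + (msc - mse) / n)
    else:
        icc = (msr - mse) / denom_single
    return {"icc": float(icc), "band": agreement_band(icc), "defined": True}


def bland_altman(pred, ref) -> dict:
    """Bias = mean(pred - ref), limits = bias +/- 1.96 SD, paired t-test p.

    The sign convention matches 'model minus specialist'.  With zero
    variance in the differences the t-test is degenerate: p is 1.0 when the
    bias is zero and NaN otherwise.
    """
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise AgreementError("paired vectors must have equal length")
    if pred.size < 2:
        raise AgreementError("need >= 2 pairs")
    d = pred - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else float("nan")
    else:
        _, p = stats.ttest_1samp(d, 0.0)
        p = float(p)
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd,
            "sd": sd, "p_bias": p}


def relative_error(pred, ref) -> float:
    """Mean per-pair |pred - ref| / ref x 100 (%).

    Per-pair, then averaged: the per-patient definition, not the relative
    difference of the means.
    """
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise AgreementError("paired vectors must have equal length")
    if np.any(ref == 0):
        raise AgreementError("reference values must be nonzero")
    return float(np.mean(np.abs(pred - ref) / np.abs(ref)) * 100.0)


@dataclass
class AgreementReport:
    """Bundle of the comparison statistics for one categorical + one
    continuous endpoint pair, as produced by the evaluation harness."""

    percent_agreement: float | None = None
    kappa: dict | None = None
    rates: dict | None = None
    icc: dict | None = None
    bland_altman: dict | None = None
    relative_error_pct: float | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def categorical_report(reference, prediction, labels=None,
                       positive_label=None, exclude_label=None) -> AgreementReport:
    """Percent agreement, kappa, and binary rates for paired labels."""
    table = ConfusionTable.from_pairs(reference, prediction, labels)
    if exclude_label is not None:
        table = table.drop_label(exclude_label)
    report = AgreementReport(
        percent_agreement=percent_agreement(table),
        kappa=cohens_kappa(table),
    )
    if positive_label is not None and positive_label in table.labels:
        report.rates = binary_rates(table, positive_label)
    return report


def continuous_report(pred, ref) -> AgreementReport:
    """ICC, Bland-Altman, and relative error for paired measurements."""
    return AgreementReport(
        icc=icc_absolute(pred, ref),
        bland_altman=bland_altman(pred, ref),
        relative_error_pct=relative_error(pred, ref),
    )
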