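"""Categorical verification of binary maps against labelled points.

Implements the standard 2x2 contingency-table statistics used in
forecast verification and map accuracy assessment:

* ``PC``   proportion correct, (TP+TN)/n
* ``Bias`` frequency bias, (TP+FP)/(TP+FN); >1 over-, <1 underprediction
* ``POD``  probability of detection (hit rate), TP/(TP+FN)
* ``POFD`` probability of false detection, FP/(FP+TN)
* ``FAR``  false alarm ratio, FP/(TP+FP)
* ``MCC``  Matthews correlation coefficient,
  (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), in [-1, 1]

A statistic whose denominator is zero is reported as NaN and flagged,
never silently set to 0; the single documented exception is MCC, which
is defined as 0 when any table margin is zero (the correlation of a
constant is conventionally zero).

Reports can be stratified by altitude, mirroring the practice of
validating a vegetation map separately below and above a boundary
altitude where the predictors behave differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "VerificationReport",
    "confusion_from_oob",
    "statistics",
    "stratified_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table for a binary classification (positive = 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class VerificationReport:
    counts: ConfusionCounts
    mcc: float
    pc: float
    bias: float
    pod: float
    pofd: float
    far: float
    stratum: str = "all"
    undefined: list[str] = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Statistics at reporting precision (internal values stay exact)."""
        return {
            k: round(getattr(self, k), ndigits)
            for k in ("mcc", "pc", "bias", "pod", "pofd", "far")
        }

    def as_dict(self) -> dict:
        c = self.counts
        return {
            "stratum": self.stratum,
            "tp": c.tp,
            "tn": c.tn,
            "fp": c.fp,
            "fn": c.fn,
            "mcc": self.mcc,
            "pc": self.pc,
            "bias": self.bias,
            "pod": self.pod,
            "pofd": self.pofd,
            "far": self.far,
            "undefined": list(self.undefined),
        }


def confusion_from_oob(labels, predictions) -> ConfusionCounts:
    """Tally a confusion table from labels and (out-of-bag) predictions."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"labels and predictions differ in length: {labels.shape} vs {predictions.shape}"
        )
    if labels.size == 0:
        raise ValueError("empty label list")
    bad = set(np.unique(labels)) | set(np.unique(predictions))
    if not bad <= {0, 1}:
        raise ValueError(f"labels/predictions must be binary 0/1, got values {sorted(bad)}")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def statistics(counts: ConfusionCounts, stratum: str = "all") -> VerificationReport:
    """Six verification statistics from a confusion table.

    Full floating-point precision; round only at reporting time via
    :meth:`VerificationReport.rounded`.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n = counts.total
    if n == 0:
        raise ValueError("all-zero confusion counts")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    pc = (tp + tn) / n
    bias = ratio(tp + fp, tp + fn, "bias")
    pod = ratio(tp, tp + fn, "pod")
    pofd = ratio(fp, fp + tn, "pofd")
    far = ratio(fp, tp + fp, "far")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    # zero margin => constant prediction or constant truth: MCC := 0
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return VerificationReport(
        counts=counts, mcc=mcc, pc=pc, bias=bias, pod=pod, pofd=pofd, far=far,
        stratum=stratum, undefined=undefined,
    )


def _stratum_label(lo: float, hi: float) -> str:
    if math.isinf(lo) and math.isinf(hi):
        return "all"
    if math.isinf(lo):
        return f"<{hi:g} m"
    if math.isinf(hi):
        return f"≥{lo:g} m"
    return f"[{lo:g}, {hi:g}) m"


def stratified_report(labels, predictions, altitudes, edges) -> list[VerificationReport]:
    """Overall report plus one report per altitude stratum.

    Strata are ``[edge_i, edge_{i+1})`` with open ends below the first
    and at/above the last edge; the stratified counts always sum to the
    overall counts.  An empty stratum yields a report with zero counts
    and all statistics flagged undefined.
    """
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    altitudes = np.asarray(altitudes, dtype=float)
    if not (len(labels) == len(predictions) == len(altitudes)):
        raise ValueError("labels, predictions and altitudes must align")
    edges = list(edges)
    if sorted(edges) != edges:
        raise ValueError("strata edges must be sorted ascending")

    reports = [statistics(confusion_from_oob(labels, predictions), stratum="all")]
    bounds = [-math.inf, *edges, math.inf]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if math.isinf(lo) and math.isinf(hi):
            continue  # no edges: only the overall report
        sel = (altitudes >= lo) & (altitudes < hi)
        label = _stratum_label(lo, hi)
        if not sel.any():
            empty = ConfusionCounts(0, 0, 0, 0)
            reports.append(
                VerificationReport(
                    counts=empty, mcc=math.nan, pc=math.nan, bias=math.nan,
                    pod=math.nan, pofd=math.nan, far=math.nan, stratum=label,
                    undefined=["mcc", "pc", "bias", "pod", "pofd", "far"],
                )
            )
            continue
        reports.append(
            statistics(confusion_from_oob(labels[sel], predictions[sel]), stratum=label)
        )
    return reports


def format_table(reports: list[VerificationReport], ndigits: int = 2) -> str:
    """Plain-text table in the conventional column order."""
    cols = ["TP", "TN", "FP", "FN", "MCC", "PC", "Bias", "POD", "POFD", "FAR", "stratum"]
    lines = ["\t".join(cols)]
    for r in reports:
        c = r.counts
        stats = r.rounded(ndigits)
        row = [c.tp, c.tn, c.fp, c.fn] + [
            stats[k] for k in ("mcc", "pc", "bias", "pod", "pofd", "far")
        ]
        lines.append("\t".join(str(v) for v in row) + f"\t{r.stratum}")
    return "\n".join(lines)
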