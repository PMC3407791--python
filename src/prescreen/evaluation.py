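"""Screening test characteristics: contingency tables and summary metrics.

A validation study compares the tool's predicted candidate list against a
gold standard (the coordinators' manual workflow) over a common screened
population, condenses the comparison into a 2x2 contingency table, and
reports sensitivity, specificity, predictive values and the odds ratio:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)
    odds ratio  = (TP * TN) / (FP * FN)

A metric whose denominator is zero is *undefined* (``None``), never
silently 0. The optional Haldane–Anscombe correction (+0.5 to every cell)
is off by default and clearly labeled when requested.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

from .errors import InputError

__all__ = ["ContingencyTable", "ScreeningMetrics", "build_contingency", "compute_metrics"]


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True, slots=True)
class ScreeningMetrics:
    """Each field is a proportion in [0, 1] (odds ratio unbounded), or
    ``None`` where the defining denominator is zero."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    odds_ratio: float | None
    corrected: bool = False

    def to_dict(self) -> dict:
        """Proportions plus percentage renderings (validation reports
        conventionally mix the two presentations)."""

        def pct(x: float | None) -> float | None:
            return None if x is None else round(100.0 * x, 4)

        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "odds_ratio": self.odds_ratio,
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "haldane_anscombe_correction": self.corrected,
        }


def build_contingency(
    predicted: Iterable[str], gold: Iterable[str], population: Iterable[str]
) -> ContingencyTable:
    """Cross-classify predicted vs gold candidate sets over a population.

    Both ``predicted`` and ``gold`` must be subsets of ``population``; the
    four cells always sum to ``len(population)``.
    """
    predicted, gold, population = set(predicted), set(gold), set(population)
    stray = sorted(predicted - population)
    if stray:
        raise InputError(f"predicted ids not in population: {', '.join(stray)}")
    stray = sorted(gold - population)
    if stray:
        raise InputError(f"gold ids not in population: {', '.join(stray)}")
    return ContingencyTable(
        tp=len(predicted & gold),
        fp=len(predicted - gold),
        fn=len(gold - predicted),
        tn=len(population - (predicted | gold)),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(
    t: ContingencyTable, haldane_anscombe: bool = False
) -> ScreeningMetrics:
    """Summary statistics for a 2x2 table, with undefined-cell propagation."""
    tp, fp, fn, tn = float(t.tp), float(t.fp), float(t.fn), float(t.tn)
    if haldane_anscombe:
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    return ScreeningMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        odds_ratio=_ratio(tp * tn, fp * fn),
        corrected=haldane_anscombe,
    )
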