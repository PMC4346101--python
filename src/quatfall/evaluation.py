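"""Confusion-count bookkeeping and sensitivity/specificity computation.

A trial is one motion test (one trace); it counts as an alarm if the
detector emits at least one alarmed event.  Fall-class alarms are true
positives, fall-class non-alarms false negatives, ADL alarms false
positives and ADL non-alarms true negatives:

    sensitivity = 100·TP/(TP+FN)      specificity = 100·TN/(TN+FP)

Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .detector import AccelThresholdDetector, DetectorConfig, FallDetector
from .simulate import ADL_CLASSES, FALL_CLASSES, LabeledTrace

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "BenchmarkResult",
    "metrics_from_counts",
    "run_benchmark",
    "round_pct",
]


def round_pct(x: float, ndigits: int = 1) -> float:
    """Round half-up to `ndigits` decimals (97.083 → 97.1, 91.665 → 91.7)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """Per-motion-class alarm/trial counts.

    ``counts`` maps class name → (alarms, trials).  ``fall_classes`` defines
    which classes form the positive (fall) group; everything else is ADL.
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    fall_classes: frozenset[str] = frozenset(FALL_CLASSES)

    def add(self, motion_class: str, alarmed: bool, n: int = 1):
        a, t = self.counts.get(motion_class, (0, 0))
        self.counts[motion_class] = (a + (n if alarmed else 0), t + n)

    def set_counts(self, motion_class: str, alarms: int, trials: int):
        if not 0 <= alarms <= trials:
            raise ValueError(f"need 0 <= alarms <= trials, got {alarms}/{trials}")
        self.counts[motion_class] = (alarms, trials)

    @classmethod
    def from_table(cls, table: Mapping[str, tuple[int, int]],
                   fall_classes: Iterable[str] = FALL_CLASSES) -> "ConfusionCounts":
        cc = cls(fall_classes=frozenset(fall_classes))
        for k, (a, t) in table.items():
            cc.set_counts(k, a, t)
        return cc

    def totals(self) -> tuple[int, int, int, int]:
        """(tp, fn, fp, tn) aggregated over classes."""
        tp = fn = fp = tn = 0
        for cls_name, (a, t) in self.counts.items():
            if cls_name in self.fall_classes:
                tp += a
                fn += t - a
            else:
                fp += a
                tn += t - a
        return tp, fn, fp, tn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float  # percent, one decimal
    specificity: float  # percent, one decimal
    tp: int
    fn: int
    fp: int
    tn: int

    def to_dict(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
        }


def metrics_from_counts(counts: ConfusionCounts) -> Metrics:
    """Sensitivity/specificity from per-class alarm counts.

    Requires at least one fall class and one ADL class with trials.
    """
    fall_trials = sum(t for c, (a, t) in counts.counts.items() if c in counts.fall_classes)
    adl_trials = sum(t for c, (a, t) in counts.counts.items() if c not in counts.fall_classes)
    if fall_trials == 0 or adl_trials == 0:
        raise ValueError(
            "metrics need at least one fall class and one ADL class with trials "
            f"(fall trials={fall_trials}, ADL trials={adl_trials})"
        )
    tp, fn, fp, tn = counts.totals()
    return Metrics(
        sensitivity=round_pct(100.0 * tp / (tp + fn)),
        specificity=round_pct(100.0 * tn / (tn + fp)),
        tp=tp, fn=fn, fp=fp, tn=tn,
    )


@dataclass(frozen=True)
class BenchmarkResult:
    proposed_counts: ConfusionCounts
    baseline_counts: ConfusionCounts
    proposed_metrics: Metrics
    baseline_metrics: Metrics
    config: DetectorConfig

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "config": self.config.to_dict(),
            "proposed": {
                "per_class": {k: list(v) for k, v in sorted(self.proposed_counts.counts.items())},
                **self.proposed_metrics.to_dict(),
            },
            "baseline": {
                "per_class": {k: list(v) for k, v in sorted(self.baseline_counts.counts.items())},
                **self.baseline_metrics.to_dict(),
            },
        }


def run_benchmark(cohort: Sequence[LabeledTrace],
                  config: DetectorConfig | None = None) -> BenchmarkResult:
    """Run both detectors over a labeled cohort and tabulate alarm counts."""
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    config = config or DetectorConfig()
    proposed = FallDetector.from_config(config)
    baseline = AccelThresholdDetector.from_config(config)
    pc, bc = ConfusionCounts(), ConfusionCounts()
    for idx, (trace, truth) in enumerate(cohort):
        try:
            p_alarm = any(e.is_alarm for e in proposed.detect(trace))
            b_alarm = any(e.is_alarm for e in baseline.detect(trace))
        except Exception as exc:
            raise RuntimeError(
                f"detector failed on cohort trace {idx} ({truth.motion_class})"
            ) from exc
        pc.add(truth.motion_class, p_alarm)
        bc.add(truth.motion_class, b_alarm)
    return BenchmarkResult(pc, bc, metrics_from_counts(pc), metrics_from_counts(bc), config)
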