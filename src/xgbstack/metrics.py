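"""Evaluation metrics: classification accuracy and feature dimension reduction."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["EvalReport", "accuracy", "dimension_reduction", "percent"]


def accuracy(ncc: int, nas: int) -> float:
    """Fraction of correctly classified samples, NCC / NAS."""
    if nas < 1:
        raise ValueError("need at least one sample")
    if not (0 <= ncc <= nas):
        raise ValueError("correct count must lie in [0, total]")
    return ncc / nas


def dimension_reduction(nsf: int, naf: int) -> float:
    """Fraction of original features discarded by selection, 1 - NSF / NAF."""
    if naf < 1:
        raise ValueError("need at least one feature")
    if not (0 <= nsf <= naf):
        raise ValueError("selected count must lie in [0, total]")
    return 1.0 - nsf / naf


def percent(x: float, decimals: int = 2) -> float:
    """Express a fraction as a percentage, rounded half-up to `decimals` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvalReport:
    """Counts and derived metrics for one evaluated classifier.

    NCC/NAS: correctly classified / total samples; NSF/NAF: selected / all
    features.
    """

    ncc: int
    nas: int
    nsf: int
    naf: int

    @property
    def acc(self) -> float:
        return accuracy(self.ncc, self.nas)

    @property
    def dr(self) -> float:
        return dimension_reduction(self.nsf, self.naf)

    def to_dict(self) -> dict:
        return {
            "NCC": self.ncc,
            "NAS": self.nas,
            "NSF": self.nsf,
            "NAF": self.naf,
            "acc": self.acc,
            "acc_pct": percent(self.acc),
            "dr": self.dr,
            "dr_pct": percent(self.dr),
        }
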