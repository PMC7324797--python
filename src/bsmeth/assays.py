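"""Plate-based and qPCR assay quantification.

Implements the relative 5mC / 5hmC percentage formulas of the
colourimetric (hydroxy)methylated-DNA quantification kits, the DNMT
activity calculation, and Pfaffl efficiency-corrected relative
expression against one or more reference genes.

Relative 5mC % = [(sample OD - negative OD) / S]
               / [(positive OD - negative OD) * 2 / P] * 100

with S the sample DNA input (ng) and P the positive-control amount
(ng); the kit factor 2 reflects a 50 %-methylated positive control.
The 5hmC formula is identical with kit factor 5.  DNMT activity is
(sample OD - blank OD) / (protein ug * hours) * 1000, in OD/h/ug.
The Pfaffl ratio is E_target^dCq(target) / E_ref^dCq(ref) with
dCq = Cq(control) - Cq(sample) and amplification efficiencies E in
[1, 2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlateMeasurement",
    "QpcrSample",
    "AssayResult",
    "relative_5mc_percent",
    "relative_5hmc_percent",
    "dnmt_activity",
    "pfaffl_relative_expression",
    "replicate_assay_summary",
]


@dataclass
class PlateMeasurement:
    """One well's optical densities and the amounts behind them."""

    sample_od: float
    negative_od: float = 0.0
    positive_od: float = float("nan")
    blank_od: float = float("nan")
    sample_ng: float = float("nan")  # S
    positive_ng: float = float("nan")  # P
    protein_ug: float = float("nan")
    hours: float = float("nan")


@dataclass
class AssayResult:
    value: float
    flag: str | None = None  # e.g. 'undefined-denominator', 'negative'

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)

    def __float__(self) -> float:
        return self.value


@dataclass
class QpcrSample:
    """Efficiencies and Cq differences for one target/reference pairing."""

    e_target: float
    dcq_target: float  # Cq(control) - Cq(sample), target gene
    e_ref: float
    dcq_ref: float
    reference: str = "L27"

    def __post_init__(self) -> None:
        for e in (self.e_target, self.e_ref):
            if not 1.0 <= e <= 2.0:
                raise ValueError(f"efficiency {e} outside [1, 2]")
        for d in (self.dcq_target, self.dcq_ref):
            if not math.isfinite(d):
                raise ValueError("Cq differences must be finite")


def _relative_percent(m: PlateMeasurement, kit_factor: float) -> AssayResult:
    if not (m.sample_ng > 0 and m.positive_ng > 0):
        raise ValueError("sample and positive-control amounts must be positive")
    denom = (m.positive_od - m.negative_od) * kit_factor / m.positive_ng
    if not denom > 0:
        return AssayResult(float("nan"), flag="undefined-denominator")
    value = ((m.sample_od - m.negative_od) / m.sample_ng) / denom * 100.0
    return AssayResult(value, flag="negative" if value < 0 else None)


def relative_5mc_percent(m: PlateMeasurement) -> AssayResult:
    """Relative 5mC percent of input DNA (kit factor 2)."""
    return _relative_percent(m, 2.0)


def relative_5hmc_percent(m: PlateMeasurement) -> AssayResult:
    """Relative 5hmC percent of input DNA (kit factor 5)."""
    return _relative_percent(m, 5.0)


def dnmt_activity(m: PlateMeasurement) -> AssayResult:
    """DNMT activity in OD per hour per ug protein."""
    if not (m.protein_ug > 0 and m.hours > 0):
        raise ValueError("protein amount and incubation time must be positive")
    value = (m.sample_od - m.blank_od) / (m.protein_ug * m.hours) * 1000.0
    return AssayResult(value, flag="negative" if value < 0 else None)


def pfaffl_relative_expression(q: QpcrSample) -> float:
    """Efficiency-corrected expression ratio E_t^dCq(t) / E_r^dCq(r)."""
    return q.e_target**q.dcq_target / q.e_ref**q.dcq_ref


def pfaffl_per_reference(
    e_target: float,
    dcq_target: float,
    references: dict[str, tuple[float, float]],
) -> dict[str, float]:
    """One Pfaffl ratio per reference gene.

    ``references`` maps a gene label (e.g. 'L27', 'L32') to its
    (efficiency, dCq) pair.
    """
    return {
        label: pfaffl_relative_expression(
            QpcrSample(e_target, dcq_target, e_ref, dcq_ref, reference=label)
        )
        for label, (e_ref, dcq_ref) in references.items()
    }


@dataclass
class AssaySummary:
    mean: float
    sd: float  # NaN for n = 1
    n: int


def replicate_assay_summary(values: list[float]) -> AssaySummary:
    """Unweighted mean and sample (n-1) SD of replicate assay values."""
    if not values:
        raise ValueError("empty value list")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else float("nan")
    return AssaySummary(float(arr.mean()), sd, len(arr))
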