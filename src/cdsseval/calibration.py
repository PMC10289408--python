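"""Stability-calibrated indicators and internal-variation summaries.

A subgroup's *relative stability index* is its decision stability divided by
a benchmark subgroup's stability, x100; a calibrated indicator is the
relative index applied to the raw rate.  With the benchmark chosen as the
maximum-stability subgroup (the default policy) calibration can only shrink
a rate and leaves the benchmark subgroup untouched; a fixed reference
subgroup may be designated instead, in which case indices above 100 are
possible.

Internal variation across subgroups is summarised by the antisymmetric
matrix of pairwise rate differences, the standard deviation of the subgroup
rates, and the mean absolute pairwise difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .indicators import round_half_up
from .model import StudyValidationError

__all__ = [
    "BenchmarkPolicy",
    "CalibrationRow",
    "CalibrationTable",
    "VariationSummary",
    "relative_stability_index",
    "calibrate",
    "build_calibration_table",
    "pairwise_difference_matrix",
]


class BenchmarkPolicy(str, Enum):
    MAX_STABILITY = "max_stability"
    FIXED_REFERENCE = "fixed_reference"


def relative_stability_index(stability: float, benchmark_stability: float) -> float:
    """stability / benchmark stability x 100 (percent)."""
    if benchmark_stability <= 0:
        raise StudyValidationError(
            f"benchmark stability must be positive, got {benchmark_stability}"
        )
    return stability / benchmark_stability * 100.0


def calibrate(original: float, relative_index: float) -> float:
    """Calibrated indicator = relative stability index x original rate."""
    if not 0.0 <= original <= 100.0:
        raise StudyValidationError(f"original rate {original} outside [0, 100]")
    return relative_index / 100.0 * original


@dataclass(frozen=True)
class CalibrationRow:
    subgroup: str
    original: float
    stability: float
    relative_index: float
    calibrated: float


@dataclass(frozen=True)
class CalibrationTable:
    rows: tuple[CalibrationRow, ...]
    benchmark_subgroup: str
    policy: BenchmarkPolicy

    def to_frame(self, ndigits: int = 1) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "subgroup": r.subgroup,
                    "original": r.original,
                    "stability": r.stability,
                    "relative_index": round_half_up(r.relative_index, ndigits),
                    "calibrated": round_half_up(r.calibrated, ndigits),
                    "benchmark": self.benchmark_subgroup,
                    "policy": self.policy.value,
                }
                for r in self.rows
            ]
        )
        return df

    def __getitem__(self, subgroup: str) -> CalibrationRow:
        for r in self.rows:
            if r.subgroup == subgroup:
                return r
        raise KeyError(subgroup)


def build_calibration_table(
    originals: Mapping[str, float],
    stabilities: Mapping[str, float],
    policy: BenchmarkPolicy | str = BenchmarkPolicy.MAX_STABILITY,
    reference: str | None = None,
) -> CalibrationTable:
    """Calibrate every subgroup's raw rate by its relative stability index.

    ``originals`` and ``stabilities`` must share keys.  Under the
    ``max_stability`` policy the benchmark is the subgroup with the highest
    stability (ties broken by lexicographic label, with a warning); under
    ``fixed_reference`` the caller designates it.
    """
    policy = BenchmarkPolicy(policy)
    if set(originals) != set(stabilities):
        raise StudyValidationError(
            "originals and stabilities cover different subgroups: "
            f"{sorted(set(originals) ^ set(stabilities))}"
        )
    if not originals:
        raise StudyValidationError("no subgroups to calibrate")
    if policy is BenchmarkPolicy.FIXED_REFERENCE:
        if reference is None:
            raise StudyValidationError("fixed_reference policy requires a reference subgroup")
        if reference not in stabilities:
            raise StudyValidationError(f"reference subgroup {reference!r} not among inputs")
        benchmark = reference
    else:
        best = max(stabilities.values())
        tied = sorted(str(k) for k, v in stabilities.items() if v == best)
        if len(tied) > 1:
            warnings.warn(
                f"max-stability benchmark tie among {tied}; using {tied[0]}", stacklevel=2
            )
        benchmark = tied[0]
    bench_stab = stabilities[benchmark]
    rows = []
    for key in sorted(originals, key=str):
        ri = relative_stability_index(stabilities[key], bench_stab)
        rows.append(
            CalibrationRow(
                subgroup=str(key),
                original=float(originals[key]),
                stability=float(stabilities[key]),
                relative_index=ri,
                calibrated=calibrate(float(originals[key]), ri),
            )
        )
    return CalibrationTable(tuple(rows), str(benchmark), policy)


@dataclass(frozen=True)
class VariationSummary:
    """Pairwise rate-difference matrix plus dispersion summaries (percentage points)."""

    pairwise_matrix: pd.DataFrame
    sd: float
    mean_abs_diff: float


def pairwise_difference_matrix(
    rates: Mapping[str, float], ddof: int = 1
) -> VariationSummary:
    """Antisymmetric matrix of subgroup rate differences with SD and mean |difference|.

    ``matrix[i, j] = rate_i - rate_j``; ``sd`` is the standard deviation of
    the subgroup rates (sample SD by default, ``ddof=0`` for population);
    ``mean_abs_diff`` averages the absolute differences over unordered pairs.
    """
    if len(rates) < 2:
        raise StudyValidationError("pairwise differences require at least 2 subgroups")
    labels = list(rates)
    vals = np.asarray([float(rates[k]) for k in labels])
    matrix = pd.DataFrame(vals[:, None] - vals[None, :], index=labels, columns=labels)
    iu = np.triu_indices(len(vals), k=1)
    mean_abs = float(np.mean(np.abs(matrix.to_numpy()[iu])))
    return VariationSummary(
        pairwise_matrix=matrix,
        sd=float(np.std(vals, ddof=ddof)),
        mean_abs_diff=mean_abs,
    )
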