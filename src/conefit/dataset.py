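"""Dataset container pairing preprocessed series with experimental conditions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ConditionParams, Route
from .preprocess import MpTimeSeries

__all__ = ["Dataset", "condition_from_label", "CONDITION_LABELS"]

# Blocker semantics: DNDS blocks the chloride channel (eta_Cl=0), STX blocks
# the sodium channel (eta_Na=0), KT5823 inhibits PKG (pkg_active=0).
CONDITION_LABELS = ("control", "DNDS", "STX", "KT5823")


def condition_from_label(
    label: str,
    S_max: float = 10.0,
    route: Route = Route.PIPETTE,
) -> ConditionParams:
    if label not in CONDITION_LABELS:
        raise ValueError(f"unknown condition label {label!r}; expected one of {CONDITION_LABELS}")
    return ConditionParams(
        eta_Cl=0 if label == "DNDS" else 1,
        eta_Na=0 if label == "STX" else 1,
        S_max=S_max,
        route=route,
        pkg_active=0 if label == "KT5823" else 1,
    )


@dataclass
class Dataset:
    series: list[MpTimeSeries] = field(default_factory=list)
    conditions: list[ConditionParams] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.series) != len(self.conditions):
            raise ValueError("series and conditions must have equal length")
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValueError("series ids must be unique")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(zip(self.series, self.conditions))

    @property
    def total_points(self) -> int:
        return sum(s.T_i for s in self.series)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([s.sigma_i for s in self.series], dtype=float)

    def subset(self, indices) -> "Dataset":
        return Dataset(
            series=[self.series[i] for i in indices],
            conditions=[self.conditions[i] for i in indices],
            description=self.description,
        )

    def leave_one_out(self, i: int) -> tuple["Dataset", "Dataset"]:
        """(all-but-i, only-i) split."""
        rest = [j for j in range(len(self)) if j != i]
        return self.subset(rest), self.subset([i])
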