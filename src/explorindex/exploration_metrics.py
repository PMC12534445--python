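"""Per-individual object-use metrics and the composite Exploration Index.

Five metrics summarize each individual's object use: (1) total bout count,
(2) category diversity (distinct ethogram categories, 1-7), (3) proportion
of atypical bouts, (4) object-use rate (bouts per observation hour), and
(5) age diversity (distinct whole-year ages at which bouts occurred).  Each
metric is z-transformed across individuals so all five carry equal weight,
and the Exploration Index is the sum of the five z-scores.  Summing
standardized metrics makes the index location/scale free: rescaling any raw
metric (e.g. hours to minutes) leaves the index unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ethogram_data import Dataset

__all__ = ["MetricProfile", "compute_metrics", "z_transform", "exploration_index"]

METRIC_NAMES = (
    "total_bouts",
    "category_diversity",
    "atypical_proportion",
    "bout_rate",
    "age_diversity",
)


@dataclass
class MetricProfile:
    """Raw metrics, z-scores and composite index for one individual."""

    individual_id: str
    total_bouts: int
    category_diversity: int
    atypical_proportion: float
    bout_rate: float
    age_diversity: int
    central_age: float  # mean age over the individual's bouts
    z_scores: Optional[np.ndarray] = field(default=None, repr=False)
    exploration_index: Optional[float] = None

    def raw_vector(self, metric4: str = "rate", observation_hours: float | None = None) -> np.ndarray:
        if metric4 == "rate":
            m4 = self.bout_rate
        elif metric4 == "hours":
            if observation_hours is None:
                raise ValueError("observation_hours required for metric4='hours'")
            m4 = observation_hours
        else:
            raise ValueError("metric4 must be 'rate' or 'hours'")
        return np.array(
            [
                self.total_bouts,
                self.category_diversity,
                self.atypical_proportion,
                m4,
                self.age_diversity,
            ],
            dtype=float,
        )


def compute_metrics(ds: Dataset) -> list[MetricProfile]:
    """Compute the five raw metrics for every individual with >= 1 bout.

    Individuals without bouts are excluded (the study profiles only subjects
    observed using objects).  Age diversity counts distinct floor(age)
    values, realizing whole-year age points (0, 1, 2, ... yrs).
    """
    profiles: list[MetricProfile] = []
    for ind in ds.individuals:
        bouts = ds.bouts_of(ind.individual_id)
        if not bouts:
            continue
        if ind.observation_hours <= 0:  # defensive; Dataset validation forbids it
            raise ValueError(
                f"individual {ind.individual_id!r} has non-positive observation_hours"
            )
        n = len(bouts)
        ages = [b.age_at_bout for b in bouts]
        profiles.append(
            MetricProfile(
                individual_id=ind.individual_id,
                total_bouts=n,
                category_diversity=len({b.category for b in bouts}),
                atypical_proportion=sum(b.typicality == "atypical" for b in bouts) / n,
                bout_rate=n / ind.observation_hours,
                age_diversity=len({math.floor(a) for a in ages}),
                central_age=float(np.mean(ages)),
            )
        )
    return profiles


def z_transform(values: Sequence[float], ddof: int = 1) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD by default).

    A zero-variance input returns all zeros rather than erroring, so a
    degenerate metric simply contributes nothing to the composite.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("z_transform requires a 1-D vector of length >= 2")
    sd = x.std(ddof=ddof)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def exploration_index(
    profiles: list[MetricProfile],
    metric4: str = "rate",
    observation_hours: dict[str, float] | None = None,
    ddof: int = 1,
) -> list[MetricProfile]:
    """Fill z-scores metric-wise across individuals and sum them into the index.

    ``metric4`` selects the fourth metric: ``"rate"`` (bouts per observation
    hour; the operational definition) or ``"hours"`` (raw observation hours,
    for sensitivity checks; requires ``observation_hours`` keyed by
    individual_id).  Mutates and returns the profiles.
    """
    if len(profiles) < 2:
        raise ValueError("exploration_index requires >= 2 profiles")
    raw = np.vstack(
        [
            p.raw_vector(
                metric4,
                None if observation_hours is None else observation_hours[p.individual_id],
            )
            for p in profiles
        ]
    )
    z = np.column_stack([z_transform(raw[:, j], ddof=ddof) for j in range(raw.shape[1])])
    for i, p in enumerate(profiles):
        p.z_scores = z[i]
        p.exploration_index = float(z[i].sum())
    return profiles
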