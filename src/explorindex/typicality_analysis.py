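"""Bout-level accounting of typical vs. atypical object use.

Produces the category frequency table, the typical/atypical and
omission/commission breakdown with the young/old age-class comparison, and
a bout-level logistic regression of atypicality on age at bout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .ethogram_data import CATEGORIES, Dataset
from .inferential_models import ModelFit, logistic_fit

__all__ = [
    "FrequencyRow",
    "FrequencyTable",
    "TypicalityBreakdown",
    "category_frequencies",
    "typicality_breakdown",
    "atypicality_logistic",
]


def _round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal-style half-up rounding, matching printed table precision."""
    factor = 10.0**ndigits
    return float(np.floor(x * factor + 0.5) / factor)


@dataclass(frozen=True)
class FrequencyRow:
    category: str
    subcategory: str | None
    count: int
    proportion_percent: float  # of the grand total, 1 dp


@dataclass
class FrequencyTable:
    rows: list[FrequencyRow]
    total: int

    def category_rows(self) -> list[FrequencyRow]:
        return [r for r in self.rows if r.subcategory is None]

    def __getitem__(self, category: str) -> FrequencyRow:
        for r in self.rows:
            if r.category == category and r.subcategory is None:
                return r
        raise KeyError(category)


@dataclass
class TypicalityBreakdown:
    n_typical: int
    n_atypical: int
    n_omission: int
    n_commission: int
    pct_atypical: float
    pct_omission_of_atypical: float
    pct_commission_of_atypical: float
    young_atypical_pct: float  # bouts at ages <= age_cut
    old_atypical_pct: float  # bouts at ages > age_cut
    age_cut: float
    n_young: int
    n_old: int


def category_frequencies(ds: Dataset) -> FrequencyTable:
    """Count bouts per category (and subcategory) with percents of the total.

    Categories are listed in ethogram order by descending frequency, each
    followed by its subcategory rows; percentages are rounded half-up to one
    decimal place, the precision of the published table.
    """
    if not ds.bouts:
        raise ValueError("cannot tabulate an empty bout list")
    total = len(ds.bouts)
    cat_counts = Counter(b.category for b in ds.bouts)
    sub_counts = Counter((b.category, b.subcategory) for b in ds.bouts if b.subcategory)
    rows: list[FrequencyRow] = []
    order = sorted(
        (c for c in CATEGORIES if cat_counts[c]),
        key=lambda c: (-cat_counts[c], CATEGORIES.index(c)),
    )
    for cat in order:
        rows.append(
            FrequencyRow(cat, None, cat_counts[cat], _round_half_up(100 * cat_counts[cat] / total))
        )
        for (c, sub), k in sorted(sub_counts.items()):
            if c == cat:
                rows.append(FrequencyRow(cat, sub, k, _round_half_up(100 * k / total)))
    return FrequencyTable(rows=rows, total=total)


def typicality_breakdown(ds: Dataset, age_cut: float = 4.0) -> TypicalityBreakdown:
    """Typical/atypical and omission/commission counts with the age split.

    ``age_cut`` separates younger bouts (age_at_bout <= age_cut, default 4
    years, boundary-inclusive) from older ones.  Percentages are recomputed
    from their integer numerators/denominators and rounded half-up to 1 dp.
    """
    n_typ = sum(b.typicality == "typical" for b in ds.bouts)
    atyp = [b for b in ds.bouts if b.typicality == "atypical"]
    n_atyp = len(atyp)
    n_om = sum(b.atypical_mode == "omission" for b in atyp)
    n_com = sum(b.atypical_mode == "commission" for b in atyp)
    total = n_typ + n_atyp
    young = [b for b in ds.bouts if b.age_at_bout <= age_cut]
    old = [b for b in ds.bouts if b.age_at_bout > age_cut]

    def pct(num: int, den: int) -> float:
        return _round_half_up(100 * num / den) if den else 0.0

    return TypicalityBreakdown(
        n_typical=n_typ,
        n_atypical=n_atyp,
        n_omission=n_om,
        n_commission=n_com,
        pct_atypical=pct(n_atyp, total),
        pct_omission_of_atypical=pct(n_om, n_atyp),
        pct_commission_of_atypical=pct(n_com, n_atyp),
        young_atypical_pct=pct(sum(b.typicality == "atypical" for b in young), len(young)),
        old_atypical_pct=pct(sum(b.typicality == "atypical" for b in old), len(old)),
        age_cut=age_cut,
        n_young=len(young),
        n_old=len(old),
    )


def atypicality_logistic(ds: Dataset, unit: str = "bout") -> ModelFit:
    """Logistic regression of atypical (1) vs. typical (0) use on age.

    ``unit="bout"`` (default) fits one row per bout with age at bout as the
    predictor — the unit matching percentages quoted "of bouts".
    ``unit="individual"`` aggregates to one row per individual, regressing
    whether the individual produced any atypical bout on its mean bout age,
    offered as a sensitivity alternative.
    """
    if unit == "bout":
        y = np.array([1.0 if b.typicality == "atypical" else 0.0 for b in ds.bouts])
        age = np.array([b.age_at_bout for b in ds.bouts])
    elif unit == "individual":
        ids = sorted({b.individual_id for b in ds.bouts})
        y, age = [], []
        for iid in ids:
            bouts = ds.bouts_of(iid)
            y.append(1.0 if any(b.typicality == "atypical" for b in bouts) else 0.0)
            age.append(float(np.mean([b.age_at_bout for b in bouts])))
        y, age = np.array(y), np.array(age)
    else:
        raise ValueError("unit must be 'bout' or 'individual'")
    X = np.column_stack([np.ones_like(age), age])
    return logistic_fit(y, X, names=["intercept", "age"])
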