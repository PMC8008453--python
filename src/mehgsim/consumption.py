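"""Zero-inflated empirical model of single-day fish consumption.

Survey consumption data are dominated by person-days on which a given fish
group was not eaten at all, with a strongly right-skewed positive tail, so no
standard continuous distribution fits.  The model here is deliberately
non-parametric: amounts (g/day, zeros included) are resampled with replacement
from the raw record vector.  Zeros stay inside the vector — equivalent to a
separate Bernoulli consumer stage, but simpler to audit.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .concentration import GROUP_ORDER, FishGroup
from .errors import DegenerateGroupError, InvalidParameterError, MissingTagError

__all__ = [
    "ConsumptionRecords",
    "SubgroupFilter",
    "consumer_fraction",
    "sample_consumption",
    "filter_records",
    "frequency_table",
    "load_consumption_csv",
    "write_consumption_csv",
]

CONSUMPTION_CSV_COLUMNS = ("person_id", "sex", "age", "group", "amount_g")


@dataclass(frozen=True)
class ConsumptionRecords:
    """Per-person-day amounts (g/day) for one fish group, zeros included.

    ``sex`` and ``age`` are optional per-record demographic tags, aligned with
    ``amounts``; they exist so subgroup runs (e.g. women aged 16-45) can reuse
    the same records.
    """

    group: FishGroup
    amounts: np.ndarray
    sex: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        amounts = np.asarray(self.amounts, dtype=float)
        if amounts.ndim != 1:
            raise InvalidParameterError("amounts must be a 1-d vector")
        if amounts.size and (not np.all(np.isfinite(amounts)) or np.any(amounts < 0)):
            raise InvalidParameterError("amounts must be finite and >= 0")
        object.__setattr__(self, "amounts", amounts)
        for name in ("sex", "age"):
            tag = getattr(self, name)
            if tag is not None:
                tag = np.asarray(tag)
                if tag.shape != amounts.shape:
                    raise InvalidParameterError(f"{name} tags must align with amounts")
                object.__setattr__(self, name, tag)

    @property
    def n(self) -> int:
        return int(self.amounts.size)

    @property
    def n_consumers(self) -> int:
        return int((self.amounts > 0).sum())


@dataclass(frozen=True)
class SubgroupFilter:
    """Demographic selection; an empty filter keeps every record."""

    sex: str | None = None
    age_range: tuple[float, float] | None = None  # closed interval, years

    @property
    def is_empty(self) -> bool:
        return self.sex is None and self.age_range is None


def _require_nonempty(records: ConsumptionRecords) -> None:
    if records.n == 0:
        raise DegenerateGroupError(f"{records.group.value}: no records")


def consumer_fraction(records: ConsumptionRecords) -> float:
    """Fraction of person-days with strictly positive consumption."""
    _require_nonempty(records)
    if records.n_consumers == 0:
        raise DegenerateGroupError(
            f"{records.group.value}: no positive amounts; group is degenerate"
        )
    return records.n_consumers / records.n


def sample_consumption(
    records: ConsumptionRecords, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` amounts i.i.d. with replacement from the raw record vector.

    Each draw is 0 with probability 1 - consumer_fraction and otherwise an
    observed positive amount; no smoothing or binning is applied.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    _require_nonempty(records)
    idx = rng.integers(0, records.n, size=n)
    return records.amounts[idx]


def filter_records(records: ConsumptionRecords, f: SubgroupFilter) -> ConsumptionRecords:
    """Keep exactly the records whose demographic tags satisfy the filter."""
    if f.is_empty:
        return records
    mask = np.ones(records.n, dtype=bool)
    if f.sex is not None:
        if records.sex is None:
            raise MissingTagError("records carry no sex tags")
        mask &= np.asarray(records.sex) == f.sex
    if f.age_range is not None:
        if records.age is None:
            raise MissingTagError("records carry no age tags")
        lo, hi = f.age_range
        age = np.asarray(records.age, dtype=float)
        mask &= (age >= lo) & (age <= hi)
    return ConsumptionRecords(
        group=records.group,
        amounts=records.amounts[mask],
        sex=None if records.sex is None else records.sex[mask],
        age=None if records.age is None else records.age[mask],
    )


def frequency_table(records: ConsumptionRecords, bin_width: float) -> pd.DataFrame:
    """Histogram of positive amounts in half-open bins [k*w, (k+1)*w).

    Zeros (non-consumers) are excluded, matching how survey consumption
    distributions are displayed; counts sum to the number of consumers.
    """
    if not bin_width > 0:
        raise InvalidParameterError("bin_width must be positive")
    _require_nonempty(records)
    positive = records.amounts[records.amounts > 0]
    k = np.floor(positive / bin_width).astype(int)
    n_bins = int(k.max()) + 1 if k.size else 0
    counts = np.bincount(k, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_consumption_csv(path: str | Path) -> dict[FishGroup, ConsumptionRecords]:
    """Read survey records from CSV and materialize the implicit zeros.

    Expected header: ``person_id,sex,age,group,amount_g`` with one row per
    person-day per consumed group.  A person-day with no row for a group is a
    zero for that group, so every returned group vector has one entry per
    person, aligned across groups.  Duplicate (person, group) rows are summed.
    """
    frame = pd.read_csv(path)
    missing = set(CONSUMPTION_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidParameterError(f"consumption CSV missing columns: {sorted(missing)}")
    labels = {str(v) for v in frame["group"].dropna().unique()}
    bad = labels - {g.value for g in GROUP_ORDER}
    if bad:
        raise InvalidParameterError(f"unknown fish group labels: {sorted(bad)}")

    people = frame.drop_duplicates("person_id").set_index("person_id")[["sex", "age"]]
    person_ids = people.index.to_numpy()
    sex = people["sex"].to_numpy()
    age = people["age"].to_numpy(dtype=float)

    wide = (
        frame.dropna(subset=["group"])
        .pivot_table(
            index="person_id", columns="group", values="amount_g", aggfunc="sum"
        )
        .reindex(person_ids)
    )
    records: dict[FishGroup, ConsumptionRecords] = {}
    for group in GROUP_ORDER:
        if group.value in wide.columns:
            amounts = wide[group.value].fillna(0.0).to_numpy(dtype=float)
        else:
            amounts = np.zeros(person_ids.size)
        records[group] = ConsumptionRecords(group, amounts, sex=sex, age=age)
    return records


def write_consumption_csv(
    records: Mapping[FishGroup, ConsumptionRecords], path: str | Path
) -> None:
    """Write records in the dialect :func:`load_consumption_csv` reads.

    Only positive amounts are written (absent rows mean zero).  A person with
    zero consumption in every group gets a single explicit zero row so the
    person — and their demographic tags — survive a round trip.
    """
    groups = [g for g in GROUP_ORDER if g in records]
    if not groups:
        raise InvalidParameterError("no records to write")
    n = records[groups[0]].n
    for g in groups:
        if records[g].n != n:
            raise InvalidParameterError("group record vectors are not aligned")
    first = records[groups[0]]
    sex = first.sex if first.sex is not None else np.array(["unknown"] * n)
    age = first.age if first.age is not None else np.zeros(n)

    rows: list[tuple] = []
    any_positive = np.zeros(n, dtype=bool)
    for g in groups:
        amounts = records[g].amounts
        for i in np.nonzero(amounts > 0)[0]:
            rows.append((int(i), sex[i], age[i], g.value, amounts[i]))
        any_positive |= amounts > 0
    for i in np.nonzero(~any_positive)[0]:
        rows.append((int(i), sex[i], age[i], groups[0].value, 0.0))
    frame = pd.DataFrame(rows, columns=list(CONSUMPTION_CSV_COLUMNS))
    frame.sort_values(["person_id", "group"], kind="stable").to_csv(path, index=False)
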