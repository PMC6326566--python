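"""Rank-based accuracy protocol: where does the true class land?

For each test record an observation is rebuilt from the record's fields
(date, location, altitude, biotope, colours, and — by default — the true
species' suborder, which a field observer can tell apart), the model ranks
all species/sex classes, and the 1-based position of the true class is
recorded.  Aggregates are the mean and median position, top-k hit
probabilities, the empirical 95th-percentile position (smallest position
whose cumulative share reaches 0.95) and the full position histogram.

Test records without observed colours can be given plausible colours by the
seeded augmentation procedure from :mod:`odofuzz.synthetic`; pass
``colour_seed`` to enable it (without a seed such records are classified
with the colour factor neutral at 1).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import (FuzzyRelevanceClassifier, ObservationInput,
                         RankedClass, classify, collapse_sexes)
from .occurrence import OccurrenceRecord


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class RankMetrics:
    """Aggregated positions of the correct classification."""

    n_cases: int
    mean_position: float
    median_position: float
    top_k_probability: dict[int, float]
    quantile_95_position: int
    histogram: dict[int, int]
    n_unrankable: int = 0

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "mean_position": self.mean_position,
            "median_position": self.median_position,
            "top_k_probability": {str(k): v
                                  for k, v in self.top_k_probability.items()},
            "quantile_95_position": self.quantile_95_position,
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
            "n_unrankable": self.n_unrankable,
        }


def rank_of_truth(ranked: Sequence[RankedClass],
                  true_species: str,
                  true_sex: str | None = None) -> int:
    """1-based position of the true class in a relevance-sorted list.

    With ``true_sex=None`` the list is first collapsed to one entry per
    species (max over sexes).  Raises :class:`EvaluationError` when the
    truth is absent from the list.
    """
    if true_sex is None:
        for i, (sid, _) in enumerate(collapse_sexes(ranked), start=1):
            if sid == true_species:
                return i
    else:
        for i, rc in enumerate(ranked, start=1):
            if rc.species_id == true_species and rc.sex == true_sex:
                return i
    raise EvaluationError(
        f"true class {true_species!r}/{true_sex!r} absent from ranking")


def aggregate_positions(positions: Sequence[int],
                        ks: Sequence[int] = (5, 10, 15),
                        n_unrankable: int = 0) -> RankMetrics:
    """Fold raw truth positions into :class:`RankMetrics`.

    The 95th percentile follows the empirical-CDF convention: the smallest
    position whose cumulative share is at least 0.95, i.e. the value at
    index ``ceil(0.95 n) - 1`` of the sorted positions.
    """
    if not positions:
        raise EvaluationError("no rankable test cases")
    arr = np.asarray(positions)
    n = arr.size
    q95 = int(np.sort(arr)[math.ceil(0.95 * n) - 1])
    return RankMetrics(
        n_cases=n,
        mean_position=float(arr.mean()),
        median_position=float(np.median(arr)),
        top_k_probability={int(k): float((arr <= k).mean()) for k in ks},
        quantile_95_position=q95,
        histogram=dict(Counter(int(p) for p in arr)),
        n_unrankable=n_unrankable,
    )


def evaluate(model: FuzzyRelevanceClassifier,
             records: Sequence[OccurrenceRecord],
             *,
             ignore_sex: bool = False,
             ks: Sequence[int] = (5, 10, 15),
             colour_seed: int | None = None,
             supply_suborder: bool = True) -> RankMetrics:
    """Rank the truth for every test record and aggregate.

    Records whose sex is unknown are evaluated with the sexes collapsed
    regardless of ``ignore_sex``.  Deterministic given the model, records
    and ``colour_seed``; invariant to record order.
    """
    if not records:
        raise EvaluationError("empty test set")
    records = sorted(records, key=_record_key)
    if colour_seed is not None and any(not r.colours for r in records):
        from .synthetic import augment_colours
        records = augment_colours(records, model.knowledge_base,
                                  seed=colour_seed)
    species_map = model.knowledge_base.species_map
    positions: list[int] = []
    n_unrankable = 0
    for record in records:
        entry = species_map.get(record.species_id)
        if entry is None:
            n_unrankable += 1
            continue
        obs = ObservationInput(
            date=record.date,
            lat=record.lat,
            lon=record.lon,
            altitude=record.altitude,
            biotope=(record.biotope
                     if record.biotope in model.knowledge_base.biotopes
                     else None),
            colours=record.colours,
            suborder=entry.suborder if supply_suborder else None,
        )
        ranked = classify(model, obs)
        sex = record.sex if (not ignore_sex and record.sex in ("male", "female")) else None
        try:
            positions.append(rank_of_truth(ranked, record.species_id, sex))
        except EvaluationError:
            n_unrankable += 1
    return aggregate_positions(positions, ks, n_unrankable)


def _record_key(r: OccurrenceRecord):
    # canonical order so that evaluation (incl. colour augmentation driven
    # by colour_seed) is invariant to the order records arrive in
    return (r.species_id, r.date.isoformat(), r.lat, r.lon, r.sex,
            r.altitude if r.altitude is not None else -1.0,
            r.biotope or "", tuple(sorted(r.colours or ())))


def temporal_holdout(records: Sequence[OccurrenceRecord],
                     n_years: int) -> tuple[list[OccurrenceRecord],
                                            list[OccurrenceRecord]]:
    """Hold out the last ``n_years`` of data for testing.

    Test records are those with ``year > max_year - n_years``; raises when
    either side of the split would be empty.
    """
    if not records:
        raise EvaluationError("no records to split")
    max_year = max(r.date.year for r in records)
    cut = max_year - n_years
    test = [r for r in records if r.date.year > cut]
    train = [r for r in records if r.date.year <= cut]
    if not train or not test:
        raise EvaluationError(
            f"temporal holdout of {n_years} year(s) leaves an empty side "
            f"(years span up to {max_year})")
    return train, test
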