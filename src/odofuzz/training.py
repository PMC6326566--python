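"""Data-driven coefficient tables derived from training records.

Three tables are learned from occurrence data:

* **commonality** — per-species record count divided by the count of the
  most frequent species, so the modal species scores 1 and unseen species 0;
* **presence grid** — the set of (species, grid cell) pairs with at least
  one training record, backing the position coefficient (present 1,
  absent 0.5);
* **biotope preferences** — per-species habitat frequencies, max-normalised
  and affinely mapped onto [0.8, 1] so that the modal biotope scores the
  full value and an unseen habitat only mildly penalises the class.

``fit_model`` binds these tables to an expert knowledge base and returns a
fitted :class:`~odofuzz.classifier.FuzzyRelevanceClassifier`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .knowledge_base import KnowledgeBase
from .occurrence import GridCell, GridConfig, OccurrenceRecord


def compute_commonality(
        records: Sequence[OccurrenceRecord]) -> dict[str, float]:
    """Per-species record count over the most frequent species' count.

    Returns an empty map for an empty record list; species without records
    simply do not appear (lookups should default to 0).  Scale-invariant:
    duplicating every record leaves the map unchanged.
    """
    counts: dict[str, int] = {}
    for r in records:
        counts[r.species_id] = counts.get(r.species_id, 0) + 1
    if not counts:
        return {}
    max_count = max(counts.values())
    return {sid: n / max_count for sid, n in counts.items()}


def build_presence_grid(
        records: Sequence[OccurrenceRecord],
        grid: GridConfig | None = None) -> set[tuple[str, GridCell]]:
    """Set of (species_id, cell) pairs with >= 1 training record."""
    grid = grid or GridConfig()
    return {(r.species_id, grid.cell(r.lat, r.lon)) for r in records}


def build_biotope_table(
        records: Sequence[OccurrenceRecord],
        biotope_vocabulary: Sequence[str],
        floor: float = 0.8) -> dict[tuple[str, str], float]:
    """Per-(species, biotope) preference on [floor, 1].

    For each species with biotoped records, the per-biotope count is divided
    by the species' modal biotope count and mapped as
    ``floor + (1 - floor) * f``; biotopes never recorded for the species get
    the floor.  Species absent from the table should be looked up with the
    floor as default.
    """
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        if r.biotope is not None:
            per = counts.setdefault(r.species_id, {})
            per[r.biotope] = per.get(r.biotope, 0) + 1
    table: dict[tuple[str, str], float] = {}
    species_ids = {r.species_id for r in records}
    for sid in species_ids:
        per = counts.get(sid, {})
        max_count = max(per.values()) if per else 0
        for biotope in biotope_vocabulary:
            f = per.get(biotope, 0) / max_count if max_count else 0.0
            table[(sid, biotope)] = floor + (1.0 - floor) * f
    return table


def fit_model(kb: KnowledgeBase,
              records: Sequence[OccurrenceRecord],
              grid: GridConfig | None = None,
              **constants):
    """Fit a :class:`FuzzyRelevanceClassifier` on training records.

    ``constants`` are forwarded to the estimator (``additive_weight``,
    ``absent_position``, ``biotope_floor``, ...).
    """
    from .classifier import FuzzyRelevanceClassifier

    clf = FuzzyRelevanceClassifier(knowledge_base=kb, grid=grid, **constants)
    return clf.fit(records)
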