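"""Fuzzy relevance classifier: seven multiplicative coefficients per class.

For every species/sex class the relevance of a partial field observation is

    commonality * suborder * colour * position * altitude * biotope * season

with each factor in [0, 1] and any factor whose input the observer did not
provide set to 1 (missing information is neutral).  The colour factor is a
composition of fuzzy relations,

    colour = min( 0.7 * ((in o S) o A) + 0.3,  in o E ),

where ``in`` is the binary vector of the (at most three) colours the
observer selected, ``S`` the colour-similarity matrix, ``A`` the additive
colour matrix, and ``E`` the exclusion matrix stored as *permissibility*:
the additive branch is a sup-min composition shifted onto [0.3, 1], while
the exclusion branch takes the minimum permissibility over the selected
colours (a Bandler-Kohout-style inf-composition), so a single forbidden
colour caps the class at 0.

:class:`FuzzyRelevanceClassifier` is a scikit-learn style estimator:
``fit`` learns the commonality, presence-grid and biotope tables from
occurrence records, and the fitted model ranks all species/sex classes for
an observation.  The module-level functions are thin views onto a fitted
estimator so each coefficient can be exercised on its own.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .knowledge_base import (COLOUR_INDEX, COLOURS, N_COLOURS, SEXES,
                             SUBORDERS, KnowledgeBase, SpeciesKnowledge)
from .occurrence import (GridConfig, OccurrenceRecord, _parse_row)
from .training import (build_biotope_table, build_presence_grid,
                       compute_commonality)

COEFFICIENT_KEYS: tuple[str, ...] = (
    "commonality", "suborder", "colour", "position",
    "altitude", "biotope", "season",
)

MAX_SELECTED_COLOURS = 3

_SEX_ORDER = {"male": 0, "female": 1}


@dataclass(frozen=True)
class ObservationInput:
    """A partial field observation; every field is optional.

    ``lat``/``lon`` must be given together; ``colours`` holds at most three
    codes from the seven-colour vocabulary.  Sex is not an input — the
    classifier scores both sexes of every species.
    """

    date: dt.date | None = None
    lat: float | None = None
    lon: float | None = None
    altitude: float | None = None
    suborder: str | None = None
    biotope: str | None = None
    colours: frozenset[str] | None = None

    def __post_init__(self):
        if (self.lat is None) != (self.lon is None):
            raise ValueError("lat and lon must be provided together")
        if self.suborder is not None and self.suborder not in SUBORDERS:
            raise ValueError(f"unknown suborder {self.suborder!r}")
        if self.colours is not None:
            colours = frozenset(self.colours)
            if len(colours) > MAX_SELECTED_COLOURS:
                raise ValueError(
                    f"at most {MAX_SELECTED_COLOURS} colours may be selected")
            unknown = colours - set(COLOURS)
            if unknown:
                raise ValueError(f"unknown colour {sorted(unknown)[0]!r}")
            object.__setattr__(self, "colours", colours)


@dataclass(frozen=True)
class RankedClass:
    """One species/sex class with its relevance and coefficient breakdown."""

    species_id: str
    sex: str
    relevance: float
    coefficients: dict[str, float]


def relevance_from_breakdown(coefficients: Mapping[str, float]) -> float:
    """Recompute relevance as the product of the seven multiplicands."""
    product = 1.0
    for key in COEFFICIENT_KEYS:
        product = product * coefficients[key]
    return product


def colour_vector_from_names(names: Iterable[str]) -> np.ndarray:
    vec = np.zeros(N_COLOURS)
    for name in names:
        vec[COLOUR_INDEX[name]] = 1.0
    return vec


def colour_coefficient(in_vec: np.ndarray,
                       similarity: np.ndarray,
                       additive_col: np.ndarray,
                       permissibility_col: np.ndarray,
                       weight: float = 0.7,
                       offset: float = 0.3) -> float:
    """Colour factor for one class from the binary input vector.

    An empty selection returns 1 (missing-input rule).  Otherwise the
    additive branch is ``weight * max_c' min(v[c'], A[c']) + offset`` with
    ``v[c'] = max_{c selected} S[c, c']``, and the result is capped by the
    minimum permissibility ``E[c]`` over the selected colours.
    """
    selected = np.flatnonzero(in_vec)
    if selected.size == 0:
        return 1.0
    if selected.size > MAX_SELECTED_COLOURS:
        raise ValueError(
            f"at most {MAX_SELECTED_COLOURS} colours may be selected")
    v = similarity[selected, :].max(axis=0)
    w = float(np.minimum(v, additive_col).max())
    additive = weight * w + offset
    exclusion = float(permissibility_col[selected].min())
    return min(additive, exclusion)


def season_coefficient(entry: SpeciesKnowledge,
                       date: dt.date | None,
                       floor: float = 0.5) -> float:
    """Seasonality factor on [floor, 1]; 1 when no date was given."""
    if date is None:
        return 1.0
    day = date.timetuple().tm_yday
    return floor + (1.0 - floor) * entry.seasonality.membership(day)


def altitude_coefficient(entry: SpeciesKnowledge,
                         altitude: float | None,
                         floor: float = 0.5) -> float:
    """Altitude factor on [floor, 1]; 1 when no altitude was given."""
    if altitude is None:
        return 1.0
    return floor + (1.0 - floor) * entry.altitude.membership(altitude)


def suborder_coefficient(entry: SpeciesKnowledge,
                         suborder: str | None) -> float:
    """1 on match or missing input, 0 on suborder mismatch."""
    if suborder is None:
        return 1.0
    return 1.0 if entry.suborder == suborder else 0.0


def position_coefficient(model: "FuzzyRelevanceClassifier",
                         species_id: str,
                         lat: float | None,
                         lon: float | None) -> float:
    """1 if the species has a training record in the query's grid cell,
    otherwise ``absent_position`` (default 0.5); 1 without coordinates."""
    if lat is None or lon is None:
        return 1.0
    cell = model.grid_.cell(lat, lon)
    if (species_id, cell) in model.presence_:
        return 1.0
    return model.absent_position


def biotope_coefficient(model: "FuzzyRelevanceClassifier",
                        species_id: str,
                        biotope: str | None) -> float:
    """Trained biotope preference on [floor, 1]; 1 without a biotope."""
    if biotope is None:
        return 1.0
    if biotope not in model.knowledge_base.biotopes:
        raise ValueError(f"unknown biotope {biotope!r}")
    return model.biotope_pref_.get((species_id, biotope), model.biotope_floor)


def relevance(model: "FuzzyRelevanceClassifier",
              species_id: str,
              sex: str,
              obs: ObservationInput) -> RankedClass:
    """Score one species/sex class; keeps the coefficient breakdown."""
    entry = model._species_map.get(species_id)
    if entry is None:
        raise ValueError(f"unknown species {species_id!r}")
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if obs.colours:
        colour = colour_coefficient(
            colour_vector_from_names(obs.colours),
            model.knowledge_base.colour_similarity,
            entry.colours_additive[sex],
            entry.colours_permissibility[sex],
            weight=model.additive_weight,
            offset=model.additive_offset,
        )
    else:
        colour = 1.0
    coefficients = {
        "commonality": model.commonality_[species_id],
        "suborder": suborder_coefficient(entry, obs.suborder),
        "colour": colour,
        "position": position_coefficient(model, species_id, obs.lat, obs.lon),
        "altitude": altitude_coefficient(entry, obs.altitude,
                                         model.altitude_floor),
        "biotope": biotope_coefficient(model, species_id, obs.biotope),
        "season": season_coefficient(entry, obs.date, model.season_floor),
    }
    return RankedClass(species_id=species_id, sex=sex,
                       relevance=relevance_from_breakdown(coefficients),
                       coefficients=coefficients)


def _rank_key(rc: RankedClass):
    # relevance desc, commonality desc, species lexicographic, male first
    return (-rc.relevance, -rc.coefficients["commonality"],
            rc.species_id, _SEX_ORDER[rc.sex])


def classify(model: "FuzzyRelevanceClassifier",
             obs: ObservationInput) -> list[RankedClass]:
    """Rank every species/sex class by relevance, descending.

    The total order is deterministic: ties are broken by commonality
    (descending), then species id (lexicographic), then male before female.
    """
    ranked = [relevance(model, sp.species_id, sex, obs)
              for sp in model.knowledge_base.species for sex in SEXES]
    ranked.sort(key=_rank_key)
    return ranked


def collapse_sexes(ranked: Sequence[RankedClass]) -> list[tuple[str, float]]:
    """Reduce a per-sex ranking to per-species (max over sexes)."""
    best: dict[str, RankedClass] = {}
    for rc in ranked:
        cur = best.get(rc.species_id)
        if cur is None or rc.relevance > cur.relevance:
            best[rc.species_id] = rc
    collapsed = sorted(
        best.values(),
        key=lambda rc: (-rc.relevance, -rc.coefficients["commonality"],
                        rc.species_id))
    return [(rc.species_id, rc.relevance) for rc in collapsed]


class FuzzyRelevanceClassifier(BaseEstimator):
    """Rank odonate species/sex classes for partial field observations.

    Parameters
    ----------
    knowledge_base : KnowledgeBase
        Expert knowledge (fuzzy sets, colour matrices, vocabularies).
    grid : GridConfig, optional
        Graticule for the presence grid; defaults to 6' x 10' cells.
    additive_weight, additive_offset : float
        Shift of the additive colour branch onto
        ``[offset, weight + offset]``; their sum must not exceed 1.
    absent_position : float
        Position factor for a species without a training record in the
        query cell.
    biotope_floor, season_floor, altitude_floor : float
        Lower ends of the respective coefficient intervals.
    commonality_floor : float
        Minimum commonality assigned to species absent from the training
        records (default 0, meaning such species can never be ranked above
        a zero-relevance class).

    Attributes
    ----------
    commonality_ : dict[str, float]
        Per-species record share of the modal species.
    presence_ : set[tuple[str, GridCell]]
        Species presence per grid cell.
    biotope_pref_ : dict[tuple[str, str], float]
        Per-(species, biotope) preference on [biotope_floor, 1].
    classes_ : ndarray of str
        All ``"species|sex"`` labels, in knowledge-base order.
    fit_report_ : dict
        Record counts and exclusions applied during fitting.
    """

    def __init__(self, knowledge_base: KnowledgeBase | None = None,
                 grid: GridConfig | None = None,
                 additive_weight: float = 0.7,
                 additive_offset: float = 0.3,
                 absent_position: float = 0.5,
                 biotope_floor: float = 0.8,
                 season_floor: float = 0.5,
                 altitude_floor: float = 0.5,
                 commonality_floor: float = 0.0):
        self.knowledge_base = knowledge_base
        self.grid = grid
        self.additive_weight = additive_weight
        self.additive_offset = additive_offset
        self.absent_position = absent_position
        self.biotope_floor = biotope_floor
        self.season_floor = season_floor
        self.altitude_floor = altitude_floor
        self.commonality_floor = commonality_floor

    # -- fitting ---------------------------------------------------------

    def _check_params(self) -> None:
        if self.knowledge_base is None:
            raise ValueError("a knowledge_base is required to fit")
        self.knowledge_base.validate()
        if self.additive_weight + self.additive_offset > 1.0 + 1e-12:
            raise ValueError(
                "additive_weight + additive_offset must not exceed 1")
        for name in ("absent_position", "biotope_floor", "season_floor",
                     "altitude_floor", "commonality_floor"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")

    @staticmethod
    def _as_records(X) -> list[OccurrenceRecord]:
        if isinstance(X, pd.DataFrame):
            return [_parse_row(i, row)
                    for i, (_, row) in enumerate(X.iterrows(), start=1)]
        return list(X)

    def fit(self, X, y=None) -> "FuzzyRelevanceClassifier":
        """Learn the commonality, presence and biotope tables.

        ``X`` is a sequence of :class:`OccurrenceRecord` (or a DataFrame in
        the occurrence CSV layout); ``y`` is ignored (the records carry
        their species labels).  Records of species unknown to the knowledge
        base are excluded with a warning and counted in ``fit_report_``.
        """
        self._check_params()
        records = self._as_records(X)
        known = {sp.species_id for sp in self.knowledge_base.species}
        kept = [r for r in records if r.species_id in known]
        n_excluded = len(records) - len(kept)
        if records and not kept:
            raise ValueError(
                "no training record matches a knowledge-base species")
        if n_excluded:
            warnings.warn(
                f"excluded {n_excluded} record(s) of species unknown "
                f"to the knowledge base", stacklevel=2)
        self.grid_ = self.grid or GridConfig()
        raw = compute_commonality(kept)
        self.commonality_ = {
            sid: max(raw.get(sid, 0.0), self.commonality_floor)
            for sid in known}
        self.presence_ = build_presence_grid(kept, self.grid_)
        self.biotope_pref_ = build_biotope_table(
            kept, self.knowledge_base.biotopes, self.biotope_floor)
        self.classes_ = np.array(
            [f"{sp.species_id}|{sex}"
             for sp in self.knowledge_base.species for sex in SEXES])
        self._species_map = self.knowledge_base.species_map
        self.fit_report_ = {
            "n_records": len(records),
            "n_used": len(kept),
            "n_excluded_unknown_species": n_excluded,
        }
        return self

    # -- prediction ------------------------------------------------------

    def classify(self, obs: ObservationInput) -> list[RankedClass]:
        """Full descending ranking of all species/sex classes."""
        self._check_fitted()
        return classify(self, obs)

    def predict(self, X: Iterable[ObservationInput]) -> np.ndarray:
        """Top-ranked ``"species|sex"`` label for each observation."""
        self._check_fitted()
        labels = []
        for obs in X:
            top = classify(self, obs)[0]
            labels.append(f"{top.species_id}|{top.sex}")
        return np.array(labels)

    def _check_fitted(self) -> None:
        if not hasattr(self, "commonality_"):
            raise ValueError(
                "this FuzzyRelevanceClassifier instance is not fitted yet")

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model (knowledge base embedded) as JSON."""
        self._check_fitted()
        doc = {
            "schema_version": 1,
            "knowledge_base": self.knowledge_base.to_dict(),
            "grid": {"lat0": self.grid_.lat0, "lon0": self.grid_.lon0,
                     "dlat": self.grid_.dlat, "dlon": self.grid_.dlon},
            "params": {
                "additive_weight": self.additive_weight,
                "additive_offset": self.additive_offset,
                "absent_position": self.absent_position,
                "biotope_floor": self.biotope_floor,
                "season_floor": self.season_floor,
                "altitude_floor": self.altitude_floor,
                "commonality_floor": self.commonality_floor,
            },
            "commonality": dict(sorted(self.commonality_.items())),
            "presence": sorted([sid, cell.row, cell.col]
                               for sid, cell in self.presence_),
            "biotope_pref": sorted([sid, b, v]
                                   for (sid, b), v in
                                   self.biotope_pref_.items()),
            "fit_report": self.fit_report_,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "FuzzyRelevanceClassifier":
        """Reload a model written by :meth:`save`, losslessly."""
        from .occurrence import GridCell

        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        kb = KnowledgeBase.from_dict(doc["knowledge_base"])
        grid = GridConfig(**doc["grid"])
        clf = cls(knowledge_base=kb, grid=grid, **doc["params"])
        clf.grid_ = grid
        clf.commonality_ = {sid: float(v)
                            for sid, v in doc["commonality"].items()}
        clf.presence_ = {(sid, GridCell(int(row), int(col)))
                         for sid, row, col in doc["presence"]}
        clf.biotope_pref_ = {(sid, b): float(v)
                             for sid, b, v in doc["biotope_pref"]}
        clf.classes_ = np.array(
            [f"{sp.species_id}|{sex}" for sp in kb.species for sex in SEXES])
        clf._species_map = kb.species_map
        clf.fit_report_ = doc.get("fit_report", {})
        return clf
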