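"""Expert knowledge base: per-species fuzzy sets and colour matrices.

The classifier's expert knowledge consists, for each odonate species, of its
taxonomical suborder, a trapezoidal fuzzy set over day-of-year (flight
season), a trapezoidal fuzzy set over altitude in metres, and two colour
vectors per sex over a fixed seven-colour vocabulary:

* an *additive* vector (the species' column of the matrix ``A``) — degree to
  which each colour supports the species;
* a *permissibility* vector (the species' column of the matrix ``E``) —
  ``1`` means observing the colour carries no penalty, ``0`` means observing
  it excludes the class outright.

A knowledge base bundles all species with the colour-similarity matrix ``S``
and the biotope vocabulary.  Files are YAML (JSON, being a YAML subset, is
accepted too); see ``data/kb.schema.json`` for the schema.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

COLOURS: tuple[str, ...] = (
    "yellow", "orange", "red", "green", "blue", "brown", "black",
)
N_COLOURS = len(COLOURS)
COLOUR_INDEX: dict[str, int] = {c: i for i, c in enumerate(COLOURS)}

SUBORDERS: tuple[str, ...] = ("anisoptera", "zygoptera")
SEXES: tuple[str, ...] = ("male", "female")

#: Habitat categories offered to the observer, as lowercase snake_case codes.
#: The count is a property of the knowledge-base file, not a constant of the
#: library: a KB may ship a different (e.g. extended) vocabulary.
DEFAULT_BIOTOPES: tuple[str, ...] = (
    "lake",
    "puddle",
    "canal",
    "garden_pool",
    "quarry",
    "wetland",
    "brook",
    "headwaters_and_spring",
    "organic_soil_wetland",
    "pond",
    "river",
    "oxbow_lake",
    "reservoir_in_valley",
    "terrestrial_habitat",
)

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Knowledge-base invariant violation, naming the offending species/field."""

    def __init__(self, message: str, species_id: str | None = None,
                 field_name: str | None = None):
        self.species_id = species_id
        self.field_name = field_name
        prefix = ""
        if species_id is not None:
            prefix += f"species {species_id!r}: "
        if field_name is not None:
            prefix += f"field {field_name!r}: "
        super().__init__(prefix + message)


@dataclass(frozen=True)
class TrapezoidFuzzySet:
    """Trapezoidal membership function defined by corners ``a <= b <= c <= d``.

    Membership is 0 outside ``(a, d)``, 1 on the plateau ``[b, c]`` and
    linear on the ramps.  Degenerate ramps (``a == b`` and/or ``c == d``)
    are legal and behave as closed step edges: ``membership(b) == 1`` even
    when ``a == b``.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise SchemaError(
                f"trapezoid corners must satisfy a <= b <= c <= d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def membership(self, x: float) -> float:
        if self.b <= x <= self.c:
            return 1.0
        if x <= self.a or x >= self.d:
            return 0.0
        if x < self.b:
            return (x - self.a) / (self.b - self.a)
        return (self.d - x) / (self.d - self.c)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def colour_vector(spec: Mapping[str, float] | Sequence[float],
                  default: float) -> np.ndarray:
    """Build a length-7 colour vector from a colour->degree mapping or a
    full sequence in vocabulary order; unspecified colours get ``default``."""
    if isinstance(spec, Mapping):
        vec = np.full(N_COLOURS, float(default))
        for name, degree in spec.items():
            if name not in COLOUR_INDEX:
                raise SchemaError(f"unknown colour {name!r}")
            vec[COLOUR_INDEX[name]] = float(degree)
    else:
        arr = np.asarray(list(spec), dtype=float)
        if arr.shape != (N_COLOURS,):
            raise SchemaError(
                f"colour vector must have length {N_COLOURS}, got {arr.shape}"
            )
        vec = arr
    if np.any(vec < 0) or np.any(vec > 1):
        raise SchemaError("colour degrees must lie in [0, 1]")
    return vec


def _vector_to_mapping(vec: np.ndarray, default: float) -> dict[str, float]:
    return {
        COLOURS[i]: float(v)
        for i, v in enumerate(vec)
        if float(v) != default
    }


@dataclass(frozen=True)
class SpeciesKnowledge:
    """Expert knowledge for one species.

    ``colours_additive[sex]`` is the species' additive colour vector (column
    of A); ``colours_permissibility[sex]`` is the exclusion column of E
    encoded as permissibility (1 = colour carries no penalty, 0 = observing
    that colour excludes the class).  A and E are independent — only range
    checks apply between them.
    """

    species_id: str
    suborder: str
    seasonality: TrapezoidFuzzySet
    altitude: TrapezoidFuzzySet
    colours_additive: dict[str, np.ndarray]
    colours_permissibility: dict[str, np.ndarray]

    def validate(self) -> None:
        sid = self.species_id
        if not sid:
            raise SchemaError("empty species id", species_id=sid)
        if self.suborder not in SUBORDERS:
            raise SchemaError(
                f"suborder must be one of {SUBORDERS}, got {self.suborder!r}",
                species_id=sid, field_name="suborder")
        for fname, vectors in (("colours_additive", self.colours_additive),
                               ("colours_permissibility",
                                self.colours_permissibility)):
            for sex in SEXES:
                if sex not in vectors:
                    raise SchemaError(f"missing sex {sex!r}",
                                      species_id=sid, field_name=fname)
                vec = vectors[sex]
                if vec.shape != (N_COLOURS,) or np.any(vec < 0) or np.any(vec > 1):
                    raise SchemaError(
                        "colour vector must be 7 degrees in [0, 1]",
                        species_id=sid, field_name=f"{fname}.{sex}")
        # trapezoid ordering is enforced at construction; re-check day range
        if not (1 <= self.seasonality.a and self.seasonality.d <= 366):
            raise SchemaError(
                "seasonality trapezoid must lie within day-of-year [1, 366]",
                species_id=sid, field_name="seasonality")

    def to_dict(self) -> dict:
        return {
            "id": self.species_id,
            "suborder": self.suborder,
            "seasonality": [float(v) for v in self.seasonality.as_tuple()],
            "altitude": [float(v) for v in self.altitude.as_tuple()],
            "colours": {
                sex: {
                    "additive": _vector_to_mapping(
                        self.colours_additive[sex], 0.0),
                    "permissibility": _vector_to_mapping(
                        self.colours_permissibility[sex], 1.0),
                }
                for sex in SEXES
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SpeciesKnowledge":
        sid = str(doc.get("id", ""))
        try:
            seasonality = TrapezoidFuzzySet(*map(float, doc["seasonality"]))
        except SchemaError as exc:
            raise SchemaError(str(exc), species_id=sid,
                              field_name="seasonality") from None
        try:
            altitude = TrapezoidFuzzySet(*map(float, doc["altitude"]))
        except SchemaError as exc:
            raise SchemaError(str(exc), species_id=sid,
                              field_name="altitude") from None
        colours = doc.get("colours", {})
        additive = {}
        permissibility = {}
        for sex in SEXES:
            sex_doc = colours.get(sex, {})
            try:
                additive[sex] = colour_vector(sex_doc.get("additive", {}), 0.0)
                permissibility[sex] = colour_vector(
                    sex_doc.get("permissibility", {}), 1.0)
            except SchemaError as exc:
                raise SchemaError(str(exc), species_id=sid,
                                  field_name=f"colours.{sex}") from None
        return cls(species_id=sid, suborder=str(doc.get("suborder", "")),
                   seasonality=seasonality, altitude=altitude,
                   colours_additive=additive,
                   colours_permissibility=permissibility)


@dataclass(frozen=True)
class KnowledgeBase:
    """All species plus the colour-similarity matrix S and vocabularies."""

    species: tuple[SpeciesKnowledge, ...]
    colour_similarity: np.ndarray
    biotopes: tuple[str, ...] = DEFAULT_BIOTOPES

    def validate(self) -> None:
        seen: set[str] = set()
        for sp in self.species:
            if sp.species_id in seen:
                raise SchemaError("duplicate species id",
                                  species_id=sp.species_id)
            seen.add(sp.species_id)
            sp.validate()
        S = self.colour_similarity
        if S.shape != (N_COLOURS, N_COLOURS):
            raise SchemaError(
                f"colour similarity must be {N_COLOURS}x{N_COLOURS}",
                field_name="colour_similarity")
        if np.any(S < 0) or np.any(S > 1):
            raise SchemaError("similarity entries must lie in [0, 1]",
                              field_name="colour_similarity")
        if not np.array_equal(S, S.T):
            raise SchemaError("similarity matrix must be symmetric",
                              field_name="colour_similarity")
        if not np.array_equal(np.diag(S), np.ones(N_COLOURS)):
            raise SchemaError("similarity diagonal must be all ones",
                              field_name="colour_similarity")
        if len(set(self.biotopes)) != len(self.biotopes) or not self.biotopes:
            raise SchemaError("biotope vocabulary must be non-empty and unique",
                              field_name="biotopes")

    @property
    def species_map(self) -> dict[str, SpeciesKnowledge]:
        return {sp.species_id: sp for sp in self.species}

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "colour_similarity": [[float(v) for v in row]
                                  for row in self.colour_similarity],
            "biotopes": list(self.biotopes),
            "species": [sp.to_dict() for sp in self.species],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KnowledgeBase":
        if not isinstance(doc, Mapping):
            raise SchemaError("knowledge base document must be a mapping")
        if "schema_version" not in doc:
            raise SchemaError("missing required field",
                              field_name="schema_version")
        if int(doc["schema_version"]) != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {doc['schema_version']!r}",
                field_name="schema_version")
        species = tuple(SpeciesKnowledge.from_dict(s)
                        for s in doc.get("species", []))
        S = np.asarray(doc.get("colour_similarity",
                               np.eye(N_COLOURS).tolist()), dtype=float)
        biotopes = tuple(doc.get("biotopes", DEFAULT_BIOTOPES))
        kb = cls(species=species, colour_similarity=S, biotopes=biotopes)
        kb.validate()
        return kb


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base from a YAML (or JSON) file.

    Raises ``OSError`` if unreadable, ``SchemaError`` (naming the species
    and field) on invariant violations.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise OSError(f"cannot parse knowledge base file {path}: {exc}") from exc
    return KnowledgeBase.from_dict(doc)


def save_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    """Write a knowledge base as YAML (``.json`` extension writes JSON)."""
    kb.validate()
    doc = kb.to_dict()
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1, sort_keys=True),
                        encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False),
                        encoding="utf-8")
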