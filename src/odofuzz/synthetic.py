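"""Synthetic knowledge bases and occurrence records for end-to-end testing.

The generator emulates the statistical structure the classifier assumes,
without imitating any real fauna: a Zipf-skewed species frequency
distribution, per-species flight seasons (trapezoids within days 60-300)
and altitude bands (within 100-1500 m), species home ranges as sets of
grid cells inside a Central-European-sized bounding box, a modal biotope
per species, and the colour-augmentation step that assigns each record up
to three colours plausible for the species and sex.

All demonstration constants here (the similarity matrix, noise rates,
bounding box) are synthetic stand-ins, clearly non-authoritative.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .knowledge_base import (COLOURS, DEFAULT_BIOTOPES, N_COLOURS, SEXES,
                             SUBORDERS, KnowledgeBase, SpeciesKnowledge,
                             TrapezoidFuzzySet)
from .occurrence import (ABUNDANCE_CLASSES, GridCell, GridConfig,
                         OccurrenceRecord)

#: Demonstration colour-similarity matrix: identity plus a red~orange bleed
#: of 0.5 and a blue~green bleed of 0.3.  Synthetic constants, not expert
#: values.
def default_colour_similarity() -> np.ndarray:
    S = np.eye(N_COLOURS)
    red, orange = COLOURS.index("red"), COLOURS.index("orange")
    blue, green = COLOURS.index("blue"), COLOURS.index("green")
    S[red, orange] = S[orange, red] = 0.5
    S[blue, green] = S[green, blue] = 0.3
    return S


_ABUNDANCE_WEIGHTS = (0.35, 0.30, 0.15, 0.10, 0.05, 0.03, 0.02)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the generator.

    Noise rates are the fractions of records falling outside the species'
    seasonal/altitudinal support, outside its home cells, or in a
    non-modal biotope.
    """

    n_species: int = 74
    n_records: int = 20000
    commonality_skew: float = 1.0
    season_noise: float = 0.05
    altitude_noise: float = 0.05
    position_noise: float = 0.05
    biotope_offmodal: float = 0.30
    bbox: tuple[float, float, float, float] = (48.55, 51.05, 12.05, 18.85)
    year_range: tuple[int, int] = (2010, 2021)
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for name in ("season_noise", "altitude_noise", "position_noise",
                     "biotope_offmodal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lat_lo, lat_hi, lon_lo, lon_hi = self.bbox
        if not (lat_lo < lat_hi and lon_lo < lon_hi):
            raise ValueError("bbox must be (lat_lo, lat_hi, lon_lo, lon_hi)")


def generate_knowledge_base(cfg: GeneratorConfig) -> KnowledgeBase:
    """Random but schema-valid knowledge base, deterministic given the seed.

    Each species gets a random suborder, a seasonal trapezoid within days
    [60, 300], an altitude trapezoid within [100, 1500] m, 1-3 additive
    colours per sex at degree 1, and 0-2 hard exclusions per sex chosen
    outside the additive support (so a plausibly coloured individual is
    never excluded by its own species).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = max(3, len(str(cfg.n_species)))
    species = []
    for i in range(cfg.n_species):
        sid = f"species_{i + 1:0{width}d}"
        suborder = SUBORDERS[int(rng.integers(0, 2))]
        b = float(rng.uniform(90, 240))
        c = min(300.0, b + float(rng.uniform(20, 60)))
        a = max(60.0, b - float(rng.uniform(5, 30)))
        d = min(300.0, c + float(rng.uniform(5, 30)))
        seasonality = TrapezoidFuzzySet(a, b, c, d)
        ab = float(rng.uniform(150, 900))
        ac = min(1500.0, ab + float(rng.uniform(100, 400)))
        aa = max(100.0, ab - float(rng.uniform(30, 150)))
        ad = min(1500.0, ac + float(rng.uniform(30, 300)))
        altitude = TrapezoidFuzzySet(aa, ab, ac, ad)
        additive = {}
        permissibility = {}
        for sex in SEXES:
            n_add = int(rng.integers(1, 4))
            add_idx = rng.choice(N_COLOURS, size=n_add, replace=False)
            vec = np.zeros(N_COLOURS)
            vec[add_idx] = 1.0
            additive[sex] = vec
            perm = np.ones(N_COLOURS)
            complement = np.setdiff1d(np.arange(N_COLOURS), add_idx)
            n_excl = int(rng.integers(0, 3))
            if n_excl and complement.size:
                excl_idx = rng.choice(complement,
                                      size=min(n_excl, complement.size),
                                      replace=False)
                perm[excl_idx] = 0.0
            permissibility[sex] = perm
        species.append(SpeciesKnowledge(
            species_id=sid, suborder=suborder, seasonality=seasonality,
            altitude=altitude, colours_additive=additive,
            colours_permissibility=permissibility))
    kb = KnowledgeBase(species=tuple(species),
                       colour_similarity=default_colour_similarity(),
                       biotopes=DEFAULT_BIOTOPES)
    kb.validate()
    return kb


def _bbox_cells(grid: GridConfig,
                bbox: tuple[float, float, float, float]) -> list[tuple[int, int]]:
    lat_lo, lat_hi, lon_lo, lon_hi = bbox
    row_lo = math.floor((lat_lo - grid.lat0) / grid.dlat)
    row_hi = math.floor((lat_hi - grid.lat0) / grid.dlat)
    col_lo = math.floor((lon_lo - grid.lon0) / grid.dlon)
    col_hi = math.floor((lon_hi - grid.lon0) / grid.dlon)
    return [(r, c) for r in range(row_lo, row_hi)
            for c in range(col_lo, col_hi)]


def generate_records(kb: KnowledgeBase,
                     cfg: GeneratorConfig,
                     grid: GridConfig | None = None) -> list[OccurrenceRecord]:
    """Occurrence records with the configured frequency skew and noise.

    Species are drawn from a Zipf-like distribution (weight proportional to
    ``rank ** -skew`` over a random rank permutation); each record's date
    falls inside the species' seasonal support, its altitude inside the
    altitude support, its location inside one of the species' home grid
    cells and its biotope on the species' modal biotope — except for the
    configured noise fractions.  Deterministic given the seed.
    """
    cfg.validate()
    grid = grid or GridConfig()
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(kb.species)
    ranks = rng.permutation(n) + 1
    weights = ranks.astype(float) ** -cfg.commonality_skew
    weights /= weights.sum()
    cells = _bbox_cells(grid, cfg.bbox)
    w_max = weights.max()
    home_cells = []
    modal_biotopes = []
    for i in range(n):
        n_home = max(3, int(round(120 * weights[i] / w_max)))
        n_home = min(n_home, len(cells))
        idx = rng.choice(len(cells), size=n_home, replace=False)
        home_cells.append([cells[j] for j in idx])
        modal_biotopes.append(kb.biotopes[int(rng.integers(0, len(kb.biotopes)))])
    lat_lo, lat_hi, lon_lo, lon_hi = cfg.bbox
    y0, y1 = cfg.year_range
    species_idx = rng.choice(n, size=cfg.n_records, p=weights)
    records: list[OccurrenceRecord] = []
    for k in range(cfg.n_records):
        i = int(species_idx[k])
        sp = kb.species[i]
        sex = SEXES[int(rng.integers(0, 2))]
        year = int(rng.integers(y0, y1 + 1))
        if rng.random() < cfg.season_noise:
            day = int(rng.integers(1, 366))
        else:
            lo = int(math.floor(sp.seasonality.a)) + 1
            hi = int(math.ceil(sp.seasonality.d)) - 1
            day = int(rng.integers(lo, max(lo, hi) + 1))
        date = dt.date(year, 1, 1) + dt.timedelta(days=day - 1)
        if rng.random() < cfg.altitude_noise:
            altitude = float(rng.uniform(0, 1600))
        else:
            altitude = float(rng.uniform(sp.altitude.a, sp.altitude.d))
        if rng.random() < cfg.position_noise:
            lat = float(rng.uniform(lat_lo, lat_hi))
            lon = float(rng.uniform(lon_lo, lon_hi))
        else:
            row, col = home_cells[i][int(rng.integers(0, len(home_cells[i])))]
            cell_lat_lo, cell_lat_hi, cell_lon_lo, cell_lon_hi = \
                grid.cell_bounds(GridCell(row, col))
            lat = float(rng.uniform(cell_lat_lo, cell_lat_hi))
            lon = float(rng.uniform(cell_lon_lo, cell_lon_hi))
        if rng.random() < cfg.biotope_offmodal:
            others = [b for b in kb.biotopes if b != modal_biotopes[i]]
            biotope = others[int(rng.integers(0, len(others)))]
        else:
            biotope = modal_biotopes[i]
        count = str(rng.choice(ABUNDANCE_CLASSES, p=_ABUNDANCE_WEIGHTS))
        records.append(OccurrenceRecord(
            species_id=sp.species_id, sex=sex, date=date, lat=lat, lon=lon,
            altitude=altitude, biotope=biotope, count=count))
    return records


def augment_colours(records: Sequence[OccurrenceRecord],
                    kb: KnowledgeBase,
                    max_colours: int = 3,
                    seed: int = 0) -> list[OccurrenceRecord]:
    """Assign each colourless record 1..max_colours plausible colours.

    Colours are sampled without replacement from the additive support of
    the record's species and sex (union of both sexes when the sex is
    unknown), mirroring how an observer would report colours the species
    can actually show.  Records that already carry colours are returned
    unchanged; a species with empty additive support leaves its records
    colourless with a warning.  Deterministic given the seed and record
    order.
    """
    rng = np.random.default_rng(seed)
    species_map = kb.species_map
    out: list[OccurrenceRecord] = []
    for r in records:
        if r.colours:
            out.append(r)
            continue
        entry = species_map.get(r.species_id)
        if entry is None:
            raise ValueError(f"unknown species {r.species_id!r}")
        if r.sex in SEXES:
            support = np.flatnonzero(entry.colours_additive[r.sex] > 0)
        else:
            support = np.flatnonzero(
                (entry.colours_additive["male"] > 0)
                | (entry.colours_additive["female"] > 0))
        if support.size == 0:
            warnings.warn(
                f"species {r.species_id!r} has empty additive colour "
                f"support; record left colourless", stacklevel=2)
            out.append(r)
            continue
        k = int(rng.integers(1, min(max_colours, support.size) + 1))
        chosen = rng.choice(support, size=k, replace=False)
        out.append(r.with_colours(COLOURS[j] for j in chosen))
    return out
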