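import datetime as dt

import numpy as np
import pytest
from sklearn.base import clone

import odofuzz as oz
from odofuzz.classifier import _rank_key
from odofuzz.knowledge_base import COLOURS, N_COLOURS

RED = COLOURS.index("red")
ORANGE = COLOURS.index("orange")
BLUE = COLOURS.index("blue")
GREEN = COLOURS.index("green")


def brute_force_colour(in_vec, S, A_col, E_col, weight=0.7, offset=0.3):
    """Independent explicit-loop reimplementation of the colour factor."""
    selected = [c for c in range(N_COLOURS) if in_vec[c]]
    if not selected:
        return 1.0
    v = [max(min(in_vec[c], S[c][cp]) for c in selected)
         for cp in range(N_COLOURS)]
    w = max(min(v[cp], A_col[cp]) for cp in range(N_COLOURS))
    additive = weight * w + offset
    exclusion = min(E_col[c] for c in selected)
    return min(additive, exclusion)


def random_colour_instance(rng):
    S = np.eye(N_COLOURS)
    upper = rng.uniform(0, 1, size=(N_COLOURS, N_COLOURS))
    S = np.maximum(np.triu(upper, 1) + np.triu(upper, 1).T, S)
    A = rng.uniform(0, 1, size=N_COLOURS)
    E = rng.uniform(0, 1, size=N_COLOURS)
    in_vec = np.zeros(N_COLOURS)
    chosen = rng.choice(N_COLOURS, size=rng.integers(1, 4), replace=False)
    in_vec[chosen] = 1.0
    return in_vec, S, A, E


class TestColourCoefficient:
    def test_empty_selection_is_neutral(self):
        assert oz.colour_coefficient(np.zeros(7), np.eye(7),
                                     np.ones(7), np.ones(7)) == 1.0

    def test_perfect_match_scores_one(self):
        in_vec = np.zeros(7)
        in_vec[RED] = 1.0
        A = np.zeros(7)
        A[RED] = 1.0
        assert oz.colour_coefficient(in_vec, np.eye(7), A, np.ones(7)) == 1.0

    def test_forbidden_colour_zeroes_the_class(self):
        in_vec = np.zeros(7)
        in_vec[RED] = 1.0
        E = np.ones(7)
        E[RED] = 0.0
        assert oz.colour_coefficient(in_vec, np.eye(7), np.ones(7), E) == 0.0

    def test_no_additive_overlap_bottoms_at_offset(self):
        in_vec = np.zeros(7)
        in_vec[RED] = 1.0
        assert oz.colour_coefficient(in_vec, np.eye(7), np.zeros(7),
                                     np.ones(7)) == pytest.approx(0.3)

    def test_similarity_bleed(self):
        # selecting orange reaches red through S[orange, red] = 0.5
        S = np.eye(7)
        S[ORANGE, RED] = S[RED, ORANGE] = 0.5
        in_vec = np.zeros(7)
        in_vec[ORANGE] = 1.0
        A = np.zeros(7)
        A[RED] = 1.0
        value = oz.colour_coefficient(in_vec, S, A, np.ones(7))
        assert value == pytest.approx(0.7 * 0.5 + 0.3)

    def test_more_than_three_colours_rejected(self):
        in_vec = np.ones(7)
        with pytest.raises(ValueError):
            oz.colour_coefficient(in_vec, np.eye(7), np.ones(7), np.ones(7))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            in_vec, S, A, E = random_colour_instance(rng)
            assert oz.colour_coefficient(in_vec, S, A, E) == \
                brute_force_colour(in_vec, S, A, E)

    def test_additive_branch_monotone_in_selection(self):
        """Adding a colour to the selection never lowers the sup-min term."""
        rng = np.random.default_rng(321)
        for _ in range(200):
            _, S, A, _ = random_colour_instance(rng)
            E = np.ones(N_COLOURS)  # isolate the additive branch
            small = np.zeros(N_COLOURS)
            small[rng.integers(0, N_COLOURS)] = 1.0
            grown = small.copy()
            grown[rng.integers(0, N_COLOURS)] = 1.0
            assert (oz.colour_coefficient(grown, S, A, E)
                    >= oz.colour_coefficient(small, S, A, E) - 1e-15)


class TestScalarCoefficients:
    def test_season(self, demo_kb):
        hawker = demo_kb.species_map["demo_hawker"]  # plateau days 170-240
        assert oz.season_coefficient(hawker, dt.date(2015, 7, 20)) == 1.0
        assert oz.season_coefficient(hawker, dt.date(2015, 1, 10)) == 0.5
        assert oz.season_coefficient(hawker, None) == 1.0

    def test_altitude(self, demo_kb):
        hawker = demo_kb.species_map["demo_hawker"]  # plateau 200-700 m
        assert oz.altitude_coefficient(hawker, 400.0) == 1.0
        assert oz.altitude_coefficient(hawker, 2000.0) == 0.5
        assert oz.altitude_coefficient(hawker, None) == 1.0
        # rising ramp 100-200 m: membership 0.5 at 150 m
        assert oz.altitude_coefficient(hawker, 150.0) == pytest.approx(0.75)

    def test_suborder(self, demo_kb):
        hawker = demo_kb.species_map["demo_hawker"]  # anisoptera
        assert oz.suborder_coefficient(hawker, "anisoptera") == 1.0
        assert oz.suborder_coefficient(hawker, "zygoptera") == 0.0
        assert oz.suborder_coefficient(hawker, None) == 1.0

    def test_position(self, toy_model):
        # demo_hawker has a training record in the cell of (50.05, 14.05)
        assert oz.position_coefficient(toy_model, "demo_hawker",
                                       50.05, 14.05) == 1.0
        # demo_bluet only occurs near (49.05, 15.05)
        assert oz.position_coefficient(toy_model, "demo_bluet",
                                       50.05, 14.05) == 0.5
        assert oz.position_coefficient(toy_model, "demo_bluet",
                                       None, None) == 1.0

    def test_biotope(self, toy_model):
        assert oz.biotope_coefficient(toy_model, "demo_hawker", "pond") == 1.0
        assert oz.biotope_coefficient(toy_model, "demo_hawker", "lake") == \
            pytest.approx(0.8 + 0.2 / 3)
        assert oz.biotope_coefficient(toy_model, "demo_hawker", "river") == \
            pytest.approx(0.8)
        assert oz.biotope_coefficient(toy_model, "demo_hawker", None) == 1.0
        with pytest.raises(ValueError, match="biotope"):
            oz.biotope_coefficient(toy_model, "demo_hawker", "volcano")


class TestRelevance:
    FULL_OBS = dict(date=dt.date(2015, 7, 20), lat=50.05, lon=14.05,
                    altitude=400.0, suborder="anisoptera", biotope="lake",
                    colours=frozenset({"blue"}))

    def test_hand_computed_product(self, toy_model):
        """Step-by-step independent arithmetic for the male demo_hawker.

        commonality 1 (modal species), suborder match 1, colour 1 (blue is
        an additive colour with permissibility 1), position 1 (record in
        cell), altitude 1 (plateau), biotope lake = 0.8 + 0.2 * (1/3),
        season 1 (day 201 on plateau).
        """
        rc = oz.relevance(toy_model, "demo_hawker", "male",
                          oz.ObservationInput(**self.FULL_OBS))
        expected = 1.0 * 1.0 * 1.0 * 1.0 * 1.0 * (0.8 + 0.2 / 3) * 1.0
        assert rc.relevance == pytest.approx(expected)

    def test_hand_computed_exclusion(self, toy_model):
        # the male demo_darter must not be blue: relevance collapses to 0
        rc = oz.relevance(toy_model, "demo_darter", "male",
                          oz.ObservationInput(**self.FULL_OBS))
        assert rc.relevance == 0.0
        assert rc.coefficients["colour"] == 0.0

    def test_hand_computed_similarity_path(self, toy_model):
        """Selecting orange for the male demo_darter (additive red 1,
        orange 0.7; S[orange, red] = 0.5): v = S[orange, :], sup-min with A
        gives max(min(1, 0.7), min(0.5, 1)) = 0.7, additive 0.79."""
        obs = dict(self.FULL_OBS, colours=frozenset({"orange"}),
                   biotope="pond")
        rc = oz.relevance(toy_model, "demo_darter", "male",
                          oz.ObservationInput(**obs))
        # commonality 0.5, colour 0.79, position 1, altitude 1 (plateau
        # 150-500), biotope pond 1, season day 201 plateau -> 1
        assert rc.coefficients["colour"] == pytest.approx(0.79)
        assert rc.relevance == pytest.approx(0.5 * 0.79)

    def test_empty_observation_reduces_to_commonality(self, toy_model):
        for rc in toy_model.classify(oz.ObservationInput()):
            assert rc.relevance == \
                toy_model.commonality_[rc.species_id]

    def test_wrong_suborder_annihilates(self, toy_model):
        rc = oz.relevance(toy_model, "demo_bluet", "male",
                          oz.ObservationInput(**self.FULL_OBS))
        assert rc.relevance == 0.0

    def test_unknown_species_rejected(self, toy_model):
        with pytest.raises(ValueError, match="unknown species"):
            oz.relevance(toy_model, "nessie", "male", oz.ObservationInput())

    def test_breakdown_reproduces_relevance(self, synth_small):
        _, _, records, model = synth_small
        obs = oz.ObservationInput(date=dt.date(2016, 7, 1),
                                  colours=frozenset({"red", "black"}))
        for rc in model.classify(obs):
            assert rc.relevance == pytest.approx(
                oz.relevance_from_breakdown(rc.coefficients), abs=1e-12)


class TestClassify:
    def test_output_is_sorted_permutation(self, synth_small):
        _, kb, _, model = synth_small
        ranked = model.classify(oz.ObservationInput(
            suborder="anisoptera", colours=frozenset({"blue"})))
        assert len(ranked) == 2 * len(kb.species)
        labels = {(rc.species_id, rc.sex) for rc in ranked}
        assert len(labels) == len(ranked)
        values = [rc.relevance for rc in ranked]
        assert values == sorted(values, reverse=True)

    def test_tie_break_is_deterministic_total_order(self, toy_model):
        ranked = toy_model.classify(oz.ObservationInput())
        # darter and bluet tie at commonality 0.5: lexicographic species id,
        # male before female
        tail = [(rc.species_id, rc.sex) for rc in ranked[2:]]
        assert tail == [("demo_bluet", "male"), ("demo_bluet", "female"),
                        ("demo_darter", "male"), ("demo_darter", "female")]

    def test_missing_field_equals_forced_neutral_coefficient(self,
                                                             synth_small):
        """Dropping one observation field gives exactly the ranking obtained
        by forcing the corresponding coefficient to 1 for every class."""
        _, _, _, model = synth_small
        full = oz.ObservationInput(
            date=dt.date(2017, 7, 10), lat=49.6, lon=15.2, altitude=420.0,
            suborder="zygoptera", biotope="pond",
            colours=frozenset({"blue", "black"}))
        field_to_key = {"date": "season", "altitude": "altitude",
                        "suborder": "suborder", "biotope": "biotope",
                        "colours": "colour"}
        baseline = model.classify(full)
        for field_name, key in field_to_key.items():
            reduced = oz.ObservationInput(
                **{f: (None if f == field_name else getattr(full, f))
                   for f in ("date", "lat", "lon", "altitude", "suborder",
                             "biotope", "colours")})
            forced = _force_coefficient(baseline, key)
            observed = [(rc.species_id, rc.sex, rc.relevance)
                        for rc in model.classify(reduced)]
            assert observed == forced
        # coordinates drop as a pair and correspond to the position factor
        no_coords = oz.ObservationInput(
            date=full.date, altitude=full.altitude, suborder=full.suborder,
            biotope=full.biotope, colours=full.colours)
        observed = [(rc.species_id, rc.sex, rc.relevance)
                    for rc in model.classify(no_coords)]
        assert observed == _force_coefficient(baseline, "position")

    def test_predict_returns_top_label(self, toy_model):
        labels = toy_model.predict([oz.ObservationInput()])
        assert labels[0] == "demo_hawker|male"

    def test_sklearn_param_interface(self, demo_kb):
        clf = oz.FuzzyRelevanceClassifier(knowledge_base=demo_kb,
                                          absent_position=0.4)
        assert clf.get_params()["absent_position"] == 0.4
        cloned = clone(clf)
        assert cloned.get_params()["absent_position"] == 0.4
        clf.set_params(absent_position=0.6)
        assert clf.absent_position == 0.6

    def test_invalid_constants_rejected(self, demo_kb, toy_records):
        clf = oz.FuzzyRelevanceClassifier(knowledge_base=demo_kb,
                                          additive_weight=0.9,
                                          additive_offset=0.3)
        with pytest.raises(ValueError, match="additive"):
            clf.fit(toy_records)


def _force_coefficient(ranked, key):
    forced = []
    for rc in ranked:
        coefficients = dict(rc.coefficients)
        coefficients[key] = 1.0
        forced.append(oz.RankedClass(
            rc.species_id, rc.sex,
            oz.relevance_from_breakdown(coefficients), coefficients))
    forced.sort(key=_rank_key)
    return [(rc.species_id, rc.sex, rc.relevance) for rc in forced]


class TestCollapseSexes:
    def test_halves_the_list(self, toy_model):
        ranked = toy_model.classify(oz.ObservationInput())
        collapsed = oz.collapse_sexes(ranked)
        assert len(collapsed) == 3

    def test_takes_max_over_sexes(self, toy_model):
        obs = oz.ObservationInput(colours=frozenset({"blue"}))
        ranked = toy_model.classify(obs)
        by_class = {(rc.species_id, rc.sex): rc.relevance for rc in ranked}
        for sid, value in oz.collapse_sexes(ranked):
            assert value == max(by_class[(sid, "male")],
                                by_class[(sid, "female")])
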