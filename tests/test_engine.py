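import random

import pytest

from clavis import (
    Answer,
    Key,
    Session,
    SessionOptions,
    apply_answer,
    effective_frequency,
    plausibility,
    start_session,
    undo_answer,
)
from clavis.engine import (
    AFFIRM,
    ANSWERED,
    DISABLED,
    HIDDEN_PREMISE_FALSE,
    HIDDEN_PREMISE_UNKNOWN,
    HIDDEN_UNCOVERED,
    HIDDEN_UNINFORMATIVE,
    NUMERIC,
    REJECT,
    SELECTABLE,
    VISIBLE,
    AnswerRefusedError,
    EngineError,
    export_trail,
    import_trail,
)
from clavis.format import Character, Region, State, Statement, Taxon

import oracles
from conftest import consistent_script, make_key, random_script


def affirm(c, s):
    return Answer(character=c, kind=AFFIRM, state=s)


def reject(c, s):
    return Answer(character=c, kind=REJECT, state=s)


def numeric(c, v):
    return Answer(character=c, kind=NUMERIC, value=v)


def tiny_key(statements_spec, characters=None, taxa=("taxon:x", "taxon:y")):
    """A minimal two-taxon key for frequency-semantics scenarios."""
    chars = characters or [
        Character(
            id="character:color",
            title="Color",
            states=[State(id="state:blue", title="Blue"), State(id="state:red", title="Red")],
        )
    ]
    return Key(
        identifier="urn:test:tiny",
        title="tiny",
        schema="s",
        license="l",
        language=["en"],
        created="2022-01-01",
        lastModified="2022-01-01",
        creators=["person:p"],
        persons=[{"id": "person:p", "name": "P"}],
        taxa=[Taxon(id=t, scientificName=t.split(":")[1]) for t in taxa],
        characters=chars,
        statements=[
            Statement(id=f"statement:{i}", taxon=t, character=c, value=v, frequency=f,
                      geography=g)
            for i, (t, c, v, f, g) in enumerate(
                (spec + (None,))[:5] for spec in statements_spec
            )
        ],
    )


class TestCanonicalTrace:
    def test_four_taxon_trace(self, fig2):
        """Four candidates; only color visible; the color answer excludes
        two; size surfaces; the size answer resolves the session."""
        s = start_session(fig2)
        assert len(s.surviving_leaves) == 4
        assert s.visible_characters() == ["character:color"]
        assert s.character_status("character:size") == HIDDEN_UNCOVERED
        s = apply_answer(s, affirm("character:color", "state:blue"))
        assert s.surviving_leaves == ["taxon:t1", "taxon:t2"]
        assert s.character_status("character:size") == VISIBLE
        assert s.character_status("character:color") == ANSWERED
        s = apply_answer(s, affirm("character:size", "state:small"))
        assert s.surviving_leaves == ["taxon:t1"]
        assert s.resolved and s.result == "taxon:t1"

    def test_a_priori_subset(self, fig2):
        s = start_session(fig2, SessionOptions(subset=("taxon:t1", "taxon:t2")))
        assert s.surviving_leaves == ["taxon:t1", "taxon:t2"]
        assert s.character_status("character:size") == VISIBLE

    def test_unknown_subset_ids_listed(self, fig2):
        with pytest.raises(EngineError, match="taxon:nope"):
            start_session(fig2, SessionOptions(subset=("taxon:t1", "taxon:nope")))

    def test_all_characters_premise_gated_means_nothing_visible(self, fig2):
        fig2.characters[0].logicalPremise = "state:small"
        fig2.characters[1].logicalPremise = "state:blue"
        s = start_session(fig2)
        assert s.visible_characters() == []
        assert s.character_status("character:color") == HIDDEN_PREMISE_UNKNOWN

    def test_answering_hidden_character_is_refused_with_reason(self, fig2):
        s = start_session(fig2)
        with pytest.raises(AnswerRefusedError) as exc:
            apply_answer(s, affirm("character:size", "state:small"))
        assert exc.value.reason == HIDDEN_UNCOVERED


class TestEffectiveFrequency:
    def test_family_statement_inherited_by_species(self, clavidae):
        s = start_session(clavidae)
        eff = effective_frequency(s, "taxon:clavis_shiny", "character:body", "state:elongated")
        assert eff.value == 1.0
        assert eff.level == "taxon:clavidae"

    def test_exclusive_statement_implies_zero_for_siblings(self, fig2):
        s = start_session(fig2)
        eff = effective_frequency(s, "taxon:t1", "character:color", "state:red")
        assert eff.value == 0.0 and eff.implied

    def test_unscored_cell_is_undefined(self, fig2):
        eff = effective_frequency(start_session(fig2), "taxon:t4", "character:size", "state:small")
        assert not eff.defined

    def test_child_statement_shadows_inherited_one(self, clavidae):
        clavidae.statements.append(
            Statement(
                id="statement:override",
                taxon="taxon:clavis",
                character="character:body",
                value="state:elongated",
                frequency=0.5,
            )
        )
        s = start_session(clavidae)
        assert effective_frequency(
            s, "taxon:clavis_shiny", "character:body", "state:elongated"
        ).value == 0.5
        assert effective_frequency(
            s, "taxon:clavella_shiny", "character:body", "state:elongated"
        ).value == 1.0

    def test_geography_scoped_statement_takes_precedence_inside_region(self):
        square = Region(polygon=[[[[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]]])
        key = tiny_key(
            [
                ("taxon:x", "character:color", "state:blue", 0.5),
                ("taxon:x", "character:color", "state:blue", 0.9, square),
                ("taxon:y", "character:color", "state:red", 1.0),
            ]
        )
        from clavis.geography import Location

        inside = start_session(key, SessionOptions(location=Location(5, 5)))
        outside = start_session(key, SessionOptions(location=Location(20, 20)))
        nowhere = start_session(key)
        args = ("taxon:x", "character:color", "state:blue")
        assert effective_frequency(inside, *args).value == 0.9
        assert effective_frequency(inside, *args).scoped
        assert effective_frequency(outside, *args).value == 0.5
        assert effective_frequency(nowhere, *args).value == 0.5


class TestFrequencySemantics:
    def test_zero_excludes_on_affirm_one_excludes_on_reject(self):
        key = tiny_key(
            [
                ("taxon:x", "character:color", "state:blue", 0.0),
                ("taxon:y", "character:color", "state:blue", 1.0),
            ]
        )
        s = apply_answer(start_session(key), affirm("character:color", "state:blue"))
        assert s.surviving_leaves == ["taxon:y"]
        s = apply_answer(start_session(key), reject("character:color", "state:blue"))
        assert s.surviving_leaves == ["taxon:x"]

    def test_intermediate_frequency_never_excludes(self):
        key = tiny_key(
            [
                ("taxon:x", "character:color", "state:blue", 0.5),
                ("taxon:y", "character:color", "state:blue", 1.0),
            ]
        )
        assert apply_answer(
            start_session(key), affirm("character:color", "state:blue")
        ).surviving_leaves == ["taxon:x", "taxon:y"]
        assert apply_answer(
            start_session(key), reject("character:color", "state:blue")
        ).surviving_leaves == ["taxon:x"]

    def test_rejecting_the_only_possible_state_excludes(self):
        # every other state explicitly impossible => the taxon must have blue
        key = tiny_key(
            [
                ("taxon:x", "character:color", "state:blue", 0.5),
                ("taxon:x", "character:color", "state:red", 0.0),
                ("taxon:y", "character:color", "state:red", 1.0),
            ]
        )
        s = apply_answer(start_session(key), reject("character:color", "state:blue"))
        assert s.surviving_leaves == ["taxon:y"]

    def test_nonexclusive_affirm_keeps_multicolored_taxa(self, clavidae):
        s = apply_answer(start_session(clavidae), affirm("character:color", "state:col_green"))
        assert len(s.surviving_leaves) == 7  # nothing has green at frequency 0
        s2 = apply_answer(start_session(clavidae), affirm("character:color", "state:col_red"))
        # only Clavissima is stated never-red
        assert set(s2.surviving_leaves) == {
            "taxon:clavis_default", "taxon:clavis_shiny",
            "taxon:clavella_default", "taxon:clavella_shiny",
        }


NUMERIC_CHAR = Character(
    id="character:weight", title="Weight", type="numerical",
    min=0.0, max=100.0, stepSize=1.0, unit="kg",
)


class TestNumeric:
    def key(self):
        return tiny_key(
            [
                ("taxon:x", "character:weight", [6.0, 8.0], 1.0),
                ("taxon:y", "character:weight", [20.0, 30.0], 1.0),
            ],
            characters=[NUMERIC_CHAR],
        )

    def test_value_inside_stated_range_survives(self):
        s = apply_answer(start_session(self.key()), numeric("character:weight", 7.0))
        assert s.surviving_leaves == ["taxon:x"]

    def test_value_outside_all_ranges_excludes(self):
        s = apply_answer(start_session(self.key()), numeric("character:weight", 9.0))
        assert s.surviving_leaves == []

    def test_zero_frequency_range_excludes(self):
        key = tiny_key(
            [
                ("taxon:x", "character:weight", [0.0, 50.0], 1.0),
                ("taxon:x", "character:weight", [6.0, 8.0], 0.0),
                ("taxon:y", "character:weight", [0.0, 100.0], 1.0),
            ],
            characters=[NUMERIC_CHAR],
        )
        s = apply_answer(start_session(key), numeric("character:weight", 7.0))
        assert s.surviving_leaves == ["taxon:y"]

    def test_unscored_taxon_survives_numeric_answer(self):
        key = tiny_key(
            [("taxon:x", "character:weight", [6.0, 8.0], 1.0)],
            characters=[NUMERIC_CHAR],
        )
        s = start_session(key)
        assert s.character_status("character:weight") == HIDDEN_UNCOVERED
        s = start_session(key, SessionOptions(subset=("taxon:x",)))
        assert s.resolved  # single-endpoint subset resolves immediately

    @pytest.mark.parametrize("bad", [7.5, -1.0, 101.0])
    def test_off_grid_or_out_of_bounds_refused(self, bad):
        with pytest.raises(AnswerRefusedError):
            apply_answer(start_session(self.key()), numeric("character:weight", bad))


class TestStatuses:
    def test_disabled_state_remains_listed_but_unselectable(self, fig2):
        s = apply_answer(start_session(fig2), affirm("character:color", "state:blue"))
        # among survivors t1/t2 nobody can be red (implied zeros)
        assert s.state_status("state:red") == DISABLED
        with pytest.raises(AnswerRefusedError):
            apply_answer(s, affirm("character:color", "state:red"))

    def test_single_possible_answer_hides_character(self):
        key = tiny_key(
            [
                ("taxon:x", "character:color", "state:blue", 1.0),
                ("taxon:y", "character:color", "state:blue", 1.0),
                ("taxon:x", "character:size", "state:small", 1.0),
                ("taxon:y", "character:size", "state:large", 1.0),
            ],
            characters=[
                Character(id="character:color", title="Color",
                          states=[State(id="state:blue", title="B"),
                                  State(id="state:red", title="R")]),
                Character(id="character:size", title="Size",
                          states=[State(id="state:small", title="S"),
                                  State(id="state:large", title="L")]),
            ],
        )
        s = start_session(key)
        # everyone is blue; red is implied-impossible for all: only one answer
        assert s.character_status("character:color") == HIDDEN_UNINFORMATIVE
        assert s.visible_characters() == ["character:size"]

    def test_premise_unknown_vs_false_distinction(self, clavidae):
        clavidae.characters[3].logicalPremise = "state:shiny"  # colors need shininess
        s = start_session(clavidae)
        assert s.character_status("character:color") == HIDDEN_PREMISE_UNKNOWN
        s2 = apply_answer(s, affirm("character:sheen", "state:dull"))
        assert s2.character_status("character:color") == HIDDEN_PREMISE_FALSE
        s3 = apply_answer(s, affirm("character:sheen", "state:shiny"))
        assert s3.character_status("character:color") == VISIBLE

    def test_endpoint_stops_the_session(self, clavidae):
        """Once the endpoint morph is determined, the sex question beneath
        it is never asked."""
        s = start_session(clavidae)
        s = apply_answer(s, affirm("character:antennae", "state:clubbed"))
        s = apply_answer(s, affirm("character:sheen", "state:dull"))
        assert s.resolved and s.result == "taxon:clavissima_default"
        assert len(s.surviving_leaves) == 2  # both sexes still listed beneath
        assert s.visible_characters() == []
        assert s.character_status("character:ornament") != VISIBLE


class TestUndo:
    def test_fig2_undo_invalidates_dependent_answer(self, fig2):
        s = start_session(fig2)
        s = apply_answer(s, affirm("character:color", "state:blue"))
        s = apply_answer(s, affirm("character:size", "state:small"))
        u = undo_answer(s, 0)
        assert len(u.surviving_leaves) == 4
        assert [a.invalidated for a in u.answers] == [True]
        assert u.character_status("character:size") == HIDDEN_UNCOVERED

    def test_undo_only_answer_restores_start(self, fig2):
        start = start_session(fig2)
        s = apply_answer(start, affirm("character:color", "state:blue"))
        u = undo_answer(s, 0)
        assert u.surviving_leaves == start.surviving_leaves
        assert u.visible_characters() == start.visible_characters()

    @pytest.mark.parametrize("seed", range(20))
    def test_apply_then_undo_equals_never_applied(self, seed):
        rng = random.Random(seed)
        key = make_key(seed, polymorphism_rate=0.2, sparsity=0.3, hierarchy_depth=2)
        session, answers = random_script(key, rng, max_answers=3)
        if not answers:
            pytest.skip("no applicable answers for this seed")
        undone = undo_answer(session, session.answers[-1].ordinal)
        baseline = Session(key=key, answers=list(session.answers[:-1]))
        assert undone.surviving_leaves == baseline.surviving_leaves
        assert undone.visible_characters() == baseline.visible_characters()

    def test_replay_determinism(self, fig2):
        s = start_session(fig2)
        s = apply_answer(s, affirm("character:color", "state:blue"))
        s = apply_answer(s, affirm("character:size", "state:small"))
        replayed = Session(key=fig2, answers=import_trail(export_trail(s)))
        assert replayed.surviving_leaves == s.surviving_leaves
        assert replayed.resolved and replayed.result == s.result


class TestPlausibility:
    def test_certain_answers_score_one(self, fig2):
        s = start_session(fig2)
        s = apply_answer(s, affirm("character:color", "state:blue"))
        assert plausibility(s, "taxon:t1") == 1.0

    def test_half_frequency_state_scores_half(self):
        key = tiny_key(
            [
                ("taxon:x", "character:color", "state:blue", 0.5),
                ("taxon:y", "character:color", "state:red", 1.0),
            ]
        )
        s = apply_answer(start_session(key), affirm("character:color", "state:blue"))
        assert s.surviving_leaves == ["taxon:x"]
        assert plausibility(s, "taxon:x") == 0.5

    def test_scores_match_brute_force_product(self):
        rng = random.Random(11)
        for seed in range(15):
            key = make_key(seed, polymorphism_rate=0.4, sparsity=0.2)
            session, answers = random_script(key, rng, max_answers=4, affirm_only=True)
            res = session._resolver
            for leaf in session.surviving_leaves:
                expected = 1.0
                for a in answers:
                    eff = res.effective(leaf, a.character, a.state)
                    expected *= eff.value if eff.defined else 1.0
                assert plausibility(session, leaf) == pytest.approx(expected)

    def test_non_surviving_endpoint_rejected(self, fig2):
        s = apply_answer(start_session(fig2), affirm("character:color", "state:blue"))
        with pytest.raises(EngineError):
            plausibility(s, "taxon:t3")


class TestProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_monotone_elimination_and_replay_purity(self, seed):
        rng = random.Random(seed)
        key = make_key(seed, polymorphism_rate=0.2, sparsity=0.3, hierarchy_depth=1 + seed % 2)
        session, answers = random_script(key, rng)
        sizes = [len(Session(key=key, answers=list(answers[:i])).surviving_leaves)
                 for i in range(len(answers) + 1)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == len(session.surviving_leaves)

    @pytest.mark.parametrize("seed", range(20))
    def test_engine_matches_from_scratch_conflict_evaluation(self, seed):
        """Incremental elimination equals an independent per-leaf check of
        the final answer list against the statement table."""
        rng = random.Random(100 + seed)
        key = make_key(seed, polymorphism_rate=0.2, sparsity=0.3, hierarchy_depth=1 + seed % 3)
        session, answers = random_script(key, rng)
        assert session.surviving_leaves == oracles.surviving_leaves(key, answers)

    @pytest.mark.parametrize("seed", range(15))
    def test_order_independence_without_premises(self, seed):
        """On premise-free fully scored keys, permuting a consistent set of
        affirmative answers never changes the surviving set."""
        rng = random.Random(200 + seed)
        key = make_key(seed, sparsity=0.0, premise_rate=0.0, polymorphism_rate=0.2)
        _, session, answers = consistent_script(key, rng, max_answers=4)
        expected = session.surviving_leaves
        for _ in range(5):
            perm = answers[:]
            rng.shuffle(perm)
            assert Session(key=key, answers=perm).surviving_leaves == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_exclusivity_soundness(self, seed):
        """With decisive (0/1) frequencies, affirming a state of an
        exclusive character equals rejecting every other state."""
        key = make_key(seed, polymorphism_rate=0.0, sparsity=0.0,
                       states_per_character=3, n_numeric=0)
        rng = random.Random(seed)
        char = next(c for c in key.characters if c.type == "exclusive" and len(c.states) == 3)
        # decide every frequency: one state at 1 makes its siblings implied 0
        for s in key.statements:
            if s.character == char.id:
                s.frequency = 1.0
        # the affirmed state must be selectable, i.e. shown by some taxon
        stated = sorted({s.value for s in key.statements if s.character == char.id})
        target = rng.choice(stated)
        via_affirm = Session(key=key, answers=[affirm(char.id, target)])
        via_reject = Session(
            key=key,
            answers=[reject(char.id, st.id) for st in char.states if st.id != target],
        )
        assert set(via_affirm.surviving_leaves) == set(via_reject.surviving_leaves)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_character_visible_once_resolved(self, seed):
        rng = random.Random(300 + seed)
        key = make_key(seed, sparsity=0.1)
        session, _ = random_script(key, rng, max_answers=8)
        if session.resolved:
            assert session.visible_characters() == []
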