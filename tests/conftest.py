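import random

import pytest

from clavis import (
    Answer,
    GeneratorParams,
    Session,
    fixture_clavidae,
    fixture_fig2,
    generate_key,
)
from clavis.engine import AFFIRM, NUMERIC, REJECT, SELECTABLE, apply_answer, start_session


@pytest.fixture
def fig2():
    return fixture_fig2()


@pytest.fixture
def clavidae():
    return fixture_clavidae()


def make_key(seed, **overrides):
    params = GeneratorParams(**{"seed": seed, **overrides})
    return generate_key(params)


def random_script(key, rng, max_answers=6, affirm_only=False, one_per_character=False):
    """Drive a session with random valid answers; return (session, answers)."""
    session = start_session(key)
    used = set()
    answers = []
    for _ in range(max_answers):
        if session.resolved:
            break
        visible = [c for c in session.visible_characters() if c not in used]
        if not visible:
            break
        cid = rng.choice(visible)
        char = session.key.character_map()[cid]
        if char.is_numerical:
            steps = int(round((char.max - char.min) / char.stepSize))
            value = char.min + rng.randint(0, steps) * char.stepSize
            ans = Answer(character=cid, kind=NUMERIC, value=value)
        else:
            selectable = [s.id for s in char.states if session.state_status(s.id) == SELECTABLE]
            if not selectable:
                continue
            state = rng.choice(selectable)
            kind = AFFIRM if (affirm_only or rng.random() < 0.7) else REJECT
            ans = Answer(character=cid, kind=kind, state=state)
        session = apply_answer(session, ans)
        answers.append(ans)
        if one_per_character:
            used.add(cid)
    return session, answers


def consistent_script(key, rng, max_answers=4):
    """Answers that truthfully describe one randomly chosen leaf.

    Affirm-only, one answer per character, never contradicting the target
    leaf — the target always survives, like a real specimen being keyed out.
    """
    target = rng.choice(key.leaves())
    session = start_session(key)
    res = session._resolver
    used = set()
    answers = []
    while len(answers) < max_answers and not session.resolved:
        visible = [c for c in session.visible_characters() if c not in used]
        if not visible:
            break
        cid = rng.choice(visible)
        used.add(cid)
        char = session.key.character_map()[cid]
        if char.is_numerical:
            ranges = [s for s in res.numeric_statements(target, cid) if s.frequency > 0]
            if ranges:
                low, high = rng.choice(ranges).value
                steps = int(round((low - char.min) / char.stepSize))
                value = min(high, char.min + steps * char.stepSize)
            else:
                value = char.min
            ans = Answer(character=cid, kind=NUMERIC, value=value)
        else:
            ok = [
                s.id
                for s in char.states
                if session.state_status(s.id) == SELECTABLE
                and res.effective(target, cid, s.id).value != 0.0
            ]
            if not ok:
                continue
            ans = Answer(character=cid, kind=AFFIRM, state=rng.choice(ok))
        session = apply_answer(session, ans)
        answers.append(ans)
        assert target in session.surviving_leaves
    return target, session, answers
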