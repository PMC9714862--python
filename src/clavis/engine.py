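"""Identification sessions: elimination, visibility, undo, plausibility.

An identification session walks a key towards a single endpoint taxon.
Each user answer (affirming or rejecting a state, or entering a number)
excludes every candidate leaf whose statements conflict with it; characters
surface only once every remaining candidate is covered by a statement for
them, premise-gated characters only once their premise is established, and
the session stops asking as soon as exactly one endpoint remains.

Statements attached to higher taxa are inherited by every descendant
(nearest statement wins), a geography-scoped statement beats an unscoped
one when the session location lies inside its region, and in an exclusive
character a state with frequency 1 implies frequency 0 for its siblings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

from .format import (
    EXCLUSIVE,
    NUMERICAL,
    Character,
    ClavisError,
    Key,
    Statement,
    validate_structure,
)
from .geography import Location, point_in_region, UnresolvableRegionError
from .premise import (
    AFFIRMED,
    FactContext,
    IMPOSSIBLE,
    REJECTED,
    TriState,
    evaluate_premise,
    parse_premise,
)

__all__ = [
    "Answer",
    "AFFIRM",
    "REJECT",
    "NUMERIC",
    "SessionOptions",
    "Session",
    "EffectiveFrequency",
    "EngineError",
    "AnswerRefusedError",
    "start_session",
    "apply_answer",
    "undo_answer",
    "effective_frequency",
    "character_status",
    "state_status",
    "plausibility",
    "export_trail",
    "import_trail",
    # status constants
    "VISIBLE",
    "ANSWERED",
    "HIDDEN_UNCOVERED",
    "HIDDEN_PREMISE_UNKNOWN",
    "HIDDEN_PREMISE_FALSE",
    "HIDDEN_UNINFORMATIVE",
    "SELECTABLE",
    "DISABLED",
    "SELECTED",
    "REJECTED_STATE",
]

AFFIRM = "affirm"
REJECT = "reject"
NUMERIC = "numeric"

VISIBLE = "visible"
ANSWERED = "answered"
HIDDEN_UNCOVERED = "hidden_uncovered"
HIDDEN_PREMISE_UNKNOWN = "hidden_premise_unknown"
HIDDEN_PREMISE_FALSE = "hidden_premise_false"
HIDDEN_UNINFORMATIVE = "hidden_uninformative"

SELECTABLE = "selectable"
DISABLED = "disabled"
SELECTED = "selected"
REJECTED_STATE = "rejected"

_GRID_TOL = 1e-9


class EngineError(ClavisError):
    pass


class AnswerRefusedError(EngineError):
    """The answer targets a hidden character, a non-selectable state or an
    off-grid numeric value; ``reason`` carries the character's status."""

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class Answer:
    """One user input: affirm/reject a state or give a numeric value."""

    character: str
    kind: str  # AFFIRM | REJECT | NUMERIC
    state: Optional[str] = None
    value: Optional[float] = None
    ordinal: int = 0
    invalidated: bool = False


@dataclass(frozen=True)
class SessionOptions:
    language: Optional[str] = None
    location: Optional[Location] = None
    subset: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class EffectiveFrequency:
    """A resolved frequency with its provenance.

    ``value`` is None when UNDEFINED (the taxon is simply not scored).
    ``level`` names the taxon the statement was found on (the leaf itself or
    an ancestor); ``implied`` marks exclusivity-implied zeros, which carry
    the sibling statement that forced them.
    """

    value: Optional[float]
    statement_id: Optional[str] = None
    level: Optional[str] = None
    scoped: bool = False
    implied: bool = False

    @property
    def defined(self) -> bool:
        return self.value is not None


UNDEFINED = EffectiveFrequency(value=None)


# ---------------------------------------------------------------------------
# Statement resolution
# ---------------------------------------------------------------------------


class _Resolver:
    """Per-(key, options) indexes and effective-statement resolution."""

    def __init__(self, key: Key, options: SessionOptions):
        self.key = key
        self.options = options
        self.chars = key.character_map()
        self.state_owner = key.state_owner()
        self.parents = key.parent_map()
        self._chains: dict[str, list[str]] = {}
        self.by_taxon_char: dict[tuple[str, str], list[Statement]] = {}
        for s in key.statements:
            self.by_taxon_char.setdefault((s.taxon, s.character), []).append(s)
        self._eff_cache: dict[tuple[str, str, str, bool], EffectiveFrequency] = {}

    def chain(self, taxon_id: str) -> list[str]:
        if taxon_id not in self._chains:
            out = [taxon_id]
            cur = self.parents.get(taxon_id)
            while cur is not None:
                out.append(cur)
                cur = self.parents.get(cur)
            self._chains[taxon_id] = out
        return self._chains[taxon_id]

    def _applicable(self, s: Statement) -> bool:
        """Whether a statement applies under the session's location.

        Unscoped statements always apply.  Scoped statements apply only when
        a location is set and falls inside the region; a name-only region
        cannot be evaluated and is treated as not applicable.
        """
        if s.geography is None:
            return True
        if self.options.location is None:
            return False
        try:
            return point_in_region(s.geography, self.options.location)
        except UnresolvableRegionError:
            return False

    def _pick(self, stmts: list[Statement]) -> Optional[Statement]:
        """Among same-level applicable statements, scoped beats unscoped;
        ties break by document order."""
        scoped = [s for s in stmts if s.geography is not None]
        if scoped:
            return scoped[0]
        return stmts[0] if stmts else None

    def effective(self, leaf: str, character: str, state: str, allow_implied: bool = True
                  ) -> EffectiveFrequency:
        """Effective frequency of (leaf, character, state).

        Walks from the leaf up its ancestor chain; the nearest taxon with any
        applicable statement for this (character, state) decides, preferring
        a geography-scoped statement containing the session location.  With
        nothing stated anywhere and the character exclusive, a sibling state
        held with frequency 1 implies frequency 0 here.
        """
        cache_key = (leaf, character, state, allow_implied)
        if cache_key in self._eff_cache:
            return self._eff_cache[cache_key]
        result = UNDEFINED
        for level in self.chain(leaf):
            stmts = [
                s
                for s in self.by_taxon_char.get((level, character), [])
                if not s.is_numeric and s.value == state and self._applicable(s)
            ]
            chosen = self._pick(stmts)
            if chosen is not None:
                result = EffectiveFrequency(
                    value=chosen.frequency,
                    statement_id=chosen.id,
                    level=level,
                    scoped=chosen.geography is not None,
                )
                break
        else:
            char = self.chars.get(character)
            if allow_implied and char is not None and char.type == EXCLUSIVE:
                for sib in char.states:
                    if sib.id == state:
                        continue
                    eff = self.effective(leaf, character, sib.id, allow_implied=False)
                    if eff.defined and eff.value == 1.0:
                        result = EffectiveFrequency(
                            value=0.0,
                            statement_id=eff.statement_id,
                            level=eff.level,
                            scoped=eff.scoped,
                            implied=True,
                        )
                        break
        self._eff_cache[cache_key] = result
        return result

    def numeric_statements(self, leaf: str, character: str) -> list[Statement]:
        """Applicable numeric statements at the nearest stated taxon level."""
        for level in self.chain(leaf):
            stmts = [
                s
                for s in self.by_taxon_char.get((level, character), [])
                if s.is_numeric and self._applicable(s)
            ]
            if stmts:
                scoped = [s for s in stmts if s.geography is not None]
                return scoped if scoped else stmts
        return []

    def covered(self, leaf: str, character: str) -> bool:
        """Whether the leaf (or an ancestor) has any applicable statement
        for the character."""
        return any(
            any(self._applicable(s) for s in self.by_taxon_char.get((level, character), []))
            for level in self.chain(leaf)
        )


# ---------------------------------------------------------------------------
# Derived session state
# ---------------------------------------------------------------------------


@dataclass
class _Derived:
    surviving_leaves: list[str]
    surviving_endpoints: list[str]
    character_status: dict[str, str]
    state_status: dict[str, str]
    resolved: bool
    result: Optional[str]


def _endpoints(key: Key) -> dict[str, list[str]]:
    """Map endpoint taxon id → the leaf ids it aggregates.

    Default endpoints are the leaves; a node tagged ``isEndpoint`` absorbs
    everything beneath it.
    """
    out: dict[str, list[str]] = {}

    def leaves_under(t) -> list[str]:
        if not t.children:
            return [t.id]
        acc: list[str] = []
        for c in t.children:
            acc.extend(leaves_under(c))
        return acc

    def walk(t) -> None:
        if t.isEndpoint:
            out[t.id] = leaves_under(t)
            return
        if not t.children:
            out[t.id] = [t.id]
            return
        for c in t.children:
            walk(c)

    for root in key.taxa:
        walk(root)
    return out


@dataclass
class Session:
    """An identification session over a key.

    Derived state (surviving candidates, statuses, resolution) is a pure
    function of (key, options, ordered valid answers); it is recomputed by
    full replay whenever the answer list changes, which also re-flags
    answers whose character is no longer visible at their replay point as
    ``invalidated``.
    """

    key: Key
    options: SessionOptions = field(default_factory=SessionOptions)
    answers: list[Answer] = field(default_factory=list)
    _derived: Optional[_Derived] = field(default=None, repr=False, compare=False)
    _resolver: Optional[_Resolver] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self._resolver is None:
            self._resolver = _Resolver(self.key, self.options)
        if self._derived is None:
            self._replay()

    # -- views -------------------------------------------------------------

    @property
    def surviving_leaves(self) -> list[str]:
        return list(self._derived.surviving_leaves)

    @property
    def surviving_endpoints(self) -> list[str]:
        return list(self._derived.surviving_endpoints)

    @property
    def resolved(self) -> bool:
        return self._derived.resolved

    @property
    def result(self) -> Optional[str]:
        return self._derived.result

    def character_status(self, character_id: str) -> str:
        return self._derived.character_status[character_id]

    def state_status(self, state_id: str) -> str:
        return self._derived.state_status[state_id]

    def visible_characters(self) -> list[str]:
        return [
            c.id for c in self.key.characters if self._derived.character_status[c.id] == VISIBLE
        ]

    @property
    def valid_answers(self) -> list[Answer]:
        return [a for a in self.answers if not a.invalidated]

    # -- replay core -------------------------------------------------------

    def _initial_leaves(self) -> list[str]:
        tmap = self.key.taxon_map()
        if self.options.subset is None:
            return self.key.leaves()
        missing = [t for t in self.options.subset if t not in tmap]
        if missing:
            raise EngineError(f"subset taxa not in key: {', '.join(missing)}")
        wanted: set[str] = set()

        def leaves_under(t) -> list[str]:
            if not t.children:
                return [t.id]
            acc = []
            for c in t.children:
                acc.extend(leaves_under(c))
            return acc

        for tid in self.options.subset:
            wanted.update(leaves_under(tmap[tid]))
        return [l for l in self.key.leaves() if l in wanted]

    def _facts(self, surviving: list[str], applied: list[Answer]) -> FactContext:
        res = self._resolver
        states: dict[str, str] = {}
        numbers: dict[str, Optional[float]] = {
            c.id: None for c in self.key.characters if c.is_numerical
        }
        for a in applied:
            if a.kind == AFFIRM:
                states[a.state] = AFFIRMED
                owner = res.chars.get(a.character)
                if owner is not None and owner.type == EXCLUSIVE:
                    for sib in owner.states:
                        if sib.id != a.state:
                            states.setdefault(sib.id, IMPOSSIBLE)
            elif a.kind == REJECT:
                states[a.state] = REJECTED
            else:
                numbers[a.character] = a.value
        # states every surviving leaf is known not to have
        for c in self.key.characters:
            if c.is_numerical:
                continue
            for st in c.states:
                if st.id in states:
                    continue
                if surviving and all(
                    (eff := res.effective(leaf, c.id, st.id)).defined and eff.value == 0.0
                    for leaf in surviving
                ):
                    states[st.id] = IMPOSSIBLE
        return FactContext(states=states, numbers=numbers)

    def _statuses(
        self, surviving: list[str], applied: list[Answer]
    ) -> tuple[dict[str, str], dict[str, str], bool]:
        """Compute (character statuses, state statuses, resolved)."""
        res = self._resolver
        endpoints = _endpoints(self.key)
        surv_set = set(surviving)
        surviving_eps = [e for e, ls in endpoints.items() if surv_set.intersection(ls)]
        resolved = len(surviving_eps) == 1

        facts = self._facts(surviving, applied)
        affirmed = {a.state for a in applied if a.kind == AFFIRM}
        rejected = {a.state for a in applied if a.kind == REJECT}
        # an affirm on an exclusive character or a numeric answer settles the
        # question; rejects keep it open (the user may keep excluding states
        # from the list), as does an affirm on a non-exclusive character
        answered_chars = set()
        for a in applied:
            char = res.chars.get(a.character)
            if char is None:
                continue
            if char.is_numerical or (a.kind == AFFIRM and char.type == EXCLUSIVE):
                answered_chars.add(a.character)

        state_status: dict[str, str] = {}
        for c in self.key.characters:
            for st in c.states:
                if st.id in affirmed:
                    state_status[st.id] = SELECTED
                elif st.id in rejected:
                    state_status[st.id] = REJECTED_STATE
                elif surviving and all(
                    (eff := res.effective(leaf, c.id, st.id)).defined and eff.value == 0.0
                    for leaf in surviving
                ):
                    state_status[st.id] = DISABLED
                else:
                    state_status[st.id] = SELECTABLE

        char_status: dict[str, str] = {}
        for c in self.key.characters:
            cid = c.id
            if cid in answered_chars:
                char_status[cid] = ANSWERED
                continue
            if not c.is_numerical:
                undecided = [
                    st.id for st in c.states if state_status[st.id] == SELECTABLE
                ]
                all_decided = not undecided
            else:
                undecided, all_decided = [], False
            if not c.is_numerical and all_decided and cid in {a.character for a in applied}:
                # non-exclusive character with every state decided by answers
                char_status[cid] = ANSWERED
                continue
            if resolved:
                char_status[cid] = HIDDEN_UNINFORMATIVE
                continue
            if c.logicalPremise:
                try:
                    verdict = evaluate_premise(parse_premise(c.logicalPremise, self.key), facts)
                except ClavisError:
                    verdict = TriState.FALSE
                if verdict is TriState.FALSE:
                    char_status[cid] = HIDDEN_PREMISE_FALSE
                    continue
                if verdict is TriState.UNKNOWN:
                    char_status[cid] = HIDDEN_PREMISE_UNKNOWN
                    continue
            if not surviving or not all(res.covered(leaf, cid) for leaf in surviving):
                char_status[cid] = HIDDEN_UNCOVERED
                continue
            if not c.is_numerical and len(undecided) <= 1:
                char_status[cid] = HIDDEN_UNINFORMATIVE
                continue
            char_status[cid] = VISIBLE
        return char_status, state_status, resolved

    def _leaf_survives(self, leaf: str, answer: Answer) -> bool:
        res = self._resolver
        char = res.chars[answer.character]
        if answer.kind == AFFIRM:
            eff = res.effective(leaf, answer.character, answer.state)
            return not (eff.defined and eff.value == 0.0)
        if answer.kind == REJECT:
            eff = res.effective(leaf, answer.character, answer.state)
            if eff.defined and eff.value == 1.0:
                return False
            if char.type == EXCLUSIVE:
                others = [
                    res.effective(leaf, answer.character, st.id)
                    for st in char.states
                    if st.id != answer.state
                ]
                if others and all(o.defined and o.value == 0.0 for o in others):
                    return False
            return True
        # numeric
        stmts = res.numeric_statements(leaf, answer.character)
        if not stmts:
            return True
        v = answer.value
        in_positive = any(
            s.value[0] - _GRID_TOL <= v <= s.value[1] + _GRID_TOL and s.frequency > 0.0
            for s in stmts
        )
        in_zero = any(
            s.value[0] - _GRID_TOL <= v <= s.value[1] + _GRID_TOL and s.frequency == 0.0
            for s in stmts
        )
        return in_positive and not in_zero

    def _check_answer(
        self,
        answer: Answer,
        char_status: dict[str, str],
        state_status: dict[str, str],
    ) -> Optional[str]:
        """Return a refusal reason, or None when the answer is applicable."""
        res = self._resolver
        char = res.chars.get(answer.character)
        if char is None:
            return "unknown character"
        status = char_status[answer.character]
        if status != VISIBLE:
            return status
        if answer.kind == NUMERIC:
            if not char.is_numerical:
                return "numeric answer on a categorical character"
            v = answer.value
            if v is None or not (char.min - _GRID_TOL <= v <= char.max + _GRID_TOL):
                return "value outside character bounds"
            steps = round((v - char.min) / char.stepSize)
            if abs(char.min + steps * char.stepSize - v) > _GRID_TOL:
                return "value not on the step grid"
            return None
        if char.is_numerical:
            return "categorical answer on a numerical character"
        if res.state_owner.get(answer.state) != char.id:
            return "state does not belong to the character"
        if answer.kind == AFFIRM and state_status[answer.state] != SELECTABLE:
            return f"state is {state_status[answer.state]}"
        if answer.kind == REJECT and state_status[answer.state] in (SELECTED, REJECTED_STATE):
            return f"state is already {state_status[answer.state]}"
        return None

    def _replay(self) -> None:
        surviving = self._initial_leaves()
        applied: list[Answer] = []
        new_answers: list[Answer] = []
        char_status, state_status, resolved = self._statuses(surviving, applied)
        for ans in self.answers:
            reason = self._check_answer(ans, char_status, state_status)
            if reason is not None:
                new_answers.append(replace(ans, invalidated=True))
                continue
            surviving = [l for l in surviving if self._leaf_survives(l, ans)]
            applied.append(ans)
            new_answers.append(replace(ans, invalidated=False))
            char_status, state_status, resolved = self._statuses(surviving, applied)
        self.answers = new_answers

        endpoints = _endpoints(self.key)
        surv_set = set(surviving)
        order = [t.id for t, _ in self.key.iter_taxa()]
        surviving_eps = sorted(
            (e for e, ls in endpoints.items() if surv_set.intersection(ls)),
            key=order.index,
        )
        self._derived = _Derived(
            surviving_leaves=surviving,
            surviving_endpoints=surviving_eps,
            character_status=char_status,
            state_status=state_status,
            resolved=resolved,
            result=surviving_eps[0] if resolved and surviving_eps else None,
        )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def start_session(key: Key, options: Optional[SessionOptions] = None) -> Session:
    """Open a session: all leaves (or the a-priori subset's) are candidates.

    The key must be structurally valid; subset ids that do not resolve are
    reported in one error.
    """
    errors = [i for i in validate_structure(key) if i.severity == "error"]
    if errors:
        raise EngineError(
            "key is structurally invalid: "
            + "; ".join(f"{i.code} at {i.path}" for i in errors[:5])
        )
    return Session(key=key, options=options or SessionOptions())


def apply_answer(session: Session, answer: Answer) -> Session:
    """Apply one answer, returning the new session.

    Refused (with the character's hidden-reason) when the character is not
    currently visible, the affirmed state is not selectable, or a numeric
    value is off-grid or out of bounds.
    """
    d = session._derived
    reason = session._check_answer(answer, d.character_status, d.state_status)
    if reason is not None:
        raise AnswerRefusedError(
            f"answer on {answer.character} refused: {reason}", reason=reason
        )
    answer = replace(answer, ordinal=len(session.answers))
    return Session(
        key=session.key,
        options=session.options,
        answers=session.answers + [answer],
        _resolver=session._resolver,
    )


def undo_answer(session: Session, ordinal: int) -> Session:
    """Remove the answer at ``ordinal`` and replay the rest in order.

    Any remaining answer whose character is not visible at its replay point
    is kept in the log but flagged invalidated and skipped.
    """
    kept = [a for a in session.answers if a.ordinal != ordinal]
    if len(kept) == len(session.answers):
        raise EngineError(f"no answer with ordinal {ordinal}")
    return Session(
        key=session.key, options=session.options, answers=kept, _resolver=session._resolver
    )


def effective_frequency(
    session: Session, leaf: str, character: str, state: str
) -> EffectiveFrequency:
    """Resolve the effective frequency of a state for a leaf (see
    :meth:`_Resolver.effective` for the resolution order)."""
    return session._resolver.effective(leaf, character, state)


def character_status(session: Session, character_id: str) -> str:
    return session.character_status(character_id)


def state_status(session: Session, state_id: str) -> str:
    return session.state_status(state_id)


def plausibility(session: Session, endpoint: str) -> float:
    """How well the valid answers fit an endpoint, in [0, 1].

    Per surviving leaf of the endpoint, the product over valid answers of
    the answer's support: affirmed state → its effective frequency
    (undefined → 1), rejected state → 1 − frequency, numeric value → the
    highest frequency among applicable ranges containing it.  The endpoint
    takes the best of its leaves.  Used for ordering results only, never for
    exclusion.
    """
    res = session._resolver
    endpoints = _endpoints(session.key)
    if endpoint not in endpoints:
        raise EngineError(f"'{endpoint}' is not an endpoint of this key")
    surv = set(session.surviving_leaves)
    leaves = [l for l in endpoints[endpoint] if l in surv]
    if not leaves:
        raise EngineError(f"endpoint '{endpoint}' has no surviving leaves")
    best = 0.0
    for leaf in leaves:
        p = 1.0
        for a in session.valid_answers:
            if a.kind == AFFIRM:
                eff = res.effective(leaf, a.character, a.state)
                p *= eff.value if eff.defined else 1.0
            elif a.kind == REJECT:
                eff = res.effective(leaf, a.character, a.state)
                p *= 1.0 - eff.value if eff.defined else 1.0
            else:
                stmts = res.numeric_statements(leaf, a.character)
                containing = [
                    s.frequency
                    for s in stmts
                    if s.value[0] - _GRID_TOL <= a.value <= s.value[1] + _GRID_TOL
                ]
                p *= max(containing) if containing else 1.0
        best = max(best, p)
    return best


# ---------------------------------------------------------------------------
# Answer trails
# ---------------------------------------------------------------------------


def export_trail(session: Session) -> str:
    """Serialize the answer log (including invalidated entries) as JSON."""
    return json.dumps(
        [
            {
                "character": a.character,
                "kind": a.kind,
                "value": a.state if a.kind in (AFFIRM, REJECT) else a.value,
                "ordinal": a.ordinal,
                "invalidated": a.invalidated,
            }
            for a in session.answers
        ],
        indent=2,
    ) + "\n"


def import_trail(text: str) -> list[Answer]:
    """Parse an answer trail back into :class:`Answer` records."""
    raw = json.loads(text)
    out = []
    for i, d in enumerate(raw):
        kind = d["kind"]
        out.append(
            Answer(
                character=d["character"],
                kind=kind,
                state=d["value"] if kind in (AFFIRM, REJECT) else None,
                value=float(d["value"]) if kind == NUMERIC else None,
                ordinal=d.get("ordinal", i),
                invalidated=bool(d.get("invalidated", False)),
            )
        )
    return out
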