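"""Semantic quality checks for identification keys.

A key can be perfectly schema-compliant yet logically broken: a taxon
stated to always show two mutually exclusive states, the same fact stated
twice with contradicting frequencies, a premise that can never come true,
or two endpoints no character can tell apart.  The linter reports such
defects as findings; incompleteness (indistinguishable endpoint pairs) is
legal in the format and therefore only warned about.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .format import EXCLUSIVE, Key, validate_structure
from .premise import (
    PremiseSyntaxError,
    UnknownIdentifierError,
    parse_premise,
    premise_identifiers,
)

__all__ = ["Finding", "FINDING_CODES", "lint_key", "distinguishability_report"]

#: Closed catalogue of lint finding codes.
FINDING_CODES = (
    "INDISTINGUISHABLE_PAIR",
    "CONTRADICTORY_STATEMENTS",
    "MULTIPLE_ALWAYS_STATES",
    "NO_POSSIBLE_STATE",
    "RANGE_OUT_OF_BOUNDS",
    "STEP_VIOLATION",
    "DANGLING_REF",
    "UNKNOWN_PREMISE_ID",
    "PREMISE_CYCLE",
    "UNREACHABLE_STATE",
    "UNPREFIXED_ID",
    "SHADOWED_INHERITED_STATEMENT",
)

# structural codes the linter re-surfaces so its catalogue is self-contained
_STRUCTURAL_CODES = {"DANGLING_REF", "RANGE_OUT_OF_BOUNDS"}

_ID_KINDS = {
    "taxon": "taxon",
    "state": "state",
    "character": "character",
    "statement": "statement",
}


@dataclass(frozen=True)
class Finding:
    code: str
    severity: str  # "error" | "warning"
    subjects: tuple[str, ...]
    message: str

    def to_json(self) -> dict:
        return {
            "code": self.code,
            "severity": self.severity,
            "subjects": list(self.subjects),
            "message": self.message,
        }


def _scope_id(statement) -> Optional[str]:
    """A hashable identity for a statement's geographic scope (None =
    unscoped); distinct regions get distinct identities."""
    if statement.geography is None:
        return None
    return json.dumps(statement.geography.to_json(), sort_keys=True)


def lint_key(key: Key) -> list[Finding]:
    """Run every semantic check; findings sorted by (code, subjects).

    Expects a structurally valid key, but re-surfaces structural
    DANGLING_REF / RANGE_OUT_OF_BOUNDS issues as findings so the full
    catalogue is reportable from one call.
    """
    findings: list[Finding] = []

    for issue in validate_structure(key):
        if issue.code in _STRUCTURAL_CODES:
            findings.append(
                Finding(issue.code, "error", (issue.path,), issue.message)
            )

    chars = key.character_map()
    state_owner = key.state_owner()
    taxon_ids = set(key.taxon_map())

    # -- id prefix convention (conventional, never structural)
    def check_prefix(obj_id: str, kind: str) -> None:
        if not obj_id.startswith(f"{kind}:"):
            findings.append(
                Finding(
                    "UNPREFIXED_ID",
                    "warning",
                    (obj_id,),
                    f"{kind} id '{obj_id}' does not carry the conventional '{kind}:' prefix",
                )
            )

    for t, _ in key.iter_taxa():
        check_prefix(t.id, "taxon")
    for c in key.characters:
        check_prefix(c.id, "character")
        for s in c.states:
            check_prefix(s.id, "state")
    for s in key.statements:
        check_prefix(s.id, "statement")

    # -- per (taxon, character, scope scenario) frequency logic
    by_tcs: dict[tuple[str, str, Optional[str], str], list] = {}
    for s in key.statements:
        if s.character not in chars or s.taxon not in taxon_ids:
            continue  # already reported as DANGLING_REF
        if s.is_numeric:
            continue
        if not isinstance(s.value, str) or state_owner.get(s.value) != s.character:
            continue
        by_tcs.setdefault((s.taxon, s.character, _scope_id(s), s.value), []).append(s)

    # direct contradictions: same (taxon, character, state, scope) with
    # conflicting frequencies
    cross_scope: dict[tuple[str, str, str], set[float]] = {}
    for (taxon, character, scope, state), stmts in by_tcs.items():
        freqs = {s.frequency for s in stmts}
        if len(freqs) > 1:
            findings.append(
                Finding(
                    "CONTRADICTORY_STATEMENTS",
                    "error",
                    tuple(sorted(s.id for s in stmts)),
                    f"{taxon} is given conflicting frequencies {sorted(freqs)} for "
                    f"{state} within the same scope",
                )
            )
        cross_scope.setdefault((taxon, character, state), set()).update(freqs)

    # contradictions across scope scenarios (scoped overrides are legal;
    # warn so the key author can confirm the override is intended)
    for (taxon, character, state), freqs in cross_scope.items():
        scopes = {
            scope
            for (t2, c2, scope, st2) in by_tcs
            if (t2, c2, st2) == (taxon, character, state)
        }
        if len(scopes) > 1 and len(freqs) > 1 and (0.0 in freqs or 1.0 in freqs):
            findings.append(
                Finding(
                    "CONTRADICTORY_STATEMENTS",
                    "warning",
                    (taxon, character, state),
                    f"{taxon} has decisively different frequencies for {state} in "
                    "different geographic scenarios",
                )
            )

    # MULTIPLE_ALWAYS_STATES / NO_POSSIBLE_STATE per exclusive character,
    # per scope scenario
    per_taxon_char: dict[tuple[str, str, Optional[str]], dict[str, float]] = {}
    for (taxon, character, scope, state), stmts in by_tcs.items():
        per_taxon_char.setdefault((taxon, character, scope), {})[state] = stmts[0].frequency
    for (taxon, character, scope), state_freqs in per_taxon_char.items():
        char = chars[character]
        if char.type != EXCLUSIVE:
            continue
        always = sorted(st for st, f in state_freqs.items() if f == 1.0)
        if len(always) > 1:
            findings.append(
                Finding(
                    "MULTIPLE_ALWAYS_STATES",
                    "error",
                    (taxon, character, *always),
                    f"{taxon} is stated to always have {len(always)} mutually "
                    f"exclusive states of {character}",
                )
            )
        if len(state_freqs) == len(char.states) and all(
            f == 0.0 for f in state_freqs.values()
        ):
            findings.append(
                Finding(
                    "NO_POSSIBLE_STATE",
                    "error",
                    (taxon, character),
                    f"every state of {character} is stated impossible for {taxon}",
                )
            )

    # STEP_VIOLATION: numeric range endpoints off the character's step grid
    for s in key.statements:
        char = chars.get(s.character)
        if char is None or not char.is_numerical or not s.is_numeric:
            continue
        if char.min is None or char.stepSize is None:
            continue
        for bound in s.value:
            steps = round((bound - char.min) / char.stepSize)
            if abs(char.min + steps * char.stepSize - bound) > 1e-9:
                findings.append(
                    Finding(
                        "STEP_VIOLATION",
                        "warning",
                        (s.id,),
                        f"range bound {bound} of {s.id} is not on the step grid of "
                        f"{char.id}",
                    )
                )

    # -- premises
    premise_refs: dict[str, list[str]] = {}
    for c in key.characters:
        if not c.logicalPremise:
            continue
        try:
            ast = parse_premise(c.logicalPremise, key)
        except UnknownIdentifierError as e:
            findings.append(
                Finding(
                    "UNKNOWN_PREMISE_ID",
                    "error",
                    (c.id, e.name),
                    f"premise of {c.id} references unknown id '{e.name}'",
                )
            )
            continue
        except PremiseSyntaxError as e:
            findings.append(
                Finding(
                    "UNKNOWN_PREMISE_ID",
                    "error",
                    (c.id,),
                    f"premise of {c.id} does not parse: {e}",
                )
            )
            continue
        premise_refs[c.id] = premise_identifiers(ast)

    # PREMISE_CYCLE: character -> characters owning the facts its premise
    # references; a cycle means no character in it can ever surface
    graph: dict[str, set[str]] = {}
    for cid, refs in premise_refs.items():
        deps = set()
        for name in refs:
            if name in state_owner:
                deps.add(state_owner[name])
            elif name in chars:
                deps.add(name)
        graph[cid] = deps

    def find_cycle() -> Optional[list[str]]:
        color: dict[str, int] = {}
        stack: list[str] = []

        def dfs(node: str) -> Optional[list[str]]:
            color[node] = 1
            stack.append(node)
            for nxt in sorted(graph.get(node, ())):
                if color.get(nxt, 0) == 1:
                    return stack[stack.index(nxt):]
                if color.get(nxt, 0) == 0:
                    cyc = dfs(nxt)
                    if cyc:
                        return cyc
            color[node] = 2
            stack.pop()
            return None

        for node in sorted(graph):
            if color.get(node, 0) == 0:
                cyc = dfs(node)
                if cyc:
                    return cyc
        return None

    cycle = find_cycle()
    if cycle:
        findings.append(
            Finding(
                "PREMISE_CYCLE",
                "error",
                tuple(sorted(cycle)),
                "premises form a dependency cycle: " + " -> ".join(cycle + [cycle[0]]),
            )
        )

    # UNREACHABLE_STATE: a state no statement ever refers to
    referenced = {s.value for s in key.statements if isinstance(s.value, str)}
    for c in key.characters:
        for st in c.states:
            if st.id not in referenced:
                findings.append(
                    Finding(
                        "UNREACHABLE_STATE",
                        "warning",
                        (st.id,),
                        f"state {st.id} of {c.id} is never referenced by a statement",
                    )
                )

    # SHADOWED_INHERITED_STATEMENT: child statement contradicts an
    # ancestor's for the same (character, state); overriding is legal, a
    # contradictory override is worth confirming
    parents = key.parent_map()
    stated: dict[tuple[str, str, str], float] = {}
    for s in key.statements:
        if isinstance(s.value, str) and s.geography is None:
            stated[(s.taxon, s.character, s.value)] = s.frequency
    for (taxon, character, state), freq in sorted(stated.items()):
        anc = parents.get(taxon)
        while anc is not None:
            up = stated.get((anc, character, state))
            if up is not None:
                if up != freq:
                    findings.append(
                        Finding(
                            "SHADOWED_INHERITED_STATEMENT",
                            "warning",
                            (taxon, character, state, anc),
                            f"{taxon} overrides the inherited frequency {up} from "
                            f"{anc} with {freq} for {state}",
                        )
                    )
                break
            anc = parents.get(anc)

    for (a, b), count in distinguishability_report(key):
        if count == 0:
            findings.append(
                Finding(
                    "INDISTINGUISHABLE_PAIR",
                    "warning",
                    (a, b),
                    f"no character decisively separates {a} from {b}",
                )
            )

    return sorted(findings, key=lambda f: (f.code, f.subjects))


def distinguishability_report(key: Key) -> list[tuple[tuple[str, str], int]]:
    """Count separating characters for every endpoint pair.

    Returns ``[((a, b), n_separators), …]`` over all unordered endpoint
    pairs in document order.  A pair is separable when some categorical
    state has decisive (0 vs 1) effective frequencies differing between the
    two, or some numerical character gives them disjoint ranges.
    Intermediate frequencies never count: a 0.5-frequency trait cannot
    guarantee separation.  Incompleteness is legal in the format, so
    zero-separator pairs surface as warnings in :func:`lint_key`, not
    errors.
    """
    from .engine import Session, _endpoints  # deferred to avoid import cycle

    session = Session(key=key)
    res = session._resolver
    endpoints = _endpoints(key)
    ep_ids = list(endpoints)

    def decisive(leaves: list[str], character: str, state: str) -> Optional[float]:
        """0.0 / 1.0 when all the endpoint's leaves agree decisively."""
        vals = set()
        for leaf in leaves:
            eff = res.effective(leaf, character, state)
            if not eff.defined or eff.value not in (0.0, 1.0):
                return None
            vals.add(eff.value)
        return vals.pop() if len(vals) == 1 else None

    def ranges(leaves: list[str], character: str) -> Optional[tuple[float, float]]:
        lo, hi = None, None
        for leaf in leaves:
            stmts = [s for s in res.numeric_statements(leaf, character) if s.frequency > 0]
            if not stmts:
                return None
            lo_leaf = min(s.value[0] for s in stmts)
            hi_leaf = max(s.value[1] for s in stmts)
            lo = lo_leaf if lo is None else min(lo, lo_leaf)
            hi = hi_leaf if hi is None else max(hi, hi_leaf)
        return (lo, hi)

    report: list[tuple[tuple[str, str], int]] = []
    for i in range(len(ep_ids)):
        for j in range(i + 1, len(ep_ids)):
            a, b = ep_ids[i], ep_ids[j]
            separators = 0
            for c in key.characters:
                if c.is_numerical:
                    ra = ranges(endpoints[a], c.id)
                    rb = ranges(endpoints[b], c.id)
                    if ra and rb and (ra[1] < rb[0] or rb[1] < ra[0]):
                        separators += 1
                    continue
                for st in c.states:
                    fa = decisive(endpoints[a], c.id, st.id)
                    fb = decisive(endpoints[b], c.id, st.id)
                    if fa is not None and fb is not None and fa != fb:
                        separators += 1
                        break
            report.append(((a, b), separators))
    return report
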