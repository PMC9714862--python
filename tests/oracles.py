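"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written from first principles against the
documented semantics — flat scans, no reuse of the package's resolver or
evaluator — so agreement between the two routes is meaningful.
"""

from __future__ import annotations


# ---------------------------------------------------------------------------
# Three-valued logic oracle over tuple-encoded expressions
# ---------------------------------------------------------------------------
# Expressions are tuples: ("atom", name), ("not", e), ("and", l, r),
# ("or", l, r), ("eq", l, r).  Truth values are True / False / None.


def tv_not(a):
    return None if a is None else (not a)


def tv_and(a, b):
    if a is False or b is False:
        return False
    if a is None or b is None:
        return None
    return True


def tv_or(a, b):
    if a is True or b is True:
        return True
    if a is None or b is None:
        return None
    return False


def tv_eq(a, b):
    if a is None or b is None:
        return None
    return a == b


def eval_expr(expr, assignment):
    op = expr[0]
    if op == "atom":
        return assignment[expr[1]]
    if op == "not":
        return tv_not(eval_expr(expr[1], assignment))
    l, r = eval_expr(expr[1], assignment), eval_expr(expr[2], assignment)
    return {"and": tv_and, "or": tv_or, "eq": tv_eq}[op](l, r)


def expr_to_source(expr):
    """Render a tuple expression as a premise string."""
    op = expr[0]
    if op == "atom":
        return expr[1]
    if op == "not":
        return f"!({expr_to_source(expr[1])})"
    sym = {"and": "&&", "or": "||", "eq": "=="}[op]
    return f"({expr_to_source(expr[1])} {sym} {expr_to_source(expr[2])})"


def enumerate_exprs(atoms, max_depth):
    """All tuple expressions over the atoms up to the given tree depth."""
    by_depth = {1: [("atom", a) for a in atoms]}
    for d in range(2, max_depth + 1):
        smaller = [e for dd in range(1, d) for e in by_depth[dd]]
        level = [("not", e) for e in by_depth[d - 1]]
        for op in ("and", "or", "eq"):
            for l in smaller:
                for r in smaller:
                    if max(expr_depth(l), expr_depth(r)) == d - 1:
                        level.append((op, l, r))
        by_depth[d] = level
    return [e for d in range(1, max_depth + 1) for e in by_depth[d]]


def expr_depth(expr):
    op = expr[0]
    if op == "atom":
        return 1
    if op == "not":
        return 1 + expr_depth(expr[1])
    return 1 + max(expr_depth(expr[1]), expr_depth(expr[2]))


# ---------------------------------------------------------------------------
# Winding-number point-in-polygon oracle
# ---------------------------------------------------------------------------


def winding_number(ring, x, y):
    """Winding number of a closed ring around a point (non-boundary)."""
    wn = 0
    for i in range(len(ring) - 1):
        x1, y1 = ring[i][0], ring[i][1]
        x2, y2 = ring[i + 1][0], ring[i + 1][1]
        if y1 <= y:
            if y2 > y and _is_left(x1, y1, x2, y2, x, y) > 0:
                wn += 1
        else:
            if y2 <= y and _is_left(x1, y1, x2, y2, x, y) < 0:
                wn -= 1
    return wn


def _is_left(x1, y1, x2, y2, px, py):
    return (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)


def winding_inside_polygon(polygon, x, y):
    """Outer ring minus holes, by winding number."""
    if winding_number(polygon[0], x, y) == 0:
        return False
    return all(winding_number(hole, x, y) == 0 for hole in polygon[1:])


def dist_to_ring(ring, x, y):
    """Distance from a point to the nearest ring segment (to skip
    near-boundary points where oracles may legitimately disagree)."""
    best = float("inf")
    for i in range(len(ring) - 1):
        x1, y1 = ring[i][0], ring[i][1]
        x2, y2 = ring[i + 1][0], ring[i + 1][1]
        dx, dy = x2 - x1, y2 - y1
        denom = dx * dx + dy * dy
        t = 0.0 if denom == 0 else max(0.0, min(1.0, ((x - x1) * dx + (y - y1) * dy) / denom))
        px, py = x1 + t * dx, y1 + t * dy
        best = min(best, ((x - px) ** 2 + (y - py) ** 2) ** 0.5)
    return best


# ---------------------------------------------------------------------------
# From-scratch per-leaf conflict evaluation (engine oracle)
# ---------------------------------------------------------------------------
# Re-derives the elimination semantics with flat scans over the statement
# list: nearest-ancestor statements, exclusivity-implied zeros, numeric
# range membership.  Geography-free keys only (scoped statements are out of
# scope for this oracle and excluded from the keys it checks).


def _parents(key):
    out = {}

    def walk(t, parent):
        out[t.id] = parent
        for c in t.children:
            walk(c, t.id)

    for root in key.taxa:
        walk(root, None)
    return out


def _chain(parents, leaf):
    chain = [leaf]
    while parents.get(chain[-1]) is not None:
        chain.append(parents[chain[-1]])
    return chain


def _stated_frequency(key, chain, character_id, state_id):
    """Frequency from the nearest ancestor statement, else None."""
    for level in chain:
        hits = [
            s.frequency
            for s in key.statements
            if s.taxon == level and s.character == character_id and s.value == state_id
        ]
        if hits:
            return hits[0]
    return None


def _effective(key, chain, char, state_id):
    """Stated frequency, or exclusivity-implied 0, or None."""
    f = _stated_frequency(key, chain, char.id, state_id)
    if f is not None:
        return f
    if char.type == "exclusive":
        for sib in char.states:
            if sib.id != state_id and _stated_frequency(key, chain, char.id, sib.id) == 1.0:
                return 0.0
    return None


def _numeric_ranges(key, chain, character_id):
    for level in chain:
        hits = [
            (s.value[0], s.value[1], s.frequency)
            for s in key.statements
            if s.taxon == level and s.character == character_id and isinstance(s.value, list)
        ]
        if hits:
            return hits
    return []


def leaf_conflicts(key, leaf, answer):
    """Whether one answer excludes one leaf, evaluated from scratch."""
    chars = {c.id: c for c in key.characters}
    char = chars[answer.character]
    parents = _parents(key)
    chain = _chain(parents, leaf)
    if answer.kind == "affirm":
        return _effective(key, chain, char, answer.state) == 0.0
    if answer.kind == "reject":
        if _effective(key, chain, char, answer.state) == 1.0:
            return True
        if char.type == "exclusive":
            others = [
                _effective(key, chain, char, sib.id)
                for sib in char.states
                if sib.id != answer.state
            ]
            return bool(others) and all(o == 0.0 for o in others)
        return False
    ranges = _numeric_ranges(key, chain, answer.character)
    if not ranges:
        return False
    v = answer.value
    in_pos = any(lo - 1e-9 <= v <= hi + 1e-9 and f > 0 for lo, hi, f in ranges)
    in_zero = any(lo - 1e-9 <= v <= hi + 1e-9 and f == 0 for lo, hi, f in ranges)
    return (not in_pos) or in_zero


def surviving_leaves(key, answers):
    """Final surviving leaf set, each leaf checked against every answer."""
    leaves = []

    def walk(t):
        if not t.children:
            leaves.append(t.id)
        for c in t.children:
            walk(c)

    for root in key.taxa:
        walk(root)
    return [l for l in leaves if not any(leaf_conflicts(key, l, a) for a in answers)]
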