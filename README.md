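# clavis

A reference library and command-line tool for the **Clavis** identification-key
format: an open JSON dialect for storing the taxonomic knowledge behind digital
multi-access identification keys.

## The problem

Identifying an organism means excluding candidate taxa one observable trait at
a time until a single taxon remains. Digital *multi-access* keys store this
knowledge as a sparse matrix of **statements**, each linking one taxon *t* to
one character *c* (a question such as "color" or "length in mm") through a
value — a categorical state *s* or a numeric range [lo, hi] — together with a
**frequency** f ∈ [0, 1]: the proportion of individuals of *t* showing *s* for
*c* (1 = always, 0 = never, 0.5 = half the cases). Taxa may form a hierarchy
(statements attach to a family and are inherited by every species below it,
nearest statement winning), sub-groups (sexes, morphs) carry labels instead of
scientific names, and a taxon above the leaves can be tagged as an *endpoint*
where identification stops.

This package implements the whole life cycle of such keys:

- **format** — parse/serialize Clavis JSON (canonical, byte-stable form),
  structural validation with located issue codes, localized-text resolution,
  and lossless conversion to/from a sparse CSV matrix dialect for flat keys.
- **engine** — identification sessions with the elimination semantics:
  affirming state *s* excludes every leaf with effective frequency 0 for *s*
  (explicit, inherited, or implied by exclusivity — a taxon always blue is
  never red); rejecting *s* excludes leaves with frequency 1 (or whose every
  other state is impossible); a numeric answer *v* excludes leaves whose stated
  ranges cannot contain *v*. Characters surface only when every remaining
  candidate is covered by a statement for them; states all remaining taxa lack
  are disabled; questions stop at a resolved endpoint; answers can be undone,
  with dependent answers invalidated on replay. Intermediate frequencies
  never exclude — they feed a per-endpoint plausibility score
  Π over answers of the answer's support, used for ranking only.
- **premise** — JavaScript-notation logical premises gating character
  visibility, evaluated in Kleene three-valued logic (an unestablished fact is
  UNKNOWN; `UNKNOWN && FALSE = FALSE`, `UNKNOWN || TRUE = TRUE`).
- **geography** — GeoJSON MultiPolygon regions with planar even–odd
  point-in-polygon tests; a geography-scoped statement overrides a conflicting
  unscoped one when the observer's location falls inside its region.
- **lint** — semantic checks beyond schema validity: contradictory or
  impossible statement sets, premise cycles, and a distinguishability report
  counting, for every endpoint pair, the characters whose decisive (0 vs 1)
  frequencies separate them.
- **synth** — a seeded generator of valid (or deliberately defective)
  keys plus the two hand-built demonstration keys shipped as fixtures.

## Worked example

The classic four-taxon demonstration: two characters, color scored for all
four taxa, size for only three — so size stays hidden until the color answer
has excluded the unscored taxon.

```python
from clavis import *

session = start_session(fixture_fig2())
print("candidates:", session.surviving_endpoints)
print("visible characters:", session.visible_characters())
print("size status:", session.character_status("character:size"))
session = apply_answer(session, Answer(character="character:color",
                                       kind="affirm", state="state:blue"))
print("after affirming Blue:", session.surviving_endpoints)
print("visible characters:", session.visible_characters())
session = apply_answer(session, Answer(character="character:size",
                                       kind="affirm", state="state:small"))
print("after affirming Small:", session.surviving_endpoints)
print("resolved:", session.resolved, "->", session.result)
```

prints

```
candidates: ['taxon:t1', 'taxon:t2', 'taxon:t3', 'taxon:t4']
visible characters: ['character:color']
size status: hidden_uncovered
after affirming Blue: ['taxon:t1', 'taxon:t2']
visible characters: ['character:size']
after affirming Small: ['taxon:t1']
resolved: True -> taxon:t1
```

Four candidates shrink to two (the red taxa conflict with the Blue answer),
the size character becomes answerable, and the Small answer resolves the
session. The same trace from the shell, replaying a recorded answer trail:

```sh
$ clavis play src/clavis/fixtures/fig2.json --answers src/clavis/fixtures/fig2_trail.json
4 candidate(s): Taxus exemplaris 1, Taxus exemplaris 2, Taxus exemplaris 3, Taxus exemplaris 4
2 candidate(s): Taxus exemplaris 1, Taxus exemplaris 2
1 candidate(s): Taxus exemplaris 1
resolved: taxon:t1
```

The linter knows what the key author cannot fix: the taxon unscored for size
makes the two red taxa genuinely inseparable,

```sh
$ clavis lint src/clavis/fixtures/fig2.json
warning: INDISTINGUISHABLE_PAIR [taxon:t3, taxon:t4]: no character decisively separates taxon:t3 from taxon:t4
```

Other subcommands: `clavis validate KEY.json`, `clavis convert` (key ⇄ CSV
matrix), `clavis generate --taxa N --seed S -o key.json [--defect CODE]`,
`clavis stats KEY.json`. Exit codes: 0 ok, 1 findings, 2 usage errors.

## Scope and limitations

Media payloads, external services and follow-up keys are parsed and
reference-checked but never fetched; geometry is planar lon/lat (no geodesic
edges or antimeridian splitting); no graphical interface is included — see
`docs/methods.md` for the full semantics, design decisions and limitations.
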