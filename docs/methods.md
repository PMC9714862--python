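# Methods

This note records the semantics the package implements, the choices made
where the format leaves room, and what the synthetic test data does and does
not establish.

## The data model

A key is a JSON document with mandatory metadata (`identifier`, `title`,
`schema`, `license`, `language`, `created`, `lastModified`, `creator`) and
three content blocks:

- **taxa** — a forest. A node carries a `scientificName` *or* (exclusively) a
  sub-group `label` (sex, morph, caste; the empty string is a valid label for
  the default form). `isEndpoint: true` on an inner node makes it the rank at
  which identification stops; by default every leaf is an endpoint. A
  sub-group must sit below at least one named taxon.
- **characters** — `exclusive` (default; states mutually exclusive),
  `nonExclusive` (a specimen may show several states at once), or `numerical`
  (`min` < `max`, `stepSize` > 0, `unit`). Categorical characters need ≥ 2
  states; a state needs a title or at least one media reference. A character
  may carry a `logicalPremise` and a `userRequirement` reference.
- **statements** — `(taxon, character, value, frequency ∈ [0,1])`, optionally
  scoped to a geographic region. A single numeric value v is normalized to
  the degenerate range [v, v]. Absent frequency defaults to 1.

Unknown fields anywhere are preserved opaquely (`extras`) so future format
revisions round-trip. Canonical serialization sorts keys lexicographically,
indents by two spaces, uses shortest round-trip float formatting and LF
endings; equal keys serialize to identical bytes. Id prefixes
(`taxon:`, `state:`, …) are conventional: their absence is a lint warning,
never a structural error. Dates are stored verbatim (ISO-8601 date or
datetime). The persons/organizations/media/services blocks are parsed and
reference-checked only; payloads are never fetched, and external services are
passthrough metadata — a hook point for interfaces, never load-bearing.

`parse_key(strict=True)` raises on missing mandatory fields (listing each);
`strict=False` defers everything to `validate_structure`, which reports every
structural invariant violation as a located `Issue` from a closed code set
(`MISSING_FIELD`, `DUPLICATE_ID`, `DANGLING_REF`, `FREQUENCY_RANGE`,
`LANGUAGE_UNDECLARED`, `LOCALIZED_EMPTY`, `REGION_EMPTY`, `RING_NOT_CLOSED`,
`RING_TOO_SHORT`, `TAXON_NAME_CONFLICT`, `SUBGROUP_ORPHAN`, `STATE_EMPTY`,
`CHARACTER_SHAPE`, `NUMERIC_BOUNDS`, `VALUE_KIND_MISMATCH`,
`RANGE_OUT_OF_BOUNDS`, `BAD_TYPE`).

## Effective frequencies

All elimination logic reduces to one resolution rule. The effective frequency
of (leaf, character, state) is found by walking from the leaf up its ancestor
chain:

1. The **nearest** taxon level with any applicable statement for the pair
   decides — a child statement shadows an inherited one.
2. At that level, a **geography-scoped** statement whose region contains the
   session location beats an unscoped one; scoped statements are skipped
   entirely when no location is set (or the region is name-only), so sessions
   without a location fall back to the unscoped knowledge. Ties break by
   document order.
3. If nothing is stated at any level and the character is exclusive, a
   sibling state held with frequency 1 **implies** frequency 0 here.
4. Otherwise the frequency is UNDEFINED — "unscored", which is weaker than
   "absent" and never excludes.

## Session semantics

Derived session state is a pure function of (key, options, ordered valid
answers); the implementation recomputes it by full replay on every change,
which makes undo trivial and correct by construction: remove the answer,
replay the rest in order, and flag any answer whose character is not visible
at its replay point as invalidated (kept in the log, skipped in the
computation). Keys small enough to be authored by hand are far below the
scale where incremental updating would matter.

Exclusion rules per answer, applied leaf-wise:

- *affirm s*: exclude iff effective frequency is exactly 0 (explicit,
  inherited, or implied).
- *reject s*: exclude iff frequency is exactly 1, or the character is
  exclusive and every other state has defined frequency 0 (the taxon must
  show *s*).
- *numeric v*: exclude iff the leaf has applicable numeric statements and
  v lies in no range with frequency > 0, or lies inside a range stated with
  frequency 0. Range and step comparisons use absolute tolerance 1e-9 with
  inclusive boundaries; answers must lie on the step grid.

Intermediate frequencies (0 < f < 1) never exclude in either direction: a
rate is not a constraint. They surface instead in the plausibility score of a
surviving endpoint — per leaf the product over valid answers of the answer's
support (affirm → effective frequency, reject → 1 − frequency, numeric → the
highest frequency among containing ranges, UNDEFINED → 1), maximized over the
endpoint's surviving leaves. The score orders results (document-order
tie-break) and never excludes.

Character statuses: `answered` (an affirm on an exclusive character, or a
numeric answer — rejects keep a character open, and a non-exclusive character
stays answerable while ≥ 2 states remain undecided, so users can keep picking
or excluding colors); `hidden_premise_false` / `hidden_premise_unknown` (the
distinction is reported so an interface can explain *why*); `hidden_uncovered`
(some surviving leaf has no applicable statement); `hidden_uninformative`
(≤ 1 selectable state; also the status of every unanswered character once the
session is resolved, since nothing remains to distinguish); else `visible`.
A state is `disabled` when every surviving leaf has effective frequency 0 for
it — still listed for context, not selectable. Endpoints survive while ≥ 1 of
their descendant leaves survives; the session resolves when exactly one
endpoint remains, and an a-priori taxon subset recomputes candidate endpoints
within the subset.

## Premises

The premise grammar (EBNF in `clavis/premise.py`) covers boolean and numeric
literals, state ids, numerical-character ids, unary `!`/`-`, comparisons
(`== != < <= > >=`), `&&`, `||`, and parentheses — deliberately frozen to
what visibility gating needs; no ternary, calls or assignment, so premise
strings cannot smuggle computation. Categorical facts are referenced by state
id only. Evaluation is Kleene three-valued: a state id is TRUE when affirmed,
FALSE when rejected or impossible (every surviving leaf at frequency 0, or a
sibling of an affirmed state in an exclusive character), UNKNOWN otherwise;
comparisons on unanswered numerical characters are UNKNOWN. A character is
shown only when its premise is TRUE — both FALSE and UNKNOWN hide it, since
showing a wing question before wings are established is exactly what premises
exist to prevent.

## Geography

Rings are planar lon/lat polygons (the plain GeoJSON reading): no geodesic
edges and no antimeridian splitting — adequate for scoping keys to regions,
documented as a limitation. Containment is even–odd ray casting per polygon
(outer ring minus holes); boundary points count as inside, which is
deterministic and favors applying the more specific, geography-scoped
statement. Tests verify agreement with an independently written
winding-number oracle (and with shapely's `covers`) on random star-shaped
(hence simple) polygons, skipping points within 1e-9 of an edge where any two
float implementations may legitimately disagree.

## Lint

Twelve finding codes; errors for outright contradictions (the same fact
stated with conflicting frequencies in the same geographic scope, two
always-states of an exclusive character, no possible state, premise cycles,
unknown premise ids, dangling references, out-of-bounds ranges), warnings for
legal-but-suspect patterns (unprefixed ids, unreachable states, shadowed
inherited statements, step-grid violations, contradictions across geographic
scenarios, indistinguishable endpoint pairs — incompleteness is legal, so a
key that cannot separate every pair is warned about, not rejected).
Geography-scoped statements are linted per scope scenario: the unscoped
baseline plus one scenario per distinct region. The premise-cycle graph maps
each character to the characters owning the facts its premise references; any
cycle is fatal since no member can ever surface. Findings are sorted by
(code, subjects) and the whole pass is side-effect free.

The distinguishability report counts decisive separators only: a pair is
separable when some state has effective frequency 1 for one endpoint (all its
leaves) and 0 for the other, or numeric ranges are disjoint. Intermediate
frequencies and f=0-versus-unscored asymmetries are excluded on purpose —
they can separate *some* specimens but never guarantee separation, as the
exhaustive-enumeration test demonstrates on both sides of the line.

## Synthetic data

The generator emulates the sparse-matrix structure of real keys: n_taxa
leaves (default 8, optionally grouped three-per-genus per extra hierarchy
level), six two-state exclusive characters plus one numerical measurement
(0–100 mm, step 1), 20% unscored cells, 10% polymorphic statements
(f ∈ {0.25, 0.5, 0.75}), with one quarter of decisive statements at f = 0 so
rejection semantics get exercised. With `guarantee_distinguishable` each leaf
receives a unique binary signature over ⌈log₂ n⌉ fully scored exclusive
characters before sparsity applies elsewhere, so generated keys are solvable
by construction. Premises, when enabled, gate characters on states of
strictly earlier characters (cycle-free by construction); the geography
option replaces one statement with an unscoped f = 0.5 / scoped f = 0.9 pair
over a fixed square. All randomness flows from one explicitly seeded
`random.Random`, so a seed fixes the canonical serialization byte-for-byte
across platforms.

What the generator does *not* emulate: correlated characters, realistic
morphology or geographic ranges, multilingual content, media, or keys large
enough to stress performance. Passing tests therefore demonstrate logical
correctness of the semantics, not ergonomic quality on real-world keys.

The two hand-built fixtures are shipped as canonical JSON and regenerated by
code in tests (byte equality). The four-taxon key demonstrates sparse-matrix
visibility and carries one *intentional* property: its taxon unscored for
size makes the two red taxa genuinely indistinguishable — the linter reports
exactly that warning, and an exhaustive enumeration of answer scripts
confirms no session can separate them. The Clavidae key demonstrates
hierarchy inheritance, sub-group labels, a tagged endpoint with sexes below
it (no sex question is ever asked), and a non-exclusive color character.

## Numerical and procedural choices

- Step-grid and range-boundary comparisons: absolute tolerance 1e-9,
  boundaries inclusive.
- CSV matrix dialect: header `taxon` + one column per character id; cell
  tokens `state_id`, `state_id:freq`, `low..high`, or a single number,
  joined by `;`; empty = unscored. Import infers numerical characters'
  min/max (floor/ceil of observed bounds) and step (from the maximal decimal
  precision observed), since the dialect has no character-metadata row;
  single-state columns are padded with a synthetic unobserved state to keep
  the imported key structurally valid. Export is refused (listing each loss)
  for hierarchical, premise-carrying or geography-carrying keys unless
  forced, in which case the key is flattened to leaves and scoped statements
  dropped.
- Serialization refuses structurally broken keys (issue list attached)
  unless `validate=False`, which the generator CLI uses to write
  deliberately defective keys.
- Problem sizes in tests and in `scripts/acceptance.py` (100 keys × 10
  scripts for the engine/oracle comparison, 200 + 50 round-trips, 50
  polygons × 1,000 points, exhaustive premise enumeration at ≤ 3 atoms /
  depth ≤ 3) were chosen as the smallest scales at which every code path —
  hierarchy depths 1–3, premises, geography, polymorphism, all three
  character types — is exercised hundreds of times; the full suite runs in
  seconds.

## Known limitations

- Rejection is offered for non-exclusive characters as a documented
  extension (useful for "definitely not red"), though classic multi-access
  interfaces mention rejection only for multi-state exclusive choices.
- Answer-order independence holds on premise-free keys for consistent answer
  sets; premise-gated keys are inherently order-dependent (a gate must be
  opened before the gated character can be answered) and are exempt from the
  property by design.
- Name-only regions cannot be evaluated against a location and are treated
  as not applicable; sessions without a location ignore all scoped
  statements.
- Follow-up key references are stored and round-tripped, never traversed.
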