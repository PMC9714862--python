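"""Seeded synthetic keys and hand-built fixtures.

Real identification keys are sparse taxa × characters matrices with
polymorphism, hierarchy and the occasional premise or geographic override.
The generator emulates exactly that structure so every other module can be
exercised without external downloads: a forest of taxa, exclusive /
non-exclusive / numerical characters, and one statement per scored cell.
All randomness comes from a single explicitly seeded ``random.Random``, so
a seed fixes the generated key byte-for-byte across platforms.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace as dc_replace
from typing import Optional

from .format import (
    EXCLUSIVE,
    NON_EXCLUSIVE,
    NUMERICAL,
    Character,
    ClavisError,
    Key,
    Region,
    State,
    Statement,
    Taxon,
    parse_key,
    serialize_key,
)
from .lint import FINDING_CODES

__all__ = [
    "GeneratorParams",
    "generate_key",
    "inject_defect",
    "fixture_fig2",
    "fixture_clavidae",
]

_SCHEMA_URL = "https://clavis.no/schema/1.0"
_LICENSE_URL = "https://creativecommons.org/licenses/by/4.0/"


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic-key generator.

    Defaults describe a small but realistic sparse-matrix key: 8 taxa in a
    flat list, six two-state exclusive characters plus one measurement,
    20% of cells unscored and 10% of statements polymorphic (0 < f < 1).
    """

    n_taxa: int = 8
    hierarchy_depth: int = 1
    n_categorical: int = 6
    states_per_character: int = 2
    n_numeric: int = 1
    polymorphism_rate: float = 0.1
    sparsity: float = 0.2
    premise_rate: float = 0.0
    with_geography: bool = False
    guarantee_distinguishable: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ClavisError("n_taxa must be ≥ 2")
        if self.states_per_character < 2:
            raise ClavisError("states_per_character must be ≥ 2")
        if self.hierarchy_depth < 1:
            raise ClavisError("hierarchy_depth must be ≥ 1")
        for name in ("polymorphism_rate", "sparsity", "premise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ClavisError(f"{name} must lie in [0, 1]")


def _build_taxa(params: GeneratorParams) -> list[Taxon]:
    leaves = [
        Taxon(id=f"taxon:t{i:02d}", scientificName=f"Taxus synthetica {i}")
        for i in range(params.n_taxa)
    ]
    nodes = leaves
    level = 0
    # group consecutive nodes in threes per extra hierarchy level
    while level < params.hierarchy_depth - 1 and len(nodes) > 1:
        level += 1
        grouped = []
        for g in range(0, len(nodes), 3):
            children = nodes[g : g + 3]
            grouped.append(
                Taxon(
                    id=f"taxon:g{level}_{g // 3}",
                    scientificName=f"Synthogenus {level}-{g // 3}",
                    children=children,
                )
            )
        nodes = grouped
    return nodes


def generate_key(params: GeneratorParams) -> Key:
    """Generate a structurally valid key from seeded pseudo-randomness.

    With ``guarantee_distinguishable``, every leaf first receives a unique
    binary signature over ⌈log2(n_taxa)⌉ fully scored exclusive characters
    (frequencies 0/1, never sparsified), so no endpoint pair is left
    unseparable; sparsity and polymorphism only apply to the remaining
    characters.
    """
    params.validate()
    rng = random.Random(params.seed)
    taxa = _build_taxa(params)
    key = Key(
        identifier=f"urn:clavis:synthetic:{params.seed}",
        title=f"Synthetic key {params.seed}",
        schema=_SCHEMA_URL,
        license=_LICENSE_URL,
        language=["en"],
        created="2022-12-01",
        lastModified="2022-12-01",
        creators=["person:synth"],
        persons=[{"id": "person:synth", "name": "Synthetic generator"}],
        taxa=taxa,
    )
    leaves = key.leaves()
    characters: list[Character] = []
    statements: list[Statement] = []
    n_stmt = 0

    def add_statement(taxon: str, character: str, value, freq: float,
                      geography: Optional[Region] = None) -> None:
        nonlocal n_stmt
        n_stmt += 1
        statements.append(
            Statement(
                id=f"statement:s{n_stmt:04d}",
                taxon=taxon,
                character=character,
                value=value,
                frequency=freq,
                geography=geography,
            )
        )

    if params.guarantee_distinguishable:
        nbits = max(1, math.ceil(math.log2(params.n_taxa)))
        for b in range(nbits):
            cid = f"character:sig{b}"
            characters.append(
                Character(
                    id=cid,
                    title=f"signature bit {b}",
                    type=EXCLUSIVE,
                    states=[
                        State(id=f"state:sig{b}_off", title=f"bit {b} off"),
                        State(id=f"state:sig{b}_on", title=f"bit {b} on"),
                    ],
                )
            )
            for i, leaf in enumerate(leaves):
                on = (i >> b) & 1
                add_statement(leaf, cid, f"state:sig{b}_{'on' if on else 'off'}", 1.0)

    for c in range(params.n_categorical):
        cid = f"character:c{c:02d}"
        ctype = NON_EXCLUSIVE if (params.n_categorical > 3 and c == 1) else EXCLUSIVE
        states = [
            State(id=f"state:c{c:02d}_{k}", title=f"alternative {k}")
            for k in range(params.states_per_character)
        ]
        characters.append(Character(id=cid, title=f"categorical {c}", type=ctype, states=states))
        for leaf in leaves:
            if rng.random() < params.sparsity:
                continue
            state = rng.choice(states).id
            if rng.random() < params.polymorphism_rate:
                freq = rng.choice([0.25, 0.5, 0.75])
            else:
                freq = rng.choice([1.0, 1.0, 1.0, 0.0])
            add_statement(leaf, cid, state, freq)

    for n in range(params.n_numeric):
        cid = f"character:n{n:02d}"
        characters.append(
            Character(
                id=cid,
                title=f"measurement {n}",
                type=NUMERICAL,
                min=0.0,
                max=100.0,
                stepSize=1.0,
                unit="mm",
            )
        )
        for leaf in leaves:
            if rng.random() < params.sparsity:
                continue
            low = float(rng.randint(0, 90))
            high = low + float(rng.randint(0, 10))
            add_statement(leaf, cid, [low, high], 1.0)

    # premises: gate some later categorical characters on a state of an
    # earlier one (never a later one, so no cycles arise by construction)
    if params.premise_rate > 0.0:
        categorical = [c for c in characters if not c.is_numerical]
        for idx in range(1, len(categorical)):
            if rng.random() < params.premise_rate:
                target = rng.choice(categorical[:idx])
                fact = rng.choice(target.states).id
                categorical[idx].logicalPremise = fact

    if params.with_geography:
        # one scoped override: a higher frequency inside a square region
        candidates = [s for s in statements if not s.is_numeric and s.frequency == 1.0]
        if candidates:
            base = rng.choice(candidates)
            base_alt = dc_replace(
                base,
                id=base.id + "_base",
                frequency=0.5,
            )
            scoped = dc_replace(
                base,
                id=base.id + "_scoped",
                frequency=0.9,
                geography=Region(
                    name="synthetic square",
                    polygon=[[[[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0], [0.0, 0.0]]]],
                ),
            )
            statements.remove(base)
            statements.extend([base_alt, scoped])

    key.characters = characters
    key.statements = statements
    return key


def _copy_key(key: Key) -> Key:
    return parse_key(serialize_key(key, validate=False))


def inject_defect(key: Key, defect_code: str, seed: int = 0) -> Key:
    """Return a copy of ``key`` with one minimal defect of the given kind.

    The mutated key still parses; codes that need a feature the key lacks
    (e.g. SHADOWED_INHERITED_STATEMENT on a flat key) raise
    :class:`ClavisError`.
    """
    if defect_code not in FINDING_CODES:
        raise ClavisError(f"unknown defect code {defect_code!r}")
    rng = random.Random(seed)
    key = _copy_key(key)
    chars = key.character_map()
    exclusive = [c for c in key.characters if c.type == EXCLUSIVE and c.states]
    cat_statements = [
        s for s in key.statements if not s.is_numeric and s.character in chars
    ]
    num_statements = [
        s
        for s in key.statements
        if s.is_numeric and s.character in chars and chars[s.character].is_numerical
    ]

    def need(seq, what):
        if not seq:
            raise ClavisError(f"defect {defect_code} not applicable: key has no {what}")
        return seq

    if defect_code == "DANGLING_REF":
        s = rng.choice(need(key.statements, "statements"))
        s.taxon = "taxon:does_not_exist"
    elif defect_code == "RANGE_OUT_OF_BOUNDS":
        s = rng.choice(need(num_statements, "numeric statements"))
        char = chars[s.character]
        s.value = [char.max + char.stepSize, char.max + 2 * char.stepSize]
    elif defect_code == "STEP_VIOLATION":
        s = rng.choice(need(num_statements, "numeric statements"))
        char = chars[s.character]
        s.value = [char.min + char.stepSize / 3.0, char.min + char.stepSize / 3.0]
    elif defect_code == "CONTRADICTORY_STATEMENTS":
        s = rng.choice(need(cat_statements, "categorical statements"))
        twin = Statement(
            id=s.id + "_contra",
            taxon=s.taxon,
            character=s.character,
            value=s.value,
            frequency=0.0 if s.frequency != 0.0 else 1.0,
        )
        key.statements.append(twin)
    elif defect_code == "MULTIPLE_ALWAYS_STATES":
        pool = [s for s in cat_statements if chars[s.character].type == EXCLUSIVE]
        s = rng.choice(need(pool, "exclusive-character statements"))
        char = chars[s.character]
        other = next(st.id for st in char.states if st.id != s.value)
        s.frequency = 1.0
        key.statements.append(
            Statement(
                id=s.id + "_also",
                taxon=s.taxon,
                character=s.character,
                value=other,
                frequency=1.0,
            )
        )
    elif defect_code == "NO_POSSIBLE_STATE":
        char = rng.choice(need(exclusive, "exclusive characters"))
        taxon = rng.choice(key.leaves())
        key.statements = [
            s for s in key.statements if not (s.taxon == taxon and s.character == char.id)
        ]
        for k, st in enumerate(char.states):
            key.statements.append(
                Statement(
                    id=f"statement:nps{k}",
                    taxon=taxon,
                    character=char.id,
                    value=st.id,
                    frequency=0.0,
                )
            )
    elif defect_code == "UNKNOWN_PREMISE_ID":
        char = rng.choice(need(list(chars.values()), "characters"))
        char.logicalPremise = "state:no_such_fact"
    elif defect_code == "PREMISE_CYCLE":
        cats = [c for c in key.characters if not c.is_numerical and c.states]
        if len(cats) < 2:
            raise ClavisError("defect PREMISE_CYCLE not applicable: needs 2 categorical characters")
        a, b = cats[0], cats[1]
        a.logicalPremise = b.states[0].id
        b.logicalPremise = a.states[0].id
    elif defect_code == "UNREACHABLE_STATE":
        char = rng.choice(need([c for c in key.characters if c.states], "categorical characters"))
        char.states.append(State(id="state:never_stated", title="never stated"))
    elif defect_code == "UNPREFIXED_ID":
        char = rng.choice(need([c for c in key.characters if c.states], "categorical characters"))
        st = char.states[0]
        bare = st.id.split(":", 1)[-1] + "_bare"
        for s in key.statements:
            if s.value == st.id:
                s.value = bare
        st.id = bare
    elif defect_code == "SHADOWED_INHERITED_STATEMENT":
        parents = key.parent_map()
        with_parent = [l for l in key.leaves() if parents.get(l)]
        leaf = rng.choice(need(with_parent, "hierarchy"))
        char = rng.choice(need(exclusive, "exclusive characters"))
        st = char.states[0].id
        key.statements = [
            s
            for s in key.statements
            if not (s.character == char.id and s.taxon in (leaf, parents[leaf]))
        ]
        key.statements.append(
            Statement(
                id="statement:shadow_up",
                taxon=parents[leaf],
                character=char.id,
                value=st,
                frequency=1.0,
            )
        )
        key.statements.append(
            Statement(
                id="statement:shadow_down",
                taxon=leaf,
                character=char.id,
                value=st,
                frequency=0.0,
            )
        )
    elif defect_code == "INDISTINGUISHABLE_PAIR":
        leaves = key.leaves()
        if len(leaves) < 2:
            raise ClavisError("defect INDISTINGUISHABLE_PAIR needs ≥ 2 leaves")
        a, b = leaves[0], leaves[1]
        key.statements = [s for s in key.statements if s.taxon != b]
        clones = []
        for s in key.statements:
            if s.taxon == a:
                clones.append(
                    Statement(
                        id=s.id + "_clone",
                        taxon=b,
                        character=s.character,
                        value=s.value,
                        frequency=s.frequency,
                        geography=s.geography,
                    )
                )
        key.statements.extend(clones)
    else:  # pragma: no cover - guarded by the FINDING_CODES check
        raise ClavisError(f"unhandled defect code {defect_code}")
    return key


# ---------------------------------------------------------------------------
# Hand-built fixtures
# ---------------------------------------------------------------------------


def fixture_fig2() -> Key:
    """The canonical four-taxon, two-character worked example.

    Color (exclusive) is scored for all four taxa, two per state; size
    (exclusive) is scored for three of the four, and the two taxa sharing a
    color state get different sizes.  The session therefore starts with
    only the color character visible, the color answer halves the
    candidates, size surfaces, and the size answer resolves the session.
    """
    taxa = [
        Taxon(id=f"taxon:t{i}", scientificName=f"Taxus exemplaris {i}") for i in (1, 2, 3, 4)
    ]
    color = Character(
        id="character:color",
        title="Color",
        type=EXCLUSIVE,
        states=[
            State(id="state:blue", title="Blue"),
            State(id="state:red", title="Red"),
        ],
    )
    size = Character(
        id="character:size",
        title="Size",
        type=EXCLUSIVE,
        states=[
            State(id="state:small", title="Small"),
            State(id="state:large", title="Large"),
        ],
    )
    cells = [
        ("taxon:t1", "character:color", "state:blue"),
        ("taxon:t2", "character:color", "state:blue"),
        ("taxon:t3", "character:color", "state:red"),
        ("taxon:t4", "character:color", "state:red"),
        ("taxon:t1", "character:size", "state:small"),
        ("taxon:t2", "character:size", "state:large"),
        ("taxon:t3", "character:size", "state:small"),
        # taxon:t4 deliberately unscored for size: the sparse cell that
        # keeps the size character hidden at the start
    ]
    statements = [
        Statement(id=f"statement:f{i}", taxon=t, character=c, value=v, frequency=1.0)
        for i, (t, c, v) in enumerate(cells, start=1)
    ]
    return Key(
        identifier="urn:clavis:example:fig2",
        title="Four taxa, two characters",
        schema=_SCHEMA_URL,
        license=_LICENSE_URL,
        language=["en"],
        created="2022-12-01",
        lastModified="2022-12-01",
        creators=["person:example"],
        persons=[{"id": "person:example", "name": "Example Author"}],
        taxa=taxa,
        characters=[color, size],
        statements=statements,
    )


def fixture_clavidae() -> Key:
    """A hierarchical demonstration key for the fictive family Clavidae.

    Three species, each with a default and a "Shiny" morph; the default
    morph of *Clavissima* is tagged as an endpoint and carries two sexes
    below it, so the session never asks a sex question once that morph is
    determined.  A body-shape statement sits at the family level and is
    inherited by every species; the color character is non-exclusive —
    species can carry several colors at once.
    """

    def species(name: str, with_sexes: bool = False) -> Taxon:
        sid = name.lower()
        default_children = []
        if with_sexes:
            default_children = [
                Taxon(id=f"taxon:{sid}_female", label="♀"),
                Taxon(id=f"taxon:{sid}_male", label="♂"),
            ]
        return Taxon(
            id=f"taxon:{sid}",
            scientificName=name,
            children=[
                Taxon(
                    id=f"taxon:{sid}_default",
                    label="",
                    isEndpoint=True if with_sexes else None,
                    children=default_children,
                ),
                Taxon(id=f"taxon:{sid}_shiny", label="Shiny"),
            ],
        )

    family = Taxon(
        id="taxon:clavidae",
        scientificName="Clavidae",
        children=[
            species("Clavis"),
            species("Clavella"),
            species("Clavissima", with_sexes=True),
        ],
    )

    body = Character(
        id="character:body",
        title="Body shape",
        type=EXCLUSIVE,
        states=[
            State(id="state:elongated", title="Elongated"),
            State(id="state:round", title="Round"),
        ],
    )
    antennae = Character(
        id="character:antennae",
        title="Antenna shape",
        type=EXCLUSIVE,
        states=[
            State(id="state:straight", title="Straight"),
            State(id="state:curved", title="Curved"),
            State(id="state:clubbed", title="Clubbed"),
        ],
    )
    sheen = Character(
        id="character:sheen",
        title="Surface sheen",
        type=EXCLUSIVE,
        states=[
            State(id="state:shiny", title="Shiny"),
            State(id="state:dull", title="Dull"),
        ],
    )
    color = Character(
        id="character:color",
        title="Colors",
        type=NON_EXCLUSIVE,
        states=[
            State(id="state:col_red", title="Red"),
            State(id="state:col_green", title="Green"),
            State(id="state:col_blue", title="Blue"),
        ],
    )
    ornament = Character(
        id="character:ornament",
        title="Frontal ornament",
        type=EXCLUSIVE,
        states=[
            State(id="state:orn_present", title="Present"),
            State(id="state:orn_absent", title="Absent"),
        ],
    )

    rows: list[tuple[str, str, str, float]] = [
        # family-level statements, inherited by every species
        ("taxon:clavidae", "character:body", "state:elongated", 1.0),
        ("taxon:clavidae", "character:body", "state:round", 0.0),
        # species separation
        ("taxon:clavis", "character:antennae", "state:straight", 1.0),
        ("taxon:clavella", "character:antennae", "state:curved", 1.0),
        ("taxon:clavissima", "character:antennae", "state:clubbed", 1.0),
        # morph separation (stated per morph; sexes inherit from the morph)
        ("taxon:clavis_default", "character:sheen", "state:dull", 1.0),
        ("taxon:clavis_shiny", "character:sheen", "state:shiny", 1.0),
        ("taxon:clavella_default", "character:sheen", "state:dull", 1.0),
        ("taxon:clavella_shiny", "character:sheen", "state:shiny", 1.0),
        ("taxon:clavissima_default", "character:sheen", "state:dull", 1.0),
        ("taxon:clavissima_shiny", "character:sheen", "state:shiny", 1.0),
        # non-exclusive colors: several colors per species at once
        ("taxon:clavis", "character:color", "state:col_red", 1.0),
        ("taxon:clavis", "character:color", "state:col_green", 1.0),
        ("taxon:clavella", "character:color", "state:col_red", 1.0),
        ("taxon:clavissima", "character:color", "state:col_green", 1.0),
        ("taxon:clavissima", "character:color", "state:col_blue", 1.0),
        ("taxon:clavissima", "character:color", "state:col_red", 0.0),
        # sexes of the endpoint morph (never asked in a session)
        ("taxon:clavissima_female", "character:ornament", "state:orn_present", 1.0),
        ("taxon:clavissima_male", "character:ornament", "state:orn_absent", 1.0),
    ]
    statements = [
        Statement(id=f"statement:cl{i:02d}", taxon=t, character=c, value=v, frequency=f)
        for i, (t, c, v, f) in enumerate(rows, start=1)
    ]
    return Key(
        identifier="urn:clavis:example:clavidae",
        title="Key to the Clavidae",
        schema=_SCHEMA_URL,
        license=_LICENSE_URL,
        language=["en"],
        created="2022-12-01",
        lastModified="2022-12-01",
        creators=["person:example"],
        persons=[{"id": "person:example", "name": "Example Author"}],
        taxa=[family],
        characters=[body, antennae, sheen, color, ornament],
        statements=statements,
    )
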