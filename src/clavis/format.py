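"""Domain types and serialization for the Clavis identification-key format.

A Clavis key is a JSON document holding three kinds of content — taxa,
characters and the statements linking the two — plus metadata (persons,
organizations, media, external services).  This module defines the in-memory
types, the JSON parser/serializer (with a canonical form), the structural
validator, localized-text resolution, and import/export of the tabular
sparse-matrix representation.

Unknown JSON fields are preserved opaquely in each object's ``extras``
mapping so that documents written by newer format revisions survive a
parse/serialize round trip.
"""

from __future__ import annotations

import csv
import io
import json
import math
import re
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional, Union

__all__ = [
    "LocalizedText",
    "Region",
    "Taxon",
    "State",
    "Character",
    "Statement",
    "Key",
    "Issue",
    "ClavisError",
    "ParseError",
    "StructureError",
    "SerializationError",
    "MatrixExportError",
    "ISSUE_CODES",
    "parse_key",
    "serialize_key",
    "validate_structure",
    "resolve_text",
    "import_matrix",
    "export_matrix",
]

# A localized text is either a plain string or a mapping from ISO 639-1
# language code to the string in that language.
LocalizedText = Union[str, dict]

EXCLUSIVE = "exclusive"
NON_EXCLUSIVE = "nonExclusive"
NUMERICAL = "numerical"
CHARACTER_TYPES = (EXCLUSIVE, NON_EXCLUSIVE, NUMERICAL)

#: Closed set of structural issue codes emitted by :func:`validate_structure`.
ISSUE_CODES = frozenset(
    {
        "MISSING_FIELD",
        "DUPLICATE_ID",
        "DANGLING_REF",
        "FREQUENCY_RANGE",
        "LANGUAGE_UNDECLARED",
        "LOCALIZED_EMPTY",
        "REGION_EMPTY",
        "RING_NOT_CLOSED",
        "RING_TOO_SHORT",
        "TAXON_NAME_CONFLICT",
        "SUBGROUP_ORPHAN",
        "STATE_EMPTY",
        "CHARACTER_SHAPE",
        "NUMERIC_BOUNDS",
        "VALUE_KIND_MISMATCH",
        "RANGE_OUT_OF_BOUNDS",
        "BAD_TYPE",
    }
)


class ClavisError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ClavisError):
    """The input is not syntactically valid JSON."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        super().__init__(message)
        self.line = line
        self.column = column


class StructureError(ClavisError):
    """The document is valid JSON but violates the format's structure."""

    def __init__(self, issues: list["Issue"]):
        self.issues = issues
        super().__init__("; ".join(f"{i.code} at {i.path}: {i.message}" for i in issues))


class SerializationError(ClavisError):
    """Serialization refused because the key is structurally invalid."""

    def __init__(self, issues: list["Issue"]):
        self.issues = issues
        super().__init__("; ".join(f"{i.code} at {i.path}" for i in issues))


class MatrixExportError(ClavisError):
    """The key uses features the CSV matrix dialect cannot represent."""

    def __init__(self, losses: list[str]):
        self.losses = losses
        super().__init__("lossy export refused: " + "; ".join(losses))


@dataclass
class Issue:
    """A single structural problem located within a document."""

    severity: str  # "error" | "warning"
    code: str
    path: str
    message: str


@dataclass
class Region:
    """A geographic region given by a name and/or a GeoJSON MultiPolygon.

    ``polygon`` holds raw MultiPolygon coordinates (a list of polygons, each a
    list of linear rings, each ring a list of ``[lon, lat]`` positions, first
    point repeated last).
    """

    name: Optional[LocalizedText] = None
    polygon: Optional[list] = None
    extras: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        d: dict[str, Any] = {}
        if self.name is not None:
            d["name"] = self.name
        if self.polygon is not None:
            d["polygon"] = self.polygon
        d.update(self.extras)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "Region":
        extras = {k: v for k, v in d.items() if k not in ("name", "polygon")}
        return cls(name=d.get("name"), polygon=d.get("polygon"), extras=extras)


@dataclass
class Taxon:
    """A node in the taxon forest.

    Proper taxa carry a ``scientificName``; sub-groups (sexes, morphs,
    castes …) carry a ``label`` instead — possibly the empty string for the
    default form of a taxon.  ``isEndpoint`` promotes a node above the leaf
    level to an identification endpoint: once it is the only candidate left,
    no further questions are asked.
    """

    id: str
    scientificName: Optional[str] = None
    label: Optional[LocalizedText] = None
    vernacularName: Optional[LocalizedText] = None
    isEndpoint: Optional[bool] = None
    children: list["Taxon"] = field(default_factory=list)
    geography: Optional[Region] = None
    externalResources: list = field(default_factory=list)
    followup: Optional[Any] = None
    media: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    _FIELDS = (
        "id",
        "scientificName",
        "label",
        "vernacularName",
        "isEndpoint",
        "children",
        "geography",
        "externalResources",
        "followup",
        "media",
    )

    def to_json(self) -> dict:
        d: dict[str, Any] = {"id": self.id}
        if self.scientificName is not None:
            d["scientificName"] = self.scientificName
        if self.label is not None:
            d["label"] = self.label
        if self.vernacularName is not None:
            d["vernacularName"] = self.vernacularName
        if self.isEndpoint is not None:
            d["isEndpoint"] = self.isEndpoint
        if self.children:
            d["children"] = [c.to_json() for c in self.children]
        if self.geography is not None:
            d["geography"] = self.geography.to_json()
        if self.externalResources:
            d["externalResources"] = self.externalResources
        if self.followup is not None:
            d["followup"] = self.followup
        if self.media:
            d["media"] = self.media
        d.update(self.extras)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "Taxon":
        extras = {k: v for k, v in d.items() if k not in cls._FIELDS}
        return cls(
            id=d.get("id", ""),
            scientificName=d.get("scientificName"),
            label=d.get("label"),
            vernacularName=d.get("vernacularName"),
            isEndpoint=d.get("isEndpoint"),
            children=[cls.from_json(c) for c in d.get("children", [])],
            geography=Region.from_json(d["geography"]) if "geography" in d else None,
            externalResources=d.get("externalResources", []),
            followup=d.get("followup"),
            media=d.get("media", []),
            extras=extras,
        )

    @property
    def is_subgroup(self) -> bool:
        return self.scientificName is None and self.label is not None


@dataclass
class State:
    """A possible answer of a categorical character.

    States need a title or at least one media element (image-only keys).
    """

    id: str
    title: Optional[LocalizedText] = None
    media: list = field(default_factory=list)
    descriptions: Optional[Any] = None
    extras: dict = field(default_factory=dict)

    _FIELDS = ("id", "title", "media", "descriptions")

    def to_json(self) -> dict:
        d: dict[str, Any] = {"id": self.id}
        if self.title is not None:
            d["title"] = self.title
        if self.media:
            d["media"] = self.media
        if self.descriptions is not None:
            d["descriptions"] = self.descriptions
        d.update(self.extras)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "State":
        extras = {k: v for k, v in d.items() if k not in cls._FIELDS}
        return cls(
            id=d.get("id", ""),
            title=d.get("title"),
            media=d.get("media", []),
            descriptions=d.get("descriptions"),
            extras=extras,
        )


@dataclass
class Character:
    """A question posed to the user.

    Categorical characters (``exclusive`` — states mutually exclusive — or
    ``nonExclusive``) carry a list of states; numerical characters carry
    ``min``/``max``/``stepSize``/``unit``.  A ``logicalPremise`` is a
    three-valued boolean expression over established facts that must be TRUE
    before the character is shown.
    """

    id: str
    title: Optional[LocalizedText] = None
    type: str = EXCLUSIVE
    states: list[State] = field(default_factory=list)
    min: Optional[float] = None
    max: Optional[float] = None
    stepSize: Optional[float] = None
    unit: Optional[str] = None
    logicalPremise: Optional[str] = None
    userRequirement: Optional[str] = None
    media: list = field(default_factory=list)
    descriptions: Optional[Any] = None
    extras: dict = field(default_factory=dict)

    _FIELDS = (
        "id",
        "title",
        "type",
        "states",
        "min",
        "max",
        "stepSize",
        "unit",
        "logicalPremise",
        "userRequirement",
        "media",
        "descriptions",
    )

    @property
    def is_numerical(self) -> bool:
        return self.type == NUMERICAL

    def to_json(self) -> dict:
        d: dict[str, Any] = {"id": self.id}
        if self.title is not None:
            d["title"] = self.title
        if self.type != EXCLUSIVE:
            d["type"] = self.type
        if self.states:
            d["states"] = [s.to_json() for s in self.states]
        if self.min is not None:
            d["min"] = self.min
        if self.max is not None:
            d["max"] = self.max
        if self.stepSize is not None:
            d["stepSize"] = self.stepSize
        if self.unit is not None:
            d["unit"] = self.unit
        if self.logicalPremise is not None:
            d["logicalPremise"] = self.logicalPremise
        if self.userRequirement is not None:
            d["userRequirement"] = self.userRequirement
        if self.media:
            d["media"] = self.media
        if self.descriptions is not None:
            d["descriptions"] = self.descriptions
        d.update(self.extras)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "Character":
        extras = {k: v for k, v in d.items() if k not in cls._FIELDS}
        return cls(
            id=d.get("id", ""),
            title=d.get("title"),
            type=d.get("type", EXCLUSIVE),
            states=[State.from_json(s) for s in d.get("states", [])],
            min=d.get("min"),
            max=d.get("max"),
            stepSize=d.get("stepSize"),
            unit=d.get("unit"),
            logicalPremise=d.get("logicalPremise"),
            userRequirement=d.get("userRequirement"),
            media=d.get("media", []),
            descriptions=d.get("descriptions"),
            extras=extras,
        )


@dataclass
class Statement:
    """The atomic knowledge unit: taxon × character → value, with a frequency.

    ``value`` is a state id for categorical characters, or a ``[low, high]``
    numeric range for numerical ones (a single number is normalized to the
    degenerate range ``[v, v]``).  ``frequency`` is the proportion of
    individuals of the taxon showing the value: 1 = always, 0 = never,
    anything in between = polymorphism.  A statement may be scoped to a
    geographic region, in which case it takes precedence over a conflicting
    unscoped statement when the observation lies inside the region.
    """

    id: str
    taxon: str = ""
    character: str = ""
    value: Any = None
    frequency: float = 1.0
    geography: Optional[Region] = None
    media: list = field(default_factory=list)
    descriptions: Optional[Any] = None
    extras: dict = field(default_factory=dict)

    _FIELDS = (
        "id",
        "taxon",
        "character",
        "value",
        "frequency",
        "geography",
        "media",
        "descriptions",
    )

    @property
    def is_numeric(self) -> bool:
        return isinstance(self.value, list)

    def to_json(self) -> dict:
        d: dict[str, Any] = {
            "id": self.id,
            "taxon": self.taxon,
            "character": self.character,
            "value": self.value,
            "frequency": self.frequency,
        }
        if self.geography is not None:
            d["geography"] = self.geography.to_json()
        if self.media:
            d["media"] = self.media
        if self.descriptions is not None:
            d["descriptions"] = self.descriptions
        d.update(self.extras)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "Statement":
        extras = {k: v for k, v in d.items() if k not in cls._FIELDS}
        value = d.get("value")
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            value = [float(value), float(value)]
        elif isinstance(value, list):
            value = [float(v) if isinstance(v, (int, float)) else v for v in value]
        freq = d.get("frequency", 1.0)
        if isinstance(freq, (int, float)) and not isinstance(freq, bool):
            freq = float(freq)
        return cls(
            id=d.get("id", ""),
            taxon=d.get("taxon", ""),
            character=d.get("character", ""),
            value=value,
            frequency=freq,
            geography=Region.from_json(d["geography"]) if "geography" in d else None,
            media=d.get("media", []),
            descriptions=d.get("descriptions"),
            extras=extras,
        )


#: Mandatory top-level fields of a key document.
MANDATORY_KEY_FIELDS = (
    "identifier",
    "title",
    "schema",
    "license",
    "language",
    "created",
    "lastModified",
    "creator",
    "taxa",
    "characters",
    "statements",
)

_KEY_FIELDS = MANDATORY_KEY_FIELDS + (
    "media",
    "description",
    "audience",
    "source",
    "geography",
    "contributors",
    "publishers",
    "persons",
    "organizations",
    "mediaElements",
    "externalServices",
    "userRequirements",
    "url",
)


@dataclass
class Key:
    """A complete identification key document."""

    identifier: str = ""
    title: Optional[LocalizedText] = None
    schema: Optional[str] = None
    license: Optional[str] = None
    language: list[str] = field(default_factory=list)
    created: Optional[str] = None
    lastModified: Optional[str] = None
    creators: list[str] = field(default_factory=list)
    taxa: list[Taxon] = field(default_factory=list)
    characters: list[Character] = field(default_factory=list)
    statements: list[Statement] = field(default_factory=list)
    media: list = field(default_factory=list)
    description: Optional[Any] = None
    audience: Optional[LocalizedText] = None
    source: Optional[Any] = None
    geography: Optional[Region] = None
    contributors: list[str] = field(default_factory=list)
    publishers: list[str] = field(default_factory=list)
    persons: list[dict] = field(default_factory=list)
    organizations: list[dict] = field(default_factory=list)
    mediaElements: list[dict] = field(default_factory=list)
    externalServices: list[dict] = field(default_factory=list)
    userRequirements: list[dict] = field(default_factory=list)
    url: Optional[Any] = None
    extras: dict = field(default_factory=dict)
    missing_fields: list[str] = field(default_factory=list, compare=False)

    # -- indexes -----------------------------------------------------------

    def iter_taxa(self) -> Iterator[tuple[Taxon, Optional[Taxon]]]:
        """Yield every taxon node with its parent (None for roots)."""

        def walk(node: Taxon, parent: Optional[Taxon]):
            yield node, parent
            for c in node.children:
                yield from walk(c, node)

        for root in self.taxa:
            yield from walk(root, None)

    def taxon_map(self) -> dict[str, Taxon]:
        return {t.id: t for t, _ in self.iter_taxa()}

    def parent_map(self) -> dict[str, Optional[str]]:
        return {t.id: (p.id if p else None) for t, p in self.iter_taxa()}

    def ancestors(self, taxon_id: str) -> list[str]:
        """Ids from the taxon itself up to its root, nearest first."""
        parents = self.parent_map()
        chain = [taxon_id]
        cur = parents.get(taxon_id)
        while cur is not None:
            chain.append(cur)
            cur = parents.get(cur)
        return chain

    def leaves(self) -> list[str]:
        return [t.id for t, _ in self.iter_taxa() if not t.children]

    def character_map(self) -> dict[str, Character]:
        return {c.id: c for c in self.characters}

    def state_owner(self) -> dict[str, str]:
        """Map each state id to the id of the character that owns it."""
        return {s.id: c.id for c in self.characters for s in c.states}

    def statements_for(self, character_id: str) -> list[Statement]:
        return [s for s in self.statements if s.character == character_id]

    # -- JSON --------------------------------------------------------------

    def to_json(self) -> dict:
        d: dict[str, Any] = {
            "identifier": self.identifier,
            "title": self.title,
            "schema": self.schema,
            "license": self.license,
            "language": self.language,
            "created": self.created,
            "lastModified": self.lastModified,
        }
        # The printed dialect uses a singular "creator" (a person id or a
        # list of them); normalize to a string when there is exactly one.
        d["creator"] = self.creators[0] if len(self.creators) == 1 else self.creators
        d["taxa"] = [t.to_json() for t in self.taxa]
        d["characters"] = [c.to_json() for c in self.characters]
        d["statements"] = [s.to_json() for s in self.statements]
        for name in (
            "media",
            "description",
            "audience",
            "source",
            "contributors",
            "publishers",
            "url",
        ):
            v = getattr(self, name)
            if v not in (None, [], {}):
                d[name] = v
        if self.geography is not None:
            d["geography"] = self.geography.to_json()
        for name in (
            "persons",
            "organizations",
            "mediaElements",
            "externalServices",
            "userRequirements",
        ):
            v = getattr(self, name)
            if v:
                d[name] = v
        d.update(self.extras)
        for f in self.missing_fields:
            d.pop(f, None)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "Key":
        extras = {k: v for k, v in d.items() if k not in _KEY_FIELDS}
        creator = d.get("creator", [])
        creators = [creator] if isinstance(creator, str) else list(creator)
        missing = [f for f in MANDATORY_KEY_FIELDS if f not in d]
        return cls(
            identifier=d.get("identifier", ""),
            title=d.get("title"),
            schema=d.get("schema"),
            license=d.get("license"),
            language=d.get("language", []),
            created=d.get("created"),
            lastModified=d.get("lastModified"),
            creators=creators,
            taxa=[Taxon.from_json(t) for t in d.get("taxa", [])],
            characters=[Character.from_json(c) for c in d.get("characters", [])],
            statements=[Statement.from_json(s) for s in d.get("statements", [])],
            media=d.get("media", []),
            description=d.get("description"),
            audience=d.get("audience"),
            source=d.get("source"),
            geography=Region.from_json(d["geography"]) if "geography" in d else None,
            contributors=d.get("contributors", []),
            publishers=d.get("publishers", []),
            persons=d.get("persons", []),
            organizations=d.get("organizations", []),
            mediaElements=d.get("mediaElements", []),
            externalServices=d.get("externalServices", []),
            userRequirements=d.get("userRequirements", []),
            url=d.get("url"),
            extras=extras,
            missing_fields=missing,
        )


# ---------------------------------------------------------------------------
# Parse / serialize
# ---------------------------------------------------------------------------


def parse_key(text: str, strict: bool = True) -> Key:
    """Parse a Clavis JSON document into a fully linked :class:`Key`.

    Defaults are applied (character type ``exclusive``, frequency 1.0, a
    single numeric statement value normalized to a degenerate range) and
    unknown fields are preserved for round-tripping.

    With ``strict`` (default), a missing mandatory top-level field raises
    :class:`StructureError` listing each absent field; with
    ``strict=False`` the permissive Key is returned so that
    :func:`validate_structure` can report the problems as issues instead.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON: {e.msg}", line=e.lineno, column=e.colno) from e
    if not isinstance(doc, dict):
        raise ParseError("top-level JSON value must be an object")
    key = Key.from_json(doc)
    if strict and key.missing_fields:
        raise StructureError(
            [
                Issue("error", "MISSING_FIELD", f"/{f}", f"mandatory field '{f}' is missing")
                for f in key.missing_fields
            ]
        )
    return key


def serialize_key(key: Key, canonical: bool = True, validate: bool = True) -> str:
    """Serialize a key to JSON text.

    Canonical form sorts object keys lexicographically, uses two-space
    indentation, UTF-8 with LF line endings and shortest round-trip float
    formatting, so equal keys serialize to byte-identical text.  With
    ``validate`` (default) serialization is refused, with the issue list,
    when the key has structural errors such as unresolved references.
    """
    if validate:
        issues = [i for i in validate_structure(key) if i.severity == "error"]
        if issues:
            raise SerializationError(issues)
    doc = key.to_json()
    if canonical:
        return json.dumps(doc, ensure_ascii=False, sort_keys=True, indent=2) + "\n"
    return json.dumps(doc, ensure_ascii=False, indent=2) + "\n"


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------


def _check_localized(
    t: Any, path: str, languages: list[str], issues: list[Issue], optional_empty: bool = False
) -> None:
    if t is None or isinstance(t, str):
        return
    if isinstance(t, dict):
        if not t:
            issues.append(
                Issue("error", "LOCALIZED_EMPTY", path, "localized string mapping is empty")
            )
            return
        for code in t:
            if code not in languages:
                issues.append(
                    Issue(
                        "error",
                        "LANGUAGE_UNDECLARED",
                        f"{path}/{code}",
                        f"language '{code}' is not declared in the key's language list",
                    )
                )
    else:
        issues.append(Issue("error", "BAD_TYPE", path, "expected string or language mapping"))


def _check_region(r: Region, path: str, languages: list[str], issues: list[Issue]) -> None:
    if r.name is None and r.polygon is None:
        issues.append(
            Issue("error", "REGION_EMPTY", path, "region needs a name and/or a polygon")
        )
    _check_localized(r.name, f"{path}/name", languages, issues)
    if r.polygon is not None:
        for i, poly in enumerate(r.polygon):
            for j, ring in enumerate(poly):
                rpath = f"{path}/polygon/{i}/{j}"
                if len(ring) < 4:
                    issues.append(
                        Issue("error", "RING_TOO_SHORT", rpath, "ring has fewer than 4 points")
                    )
                elif ring[0] != ring[-1]:
                    issues.append(
                        Issue(
                            "error",
                            "RING_NOT_CLOSED",
                            rpath,
                            "first and last point of a ring must coincide",
                        )
                    )


def validate_structure(key: Key) -> list[Issue]:
    """Check every structural invariant of the format; return found issues.

    Purely structural — logical completeness/consistency checks live in
    :mod:`clavis.lint`.  An empty list means the document is compliant.
    """
    issues: list[Issue] = []
    langs = key.language or []

    for f in key.missing_fields:
        issues.append(
            Issue("error", "MISSING_FIELD", f"/{f}", f"mandatory field '{f}' is missing")
        )
    if "creator" not in key.missing_fields and not key.creators:
        issues.append(Issue("error", "MISSING_FIELD", "/creator", "key needs ≥1 creator"))

    _check_localized(key.title, "/title", langs, issues)
    if key.geography is not None:
        _check_region(key.geography, "/geography", langs, issues)

    # -- id uniqueness across the whole document
    seen: dict[str, str] = {}

    def register(obj_id: str, path: str) -> None:
        if obj_id in seen:
            issues.append(
                Issue(
                    "error",
                    "DUPLICATE_ID",
                    path,
                    f"id '{obj_id}' already used at {seen[obj_id]}",
                )
            )
        else:
            seen[obj_id] = path

    person_ids = set()
    for i, p in enumerate(key.persons):
        pid = p.get("id")
        if pid:
            register(pid, f"/persons/{i}")
            person_ids.add(pid)
    org_ids = set()
    for i, o in enumerate(key.organizations):
        oid = o.get("id")
        if oid:
            register(oid, f"/organizations/{i}")
            org_ids.add(oid)
    media_ids = set()
    for i, m in enumerate(key.mediaElements):
        mid = m.get("id")
        if mid:
            register(mid, f"/mediaElements/{i}")
            media_ids.add(mid)
    service_ids = set()
    for i, s in enumerate(key.externalServices):
        sid = s.get("id")
        if sid:
            register(sid, f"/externalServices/{i}")
            service_ids.add(sid)
    req_ids = set()
    for i, r in enumerate(key.userRequirements):
        rid = r.get("id")
        if rid:
            register(rid, f"/userRequirements/{i}")
            req_ids.add(rid)

    def dangling(ref: str, path: str, what: str) -> None:
        issues.append(
            Issue("error", "DANGLING_REF", path, f"{what} '{ref}' does not resolve")
        )

    def check_media_refs(media: list, path: str) -> None:
        for i, m in enumerate(media):
            if isinstance(m, str) and m not in media_ids:
                dangling(m, f"{path}/{i}", "media element")

    # -- taxa
    taxon_ids: set[str] = set()

    def walk_taxon(t: Taxon, path: str, named_ancestor: bool) -> None:
        register(t.id, path)
        taxon_ids.add(t.id)
        has_name = t.scientificName is not None
        has_label = t.label is not None
        if has_name == has_label:
            issues.append(
                Issue(
                    "error",
                    "TAXON_NAME_CONFLICT",
                    path,
                    "a taxon needs a scientificName or (exclusively) a sub-group label",
                )
            )
        if has_label and not has_name and not named_ancestor:
            issues.append(
                Issue(
                    "error",
                    "SUBGROUP_ORPHAN",
                    path,
                    "a sub-group must sit below at least one named taxon",
                )
            )
        _check_localized(t.label, f"{path}/label", langs, issues)
        _check_localized(t.vernacularName, f"{path}/vernacularName", langs, issues)
        if t.geography is not None:
            _check_region(t.geography, f"{path}/geography", langs, issues)
        check_media_refs(t.media, f"{path}/media")
        for i, res in enumerate(t.externalResources):
            sid = res.get("serviceId") if isinstance(res, dict) else None
            if sid and sid not in service_ids:
                dangling(sid, f"{path}/externalResources/{i}/serviceId", "external service")
        for i, c in enumerate(t.children):
            walk_taxon(c, f"{path}/children/{i}", named_ancestor or has_name)

    for i, t in enumerate(key.taxa):
        walk_taxon(t, f"/taxa/{i}", False)

    # -- characters and states
    state_owner: dict[str, str] = {}
    char_ids: set[str] = set()
    for i, c in enumerate(key.characters):
        path = f"/characters/{i}"
        register(c.id, path)
        char_ids.add(c.id)
        _check_localized(c.title, f"{path}/title", langs, issues)
        check_media_refs(c.media, f"{path}/media")
        if c.type not in CHARACTER_TYPES:
            issues.append(
                Issue("error", "BAD_TYPE", f"{path}/type", f"unknown character type '{c.type}'")
            )
        if c.userRequirement is not None and c.userRequirement not in req_ids:
            dangling(c.userRequirement, f"{path}/userRequirement", "user requirement")
        if c.is_numerical:
            if c.states:
                issues.append(
                    Issue(
                        "error",
                        "CHARACTER_SHAPE",
                        path,
                        "a numerical character must not carry states",
                    )
                )
            if c.min is None or c.max is None or c.stepSize is None:
                issues.append(
                    Issue(
                        "error",
                        "CHARACTER_SHAPE",
                        path,
                        "a numerical character needs min, max and stepSize",
                    )
                )
            else:
                if not c.min < c.max:
                    issues.append(
                        Issue("error", "NUMERIC_BOUNDS", f"{path}/min", "min must be < max")
                    )
                if not c.stepSize > 0:
                    issues.append(
                        Issue(
                            "error",
                            "NUMERIC_BOUNDS",
                            f"{path}/stepSize",
                            "stepSize must be > 0",
                        )
                    )
        else:
            if any(v is not None for v in (c.min, c.max, c.stepSize, c.unit)):
                issues.append(
                    Issue(
                        "error",
                        "CHARACTER_SHAPE",
                        path,
                        "a categorical character must not carry numeric bounds",
                    )
                )
            if len(c.states) < 2:
                issues.append(
                    Issue(
                        "error",
                        "CHARACTER_SHAPE",
                        path,
                        "a categorical character needs at least two states",
                    )
                )
        for j, s in enumerate(c.states):
            spath = f"{path}/states/{j}"
            register(s.id, spath)
            state_owner[s.id] = c.id
            _check_localized(s.title, f"{spath}/title", langs, issues)
            check_media_refs(s.media, f"{spath}/media")
            if s.title is None and not s.media:
                issues.append(
                    Issue(
                        "error",
                        "STATE_EMPTY",
                        spath,
                        "a state needs a title or at least one media element",
                    )
                )

    # -- statements
    char_by_id = key.character_map()
    for i, s in enumerate(key.statements):
        path = f"/statements/{i}"
        register(s.id, path)
        if s.taxon not in taxon_ids:
            dangling(s.taxon, f"{path}/taxon", "taxon")
        check_media_refs(s.media, f"{path}/media")
        if s.geography is not None:
            _check_region(s.geography, f"{path}/geography", langs, issues)
        if not (
            isinstance(s.frequency, (int, float))
            and not isinstance(s.frequency, bool)
            and 0.0 <= s.frequency <= 1.0
        ):
            issues.append(
                Issue(
                    "error",
                    "FREQUENCY_RANGE",
                    f"{path}/frequency",
                    f"frequency {s.frequency!r} outside [0, 1]",
                )
            )
        if s.character not in char_ids:
            dangling(s.character, f"{path}/character", "character")
            continue
        char = char_by_id[s.character]
        if char.is_numerical:
            if not (
                isinstance(s.value, list)
                and len(s.value) == 2
                and all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in s.value)
            ):
                issues.append(
                    Issue(
                        "error",
                        "VALUE_KIND_MISMATCH",
                        f"{path}/value",
                        "numerical character requires a number or [low, high] range",
                    )
                )
            else:
                low, high = s.value
                if low > high:
                    issues.append(
                        Issue(
                            "error",
                            "RANGE_OUT_OF_BOUNDS",
                            f"{path}/value",
                            f"range low {low} exceeds high {high}",
                        )
                    )
                elif char.min is not None and char.max is not None and (
                    low < char.min - 1e-9 or high > char.max + 1e-9
                ):
                    issues.append(
                        Issue(
                            "error",
                            "RANGE_OUT_OF_BOUNDS",
                            f"{path}/value",
                            f"range [{low}, {high}] outside character bounds"
                            f" [{char.min}, {char.max}]",
                        )
                    )
        else:
            if not isinstance(s.value, str):
                issues.append(
                    Issue(
                        "error",
                        "VALUE_KIND_MISMATCH",
                        f"{path}/value",
                        "categorical character requires a state id value",
                    )
                )
            elif state_owner.get(s.value) != char.id:
                dangling(s.value, f"{path}/value", "state of this character")

    # -- role references
    for i, pid in enumerate(key.creators):
        if pid not in person_ids:
            dangling(pid, f"/creator/{i}", "person")
    for i, pid in enumerate(key.contributors):
        if pid not in person_ids and pid not in org_ids:
            dangling(pid, f"/contributors/{i}", "person or organization")
    for i, pid in enumerate(key.publishers):
        if pid not in person_ids and pid not in org_ids:
            dangling(pid, f"/publishers/{i}", "person or organization")
    check_media_refs(key.media, "/media")

    return issues


# ---------------------------------------------------------------------------
# Localized text resolution
# ---------------------------------------------------------------------------


def resolve_text(
    t: LocalizedText, requested: str, key_languages: list[str], path: str = "<text>"
) -> str:
    """Resolve a localized string for a requested language.

    A plain string resolves to itself.  A mapping resolves to the requested
    language's entry when present, otherwise to the first available entry in
    the key's declared language order.
    """
    if not key_languages:
        raise ClavisError("key_languages must be non-empty")
    if isinstance(t, str):
        return t
    if isinstance(t, dict):
        if requested in t:
            return t[requested]
        for lang in key_languages:
            if lang in t:
                return t[lang]
        raise ClavisError(f"no resolvable language entry at {path}: have {sorted(t)}")
    raise ClavisError(f"not a localized string at {path}: {t!r}")


# ---------------------------------------------------------------------------
# CSV matrix import / export
# ---------------------------------------------------------------------------

_NUM_TOKEN = re.compile(r"^-?\d+(?:\.\d+)?(?:\.\.(-?\d+(?:\.\d+)?))?$")
_ID_TOKEN = re.compile(r"^[A-Za-z_][\w:.\-]*$")


def _fmt_number(v: float) -> str:
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def _fmt_cell_token(s: Statement) -> str:
    if s.is_numeric:
        low, high = s.value
        tok = _fmt_number(low) if low == high else f"{_fmt_number(low)}..{_fmt_number(high)}"
    else:
        tok = s.value
    if s.frequency != 1.0:
        tok += f":{_fmt_number(s.frequency) if s.frequency in (0.0, 1.0) else repr(s.frequency)}"
    return tok


def export_matrix(key: Key, force: bool = False) -> str:
    """Export a key as a sparse taxa × characters CSV matrix.

    The dialect is lossless only for flat, premise-free, geography-free
    keys; exporting anything else is refused with the list of lossy
    features unless ``force`` is given (hierarchy is then flattened to its
    leaves, geography-scoped statements are dropped and premises ignored).
    """
    losses: list[str] = []
    if any(t.children for t in key.taxa):
        losses.append("taxon hierarchy deeper than one level")
    if key.geography is not None or any(
        t.geography is not None for t, _ in key.iter_taxa()
    ) or any(s.geography is not None for s in key.statements):
        losses.append("geographic scope on the key, a taxon or a statement")
    premised = [c.id for c in key.characters if c.logicalPremise]
    for cid in premised:
        losses.append(f"logical premise on {cid}")
    if losses and not force:
        raise MatrixExportError(losses)

    leaf_ids = key.leaves()
    out = io.StringIO()
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(["taxon"] + [c.id for c in key.characters])
    by_cell: dict[tuple[str, str], list[Statement]] = {}
    for s in key.statements:
        if s.geography is not None:
            continue
        by_cell.setdefault((s.taxon, s.character), []).append(s)
    for tid in leaf_ids:
        row = [tid]
        for c in key.characters:
            row.append(";".join(_fmt_cell_token(s) for s in by_cell.get((tid, c.id), [])))
        writer.writerow(row)
    return out.getvalue()


def _parse_cell_token(tok: str) -> tuple[str | list, float]:
    """Split a cell token into (value, frequency)."""
    freq = 1.0
    head, sep, tail = tok.rpartition(":")
    if sep:
        try:
            freq = float(tail)
            tok = head
        except ValueError:
            pass
    m = _NUM_TOKEN.match(tok)
    if m:
        if m.group(1) is not None:
            low = float(tok.split("..")[0])
            high = float(m.group(1))
        else:
            low = high = float(tok)
        return [low, high], freq
    if not _ID_TOKEN.match(tok):
        raise ValueError(f"malformed cell token {tok!r}")
    return tok, freq


def import_matrix(
    csv_text: str,
    declared_states: Optional[dict[str, list[str]]] = None,
    identifier: str = "urn:clavis:matrix-import",
) -> Key:
    """Import a sparse taxa × characters CSV matrix as a flat key.

    One statement is produced per non-empty cell token; an empty cell means
    the taxon is simply not scored for that character.  Column kinds are
    inferred from their tokens (all numeric → numerical character, with
    min/max/stepSize inferred from the observed ranges; otherwise an
    exclusive categorical character whose states are collected from the
    column).  ``declared_states`` may map character ids to their allowed
    state ids, in which case an unknown state token is a structural error
    reported with its row and column.
    """
    rows = list(csv.reader(io.StringIO(csv_text)))
    rows = [r for r in rows if r]
    issues: list[Issue] = []
    if not rows or not rows[0] or rows[0][0] != "taxon":
        raise StructureError(
            [Issue("error", "MISSING_FIELD", "/0/0", "header row must start with 'taxon'")]
        )
    char_ids = rows[0][1:]
    body = rows[1:]
    if not body:
        raise StructureError(
            [Issue("error", "MISSING_FIELD", "/", "matrix contains no taxa")]
        )

    # Parse all cells first so column kinds can be inferred.
    cells: dict[tuple[int, int], list[tuple[Any, float]]] = {}
    for r, row in enumerate(body):
        for cidx, cell in enumerate(row[1:]):
            cell = cell.strip()
            if not cell:
                continue
            parsed = []
            for tok in cell.split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                try:
                    parsed.append(_parse_cell_token(tok))
                except ValueError as e:
                    issues.append(
                        Issue("error", "VALUE_KIND_MISMATCH", f"/{r + 2}/{cidx + 2}", str(e))
                    )
            cells[(r, cidx)] = parsed
    if issues:
        raise StructureError(issues)

    characters: list[Character] = []
    for cidx, cid in enumerate(char_ids):
        toks = [v for (r, c), vs in sorted(cells.items()) if c == cidx for v, _ in vs]
        numeric = toks and all(isinstance(v, list) for v in toks)
        if numeric:
            lows = [v[0] for v in toks]
            highs = [v[1] for v in toks]
            decimals = max(
                (len(str(x).split(".")[1]) if "." in str(x) and str(x).split(".")[1] != "0" else 0)
                for x in lows + highs
            )
            step = 10.0 ** -decimals
            characters.append(
                Character(
                    id=cid,
                    title=_local_name(cid),
                    type=NUMERICAL,
                    min=float(math.floor(min(lows))),
                    max=float(math.ceil(max(highs))),
                    stepSize=step,
                    unit="",
                )
            )
        else:
            if declared_states and cid in declared_states:
                state_ids = list(declared_states[cid])
                allowed = set(state_ids)
                for (r, c), vs in sorted(cells.items()):
                    if c != cidx:
                        continue
                    for v, _ in vs:
                        if isinstance(v, str) and v not in allowed:
                            issues.append(
                                Issue(
                                    "error",
                                    "DANGLING_REF",
                                    f"/{r + 2}/{cidx + 2}",
                                    f"state '{v}' is not declared for {cid}",
                                )
                            )
            else:
                state_ids = []
                for (r, c), vs in sorted(cells.items()):
                    if c == cidx:
                        for v, _ in vs:
                            if isinstance(v, str) and v not in state_ids:
                                state_ids.append(v)
            # Categorical characters need ≥2 states; pad single-state columns
            # with a synthetic complement so the imported key is valid.
            while len(state_ids) < 2:
                state_ids.append(f"state:{_local_name(cid)}_unobserved{len(state_ids)}")
            characters.append(
                Character(
                    id=cid,
                    title=_local_name(cid),
                    type=EXCLUSIVE,
                    states=[State(id=sid, title=_local_name(sid)) for sid in state_ids],
                )
            )
    if issues:
        raise StructureError(issues)

    taxa = [Taxon(id=row[0], scientificName=_local_name(row[0])) for row in body]
    statements: list[Statement] = []
    n = 0
    for r, row in enumerate(body):
        for cidx in range(len(char_ids)):
            for v, freq in cells.get((r, cidx), []):
                n += 1
                statements.append(
                    Statement(
                        id=f"statement:m{n}",
                        taxon=row[0],
                        character=char_ids[cidx],
                        value=v,
                        frequency=freq,
                    )
                )

    return Key(
        identifier=identifier,
        title="Imported matrix key",
        schema="https://clavis.no/schema/1.0",
        license="https://creativecommons.org/licenses/by/4.0/",
        language=["en"],
        created="1970-01-01",
        lastModified="1970-01-01",
        creators=["person:importer"],
        persons=[{"id": "person:importer", "name": "Matrix importer"}],
        taxa=taxa,
        characters=characters,
        statements=statements,
    )


def _local_name(obj_id: str) -> str:
    """Human-ish title from an id like 'character:color' → 'color'."""
    return obj_id.split(":", 1)[-1].replace("_", " ")
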