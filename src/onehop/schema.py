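"""Semantic layer: category and predicate hierarchies with predicate metadata.

The schema plays the role the Biolink Model plays for production biomedical
knowledge graphs: two rooted DAGs of labels (node *categories* and edge
*predicates*), where each predicate additionally declares whether it is
*symmetric* (``A interacts_with B`` entails ``B interacts_with A``), whether
it is the *canonical* direction of an inverse pair, and the label of its
*inverse* if it has one.  Ancestor/descendant closures over both hierarchies
are precomputed at load time into plain ``dict[str, frozenset[str]]`` tables
so that every query-time hierarchy question is a single dictionary lookup.

Schema documents are small YAML or JSON files::

    categories:
      - {name: NamedThing}
      - {name: ChemicalEntity, parents: [NamedThing]}
    predicates:
      - {name: related_to, symmetric: true}
      - {name: treats, parents: [related_to], canonical: true, inverse: treated_by}
      - {name: treated_by, parents: [related_to], inverse: treats}

Labels may carry a ``biolink:`` prefix in input documents and KGX files; it
is stripped at parse time and matching is case-sensitive thereafter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import yaml

from .errors import SchemaInvalidError, UnknownElementError

logger = logging.getLogger(__name__)

Kind = Literal["category", "predicate"]

_PREFIX = "biolink:"

#: Fields understood in schema element entries; anything else is ignored
#: with a warning so documents can carry extra annotations.
_KNOWN_FIELDS = {"name", "parents", "symmetric", "canonical", "inverse", "description"}


def strip_prefix(label: str) -> str:
    """Drop an optional ``biolink:`` CURIE prefix from a schema label."""
    if label.startswith(_PREFIX):
        return label[len(_PREFIX):]
    return label


@dataclass(frozen=True)
class SchemaElement:
    """One category or predicate in the semantic layer."""

    name: str
    kind: Kind
    parents: tuple[str, ...] = ()
    symmetric: bool = False
    canonical: bool = True
    inverse: str | None = None


@dataclass
class Schema:
    """Validated category/predicate hierarchies with precomputed closures.

    ``descendants``/``ancestors`` are reflexive-transitive: every label is a
    member of its own closure sets.
    """

    categories: dict[str, SchemaElement]
    predicates: dict[str, SchemaElement]
    category_root: str
    predicate_root: str
    _desc: dict[tuple[Kind, str], frozenset[str]] = field(default_factory=dict, repr=False)
    _anc: dict[tuple[Kind, str], frozenset[str]] = field(default_factory=dict, repr=False)

    # -- hierarchy queries ------------------------------------------------

    def _elements(self, kind: Kind) -> dict[str, SchemaElement]:
        return self.categories if kind == "category" else self.predicates

    def element(self, label: str, kind: Kind) -> SchemaElement:
        try:
            return self._elements(kind)[strip_prefix(label)]
        except KeyError:
            raise UnknownElementError(f"unknown {kind} label: {label!r}") from None

    def has(self, label: str, kind: Kind) -> bool:
        return strip_prefix(label) in self._elements(kind)

    def descendants(self, label: str, kind: Kind) -> frozenset[str]:
        """Reflexive-transitive descendants of ``label`` (precomputed)."""
        name = self.element(label, kind).name
        return self._desc[(kind, name)]

    def ancestors(self, label: str, kind: Kind) -> frozenset[str]:
        """Reflexive-transitive ancestors of ``label`` (precomputed)."""
        name = self.element(label, kind).name
        return self._anc[(kind, name)]

    def canonical_form(self, predicate: str) -> tuple[str, bool]:
        """Resolve a predicate to its canonical direction.

        Returns ``(canonical_label, flipped)``.  Canonical and symmetric
        predicates map to themselves with ``flipped=False``; a non-canonical
        predicate maps to its inverse with ``flipped=True``, meaning an edge
        asserted with it must swap subject and object to be stored in
        canonical orientation.
        """
        el = self.element(predicate, "predicate")
        if el.symmetric or el.canonical or el.inverse is None:
            return el.name, False
        return el.inverse, True

    # -- construction -----------------------------------------------------

    def _freeze_closures(self) -> None:
        for kind in ("category", "predicate"):
            elements = self._elements(kind)  # type: ignore[arg-type]
            children: dict[str, list[str]] = {name: [] for name in elements}
            for el in elements.values():
                for p in el.parents:
                    children[p].append(el.name)
            for name in elements:
                self._desc[(kind, name)] = _reachable(name, children)  # type: ignore[index]
            parents = {name: list(el.parents) for name, el in elements.items()}
            for name in elements:
                self._anc[(kind, name)] = _reachable(name, parents)  # type: ignore[index]


def _reachable(start: str, succ: Mapping[str, list[str]]) -> frozenset[str]:
    seen = {start}
    stack = [start]
    while stack:
        for nxt in succ[stack.pop()]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(seen)


def load_schema(document: str | Path | Mapping) -> Schema:
    """Load and validate a schema from a YAML/JSON file path or a mapping.

    Raises
    ------
    SchemaInvalidError
        On a hierarchy cycle (one cycle member is named), a dangling parent,
        multiple roots, or an inconsistent inverse/canonicity declaration.
    """
    if isinstance(document, (str, Path)):
        text = Path(document).read_text()
        data = yaml.safe_load(text)
    else:
        data = document
    if not isinstance(data, Mapping):
        raise SchemaInvalidError("schema document must be a mapping")

    categories = _parse_elements(data.get("categories", ()), "category")
    predicates = _parse_elements(data.get("predicates", ()), "predicate")

    cat_root = _validate_hierarchy(categories, "category")
    pred_root = _validate_hierarchy(predicates, "predicate")
    _validate_predicate_metadata(predicates)

    schema = Schema(categories, predicates, cat_root, pred_root)
    schema._freeze_closures()
    return schema


def _parse_elements(entries: Iterable[Mapping], kind: Kind) -> dict[str, SchemaElement]:
    out: dict[str, SchemaElement] = {}
    for entry in entries:
        unknown = set(entry) - _KNOWN_FIELDS
        if unknown:
            logger.warning("ignoring unknown schema fields %s on %r", sorted(unknown), entry.get("name"))
        name = strip_prefix(str(entry["name"]))
        if name in out:
            raise SchemaInvalidError(f"duplicate {kind} {name!r}")
        parents = tuple(strip_prefix(str(p)) for p in entry.get("parents", ()))
        inverse = entry.get("inverse")
        symmetric = bool(entry.get("symmetric", False))
        if kind == "predicate":
            # Predicates without an inverse (or symmetric ones) are their own
            # canonical direction; an explicit flag overrides only for
            # inverse pairs.
            canonical = bool(entry.get("canonical", inverse is None or symmetric))
        else:
            canonical = True
        out[name] = SchemaElement(
            name=name,
            kind=kind,
            parents=parents,
            symmetric=symmetric,
            canonical=canonical,
            inverse=strip_prefix(str(inverse)) if inverse else None,
        )
    return out


def _validate_hierarchy(elements: dict[str, SchemaElement], kind: Kind) -> str:
    if not elements:
        raise SchemaInvalidError(f"schema declares no {kind} elements")
    roots = [name for name, el in elements.items() if not el.parents]
    if len(roots) != 1:
        raise SchemaInvalidError(f"{kind} hierarchy must have exactly one root, found {roots}")
    for el in elements.values():
        for p in el.parents:
            if p not in elements:
                raise SchemaInvalidError(f"{kind} {el.name!r} lists unknown parent {p!r}")
    # Kahn's algorithm; leftovers after peeling are cycle members.
    indeg = {name: len(el.parents) for name, el in elements.items()}
    children: dict[str, list[str]] = {name: [] for name in elements}
    for el in elements.values():
        for p in el.parents:
            children[p].append(el.name)
    queue = [n for n, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if seen != len(elements):
        member = sorted(n for n, d in indeg.items() if d > 0)[0]
        raise SchemaInvalidError(f"cycle detected in {kind} hierarchy involving {member!r}")
    root = roots[0]
    unreachable = set(elements) - _reachable(root, children)
    if unreachable:
        raise SchemaInvalidError(f"{kind} elements unreachable from root {root!r}: {sorted(unreachable)}")
    return root


def _validate_predicate_metadata(predicates: dict[str, SchemaElement]) -> None:
    for el in predicates.values():
        if el.symmetric and el.inverse is not None:
            raise SchemaInvalidError(f"symmetric predicate {el.name!r} must not declare an inverse")
        if not el.canonical and el.inverse is None:
            raise SchemaInvalidError(f"non-canonical predicate {el.name!r} must declare an inverse")
        if el.inverse is not None:
            partner = predicates.get(el.inverse)
            if partner is None:
                raise SchemaInvalidError(f"predicate {el.name!r} declares unknown inverse {el.inverse!r}")
            if partner.inverse != el.name:
                raise SchemaInvalidError(
                    f"inverse declaration is not mutual: {el.name!r} -> {el.inverse!r} "
                    f"but {partner.name!r} -> {partner.inverse!r}"
                )
            if partner.canonical == el.canonical:
                raise SchemaInvalidError(
                    f"exactly one of inverse pair {{{el.name!r}, {partner.name!r}}} must be canonical"
                )
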