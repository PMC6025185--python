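"""Gene Ontology DAG handling and true-path annotation propagation.

The Gene Ontology is a directed acyclic graph of terms split into three
aspects (namespaces): molecular function (MF), biological process (BP) and
cellular component (CC).  An entity annotated with a term is implicitly
annotated with every ancestor of that term within the same aspect (the
"true-path rule"); all counting-based scorers in this package assume their
input annotation sets have been closed under that rule first.

Parsing is delegated to :mod:`obonet`; this module wraps the raw graph in a
:class:`GoOntology` that enforces aspect-pure edges, resolves alternate
accessions, and caches ancestor closures.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
from Bio.UniProt import GOA as _goa

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: OBO namespace -> two-letter aspect code
NAMESPACE_TO_ASPECT = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}
#: GAF column-9 code -> two-letter aspect code
GAF_ASPECT = {"F": "MF", "P": "BP", "C": "CC"}

DEFAULT_RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Malformed OBO input; the message names the offending line."""


class OntologyValidationError(ValueError):
    """Structurally invalid ontology (e.g. a cyclic is_a graph)."""


class UnknownTermError(KeyError):
    """A GO accession that resolves to nothing, even via alt_id."""


@dataclass(frozen=True)
class GoTerm:
    """A single GO term.

    ``parents`` maps each parent accession to the relation label
    (``is_a`` / ``part_of``) through which it is reached.  Obsolete terms
    carry ``obsolete=True`` and have no parents.
    """

    id: str
    name: str
    aspect: str
    parents: Mapping[str, str] = field(default_factory=dict)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.id):
            raise ValueError(f"not a GO accession: {self.id!r}")
        if self.aspect not in ("MF", "BP", "CC"):
            raise ValueError(f"unknown aspect {self.aspect!r} for {self.id}")
        if self.obsolete and self.parents:
            raise ValueError(f"obsolete term {self.id} must not have parents")


class GoOntology:
    """The GO DAG restricted to non-obsolete terms with aspect-pure edges."""

    def __init__(
        self,
        terms: Mapping[str, GoTerm],
        alt_ids: Mapping[str, str] | None = None,
        obsolete: Mapping[str, GoTerm] | None = None,
    ):
        self.terms: dict[str, GoTerm] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.obsolete: dict[str, GoTerm] = dict(obsolete or {})
        # child -> parent digraph over live terms only
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for parent, rel in t.parents.items():
                if parent not in self.terms:
                    continue
                if self.terms[parent].aspect != t.aspect:
                    # rare cross-aspect part_of links would leak annotations
                    # between MF/BP/CC; aspect-pure closure keeps the three
                    # evaluations independent
                    logger.warning(
                        "ignoring cross-aspect %s edge %s -> %s", rel, t.id, parent
                    )
                    continue
                g.add_edge(t.id, parent, relation=rel)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyValidationError(f"cyclic ontology graph: {cycle}")
        self.graph = g
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- lookup ---------------------------------------------------------
    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, accession: str) -> str:
        """Map an accession to its primary id via the alt_id table.

        Raises :class:`UnknownTermError` if the accession is neither a live
        term, an alternate id, nor an obsolete term (obsolete ids resolve to
        ``None``-like failure so callers can drop them explicitly).
        """
        if accession in self.terms:
            return accession
        if accession in self.alt_ids:
            return self.alt_ids[accession]
        raise UnknownTermError(accession)

    def aspect(self, accession: str) -> str:
        return self.terms[self.resolve(accession)].aspect

    def roots(self) -> dict[str, str]:
        """Aspect code -> root accession (the unique parentless term)."""
        out: dict[str, str] = {}
        for t in self.terms.values():
            if self.graph.out_degree(t.id) == 0:
                if t.aspect in out:
                    raise OntologyValidationError(
                        f"aspect {t.aspect} has multiple roots: {out[t.aspect]}, {t.id}"
                    )
                out[t.aspect] = t.id
        return out

    # -- closure --------------------------------------------------------
    def ancestors(self, accession: str) -> frozenset[str]:
        """Non-reflexive transitive closure of ``accession`` over the
        configured relations, restricted to the term's aspect."""
        term = self.resolve(accession)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term))
            self._ancestor_cache[term] = cached
        return cached


def _prescan_obo(text: str) -> None:
    """Cheap structural check so errors can name a line.

    obonet raises opaque errors on malformed stanzas; this pass rejects
    non-comment, non-blank lines outside a stanza that are not ``key: value``.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            continue
        if ":" not in stripped:
            raise OboParseError(f"line {lineno}: not 'key: value' nor a stanza header: {line!r}")


def parse_obo(stream, relations: Iterable[str] = DEFAULT_RELATIONS) -> GoOntology:
    """Parse OBO 1.2/1.4 text into a :class:`GoOntology`.

    ``relations`` selects which edge types enter the DAG (default
    ``is_a`` + ``part_of``, the standard GOA propagation set; ``regulates``
    is always excluded).  Obsolete terms are kept in a side registry and
    alternate ids are retained for remapping.
    """
    if isinstance(stream, (str, bytes)):
        text = stream.decode() if isinstance(stream, bytes) else stream
    else:
        text = stream.read()
    _prescan_obo(text)
    relations = tuple(relations)
    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - defensive
        raise OboParseError(f"OBO parse failed: {exc}") from exc

    terms: dict[str, GoTerm] = {}
    obsolete: dict[str, GoTerm] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns not in NAMESPACE_TO_ASPECT:
            raise OboParseError(f"term {node}: missing or unknown namespace {ns!r}")
        aspect = NAMESPACE_TO_ASPECT[ns]
        is_obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: dict[str, str] = {}
        if not is_obsolete:
            for parent in data.get("is_a", []):
                if "is_a" in relations:
                    parents[parent] = "is_a"
            for rel_line in data.get("relationship", []):
                rel, _, target = rel_line.partition(" ")
                target = target.split("!")[0].strip()
                if rel in relations and rel != "is_a":
                    parents[target] = rel
        term = GoTerm(id=node, name=data.get("name", ""), aspect=aspect,
                      parents=parents, obsolete=is_obsolete)
        if is_obsolete:
            obsolete[node] = term
            logger.warning("dropping obsolete term %s from the DAG", node)
        else:
            terms[node] = term
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    return GoOntology(terms, alt_ids=alt_ids, obsolete=obsolete)


def ancestors(onto: GoOntology, term: str) -> frozenset[str]:
    """Functional alias for :meth:`GoOntology.ancestors`."""
    return onto.ancestors(term)


@dataclass
class AnnotationSet:
    """Entity -> set of GO accessions, with a rejects report.

    ``rejects`` lists ``(entity, accession, reason)`` triples for annotation
    rows that could not be resolved against the ontology; they are reported,
    never silently dropped.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    rejects: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, entity: str, term: str) -> None:
        self.entries.setdefault(entity, set()).add(term)

    def terms_of(self, entity: str) -> frozenset[str]:
        return frozenset(self.entries.get(entity, ()))

    def __len__(self) -> int:
        return len(self.entries)

    def total_annotations(self) -> int:
        return sum(len(v) for v in self.entries.values())


def normalize(anno: AnnotationSet, onto: GoOntology) -> AnnotationSet:
    """Remap alt_ids to primary accessions and drop obsolete/unknown terms.

    Unresolvable accessions go to the rejects report; obsolete terms are
    dropped with a warning (they have no place in the live DAG).
    """
    out = AnnotationSet(rejects=list(anno.rejects))
    for entity, terms in anno.entries.items():
        out.entries.setdefault(entity, set())
        for t in terms:
            if t in onto.obsolete:
                logger.warning("dropping obsolete annotation %s on %s", t, entity)
                out.rejects.append((entity, t, "obsolete"))
                continue
            try:
                out.entries[entity].add(onto.resolve(t))
            except UnknownTermError:
                out.rejects.append((entity, t, "unknown accession"))
    return out


def propagate(anno: AnnotationSet, onto: GoOntology) -> AnnotationSet:
    """Close every entity's term set under ancestors (the true-path rule).

    Idempotent and monotone: the output is a superset of the input and a
    second application is a no-op.  Input accessions are normalized
    (alt_id remap, obsolete drop) first.
    """
    normed = normalize(anno, onto)
    out = AnnotationSet(rejects=list(normed.rejects))
    for entity, terms in normed.entries.items():
        closed: set[str] = set()
        for t in terms:
            closed.add(t)
            closed |= onto.ancestors(t)
        out.entries[entity] = closed
    return out


def read_gaf(stream, onto: GoOntology | None = None) -> AnnotationSet:
    """Read a GAF 2.1/2.2 file into an :class:`AnnotationSet`.

    Uses columns 2 (object id), 4 (qualifier, rows containing ``NOT``
    dropped) and 5 (GO id).  If an ontology is given, accessions are
    normalized against it.
    """
    anno = AnnotationSet()
    for rec in _goa.gafiterator(stream):
        quals = rec.get("Qualifier") or []
        if any("NOT" in q for q in quals if q):
            continue
        anno.add(rec["DB_Object_ID"], rec["GO_ID"])
    if onto is not None:
        anno = normalize(anno, onto)
    return anno


def write_gaf(anno: AnnotationSet, stream, onto: GoOntology | None = None,
              db: str = "gofuse") -> None:
    """Write an :class:`AnnotationSet` as minimal GAF 2.1."""
    stream.write("!gaf-version: 2.1\n")
    aspect_code = {"MF": "F", "BP": "P", "CC": "C"}
    for entity in sorted(anno.entries):
        for term in sorted(anno.entries[entity]):
            asp = aspect_code[onto.aspect(term)] if onto is not None else "F"
            row = [db, entity, entity, "", term, "GO_REF:0000001", "IEA", "",
                   asp, "", "", "protein", "taxon:0", "20180101", db, "", ""]
            stream.write("\t".join(row) + "\n")
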