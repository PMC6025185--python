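"""Structure-based scorer: P1(g|d) from domain-protein neighbor mappings.

A PDB protein is a structural neighbor of a SCOP domain when their protein
structure distance (PSD) is below 0.1.  Given the set of neighbor proteins
of a domain d and true-path-propagated protein GO annotations, the
probability that d carries term g is the fraction of neighbors annotated
with g:

    P1(g | d) = P(d, g) / P(d)

where P(d, g) counts neighbor proteins of d having g and P(d) counts all
neighbor proteins of d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import NeighborHit
from .ontology import AnnotationSet

#: neighbors are defined at PSD strictly below this
DEFAULT_PSD_THRESHOLD = 0.1


@dataclass
class P2dMapping:
    """Protein-to-domain pairs surviving the PSD filter, deduplicated."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def proteins_of(self, domain_id: str) -> frozenset[str]:
        return frozenset(p for d, p in self.pairs if d == domain_id)

    def domains(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs)


@dataclass(frozen=True)
class StructuralScore:
    domain_id: str
    term: str
    p1: float
    support: int  # P(d): neighbor proteins of d
    hits: int     # P(d, g): neighbor proteins of d carrying g

    def __post_init__(self):
        if not (0 <= self.hits <= self.support):
            raise ValueError(f"hits {self.hits} outside [0, {self.support}]")


def _entry_id(protein_id: str) -> str:
    """Collapse a chain-qualified PDB id (e.g. ``1abc_A``) to the entry."""
    return protein_id[:4].lower()


def filter_neighbors(
    hits: list[NeighborHit],
    psd_threshold: float = DEFAULT_PSD_THRESHOLD,
    chain_level: bool = False,
) -> P2dMapping:
    """Keep hits with PSD strictly below the threshold.

    Proteins are collapsed to PDB-entry granularity unless ``chain_level``
    is set (P(d) counts PDB proteins, not chains).
    """
    if psd_threshold <= 0:
        raise ValueError(f"psd_threshold must be > 0, got {psd_threshold}")
    pairs = set()
    for h in hits:
        if h.psd < psd_threshold:
            pid = h.protein_id if chain_level else _entry_id(h.protein_id)
            pairs.add((h.domain_id, pid))
    return P2dMapping(pairs)


def score_structural(
    mapping: P2dMapping,
    protein_annotations: AnnotationSet,
    min_support: int = 1,
) -> list[StructuralScore]:
    """Compute P1(g|d) for every domain with enough neighbors.

    ``protein_annotations`` must already be true-path propagated.  Terms no
    neighbor carries are omitted rather than emitted as zero; domains with
    fewer than ``min_support`` neighbors produce no rows (no structural
    evidence).
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    by_domain: dict[str, set[str]] = {}
    for d, p in mapping.pairs:
        by_domain.setdefault(d, set()).add(p)
    out: list[StructuralScore] = []
    for domain, proteins in sorted(by_domain.items()):
        support = len(proteins)
        if support < min_support:
            continue
        counts: dict[str, int] = {}
        for p in proteins:
            for g in protein_annotations.terms_of(p):
                counts[g] = counts.get(g, 0) + 1
        for g, k in sorted(counts.items()):
            out.append(StructuralScore(domain, g, k / support, support, k))
    return out
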