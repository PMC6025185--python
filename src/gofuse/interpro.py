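"""InterPro-mapping scorer: P2(g) as the fraction of a domain's InterPro
hits whose curated InterPro2GO entry carries g.

    P2(g) = (1/n) * sum_i I_i(g)

where n is the number of distinct InterPro domains the SCOP sequence hits
and I_i(g) is 1 when the i-th InterPro entry maps to g (after true-path
propagation of each entry's GO set).  InterPro hits without any InterPro2GO
entry stay in the denominator: the equation divides by the number of
InterPro domains owned by the SCOP domain, not the number of mapped ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import InterProHit, Interpro2GoMap
from .ontology import GoOntology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InterproScore:
    domain_id: str
    term: str
    p2: float
    n: int  # distinct InterPro hits of the domain

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("emitted rows require n >= 1")
        if not 0 < self.p2 <= 1:
            raise ValueError(f"p2 must be in (0,1], got {self.p2}")


def score_interpro(
    hits: list[InterProHit],
    mapping: Interpro2GoMap,
    onto: GoOntology,
) -> list[InterproScore]:
    """Compute P2(g) per (domain, term).

    Each hit's GO set is closed under ancestors before counting, so parent
    terms never score below their children.  Unmapped IPR accessions are
    logged and contribute only to n.
    """
    by_domain: dict[str, set[str]] = {}
    for h in hits:
        by_domain.setdefault(h.domain_id, set()).add(h.interpro_acc)

    # propagate each IPR's GO set once, shared across domains
    ipr_terms: dict[str, frozenset[str]] = {}
    for iprs in by_domain.values():
        for ipr in iprs:
            if ipr in ipr_terms:
                continue
            raw = mapping.terms_of(ipr)
            if not raw:
                logger.info("InterPro hit %s has no InterPro2GO entry", ipr)
                ipr_terms[ipr] = frozenset()
                continue
            closed: set[str] = set()
            for g in raw:
                try:
                    primary = onto.resolve(g)
                except KeyError:
                    logger.warning("InterPro2GO term %s not in ontology; skipped", g)
                    continue
                closed.add(primary)
                closed |= onto.ancestors(primary)
            ipr_terms[ipr] = frozenset(closed)

    out: list[InterproScore] = []
    for domain, iprs in sorted(by_domain.items()):
        n = len(iprs)
        counts: dict[str, int] = {}
        for ipr in iprs:
            for g in ipr_terms[ipr]:
                counts[g] = counts.get(g, 0) + 1
        for g, k in sorted(counts.items()):
            out.append(InterproScore(domain, g, k / n, n))
    return out
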