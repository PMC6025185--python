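"""Homology-transfer scorer: P4(g) as the normalized -log(E)-weighted vote
of sequence homologs carrying g.

Homologs with alignment coverage > 60% are retained; each homolog i gets
weight (-log E_i + b) with b = log 10, and

    P4(g) = sum_i w_i * I_i(g) / sum_j w_j

The result is invariant to the logarithm base, because b = log 10 scales
with the base along with -log E (every weight is log(10 / E) up to a common
positive factor).  Natural log is used internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .io_formats import BlastHit
from .ontology import AnnotationSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 0.6


@dataclass(frozen=True)
class HomologScore:
    domain_id: str
    term: str
    p4: float
    n: int  # homologs retained for the domain

    def __post_init__(self):
        if not 0 <= self.p4 <= 1 + 1e-12:
            raise ValueError(f"p4 out of [0,1]: {self.p4}")


def filter_homologs(
    hits: list[BlastHit],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[BlastHit]:
    """Keep hits with coverage strictly above the threshold, one per
    (query, subject) pair at the minimum E-value."""
    if not 0 < min_coverage <= 1:
        raise ValueError(f"min_coverage must be in (0,1], got {min_coverage}")
    best: dict[tuple[str, str], BlastHit] = {}
    for h in hits:
        if h.query_coverage <= min_coverage:
            continue
        key = (h.query_id, h.subject_id)
        if key not in best or h.evalue < best[key].evalue:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.query_id, h.subject_id))


def score_homolog(
    hits: list[BlastHit],
    homolog_annotations: AnnotationSet,
    base: float = math.e,
) -> list[HomologScore]:
    """Compute P4(g) per (domain, term) from filtered hits.

    ``homolog_annotations`` must be true-path propagated.  Hits whose weight
    -log E + log 10 is non-positive (E >= 10) are dropped with a warning:
    a negative weight would break the probability contract, and such hits
    are beyond any sensible homology threshold.  Terms with p4 = 0 are not
    emitted; a domain with no retained homolog emits nothing.
    """
    logb = math.log(base)
    b = math.log(10) / logb
    by_domain: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_domain.setdefault(h.query_id, []).append(h)

    out: list[HomologScore] = []
    for domain, dhits in sorted(by_domain.items()):
        weighted: list[tuple[float, frozenset[str]]] = []
        for h in dhits:
            w = -math.log(h.evalue) / logb + b
            if w <= 0:
                logger.warning(
                    "dropping homolog %s of %s: E=%g gives non-positive weight",
                    h.subject_id, domain, h.evalue,
                )
                continue
            weighted.append((w, homolog_annotations.terms_of(h.subject_id)))
        if not weighted:
            continue
        total = sum(w for w, _ in weighted)
        sums: dict[str, float] = {}
        for w, terms in weighted:
            for g in terms:
                sums[g] = sums.get(g, 0.0) + w
        for g, s in sorted(sums.items()):
            out.append(HomologScore(domain, g, min(s / total, 1.0), len(weighted)))
    return out
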