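"""CAFA-style evaluation: precision-recall curves, Fmax and coverage.

The protocol is domain-centric (CAFA-1): at a score threshold t, precision
is averaged over the domains that predict at least one term at >= t, and
recall is averaged over every gold-annotated domain in the universe.  Fmax
is the maximum over thresholds of the harmonic mean 2PR/(P+R); the
thresholds are the distinct prediction scores themselves, so the maximum is
exact.  Coverage is the fraction of the domain universe receiving at least
one predicted annotation at any score.

Aspect roots are excluded from both gold and predictions before scoring
(they are trivially true for any annotated domain), and prediction scores
are propagated up the DAG by the max-over-descendants rule so thresholded
prediction sets respect the true-path rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ontology import AnnotationSet, GoOntology


@dataclass
class EvalReport:
    aspect: str
    thresholds: np.ndarray   # descending
    precision: np.ndarray
    recall: np.ndarray
    fmax: float
    fmax_threshold: float
    coverage: float

    def to_rows(self):
        for t, p, r in zip(self.thresholds, self.precision, self.recall):
            yield t, p, r


class EvaluationError(ValueError):
    pass


def propagate_scores(
    predictions: dict[str, dict[str, float]], onto: GoOntology
) -> dict[str, dict[str, float]]:
    """Per domain, give each ancestor at least the max score of its
    descendants (standard CAFA prediction propagation)."""
    out: dict[str, dict[str, float]] = {}
    for domain, term_scores in predictions.items():
        prop: dict[str, float] = {}
        for term, s in term_scores.items():
            for t in (term, *onto.ancestors(term)):
                if s > prop.get(t, -1.0):
                    prop[t] = s
        out[domain] = prop
    return out


def _as_nested(predictions) -> dict[str, dict[str, float]]:
    """Accept AnnotationResult lists or (domain, term, score) triples."""
    nested: dict[str, dict[str, float]] = {}
    for item in predictions:
        if hasattr(item, "posterior"):
            d, g, s = item.domain_id, item.term, item.posterior
        else:
            d, g, s = item
        prev = nested.setdefault(d, {}).get(g)
        if prev is None or s > prev:
            nested[d][g] = s
    return nested


def evaluate_fmax(
    predictions,
    gold: AnnotationSet,
    onto: GoOntology,
    universe: list[str],
    aspect: str,
    propagate_predictions: bool = True,
) -> EvalReport:
    """Evaluate predictions of one aspect against propagated gold.

    ``predictions`` is a list of AnnotationResult or (domain, term, score)
    triples; terms of other aspects are ignored.  ``universe`` is the full
    domain set over which coverage is computed; recall averages over the
    gold-annotated domains of the universe.
    """
    if not universe:
        raise EvaluationError("empty domain universe")
    roots = set(onto.roots().values())
    universe_set = set(universe)

    nested = _as_nested(predictions)
    nested = {d: ts for d, ts in nested.items() if d in universe_set}
    if propagate_predictions:
        nested = propagate_scores(nested, onto)
    preds: dict[str, dict[str, float]] = {}
    for d, ts in nested.items():
        kept = {g: s for g, s in ts.items()
                if onto.aspect(g) == aspect and g not in roots}
        if kept:
            preds[d] = kept

    gold_sets: dict[str, frozenset[str]] = {}
    for d in universe_set & set(gold.entries):
        terms = frozenset(g for g in gold.entries[d]
                          if onto.aspect(g) == aspect and g not in roots)
        if terms:
            gold_sets[d] = terms
    if not gold_sets:
        raise EvaluationError(f"no gold annotations for aspect {aspect}")

    coverage = len(nested) / len(universe_set)

    thresholds = np.array(sorted({s for ts in preds.values() for s in ts.values()},
                                 reverse=True))
    if thresholds.size == 0:
        return EvalReport(aspect, thresholds, np.array([]), np.array([]),
                          0.0, 0.0, coverage)

    precisions, recalls = [], []
    for t in thresholds:
        prec_terms, rec_terms = [], []
        for d, ts in preds.items():
            above = {g for g, s in ts.items() if s >= t}
            if not above:
                continue
            tp = len(above & gold_sets.get(d, frozenset()))
            prec_terms.append(tp / len(above))
            if d in gold_sets:
                rec_terms.append(tp / len(gold_sets[d]))
        precision = float(np.mean(prec_terms)) if prec_terms else 0.0
        # domains with no prediction above t contribute zero recall
        recall = float(sum(rec_terms) / len(gold_sets))
        precisions.append(precision)
        recalls.append(recall)
    precision = np.array(precisions)
    recall = np.array(recalls)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(precision + recall > 0,
                     2 * precision * recall / (precision + recall), 0.0)
    best = int(np.argmax(f))
    return EvalReport(
        aspect=aspect, thresholds=thresholds, precision=precision,
        recall=recall, fmax=float(f[best]),
        fmax_threshold=float(thresholds[best]), coverage=coverage,
    )


def decontaminate(
    test_domains: list[str],
    train_domains: list[str],
    identity: dict[tuple[str, str], float],
    max_identity: float = 0.9,
) -> list[str]:
    """Remove test entries with sequence identity strictly above
    ``max_identity`` to any training entry (default 90%).

    ``identity`` maps (test, train) pairs to identity fractions; missing
    pairs count as 0 (no detectable similarity).
    """
    train = set(train_domains)
    kept = []
    for d in test_domains:
        contaminated = any(
            identity.get((d, t), identity.get((t, d), 0.0)) > max_identity
            for t in train
        )
        if not contaminated:
            kept.append(d)
    return kept


def write_eval_report(report: EvalReport, stream) -> None:
    """Emit the PR rows plus a summary block as self-describing TSV."""
    stream.write("threshold\tprecision\trecall\n")
    for t, p, r in report.to_rows():
        stream.write(f"{t:.6f}\t{p:.6f}\t{r:.6f}\n")
    stream.write(f"# aspect\t{report.aspect}\n")
    stream.write(f"# fmax\t{report.fmax:.6f}\n")
    stream.write(f"# fmax_threshold\t{report.fmax_threshold:.6f}\n")
    stream.write(f"# coverage\t{report.coverage:.6f}\n")
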