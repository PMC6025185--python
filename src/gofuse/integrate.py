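"""Naive-Bayes integration of component scores via binned likelihood ratios.

Each component method (Str, IPR, PSSM, Seq) emits per-(domain, term)
probabilities in [0, 1].  On labelled calibration data the scores are split
into bins; the likelihood ratio of a bin is the ratio of the odds that an
annotation is true after versus before knowing its score fell in the bin:

    LR_bin = [ (pos_bin + s) / (neg_bin + s) ] / [ (pos_tot + s) / (neg_tot + s) ]

with additive smoothing s.  Pairs a method produced no score for fall in a
dedicated "absent" pseudo-bin fitted the same way.  Methods combine by the
product LR = prod_i LR_i (conditional independence given the label), and
the posterior follows from the prior odds:

    posterior = prior_odds * LR / (1 + prior_odds * LR)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np

from .ontology import AnnotationSet, GoOntology

logger = logging.getLogger(__name__)

METHODS = ("Str", "IPR", "PSSM", "Seq")
ASPECTS = ("MF", "BP", "CC")

DEFAULT_BINS = 10
DEFAULT_SMOOTHING = 1.0
DEFAULT_CUTOFF = 0.5


@dataclass
class ComponentScoreSet:
    """Scores of one component method: (domain, term) -> probability."""

    method: str
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for (d, g), s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"{self.method} score for ({d}, {g}) out of [0,1]: {s}")

    def add(self, domain: str, term: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score out of [0,1]: {score}")
        self.scores[(domain, term)] = score

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class LikelihoodRatioTable:
    """Per-method, per-aspect binned LRs plus the absent pseudo-bin and the
    prior odds of the calibration universe."""

    method: str
    aspect: str
    bin_edges: np.ndarray     # len bins+1, partitioning [0, 1]
    lr_per_bin: np.ndarray    # len bins, all > 0
    absent_lr: float
    prior_odds: float

    def __post_init__(self):
        e = np.asarray(self.bin_edges, dtype=float)
        if e[0] != 0.0 or e[-1] != 1.0 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must increase from 0 to 1")
        if np.any(np.asarray(self.lr_per_bin) <= 0) or self.absent_lr <= 0:
            raise ValueError("all likelihood ratios must be > 0")
        if self.prior_odds <= 0:
            raise ValueError("prior odds must be > 0")

    @property
    def n_bins(self) -> int:
        return len(self.lr_per_bin)

    def bin_index(self, score: float) -> int:
        """Bins are [left, right) with the last bin closed at 1."""
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score out of [0,1]: {score}")
        idx = int(np.searchsorted(self.bin_edges, score, side="right")) - 1
        return min(idx, self.n_bins - 1)

    def lookup(self, score: float | None) -> float:
        if score is None:
            return self.absent_lr
        return float(self.lr_per_bin[self.bin_index(score)])


@dataclass(frozen=True)
class AnnotationResult:
    """A fused annotation: posterior probability that domain carries term."""

    domain_id: str
    term: str
    aspect: str
    combined_lr: float
    posterior: float
    component_scores: dict

    def __post_init__(self):
        if self.combined_lr <= 0:
            raise ValueError("combined LR must be > 0")


class LrFitError(ValueError):
    """Calibration data cannot support an LR table (e.g. no positives)."""


def _count_bins(scores: Iterable[float], edges: np.ndarray) -> np.ndarray:
    arr = np.asarray(list(scores), dtype=float)
    n_bins = len(edges) - 1
    if arr.size == 0:
        return np.zeros(n_bins, dtype=int)
    idx = np.clip(np.searchsorted(edges, arr, side="right") - 1, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def fit_lr_table(
    scores: ComponentScoreSet,
    gold: AnnotationSet,
    onto: GoOntology,
    aspect: str,
    bins: int = DEFAULT_BINS,
    smoothing: float = DEFAULT_SMOOTHING,
    candidates: set[tuple[str, str]] | None = None,
) -> LikelihoodRatioTable:
    """Fit one LR table for one method and aspect.

    ``gold`` must be true-path propagated.  ``candidates`` is the calibration
    universe of (domain, term) pairs; pairs in propagated gold are positives,
    the rest negatives.  By default the universe is the method's own scored
    pairs (of the aspect); the training driver normally passes the union over
    all methods so the absent pseudo-bin is informative.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    if smoothing < 0:
        raise ValueError(f"smoothing must be >= 0, got {smoothing}")
    aspect_scores = {
        pair: s for pair, s in scores.scores.items() if onto.aspect(pair[1]) == aspect
    }
    if candidates is None:
        universe = set(aspect_scores)
    else:
        universe = {p for p in candidates if onto.aspect(p[1]) == aspect}

    def is_pos(pair):
        d, g = pair
        return g in gold.entries.get(d, ())

    pos_scores, neg_scores = [], []
    pos_absent = neg_absent = 0
    for pair in universe:
        s = aspect_scores.get(pair)
        if s is None:
            if is_pos(pair):
                pos_absent += 1
            else:
                neg_absent += 1
        elif is_pos(pair):
            pos_scores.append(s)
        else:
            neg_scores.append(s)

    pos_total = len(pos_scores) + pos_absent
    neg_total = len(neg_scores) + neg_absent
    if pos_total == 0:
        raise LrFitError(
            f"no positive calibration pairs for method {scores.method}, aspect {aspect}"
        )
    if neg_total == 0:
        raise LrFitError(
            f"no negative calibration pairs for method {scores.method}, aspect {aspect}"
        )

    edges = np.linspace(0.0, 1.0, bins + 1)
    pos_bin = _count_bins(pos_scores, edges)
    neg_bin = _count_bins(neg_scores, edges)
    base_odds = (pos_total + smoothing) / (neg_total + smoothing)
    lr = ((pos_bin + smoothing) / (neg_bin + smoothing)) / base_odds
    if pos_absent + neg_absent == 0:
        absent_lr = 1.0  # no unscored calibration pairs: absence is uninformative
    else:
        absent_lr = ((pos_absent + smoothing) / (neg_absent + smoothing)) / base_odds
    if smoothing == 0 and (np.any(lr <= 0) or not np.all(np.isfinite(lr))):
        raise LrFitError("unsmoothed LR table has empty cells; use smoothing > 0")
    return LikelihoodRatioTable(
        method=scores.method, aspect=aspect, bin_edges=edges,
        lr_per_bin=lr.astype(float), absent_lr=float(absent_lr),
        prior_odds=pos_total / neg_total,
    )


def candidate_universe(score_sets: Iterable[ComponentScoreSet]) -> set[tuple[str, str]]:
    """(domain, term) pairs any method produced a score for."""
    out: set[tuple[str, str]] = set()
    for s in score_sets:
        out |= set(s.scores)
    return out


def fit_all_lr_tables(
    score_sets: Iterable[ComponentScoreSet],
    gold: AnnotationSet,
    onto: GoOntology,
    bins: int = DEFAULT_BINS,
    smoothing: float = DEFAULT_SMOOTHING,
) -> dict[tuple[str, str], LikelihoodRatioTable]:
    """Fit tables for every (method, aspect) on the shared union universe.

    Aspects with no positive calibration pairs are skipped with a warning.
    """
    score_sets = list(score_sets)
    universe = candidate_universe(score_sets)
    tables: dict[tuple[str, str], LikelihoodRatioTable] = {}
    for s in score_sets:
        for aspect in ASPECTS:
            try:
                tables[(s.method, aspect)] = fit_lr_table(
                    s, gold, onto, aspect, bins=bins, smoothing=smoothing,
                    candidates=universe,
                )
            except LrFitError as exc:
                logger.warning("skipping (%s, %s): %s", s.method, aspect, exc)
    return tables


def posterior_from_lr(prior_odds: float, combined_lr: float) -> float:
    odds = prior_odds * combined_lr
    return odds / (1.0 + odds)


def combine(
    score_sets: Iterable[ComponentScoreSet],
    tables: Mapping[tuple[str, str], LikelihoodRatioTable],
    onto: GoOntology,
) -> list[AnnotationResult]:
    """Fuse the component scores into posterior probabilities.

    For every (domain, term) pair any method scored: look up each method's
    LR (the absent-bin LR when that method produced no score), take the
    product, and convert through the aspect's prior odds.  The product is
    order-independent; tables fitted on a shared universe carry identical
    priors per aspect, and the first method's table supplies it.
    """
    score_sets = list(score_sets)
    by_method = {s.method: s.scores for s in score_sets}
    methods = [s.method for s in score_sets]
    results: list[AnnotationResult] = []
    for domain, term in sorted(candidate_universe(score_sets)):
        aspect = onto.aspect(term)
        method_tables = [(m, tables.get((m, aspect))) for m in methods]
        if all(t is None for _, t in method_tables):
            continue
        combined_lr = 1.0
        comp: dict[str, float | None] = {}
        prior = None
        for m, table in method_tables:
            s = by_method[m].get((domain, term))
            comp[m] = s
            if table is None:
                continue
            combined_lr *= table.lookup(s)
            if prior is None:
                prior = table.prior_odds
        results.append(AnnotationResult(
            domain_id=domain, term=term, aspect=aspect,
            combined_lr=combined_lr,
            posterior=posterior_from_lr(prior, combined_lr),
            component_scores=comp,
        ))
    return results


def threshold_annotations(
    results: Iterable[AnnotationResult], cutoff: float = DEFAULT_CUTOFF
) -> list[AnnotationResult]:
    """Keep results with posterior >= cutoff (inclusive; default 0.5)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0,1], got {cutoff}")
    return [r for r in results if r.posterior >= cutoff]


# ---------------------------------------------------------------------------
# serialization: self-describing TSV
# ---------------------------------------------------------------------------

def write_lr_tables(tables: Mapping[tuple[str, str], LikelihoodRatioTable],
                    stream: TextIO) -> None:
    stream.write("method\taspect\tkind\tbin_lo\tbin_hi\tvalue\n")
    for (method, aspect), t in sorted(tables.items()):
        for i in range(t.n_bins):
            stream.write(
                f"{method}\t{aspect}\tbin\t{t.bin_edges[i]:.6f}\t"
                f"{t.bin_edges[i + 1]:.6f}\t{t.lr_per_bin[i]:.10g}\n"
            )
        stream.write(f"{method}\t{aspect}\tabsent\t\t\t{t.absent_lr:.10g}\n")
        stream.write(f"{method}\t{aspect}\tprior_odds\t\t\t{t.prior_odds:.10g}\n")


def read_lr_tables(stream: TextIO) -> dict[tuple[str, str], LikelihoodRatioTable]:
    import csv

    rows = list(csv.DictReader(stream, delimiter="\t"))
    grouped: dict[tuple[str, str], dict] = {}
    for row in rows:
        key = (row["method"], row["aspect"])
        g = grouped.setdefault(key, {"edges": [], "lr": [], "absent": None, "prior": None})
        if row["kind"] == "bin":
            g["edges"].append((float(row["bin_lo"]), float(row["bin_hi"])))
            g["lr"].append(float(row["value"]))
        elif row["kind"] == "absent":
            g["absent"] = float(row["value"])
        elif row["kind"] == "prior_odds":
            g["prior"] = float(row["value"])
    out = {}
    for (method, aspect), g in grouped.items():
        edges = np.array([lo for lo, _ in g["edges"]] + [g["edges"][-1][1]])
        out[(method, aspect)] = LikelihoodRatioTable(
            method=method, aspect=aspect, bin_edges=edges,
            lr_per_bin=np.array(g["lr"]), absent_lr=g["absent"],
            prior_odds=g["prior"],
        )
    return out
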