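"""End-to-end orchestration: load a bundle directory, run the four
component scorers, fit the likelihood-ratio integrator, annotate, evaluate.

The directory layout consumed here is the one `gofuse simulate` emits (and
that real inputs can be arranged into):

    ontology.obo            GO ontology (OBO)
    gold.gaf                domain gold annotations (training labels)
    neighbors.tsv           structural-neighbor table with PSD scores
    neighbor_proteins.gaf   GO annotations of the neighbor proteins
    interproscan.tsv        InterProScan output
    interpro2go.txt         curated InterPro2GO mapping
    blast_hits.tsv          homolog hits (BLAST outfmt 6 + qcovs)
    homologs.gaf            GO annotations of the homolog subjects
    pssm/<domain>.pssm      ASCII PSSM per domain
    domains.fasta           domain sequences
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import homolog as homolog_mod
from . import interpro as interpro_mod
from . import pssm as pssm_mod
from . import structural as structural_mod
from .config import RunConfig
from .evaluate import EvalReport, evaluate_fmax
from .integrate import (
    AnnotationResult, ComponentScoreSet, LikelihoodRatioTable,
    combine, fit_all_lr_tables, threshold_annotations,
)
from .io_formats import (
    read_blast_tab, read_fasta_lengths, read_interpro2go,
    read_interproscan_tsv, read_neighbor_table, read_pssm_ascii,
)
from .ontology import AnnotationSet, GoOntology, parse_obo, propagate, read_gaf

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    ontology: GoOntology
    gold: AnnotationSet                  # propagated
    neighbor_hits: list
    protein_annotations: AnnotationSet   # propagated
    interpro_hits: list
    interpro2go: object
    blast_hits: list
    homolog_annotations: AnnotationSet   # propagated
    profiles: dict[str, object]
    domains: list[str]


def load_inputs(directory: str | Path, config: RunConfig | None = None) -> PipelineInputs:
    config = config or RunConfig()
    d = Path(directory)
    with open(d / "ontology.obo") as fh:
        onto = parse_obo(fh, relations=config.relations())
    with open(d / "gold.gaf") as fh:
        gold = propagate(read_gaf(fh), onto)
    with open(d / "neighbors.tsv") as fh:
        neighbor_hits = read_neighbor_table(fh)
    with open(d / "neighbor_proteins.gaf") as fh:
        protein_anno = propagate(read_gaf(fh), onto)
    with open(d / "interproscan.tsv") as fh:
        interpro_hits = read_interproscan_tsv(fh)
    with open(d / "interpro2go.txt") as fh:
        ipr2go = read_interpro2go(fh)
    with open(d / "domains.fasta") as fh:
        qlens = read_fasta_lengths(fh)
    with open(d / "blast_hits.tsv") as fh:
        blast_hits = read_blast_tab(fh, query_lengths=qlens,
                                    drop_self=config.drop_self_hits)
    with open(d / "homologs.gaf") as fh:
        homolog_anno = propagate(read_gaf(fh), onto)
    profiles = {}
    for path in sorted((d / "pssm").glob("*.pssm")) if (d / "pssm").is_dir() else []:
        with open(path) as fh:
            profiles[path.stem] = read_pssm_ascii(fh, domain_id=path.stem)
    domains = sorted(qlens)
    for name, n in [("neighbor hits", len(neighbor_hits)),
                    ("interpro hits", len(interpro_hits)),
                    ("blast hits", len(blast_hits)),
                    ("pssm profiles", len(profiles)),
                    ("domains", len(domains))]:
        logger.info("stage-count loaded %s: %d", name, n)
    return PipelineInputs(onto, gold, neighbor_hits, protein_anno,
                          interpro_hits, ipr2go, blast_hits, homolog_anno,
                          profiles, domains)


def subset_inputs(inputs: PipelineInputs, domains: list[str]) -> PipelineInputs:
    """Restrict an input set to a subset of domains (for train/test splits).

    Evidence carriers (neighbor proteins, homologs, profiles) attached to
    other domains are dropped; the ontology and carrier annotation sets are
    shared, not copied.
    """
    keep = set(domains)
    gold = AnnotationSet(entries={d: set(ts) for d, ts in inputs.gold.entries.items()
                                  if d in keep})
    return PipelineInputs(
        ontology=inputs.ontology,
        gold=gold,
        neighbor_hits=[h for h in inputs.neighbor_hits if h.domain_id in keep],
        protein_annotations=inputs.protein_annotations,
        interpro_hits=[h for h in inputs.interpro_hits if h.domain_id in keep],
        interpro2go=inputs.interpro2go,
        blast_hits=[h for h in inputs.blast_hits if h.query_id in keep],
        homolog_annotations=inputs.homolog_annotations,
        profiles={d: p for d, p in inputs.profiles.items() if d in keep},
        domains=[d for d in inputs.domains if d in keep],
    )


# ---------------------------------------------------------------------------
# component scoring
# ---------------------------------------------------------------------------

def compute_counting_scores(inputs: PipelineInputs,
                            config: RunConfig) -> dict[str, ComponentScoreSet]:
    """Run the three counting scorers (Str, IPR, Seq)."""
    mapping = structural_mod.filter_neighbors(
        inputs.neighbor_hits, config.psd_threshold, chain_level=config.chain_level)
    str_rows = structural_mod.score_structural(
        mapping, inputs.protein_annotations, min_support=config.min_support)
    s_str = ComponentScoreSet("Str")
    for r in str_rows:
        s_str.add(r.domain_id, r.term, r.p1)

    ipr_rows = interpro_mod.score_interpro(
        inputs.interpro_hits, inputs.interpro2go, inputs.ontology)
    s_ipr = ComponentScoreSet("IPR")
    for r in ipr_rows:
        s_ipr.add(r.domain_id, r.term, r.p2)

    filtered = homolog_mod.filter_homologs(inputs.blast_hits,
                                           config.coverage_threshold)
    seq_rows = homolog_mod.score_homolog(filtered, inputs.homolog_annotations)
    s_seq = ComponentScoreSet("Seq")
    for r in seq_rows:
        s_seq.add(r.domain_id, r.term, r.p4)

    for s in (s_str, s_ipr, s_seq):
        logger.info("stage-count %s scores: %d", s.method, len(s))
    return {"Str": s_str, "IPR": s_ipr, "Seq": s_seq}


def train_pssm_channel(inputs: PipelineInputs,
                       config: RunConfig) -> dict[str, pssm_mod.TermClassifier]:
    """Train one calibrated classifier per trainable GO term."""
    vectors = [pssm_mod.acc_transform(p, lag=config.acc_lag)
               for _, p in sorted(inputs.profiles.items())]
    if not vectors:
        return {}
    terms = sorted({g for ts in inputs.gold.entries.values() for g in ts}
                   - set(inputs.ontology.roots().values()))
    train_cfg = pssm_mod.PssmTrainConfig(
        min_pos=config.min_pos, min_neg=config.min_neg,
        kernel=config.svm_kernel, seed=config.seed)
    models = {}
    for term in terms:
        labels = [int(term in inputs.gold.entries.get(v.domain_id, ()))
                  for v in vectors]
        clf = pssm_mod.train_term_classifier(vectors, labels, term, train_cfg)
        if clf is not None:
            models[term] = clf
    logger.info("stage-count PSSM term models: %d of %d candidate terms",
                len(models), len(terms))
    return models


def compute_pssm_scores(inputs: PipelineInputs,
                        models: dict[str, pssm_mod.TermClassifier],
                        config: RunConfig) -> ComponentScoreSet:
    s = ComponentScoreSet("PSSM")
    if not models:
        return s
    vectors = [pssm_mod.acc_transform(p, lag=config.acc_lag)
               for _, p in sorted(inputs.profiles.items())]
    for domain, term, p3 in pssm_mod.score_pssm(vectors, models):
        s.add(domain, term, p3)
    logger.info("stage-count PSSM scores: %d", len(s))
    return s


# ---------------------------------------------------------------------------
# training / annotation / evaluation drivers
# ---------------------------------------------------------------------------

@dataclass
class TrainedAnnotator:
    tables: dict[tuple[str, str], LikelihoodRatioTable]
    pssm_models: dict[str, pssm_mod.TermClassifier]
    component_scores: dict[str, ComponentScoreSet] = field(default_factory=dict)


def train(inputs: PipelineInputs, config: RunConfig | None = None) -> TrainedAnnotator:
    config = config or RunConfig()
    scores = compute_counting_scores(inputs, config)
    models = train_pssm_channel(inputs, config)
    scores["PSSM"] = compute_pssm_scores(inputs, models, config)
    tables = fit_all_lr_tables(scores.values(), inputs.gold, inputs.ontology,
                               bins=config.bins, smoothing=config.smoothing)
    return TrainedAnnotator(tables=tables, pssm_models=models,
                            component_scores=scores)


def annotate(inputs: PipelineInputs, trained: TrainedAnnotator,
             config: RunConfig | None = None,
             cutoff: float | None = None) -> tuple[list[AnnotationResult], list[str]]:
    """Score a (possibly new) input set against a trained annotator.

    Returns (thresholded results, unannotated domain ids).
    """
    config = config or RunConfig()
    scores = compute_counting_scores(inputs, config)
    scores["PSSM"] = compute_pssm_scores(inputs, trained.pssm_models, config)
    results = combine(scores.values(), trained.tables, inputs.ontology)
    cutoff = config.score_cutoff if cutoff is None else cutoff
    kept = threshold_annotations(results, cutoff)
    annotated = {r.domain_id for r in kept}
    unannotated = [d for d in inputs.domains if d not in annotated]
    logger.info("stage-count annotations kept at cutoff %.2f: %d (of %d raw)",
                cutoff, len(kept), len(results))
    return kept, unannotated


def evaluate(results, inputs: PipelineInputs,
             config: RunConfig | None = None) -> dict[str, EvalReport]:
    config = config or RunConfig()
    reports = {}
    for aspect in config.aspects:
        try:
            reports[aspect] = evaluate_fmax(
                results, inputs.gold, inputs.ontology, inputs.domains, aspect)
        except Exception as exc:
            logger.warning("skipping aspect %s: %s", aspect, exc)
    return reports
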