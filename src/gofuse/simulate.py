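"""Synthetic fixture generation with known ground truth.

Builds a self-consistent miniature of every input the annotation pipeline
consumes — a random GO-like DAG, a domain inventory with sequences, gold
domain annotations, a structural-neighbor table with PSD scores, InterPro
hits plus an InterPro2GO mapping, ASCII PSSM profiles, and homolog hits
with a GAF — from a seeded configuration, so every scorer and the
integrator can be exercised and checked against the generating parameters
without any external downloads.

Signal model
------------
Each evidence channel has a signal strength in [0, 1]: the probability that
an evidence carrier (neighbor protein, InterPro entry, homolog) inherits
each of its domain's primitive gold terms.  Noise is modelled by per-domain
*decoy terms* — functionally related but wrong terms (structural analogues,
promiscuous signatures, spurious homologs carry them) that each carrier
inherits independently with probability ``noise_rate``.  Counting scorers
therefore concentrate around the channel signal on gold pairs and around
the noise rate on decoy pairs (binomial means), so individual channels make
real mistakes at desk scale while their errors stay independent across
channels — the regime in which evidence fusion can help.  The PSSM channel
encodes term membership as elevated lag-one autocorrelation on a per-term
subset of descriptor columns, which the auto-covariance features pick up.

Everything is deterministic given the seed; ``generate`` called twice with
the same config yields byte-identical file contents.
"""

from __future__ import annotations

import io
import string
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io_formats
from .io_formats import (
    BlastHit, Interpro2GoMap, NeighborHit, PssmProfile,
    write_blast_tab, write_interpro2go, write_neighbor_table, write_pssm_ascii,
)
from .ontology import AnnotationSet, GoOntology, parse_obo, propagate, write_gaf

_ASPECT_NS = {"MF": "molecular_function", "BP": "biological_process",
              "CC": "cellular_component"}
_B36 = string.digits + string.ascii_lowercase


class FixtureConfigError(ValueError):
    pass


@dataclass
class FixtureConfig:
    """Generating parameters of a fixture bundle.

    Signal strengths are per-term inheritance probabilities; the defaults
    describe a high-signal regime in which each channel is informative but
    imperfect, with a modest uniform noise floor.
    """

    seed: int = 0
    n_domains: int = 40
    n_terms: int = 60
    dag_depth: int = 4
    terms_per_aspect: int = 2           # primitive gold terms per domain/aspect
    decoys_per_aspect: int = 2          # decoy (noise) terms per domain/aspect
    neighbors_per_domain: int = 5
    decoys_per_domain: int = 4          # neighbor rows above the PSD cut
    interpro_hits_per_domain: int = 4
    homologs_per_domain: int = 6
    low_coverage_per_domain: int = 2    # homolog rows below the coverage cut
    structural_signal: float = 0.9
    interpro_signal: float = 0.9
    pssm_signal: float = 0.9
    homolog_signal: float = 0.9
    noise_rate: float = 0.4             # decoy-term inheritance probability
    channel_coverage: float = 0.8       # P(a channel has evidence for a domain)
    seq_len: tuple[int, int] = (60, 120)
    acc_lag: int = 10

    def validate(self) -> None:
        if self.n_terms < 3 * (self.dag_depth + 1):
            raise FixtureConfigError(
                f"n_terms={self.n_terms} too small for 3 aspects of depth {self.dag_depth}"
            )
        for name in ("structural_signal", "interpro_signal", "pssm_signal",
                     "homolog_signal", "noise_rate", "channel_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureConfigError(f"{name}={v} outside [0,1]")
        if self.seq_len[0] <= self.acc_lag:
            raise FixtureConfigError("minimum sequence length must exceed the AC lag")


@dataclass
class FixtureBundle:
    """Generated inputs plus their exact generating parameters."""

    config: FixtureConfig
    files: dict[str, str]
    ontology: GoOntology
    gold: AnnotationSet                  # true-path closed
    primitive_gold: dict[str, set[str]]  # pre-closure gold per domain
    decoy_terms: dict[str, set[str]]     # noise-channel terms per domain
    domains: list[str]
    manifest: dict[str, object]

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        for rel, content in self.files.items():
            path = outdir / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(content)
        return outdir


def _b36(i: int, width: int) -> str:
    out = []
    for _ in range(width):
        out.append(_B36[i % 36])
        i //= 36
    return "".join(reversed(out))


def _go_id(i: int) -> str:
    return f"GO:{i:07d}"


def _make_ontology_obo(cfg: FixtureConfig, rng: np.random.Generator):
    """Random aspect-pure DAG written as OBO text.

    Terms are dealt round-robin to the three aspects; each aspect gets a
    root at level 0 and each deeper term 1-2 parents from shallower levels
    (a second parent is occasionally a part_of edge).
    Returns (obo text, {aspect: [term ids by level]}).
    """
    per_aspect = {a: [] for a in _ASPECT_NS}
    aspects = list(_ASPECT_NS)
    for i in range(cfg.n_terms):
        per_aspect[aspects[i % 3]].append(_go_id(i + 1))

    lines = ["format-version: 1.2", "ontology: go", ""]
    levels: dict[str, list[list[str]]] = {}
    for aspect in aspects:
        terms = per_aspect[aspect]
        root, rest = terms[0], terms[1:]
        # deal remaining terms into dag_depth levels, roughly even
        lv: list[list[str]] = [[root]]
        n_levels = min(cfg.dag_depth, max(1, len(rest)))
        splits = np.array_split(np.array(rest, dtype=object), n_levels)
        lv.extend([list(s) for s in splits if len(s)])
        levels[aspect] = lv
        for depth, layer in enumerate(lv):
            for t in layer:
                lines += [f"[Term]", f"id: {t}",
                          f"name: synthetic {aspect} term {t[3:]}",
                          f"namespace: {_ASPECT_NS[aspect]}"]
                if depth > 0:
                    pool = [x for l in lv[:depth] for x in l]
                    primary = lv[depth - 1][int(rng.integers(len(lv[depth - 1])))]
                    lines.append(f"is_a: {primary} ! parent")
                    if len(pool) > 1 and rng.random() < 0.4:
                        extra = pool[int(rng.integers(len(pool)))]
                        if extra != primary:
                            rel = "part_of" if rng.random() < 0.25 else "is_a"
                            if rel == "is_a":
                                lines.append(f"is_a: {extra} ! parent")
                            else:
                                lines.append(f"relationship: part_of {extra} ! parent")
                lines.append("")
    return "\n".join(lines) + "\n", levels


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 20, size=length)
    return "".join(io_formats.AMINO_ACIDS[i] for i in idx)


def _inherit(rng, domain: str, primitive: dict[str, set[str]],
             decoys: dict[str, set[str]], signal: float, noise: float) -> set[str]:
    """One evidence carrier's term set: gold terms at the signal rate,
    decoy terms at the noise rate."""
    got: set[str] = set()
    for g in sorted(primitive[domain]):
        if rng.random() < signal:
            got.add(g)
    for g in sorted(decoys[domain]):
        if rng.random() < noise:
            got.add(g)
    return got


def generate(config: FixtureConfig) -> FixtureBundle:
    """Generate a complete fixture bundle from the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    obo_text, levels = _make_ontology_obo(config, rng)
    onto = parse_obo(obo_text)
    roots = set(onto.roots().values())
    nonroot = {a: [t for lv in levels[a][1:] for t in lv] for a in levels}
    all_nonroot = sorted(t for ts in nonroot.values() for t in ts)

    domains = [f"d{_b36(i, 4)}a1" for i in range(config.n_domains)]
    seq_lo, seq_hi = config.seq_len
    seq_lens = {d: int(rng.integers(seq_lo, seq_hi + 1)) for d in domains}
    sequences = {d: _random_sequence(rng, seq_lens[d]) for d in domains}

    # ---- gold: primitive terms drawn from the deeper levels per aspect ----
    # decoy terms are drawn from the same pools, disjoint from gold: they
    # stand in for functionally related but wrong evidence
    primitive: dict[str, set[str]] = {}
    decoys: dict[str, set[str]] = {}
    gold = AnnotationSet()
    for d in domains:
        chosen: set[str] = set()
        wrong: set[str] = set()
        for aspect, lv in levels.items():
            # draw from one level so gold and decoy picks are never
            # ancestor-related (keeps generating rates exact after closure)
            deep = list(lv[-1])
            if len(deep) < config.terms_per_aspect + config.decoys_per_aspect:
                deep = [t for layer in lv[len(lv) // 2:] for t in layer] or nonroot[aspect]
            k = min(config.terms_per_aspect, len(deep))
            kd = min(config.decoys_per_aspect, max(0, len(deep) - k))
            picks = rng.choice(len(deep), size=k + kd, replace=False)
            chosen |= {deep[int(i)] for i in picks[:k]}
            wrong |= {deep[int(i)] for i in picks[k:]}
        primitive[d] = chosen
        decoys[d] = wrong
        for g in chosen:
            gold.add(d, g)
    gold = propagate(gold, onto)

    # ---- per-channel evidence presence --------------------------------
    # real evidence sources each cover only part of the domain universe;
    # a domain lacking a channel simply has no rows/files in that input
    present: dict[str, dict[str, bool]] = {}
    for ch in ("Str", "IPR", "PSSM", "Seq"):
        present[ch] = {d: bool(rng.random() < config.channel_coverage)
                       for d in domains}

    # ---- structural neighbors ----------------------------------------
    neighbor_hits: list[NeighborHit] = []
    protein_gold = AnnotationSet()
    pid_counter = 0

    def next_pid():
        nonlocal pid_counter
        pid = "1" + _b36(pid_counter, 3)
        pid_counter += 1
        return pid

    for d in domains:
        if not present["Str"][d]:
            continue
        for _ in range(config.neighbors_per_domain):
            pid = next_pid()
            neighbor_hits.append(NeighborHit(d, pid, float(rng.uniform(0.02, 0.0999))))
            got = _inherit(rng, d, primitive, decoys,
                           config.structural_signal, config.noise_rate)
            for g in got:
                protein_gold.add(pid, g)
            if not got:  # GAF rows need >= 1 term; give an uninformative root
                protein_gold.add(pid, sorted(roots)[0])
        for _ in range(config.decoys_per_domain):
            pid = next_pid()
            neighbor_hits.append(NeighborHit(d, pid, float(rng.uniform(0.1, 0.6))))
            protein_gold.add(pid, all_nonroot[int(rng.integers(len(all_nonroot)))])

    # ---- InterPro hits + mapping --------------------------------------
    ipr_counter = 0
    interpro_rows: list[str] = []
    ipr_map = Interpro2GoMap()
    for d in domains:
        if not present["IPR"][d]:
            continue
        for _ in range(config.interpro_hits_per_domain):
            ipr_counter += 1
            acc = f"IPR{ipr_counter:06d}"
            interpro_rows.append(
                "\t".join([d, "md5", str(seq_lens[d]), "SYNT", f"SIG{ipr_counter:05d}",
                           "synthetic signature", "1", str(seq_lens[d]), "1e-10", "T",
                           "20180101", acc])
            )
            for g in _inherit(rng, d, primitive, decoys,
                              config.interpro_signal, config.noise_rate):
                ipr_map.entries.setdefault(acc, set()).add(g)
        # one unintegrated signature row, dropped by the reader
        interpro_rows.append(
            "\t".join([d, "md5", str(seq_lens[d]), "SYNT", "SIGX", "unintegrated",
                       "1", str(seq_lens[d]), "1e-3", "T", "20180101", "-"])
        )

    # ---- PSSM profiles -------------------------------------------------
    # each term marks a subset of descriptor columns; domains carrying the
    # term get elevated lag-one autocorrelation on those columns
    term_columns: dict[str, np.ndarray] = {
        t: rng.choice(20, size=4, replace=False) for t in all_nonroot
    }
    pssm_files: dict[str, str] = {}
    for d in domains:
        if not present["PSSM"][d]:
            continue
        L = seq_lens[d]
        active = np.zeros(20, dtype=bool)
        for g in sorted(primitive[d]):
            if rng.random() < config.pssm_signal:
                active[term_columns[g]] = True
        for g in sorted(decoys[d]):
            if rng.random() < config.noise_rate:
                active[term_columns[g]] = True
        rho = np.where(active, 0.65, 0.0)
        M = np.empty((L, 20))
        M[0] = rng.normal(0, 1, size=20)
        eps = rng.normal(0, 1, size=(L - 1, 20))
        for i in range(1, L):
            M[i] = rho * M[i - 1] + np.sqrt(1 - rho ** 2) * eps[i - 1]
        matrix = np.clip(np.round(M * 3), -9, 9)
        profile = PssmProfile(domain_id=d, matrix=matrix.tolist(),
                              sequence=sequences[d])
        buf = io.StringIO()
        write_pssm_ascii(profile, buf)
        pssm_files[f"pssm/{d}.pssm"] = buf.getvalue()

    # ---- homolog hits ---------------------------------------------------
    blast_hits: list[BlastHit] = []
    homolog_gold = AnnotationSet()
    hom_counter = 0
    for d in domains:
        if not present["Seq"][d]:
            continue
        for j in range(config.homologs_per_domain + config.low_coverage_per_domain):
            hom_counter += 1
            sid = f"Q{_b36(hom_counter, 5).upper()}"
            evalue = float(10.0 ** rng.uniform(-30, -2))
            if j < config.homologs_per_domain:
                cov = float(rng.uniform(0.62, 1.0))
            else:
                cov = float(rng.uniform(0.30, 0.59))
            blast_hits.append(BlastHit(d, sid, evalue, cov,
                                       pident=float(rng.uniform(30, 90))))
            got = _inherit(rng, d, primitive, decoys,
                           config.homolog_signal, config.noise_rate)
            for g in got:
                homolog_gold.add(sid, g)
            if not got:
                homolog_gold.add(sid, sorted(roots)[0])

    # ---- assemble text files -------------------------------------------
    files: dict[str, str] = {"ontology.obo": obo_text}
    buf = io.StringIO(); write_gaf(gold, buf, onto); files["gold.gaf"] = buf.getvalue()
    buf = io.StringIO(); write_neighbor_table(neighbor_hits, buf)
    files["neighbors.tsv"] = buf.getvalue()
    buf = io.StringIO(); write_gaf(protein_gold, buf, onto)
    files["neighbor_proteins.gaf"] = buf.getvalue()
    files["interproscan.tsv"] = "\n".join(interpro_rows) + "\n"
    buf = io.StringIO(); write_interpro2go(ipr_map, buf)
    files["interpro2go.txt"] = buf.getvalue()
    buf = io.StringIO(); write_blast_tab(blast_hits, buf, with_qcovs=True)
    files["blast_hits.tsv"] = buf.getvalue()
    buf = io.StringIO(); write_gaf(homolog_gold, buf, onto)
    files["homologs.gaf"] = buf.getvalue()
    files.update(pssm_files)

    fasta = []
    meta = ["domain_id\tlength"]
    for d in domains:
        fasta.append(f">{d}\n{sequences[d]}")
        meta.append(f"{d}\t{seq_lens[d]}")
    files["domains.fasta"] = "\n".join(fasta) + "\n"
    files["domains.tsv"] = "\n".join(meta) + "\n"

    manifest: dict[str, object] = {k: v for k, v in asdict(config).items()}
    manifest.update({
        "n_primitive_gold": sum(len(v) for v in primitive.values()),
        "n_gold_closed": gold.total_annotations(),
    })
    files["manifest.txt"] = "".join(f"{k} = {v}\n" for k, v in manifest.items())

    return FixtureBundle(
        config=config, files=files, ontology=onto, gold=gold,
        primitive_gold=primitive, decoy_terms=decoys, domains=domains,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# direct binned-score generator for likelihood-ratio recovery checks
# ---------------------------------------------------------------------------

def binned_calibration_sample(
    bin_positive_rates: list[float],
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (score, label) pairs with a known per-bin positive rate.

    Scores are uniform on [0, 1) over equal-width bins; the label of a
    sample in bin b is Bernoulli(bin_positive_rates[b]).  The analytic
    likelihood ratio of bin b is then

        LR_b = [r_b / (1 - r_b)] / [rbar / (1 - rbar)],  rbar = mean(r)

    since equal-width bins are equiprobable under the uniform score.
    """
    rates = np.asarray(bin_positive_rates, dtype=float)
    if np.any((rates <= 0) | (rates >= 1)):
        raise ValueError("bin positive rates must lie strictly inside (0,1)")
    scores = rng.uniform(0.0, 1.0, size=n)
    bins = np.minimum((scores * len(rates)).astype(int), len(rates) - 1)
    labels = (rng.uniform(size=n) < rates[bins]).astype(int)
    return scores, labels


def analytic_bin_lrs(bin_positive_rates: list[float]) -> np.ndarray:
    rates = np.asarray(bin_positive_rates, dtype=float)
    rbar = rates.mean()
    return (rates / (1 - rates)) / (rbar / (1 - rbar))
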