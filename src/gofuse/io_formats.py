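"""Readers and writers for the external file dialects the scorers consume.

Covers: the domain-protein structural-neighbor table (TSV with PSD scores),
BLAST tabular output (outfmt 6, with or without a trailing ``qcovs``
column), PSI-BLAST ASCII PSSM profiles, InterProScan TSV, the InterPro2GO
flat mapping file, and the annotation table this tool emits.

All readers validate rather than coerce: malformed rows raise with line
provenance, and every deliberate drop (e.g. unintegrated InterProScan rows)
is logged.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

logger = logging.getLogger(__name__)

IPR_RE = re.compile(r"^IPR\d{6}$")

#: reported 0.0 E-values are clamped here so -log E stays finite
EVALUE_FLOOR = 1e-180

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


class SchemaError(ValueError):
    """A table is missing a required column."""


class ParseError(ValueError):
    """A row failed validation; the message carries the line number."""


# ---------------------------------------------------------------------------
# structural neighbor table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborHit:
    """One structural-neighbor relation: SCOP domain vs PDB protein with its
    protein structure distance (PSD; lower = more similar)."""

    domain_id: str
    protein_id: str
    psd: float

    def __post_init__(self):
        if self.psd < 0:
            raise ValueError(f"psd must be >= 0, got {self.psd}")


def read_neighbor_table(stream: TextIO) -> list[NeighborHit]:
    """Read a TSV with header ``domain_id  protein_id  psd``.

    Duplicate (domain, protein) rows collapse to the minimum PSD (the best
    alignment wins).  Negative PSD values are a hard error.
    """
    reader = csv.DictReader(stream, delimiter="\t")
    required = {"domain_id", "protein_id", "psd"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise SchemaError(
            f"neighbor table needs columns {sorted(required)}, got {reader.fieldnames}"
        )
    best: dict[tuple[str, str], float] = {}
    for lineno, row in enumerate(reader, start=2):
        try:
            psd = float(row["psd"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"line {lineno}: non-numeric psd {row['psd']!r}") from exc
        if psd < 0:
            raise ParseError(f"line {lineno}: negative psd {psd}")
        key = (row["domain_id"], row["protein_id"])
        if key not in best or psd < best[key]:
            best[key] = psd
    return [NeighborHit(d, p, s) for (d, p), s in best.items()]


def write_neighbor_table(hits: Iterable[NeighborHit], stream: TextIO) -> None:
    stream.write("domain_id\tprotein_id\tpsd\n")
    for h in hits:
        stream.write(f"{h.domain_id}\t{h.protein_id}\t{h.psd:.6g}\n")


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlastHit:
    """A homolog hit: query SCOP domain vs subject protein, with E-value,
    percent identity and query coverage (fraction of the query aligned)."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float
    pident: float = 0.0

    def __post_init__(self):
        if self.evalue <= 0:
            raise ValueError(f"evalue must be > 0 (clamp upstream), got {self.evalue}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"coverage must be in [0,1], got {self.query_coverage}")


_OUTFMT6_NCOLS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


def read_blast_tab(
    stream: TextIO,
    query_lengths: Mapping[str, int] | None = None,
    drop_self: bool = False,
    self_map: Mapping[str, str] | None = None,
    evalue_floor: float = EVALUE_FLOOR,
) -> list[BlastHit]:
    """Read BLAST tabular (outfmt 6) hits, optionally with a 13th ``qcovs``
    percentage column.

    If ``qcovs`` is absent, coverage is (qend - qstart + 1) / query_length,
    which requires ``query_lengths``.  E-values printed ``0.0`` are clamped
    to ``evalue_floor``.  With ``drop_self``, hits whose subject equals
    ``self_map[query]`` (or the query id itself) are removed.
    """
    hits: list[BlastHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < _OUTFMT6_NCOLS:
            raise ParseError(f"line {lineno}: expected >= {_OUTFMT6_NCOLS} columns, got {len(cols)}")
        qid, sid = cols[0], cols[1]
        try:
            pident = float(cols[2])
            qstart, qend = int(cols[6]), int(cols[7])
            evalue = float(cols[10])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric field: {exc}") from exc
        if evalue <= 0:
            evalue = evalue_floor
        if len(cols) >= 13:
            coverage = float(cols[12]) / 100.0
        else:
            if query_lengths is None or qid not in query_lengths:
                raise ParseError(
                    f"line {lineno}: no qcovs column and no query length for {qid!r}"
                )
            coverage = (qend - qstart + 1) / query_lengths[qid]
        coverage = min(coverage, 1.0)
        if drop_self:
            self_id = (self_map or {}).get(qid, qid)
            if sid == self_id:
                continue
        hits.append(BlastHit(qid, sid, evalue, coverage, pident))
    return hits


def write_blast_tab(hits: Iterable[BlastHit], stream: TextIO,
                    with_qcovs: bool = True) -> None:
    """Emit hits in outfmt-6 order (+ qcovs when requested); alignment
    coordinates are placeholders reconstructed from the coverage."""
    for h in hits:
        qend = max(1, round(h.query_coverage * 100))
        row = [h.query_id, h.subject_id, f"{h.pident:.1f}", str(qend), "0", "0",
               "1", str(qend), "1", str(qend), f"{h.evalue:.3g}", "50.0"]
        if with_qcovs:
            row.append(f"{100.0 * h.query_coverage:.0f}")
        stream.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# InterProScan TSV + InterPro2GO
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterProHit:
    domain_id: str
    interpro_acc: str

    def __post_init__(self):
        if not IPR_RE.match(self.interpro_acc):
            raise ValueError(f"not an InterPro accession: {self.interpro_acc!r}")


def read_interproscan_tsv(stream: TextIO) -> list[InterProHit]:
    """Read InterProScan TSV: column 1 is the sequence id, column 12 the
    integrated InterPro accession.  Rows with ``-`` in column 12 (signatures
    not integrated into InterPro) are dropped with a log line; duplicate
    (domain, IPR) pairs collapse."""
    seen: set[tuple[str, str]] = set()
    out: list[InterProHit] = []
    n_dropped = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ParseError(f"line {lineno}: InterProScan TSV needs >= 12 columns, got {len(cols)}")
        acc = cols[11]
        if acc == "-" or acc == "":
            n_dropped += 1
            continue
        if not IPR_RE.match(acc):
            raise ParseError(f"line {lineno}: bad InterPro accession {acc!r}")
        key = (cols[0], acc)
        if key in seen:
            continue
        seen.add(key)
        out.append(InterProHit(cols[0], acc))
    if n_dropped:
        logger.info("dropped %d unintegrated InterProScan rows", n_dropped)
    return out


@dataclass
class Interpro2GoMap:
    """IPR accession -> set of GO accessions, from the curated flat file."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def terms_of(self, ipr: str) -> frozenset[str]:
        return frozenset(self.entries.get(ipr, ()))


_IPR2GO_RE = re.compile(r"^InterPro:(IPR\d{6})\s.*;\s*(GO:\d{7})\s*$")


def read_interpro2go(stream: TextIO) -> Interpro2GoMap:
    """Parse the flat InterPro2GO mapping file
    (``InterPro:IPRxxxxxx name > GO:name ; GO:xxxxxxx`` lines)."""
    out = Interpro2GoMap()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        m = _IPR2GO_RE.match(line)
        if not m:
            raise ParseError(f"line {lineno}: unparseable InterPro2GO line: {line!r}")
        out.entries.setdefault(m.group(1), set()).add(m.group(2))
    return out


def write_interpro2go(mapping: Interpro2GoMap, stream: TextIO) -> None:
    for ipr in sorted(mapping.entries):
        for go in sorted(mapping.entries[ipr]):
            stream.write(f"InterPro:{ipr} synthetic entry > GO:synthetic ; {go}\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

@dataclass
class PssmProfile:
    """A position-specific scoring matrix: one row of 20 log-odds scores per
    residue position, plus the residue string itself."""

    domain_id: str
    matrix: list[list[float]]
    sequence: str

    def __post_init__(self):
        if len(self.matrix) != len(self.sequence):
            raise ValueError(
                f"{self.domain_id}: {len(self.matrix)} matrix rows vs "
                f"{len(self.sequence)} residues"
            )
        for i, row in enumerate(self.matrix):
            if len(row) != 20:
                raise ValueError(f"{self.domain_id}: row {i + 1} has {len(row)} scores, expected 20")

    def __len__(self) -> int:
        return len(self.sequence)


def read_pssm_ascii(stream: TextIO, domain_id: str = "") -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` style).

    Rows look like ``   12 K   -1  2 ...`` with 20 log-odds integers first
    and, in full files, 20 weighted-percentage columns after them; only the
    first (log-odds) block is kept.  Header and trailing statistics lines
    (K, lambda) are ignored.
    """
    matrix: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(stream, start=1):
        parts = line.split()
        if len(parts) < 22:
            continue  # header, blank, or footer (K/lambda) line
        try:
            pos = int(parts[0])
        except ValueError:
            continue  # the residue-letter header row
        residue = parts[1]
        if len(residue) != 1 or not residue.isalpha():
            raise ParseError(f"line {lineno}: expected a residue letter, got {residue!r}")
        if pos != expected_pos:
            raise ParseError(f"line {lineno}: position {pos}, expected {expected_pos}")
        try:
            scores = [float(x) for x in parts[2:22]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric score: {exc}") from exc
        matrix.append(scores)
        residues.append(residue)
        expected_pos += 1
    if not matrix:
        raise ParseError("no PSSM rows found (empty matrix)")
    return PssmProfile(domain_id=domain_id, matrix=matrix, sequence="".join(residues))


def write_pssm_ascii(profile: PssmProfile, stream: TextIO) -> None:
    """Emit an ASCII PSSM in the PSI-BLAST layout (log-odds block only,
    padded with a zero percentage block so the column count is realistic)."""
    stream.write("\nLast position-specific scoring matrix computed\n")
    header = "            " + "   ".join(AMINO_ACIDS) + "   " + "   ".join(AMINO_ACIDS)
    stream.write(header + "\n")
    for i, (res, row) in enumerate(zip(profile.sequence, profile.matrix), start=1):
        scores = " ".join(f"{int(round(v)):3d}" for v in row)
        pct = " ".join("  0" for _ in range(20))
        stream.write(f"{i:5d} {res}  {scores}  {pct}  0.50 0.10\n")
    stream.write("\n                      K         Lambda\n")
    stream.write("Standard Ungapped    0.1377     0.3163\n")


# ---------------------------------------------------------------------------
# annotation output
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "domain_id", "go_id", "aspect", "score",
    "p_structure", "p_interpro", "p_pssm", "p_homolog",
]


def write_annotations(results, stream: TextIO, fmt: str = "tsv") -> None:
    """Write fused annotation rows, one per (domain, term).

    Rows are sorted by domain then descending score; scores carry 6 decimals;
    absent component scores print as ``NA``.
    """
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"format must be tsv or csv, got {fmt!r}")
    delim = "\t" if fmt == "tsv" else ","
    writer = csv.writer(stream, delimiter=delim, lineterminator="\n")
    writer.writerow(ANNOTATION_COLUMNS)

    def fmt6(v):
        return "NA" if v is None else f"{v:.6f}"

    ordered = sorted(results, key=lambda r: (r.domain_id, -r.posterior, r.term))
    for r in ordered:
        comp = r.component_scores
        writer.writerow([
            r.domain_id, r.term, r.aspect, f"{r.posterior:.6f}",
            fmt6(comp.get("Str")), fmt6(comp.get("IPR")),
            fmt6(comp.get("PSSM")), fmt6(comp.get("Seq")),
        ])


def read_annotations(stream: TextIO, fmt: str = "tsv") -> list[dict]:
    """Re-read an annotation table written by :func:`write_annotations` into
    plain dicts (used for round-trip checks and the evaluate command)."""
    delim = "\t" if fmt == "tsv" else ","
    reader = csv.DictReader(stream, delimiter=delim)
    out = []
    for row in reader:
        rec = dict(row)
        rec["score"] = float(row["score"])
        for k in ("p_structure", "p_interpro", "p_pssm", "p_homolog"):
            rec[k] = None if row[k] == "NA" else float(row[k])
        out.append(rec)
    return out


def read_fasta_lengths(stream: TextIO) -> dict[str, int]:
    """Sequence id -> length, for BLAST coverage computation."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(stream, "fasta")}
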