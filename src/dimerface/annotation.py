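"""Located domain and motif annotations on protein sequences.

Domains arrive as InterProScan TSV rows (or from the InterPro REST API);
short linear motifs (SLiMs) arrive as ELM-Predict-style TSV rows or are
found by scanning the sequence with each motif class's regular expression.
All coordinates are 1-based inclusive residue indices, the convention shared
by InterProScan, ELM and PDB numbering; no half-open intervals cross module
boundaries.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .interaction_db import MotifClass, is_pfam_id, normalize_pfam

logger = logging.getLogger(__name__)

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XUBZ")

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"
INTERPRO_PFAM_URL = (
    "https://www.ebi.ac.uk/interpro/api/entry/pfam/protein/uniprot/{accession}"
)

# A fetcher maps a URL to the response body (bytes); injecting it keeps all
# network access behind an explicit capability and lets tests use stored
# payloads.
Fetcher = Callable[[str], bytes]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file violates its dialect."""


class NetworkDisabledError(RuntimeError):
    """Raised when a network-backed operation is called without a fetcher."""


class LookupFailedError(RuntimeError):
    """Raised when a remote lookup fails (HTTP error, unknown accession)."""


@dataclass(frozen=True)
class ProteinRecord:
    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.identifier}: empty sequence")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.identifier}: invalid residue codes {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class DomainHit:
    """A Pfam domain located on a protein (1-based inclusive range)."""

    protein: str
    pfam: str
    start: int
    end: int
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pfam", normalize_pfam(self.pfam))
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein}/{self.pfam}: bad range {self.start}-{self.end}"
            )


@dataclass(frozen=True, order=True)
class MotifHit:
    """A SLiM occurrence on a protein; ``matched`` is the matched subsequence."""

    protein: str
    elm_id: str
    start: int
    end: int
    matched: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein}/{self.elm_id}: bad range {self.start}-{self.end}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file; identifier is the header up to whitespace."""
    records = [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AnnotationFormatError(f"{path}: no FASTA records")
    return records


def parse_fasta_text(text: str) -> ProteinRecord:
    """Parse a single-record FASTA payload (e.g. a UniProt response body)."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise AnnotationFormatError("payload is not FASTA (missing '>' header)")
    identifier = lines[0][1:].split()[0]
    # UniProt headers look like sp|P12004|PCNA_HUMAN; prefer the accession field
    parts = identifier.split("|")
    if len(parts) >= 2 and parts[0] in {"sp", "tr"}:
        identifier = parts[1]
    sequence = "".join(lines[1:])
    if not sequence:
        raise AnnotationFormatError("FASTA payload has no sequence lines")
    return ProteinRecord(identifier, sequence)


# ---------------------------------------------------------------------------
# InterProScan TSV

_IPS_MIN_COLUMNS = 11


def parse_interproscan_tsv(
    path: str | Path,
    keep_analyses: Iterable[str] = ("Pfam",),
) -> list[DomainHit]:
    """Extract domain hits from an InterProScan TSV.

    The InterProScan convention is >= 11 tab-separated columns: protein
    accession, sequence MD5, length, analysis, signature accession,
    signature description, start, stop, score, status, date, [...].  Only
    rows whose analysis is in ``keep_analyses`` (default Pfam) are kept;
    with the default, any signature accession that is not a Pfam ID is also
    excluded.  Duplicate (protein, pfam, start, end) hits are collapsed.
    """
    keep = set(keep_analyses)
    pfam_only = keep == {"Pfam"}
    path = Path(path)
    hits: list[DomainHit] = []
    seen: set[tuple[str, str, int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _IPS_MIN_COLUMNS:
                raise AnnotationFormatError(
                    f"{path} line {lineno}: expected >= {_IPS_MIN_COLUMNS} "
                    f"tab-separated columns, got {len(fields)}"
                )
            protein, analysis, signature = fields[0], fields[3], fields[4]
            if analysis not in keep:
                continue
            if pfam_only and not is_pfam_id(signature):
                continue
            try:
                start, end = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"{path} line {lineno}: non-integer coordinates "
                    f"{fields[6]!r}/{fields[7]!r}"
                ) from exc
            hit = DomainHit(protein, signature, start, end, fields[5])
            key = (hit.protein, hit.pfam, hit.start, hit.end)
            if key in seen:
                continue
            seen.add(key)
            hits.append(hit)
    return hits


def write_interproscan_tsv(hits: Sequence[DomainHit], path: str | Path,
                           seq_length: int = 0) -> None:
    """Write domain hits back out in the InterProScan TSV dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.protein, "0" * 32, str(seq_length or h.end), "Pfam",
                        h.pfam, h.description, str(h.start), str(h.end),
                        "0.0", "T", "01-01-2025",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SLiM scanning


class MotifPatternError(ValueError):
    """Raised when a motif class pattern fails to compile during a scan."""


def scan_slims(
    protein: ProteinRecord,
    classes: Sequence[MotifClass],
    overlapping: bool = True,
) -> list[MotifHit]:
    """Scan a sequence for every occurrence of each motif class pattern.

    By default every match position is reported, *including overlapping
    occurrences*, by restarting the search one position after each match
    start -- SLiM occurrences can overlap and dropping one would silently
    lose interaction candidates.  ``overlapping=False`` gives the strict
    non-overlapping left-to-right scan for parity with simpler scanners.
    Anchors ``^``/``$`` are interpreted relative to the full sequence.
    Hits are sorted by (elm_id, start).
    """
    seq = protein.sequence
    hits: list[MotifHit] = []
    for cls in classes:
        try:
            rx = re.compile(cls.pattern)
        except re.error as exc:
            raise MotifPatternError(f"class {cls.elm_id}: {exc}") from exc
        pos = 0
        while pos <= len(seq):
            m = rx.search(seq, pos)
            if m is None:
                break
            if m.end() > m.start():  # ignore empty matches
                hits.append(
                    MotifHit(protein.identifier, cls.elm_id,
                             m.start() + 1, m.end(), m.group())
                )
            pos = m.start() + 1 if overlapping else max(m.end(), m.start() + 1)
    hits.sort(key=lambda h: (h.elm_id, h.start, h.end))
    return hits


# ---------------------------------------------------------------------------
# ELM-Predict TSV

_ELM_PREDICT_COLUMNS = {
    "elm": ("elm_identifier", "ELMIdentifier", "ELM identifier", "elm_id"),
    "start": ("start", "Start"),
    "stop": ("stop", "Stop", "end", "End"),
}


def parse_elm_predict_tsv(path: str | Path, protein: str | None = None) -> list[MotifHit]:
    """Parse an ELM-Predict-style TSV of motif occurrences.

    Requires ELM identifier, start and stop columns (1-based inclusive); a
    protein/sequence-name column and a matched-sequence column are used when
    present, otherwise ``protein`` supplies the record identifier.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"motif table not readable: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols: dict[str, str] = {}
    for key, candidates in _ELM_PREDICT_COLUMNS.items():
        found = next((c for c in candidates if c in df.columns), None)
        if found is None:
            raise AnnotationFormatError(
                f"{path}: missing required column for {key!r} "
                f"(looked for {candidates})"
            )
        cols[key] = found
    prot_col = next((c for c in ("protein", "sequence_name", "Protein") if c in df.columns), None)
    match_col = next((c for c in ("matched", "matched_sequence") if c in df.columns), None)
    hits = []
    for _, row in df.iterrows():
        ident = str(row[prot_col]) if prot_col else (protein or "query")
        matched = "" if match_col is None or pd.isna(row[match_col]) else str(row[match_col])
        hits.append(
            MotifHit(ident, str(row[cols["elm"]]),
                     int(row[cols["start"]]), int(row[cols["stop"]]), matched)
        )
    return hits


def write_elm_predict_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\telm_identifier\tstart\tstop\tmatched\n")
        for h in hits:
            fh.write(f"{h.protein}\t{h.elm_id}\t{h.start}\t{h.end}\t{h.matched}\n")


# ---------------------------------------------------------------------------
# Network lookups (optional; always behind an injected fetcher)


def urlopen_fetcher(url: str, timeout: float = 30.0) -> bytes:
    """Default fetcher using stdlib urllib; only wired up when networking is
    explicitly enabled (e.g. the CLI ``--network`` flag)."""
    from urllib.error import URLError
    from urllib.request import urlopen

    try:
        with urlopen(url, timeout=timeout) as resp:  # noqa: S310
            return resp.read()
    except URLError as exc:
        raise LookupFailedError(f"lookup failed for {url}: {exc}") from exc


def fetch_sequence(accession: str, fetcher: Fetcher | None = None) -> ProteinRecord:
    """Fetch a protein sequence from UniProt (FASTA endpoint)."""
    if fetcher is None:
        raise NetworkDisabledError(
            "network access is disabled; pass a fetcher or enable --network"
        )
    payload = fetcher(UNIPROT_FASTA_URL.format(accession=accession))
    record = parse_fasta_text(payload.decode())
    # UniProt headers carry the accession; fall back to the query accession
    if record.identifier != accession:
        record = ProteinRecord(accession, record.sequence)
    return record


def fetch_domains(accession: str, fetcher: Fetcher | None = None) -> list[DomainHit]:
    """Fetch Pfam domain locations for a UniProt accession from InterPro.

    Each Pfam entry may map to several fragments on the protein; one
    DomainHit is emitted per fragment.
    """
    if fetcher is None:
        raise NetworkDisabledError(
            "network access is disabled; pass a fetcher or enable --network"
        )
    payload = fetcher(INTERPRO_PFAM_URL.format(accession=accession))
    try:
        doc = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(f"InterPro payload is not JSON: {exc}") from exc
    hits: list[DomainHit] = []
    seen: set[tuple[str, str, int, int]] = set()
    for entry in doc.get("results", []):
        meta = entry.get("metadata", {})
        acc = meta.get("accession", "")
        if not is_pfam_id(acc):
            continue
        name = meta.get("name", "") or ""
        for prot in entry.get("proteins", []):
            for loc in prot.get("entry_protein_locations", []) or []:
                for frag in loc.get("fragments", []):
                    hit = DomainHit(accession, acc, int(frag["start"]),
                                    int(frag["end"]), name)
                    key = (hit.protein, hit.pfam, hit.start, hit.end)
                    if key not in seen:
                        seen.add(key)
                        hits.append(hit)
    hits.sort()
    return hits
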