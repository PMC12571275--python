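"""Catalogs of known domain-domain and domain-motif interactions.

A domain-domain interaction (DDI) is an unordered pair of Pfam accessions
whose domains have been observed (or confidently predicted) to bind each
other.  A domain-motif interaction (DMI) links an ELM motif class -- a short
linear motif (SLiM) defined by a regular expression -- to the Pfam domain it
binds.  Catalogs are compiled from user-supplied snapshots of resources such
as 3did, DOMINE and the ELM "interaction domains" table; this module only
normalizes, deduplicates and indexes them.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_PFAM_RE = re.compile(r"PF\d{5}$")


class PfamIdError(ValueError):
    """Raised when a string cannot be normalized to a Pfam accession."""


class CatalogSchemaError(ValueError):
    """Raised when a source table lacks the columns a catalog needs."""


def normalize_pfam(raw: str) -> str:
    """Normalize a Pfam accession: strip whitespace and any ``.N`` version suffix.

    Raises :class:`PfamIdError` unless the result matches ``PF`` + 5 digits.
    """
    if not isinstance(raw, str):
        raise PfamIdError(f"not a Pfam accession: {raw!r}")
    value = raw.strip().split(".", 1)[0]
    if not _PFAM_RE.match(value):
        raise PfamIdError(f"not a Pfam accession: {raw!r}")
    return value


def is_pfam_id(raw: str) -> bool:
    try:
        normalize_pfam(raw)
    except PfamIdError:
        return False
    return True


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    a, b = normalize_pfam(a), normalize_pfam(b)
    return (a, b) if a <= b else (b, a)


@dataclass
class DdiSource:
    """One tabular source of Pfam pairs.

    ``columns`` selects the two Pfam-ID columns either by 0-based index or,
    when ``header`` is true, by column name.  Lines starting with ``#`` are
    ignored.  The DOMINE dialect is a headerless TSV with Pfam IDs in the
    first two columns; 3did-style exports carry versioned accessions and
    extra annotation columns, handled by index selection plus version
    stripping.
    """

    path: str | Path
    columns: tuple[int, int] | tuple[str, str] = (0, 1)
    name: str | None = None
    header: bool = False

    @property
    def label(self) -> str:
        return self.name if self.name is not None else Path(self.path).name


def ddi_source_domine(path: str | Path, name: str | None = None) -> DdiSource:
    """DOMINE dialect: headerless TSV, Pfam IDs in the first two columns."""
    return DdiSource(path, columns=(0, 1), name=name or "domine", header=False)


def ddi_source_3did(
    path: str | Path,
    columns: tuple[int, int] | tuple[str, str] = (0, 1),
    name: str | None = None,
    header: bool = False,
) -> DdiSource:
    """3did dialect: per-interaction rows carrying two (possibly versioned) accessions."""
    return DdiSource(path, columns=columns, name=name or "3did", header=header)


class DDICatalog:
    """Set of unordered Pfam pairs with per-pair source provenance.

    ``(A, B)`` and ``(B, A)`` are the same entry (physical interaction is
    symmetric); self-pairs ``(A, A)`` are allowed because homotypic domain
    interactions exist.
    """

    def __init__(self) -> None:
        self._provenance: dict[tuple[str, str], set[str]] = {}
        self.n_skipped: int = 0

    # -- construction -------------------------------------------------

    def add(self, a: str, b: str, source: str = "manual") -> None:
        pair = _canonical_pair(a, b)
        self._provenance.setdefault(pair, set()).add(source)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._provenance)

    def provenance(self, a: str, b: str) -> list[str]:
        return sorted(self._provenance.get(_canonical_pair(a, b), ()))

    # -- queries -------------------------------------------------------

    def has(self, a: str, b: str) -> bool:
        return _canonical_pair(a, b) in self._provenance

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.has(*pair)

    def __len__(self) -> int:
        return len(self._provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DDICatalog):
            return NotImplemented
        return self._provenance.keys() == other._provenance.keys()

    def __repr__(self) -> str:
        return f"DDICatalog({len(self)} pairs)"

    # -- persistence ---------------------------------------------------

    def write(self, tsv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Serialize to a two-column TSV of lexicographically sorted pairs.

        Output ordering is bit-stable (lexicographic) so diffs are
        reproducible.  A JSON sidecar records per-pair provenance.
        """
        tsv_path = Path(tsv_path)
        with open(tsv_path, "w") as fh:
            fh.write("pfam_a\tpfam_b\n")
            for a, b in sorted(self._provenance):
                fh.write(f"{a}\t{b}\n")
        if sidecar_path is None:
            sidecar_path = tsv_path.with_suffix(tsv_path.suffix + ".provenance.json")
        payload = {
            f"{a}\t{b}": sorted(sources)
            for (a, b), sources in sorted(self._provenance.items())
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def has_ddi(catalog: DDICatalog, a: str, b: str) -> bool:
    """True iff the unordered pair (a, b) is catalogued.  Symmetric in arguments."""
    return catalog.has(a, b)


def _iter_source_rows(source: DdiSource) -> Iterable[tuple[str, str]]:
    path = Path(source.path)
    if not path.is_file():
        raise IOError(f"DDI source not readable: {path}")
    by_name = isinstance(source.columns[0], str)
    if by_name and not source.header:
        raise CatalogSchemaError(
            f"{path}: column selection by name requires a header row"
        )
    with open(path) as fh:
        header_fields: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if source.header and header_fields is None:
                header_fields = fields
                if by_name:
                    missing = [c for c in source.columns if c not in fields]
                    if missing:
                        raise CatalogSchemaError(
                            f"{path}: Pfam columns not found: {missing}"
                        )
                continue
            if by_name:
                assert header_fields is not None
                idx = tuple(header_fields.index(c) for c in source.columns)  # type: ignore[arg-type]
            else:
                idx = source.columns  # type: ignore[assignment]
            if max(idx) >= len(fields):
                yield ("", "")  # too few columns: counts as unparseable
                continue
            yield (fields[idx[0]], fields[idx[1]])


def compile_ddi_catalog(sources: Sequence[DdiSource]) -> DDICatalog:
    """Merge Pfam-pair source tables into a deduplicated unordered-pair catalog.

    Rows whose ID columns do not normalize to Pfam accessions are skipped and
    counted in ``catalog.n_skipped`` (DOMINE-style exports carry annotation
    columns and odd rows; these must not be fatal).
    """
    catalog = DDICatalog()
    for source in sources:
        for raw_a, raw_b in _iter_source_rows(source):
            try:
                catalog.add(raw_a, raw_b, source=source.label)
            except PfamIdError:
                catalog.n_skipped += 1
                logger.debug("skipping non-Pfam row in %s: %r / %r",
                             source.label, raw_a, raw_b)
    logger.info("compiled DDI catalog: %d pairs from %d source(s), %d rows skipped",
                len(catalog), len(sources), catalog.n_skipped)
    return catalog


def read_ddi_catalog(tsv_path: str | Path, name: str | None = None) -> DDICatalog:
    """Load a catalog from its own serialized two-column TSV."""
    source = DdiSource(tsv_path, columns=("pfam_a", "pfam_b"), header=True,
                       name=name or Path(tsv_path).name)
    return compile_ddi_catalog([source])


# ---------------------------------------------------------------------------
# Domain-motif catalog


@dataclass(frozen=True)
class DMIRecord:
    elm_id: str
    domain: str
    pattern: str | None = None

    def __post_init__(self) -> None:
        if not self.elm_id:
            raise ValueError("elm_id must be non-empty")
        object.__setattr__(self, "domain", normalize_pfam(self.domain))


class DMICatalog:
    """Records linking an ELM motif class to the Pfam domain it binds."""

    def __init__(self, records: Iterable[DMIRecord] = ()) -> None:
        self._records: dict[tuple[str, str], DMIRecord] = {}
        self._by_motif: dict[str, set[str]] = {}
        self._by_domain: dict[str, set[str]] = {}
        for record in records:
            self.add(record)

    def add(self, record: DMIRecord) -> None:
        key = (record.elm_id, record.domain)
        if key in self._records:
            return
        self._records[key] = record
        self._by_motif.setdefault(record.elm_id, set()).add(record.domain)
        self._by_domain.setdefault(record.domain, set()).add(record.elm_id)

    @property
    def records(self) -> list[DMIRecord]:
        return sorted(self._records.values(), key=lambda r: (r.elm_id, r.domain))

    def has(self, elm_id: str, domain: str) -> bool:
        return (elm_id, normalize_pfam(domain)) in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DMICatalog):
            return NotImplemented
        return self._records.keys() == other._records.keys()

    def __repr__(self) -> str:
        return f"DMICatalog({len(self)} records)"


def dmi_domains_for_motif(catalog: DMICatalog, elm_id: str) -> set[str]:
    """Pfam domains recorded as binding the given ELM class (empty if unknown)."""
    return set(catalog._by_motif.get(elm_id, ()))


def dmi_motifs_for_domain(catalog: DMICatalog, domain: str) -> set[str]:
    """Inverse query: ELM classes recorded as binding the given domain."""
    return set(catalog._by_domain.get(normalize_pfam(domain), ()))


_ELM_ID_COLUMNS = ("ELM identifier", "ELMIdentifier", "elm_identifier", "elm_id")
_ELM_DOMAIN_COLUMNS = ("Interaction Domain Id", "interaction_domain_id", "pfam", "domain")


def _find_column(df: pd.DataFrame, candidates: Sequence[str], what: str,
                 path: Path) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise CatalogSchemaError(f"{path}: no {what} column among {list(df.columns)}")


def load_dmi_catalog(path: str | Path) -> DMICatalog:
    """Load a DMI catalog from an ELM interaction-domains TSV.

    Expects a header row with an ELM identifier column and an interaction
    domain (Pfam) column; duplicate rows collapse to one record, and rows
    missing either identifier are skipped with a logged warning.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"DMI table not readable: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    elm_col = _find_column(df, _ELM_ID_COLUMNS, "ELM identifier", path)
    dom_col = _find_column(df, _ELM_DOMAIN_COLUMNS, "interaction-domain Pfam", path)
    catalog = DMICatalog()
    for i, row in df.iterrows():
        elm_id, domain = row[elm_col], row[dom_col]
        if pd.isna(elm_id) or pd.isna(domain) or not str(elm_id).strip():
            logger.warning("%s row %d: missing ELM or Pfam identifier, skipped", path, i)
            continue
        try:
            catalog.add(DMIRecord(str(elm_id).strip(), str(domain)))
        except (PfamIdError, ValueError) as exc:
            logger.warning("%s row %d: %s, skipped", path, i, exc)
    logger.info("loaded DMI catalog: %d records from %s", len(catalog), path)
    return catalog


# ---------------------------------------------------------------------------
# Motif classes (ELM regex definitions)


@dataclass(frozen=True)
class MotifClass:
    """An ELM motif class: identifier plus the regular expression defining it."""

    elm_id: str
    pattern: str
    description: str = ""

    def __post_init__(self) -> None:
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(
                f"motif class {self.elm_id}: invalid pattern {self.pattern!r}: {exc}"
            ) from exc


def load_motif_classes(path: str | Path) -> list[MotifClass]:
    """Read an ELM classes TSV (columns ELMIdentifier, Regex, Description)."""
    path = Path(path)
    if not path.is_file():
        raise IOError(f"ELM classes table not readable: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    elm_col = _find_column(df, _ELM_ID_COLUMNS, "ELM identifier", path)
    rx_col = _find_column(df, ("Regex", "regex", "pattern"), "regex", path)
    desc_col = next((c for c in ("Description", "description") if c in df.columns), None)
    classes = []
    for _, row in df.iterrows():
        desc = "" if desc_col is None or pd.isna(row[desc_col]) else str(row[desc_col])
        classes.append(MotifClass(str(row[elm_col]).strip(), str(row[rx_col]), desc))
    return classes
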