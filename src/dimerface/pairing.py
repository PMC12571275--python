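"""Bottom-up interface prediction by catalog cross-referencing.

Given the located domains and motifs of two proteins, emit an interaction
candidate for every cross-protein region pair that is a catalogued
domain-domain (DDI) or domain-motif (DMI) interaction -- i.e. only when
each protein carries one-half of a known pair.  Motif-motif pairing is not
a capability: no catalog documents motif-motif interactions, so motif-only
input on both sides is an explicit error rather than an empty result.

Candidates are occurrence-level (one row per concrete region pair) because
the downstream structural filter needs concrete coordinates, and the
candidate table can directly drive cropped-FASTA export for structure
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import DomainHit, MotifHit, ProteinRecord
from .interaction_db import DDICatalog, DMICatalog, dmi_domains_for_motif

DOMAIN = "domain"
MOTIF = "motif"


class MotifMotifError(ValueError):
    """Motif-only x motif-only input: prediction requires domain information
    for at least one protein."""

    def __init__(self) -> None:
        super().__init__(
            "motif-motif interactions not supported; "
            "provide domain information for at least one protein"
        )


@dataclass(frozen=True, order=True)
class RegionRef:
    """A located region on one protein: a domain (Pfam ID) or motif (ELM ID)."""

    protein: str
    kind: str  # DOMAIN or MOTIF
    id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in (DOMAIN, MOTIF):
            raise ValueError(f"kind must be {DOMAIN!r} or {MOTIF!r}: {self.kind!r}")


@dataclass(frozen=True, order=True)
class InteractionCandidate:
    """A matched cross-protein region pair with its catalog provenance."""

    a: RegionRef
    b: RegionRef
    interaction_kind: str  # "DDI" or "DMI"
    catalog_key: str

    def __post_init__(self) -> None:
        kinds = {self.a.kind, self.b.kind}
        if self.interaction_kind == "DDI" and kinds != {DOMAIN}:
            raise ValueError("DDI candidates must pair two domains")
        if self.interaction_kind == "DMI" and kinds != {DOMAIN, MOTIF}:
            raise ValueError("DMI candidates must pair one domain with one motif")

    def swapped(self) -> "InteractionCandidate":
        return InteractionCandidate(self.b, self.a, self.interaction_kind,
                                    self.catalog_key)


@dataclass
class ProteinAnnotations:
    """The annotation bundle for one protein: domain hits, motif hits, or both."""

    identifier: str
    domains: list[DomainHit] = field(default_factory=list)
    motifs: list[MotifHit] = field(default_factory=list)


def _domain_ref(hit: DomainHit) -> RegionRef:
    return RegionRef(hit.protein, DOMAIN, hit.pfam, hit.start, hit.end)


def _motif_ref(hit: MotifHit) -> RegionRef:
    return RegionRef(hit.protein, MOTIF, hit.elm_id, hit.start, hit.end)


_SORT_KEY = lambda c: (c.interaction_kind, c.a.start, c.b.start, c.a.id, c.b.id)  # noqa: E731


def predict_ddis(
    hits_a: Sequence[DomainHit],
    hits_b: Sequence[DomainHit],
    catalog: DDICatalog,
) -> list[InteractionCandidate]:
    """One candidate per (domain occurrence on A, domain occurrence on B)
    whose Pfam pair is catalogued.  Repeated domains yield one candidate per
    occurrence pair.  Deterministic order: (a.start, b.start)."""
    out = [
        InteractionCandidate(
            _domain_ref(ha), _domain_ref(hb), "DDI",
            "--".join(sorted((ha.pfam, hb.pfam))),
        )
        for ha in hits_a
        for hb in hits_b
        if catalog.has(ha.pfam, hb.pfam)
    ]
    out.sort(key=_SORT_KEY)
    return out


def predict_dmis(
    domain_hits: Sequence[DomainHit],
    motif_hits: Sequence[MotifHit],
    catalog: DMICatalog,
) -> list[InteractionCandidate]:
    """One candidate per (domain occurrence, motif occurrence) whose
    (ELM class, Pfam) pairing is catalogued.  The domain and motif hits must
    annotate *different* proteins of the input pair; the caller invokes both
    directions."""
    out = []
    for hm in motif_hits:
        domains = dmi_domains_for_motif(catalog, hm.elm_id)
        if not domains:
            continue
        for hd in domain_hits:
            if hd.pfam in domains:
                out.append(
                    InteractionCandidate(
                        _domain_ref(hd), _motif_ref(hm), "DMI",
                        f"{hm.elm_id}--{hd.pfam}",
                    )
                )
    out.sort(key=_SORT_KEY)
    return out


def predict_interactions(
    annot_a: ProteinAnnotations,
    annot_b: ProteinAnnotations,
    ddi_catalog: DDICatalog,
    dmi_catalog: DMICatalog,
) -> list[InteractionCandidate]:
    """Full bottom-up prediction for one protein pair.

    Union of DDI(A, B), DMI(domains of A, motifs of B) and DMI(domains of B,
    motifs of A), with every candidate normalized so that RegionRef ``a``
    belongs to ``annot_a``.  Raises :class:`MotifMotifError` when both
    proteins are motif-only.
    """
    if not annot_a.domains and not annot_b.domains:
        raise MotifMotifError()
    candidates = list(predict_ddis(annot_a.domains, annot_b.domains, ddi_catalog))
    candidates += predict_dmis(annot_a.domains, annot_b.motifs, dmi_catalog)
    # domain on B, motif on A: swap so `a` stays on protein A's side
    candidates += [
        c.swapped() for c in predict_dmis(annot_b.domains, annot_a.motifs, dmi_catalog)
    ]
    candidates.sort(key=_SORT_KEY)
    return candidates


def count_candidate_pairings(n_domains: int, n_motifs: int) -> int:
    """Number of domain:motif compatibility checks before catalog filtering.

    This is the size of the manual-inspection burden the catalog lookup
    replaces: every domain occurrence against every motif occurrence.
    """
    if n_domains < 0 or n_motifs < 0:
        raise ValueError("counts must be non-negative")
    return n_domains * n_motifs


# ---------------------------------------------------------------------------
# Candidate table I/O

_TABLE_COLUMNS = [
    "protein_a", "kind_a", "id_a", "start_a", "end_a",
    "protein_b", "kind_b", "id_b", "start_b", "end_b",
    "interaction_kind", "catalog_key",
]


def candidates_to_dataframe(candidates: Sequence[InteractionCandidate]) -> pd.DataFrame:
    rows = [
        {
            "protein_a": c.a.protein, "kind_a": c.a.kind, "id_a": c.a.id,
            "start_a": c.a.start, "end_a": c.a.end,
            "protein_b": c.b.protein, "kind_b": c.b.kind, "id_b": c.b.id,
            "start_b": c.b.start, "end_b": c.b.end,
            "interaction_kind": c.interaction_kind, "catalog_key": c.catalog_key,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_candidates_tsv(candidates: Sequence[InteractionCandidate],
                         path: str | Path) -> None:
    candidates_to_dataframe(candidates).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> list[InteractionCandidate]:
    path = Path(path)
    if not path.is_file():
        raise IOError(f"candidate table not readable: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    out = []
    for _, r in df.iterrows():
        out.append(
            InteractionCandidate(
                RegionRef(str(r.protein_a), str(r.kind_a), str(r.id_a),
                          int(r.start_a), int(r.end_a)),
                RegionRef(str(r.protein_b), str(r.kind_b), str(r.id_b),
                          int(r.start_b), int(r.end_b)),
                str(r.interaction_kind), str(r.catalog_key),
            )
        )
    return out


def write_cropped_fasta(
    candidates: Sequence[InteractionCandidate],
    sequences: Mapping[str, ProteinRecord],
    path: str | Path,
    flank: int = 0,
) -> None:
    """Write each protein's candidate regions as FASTA records (with an
    optional symmetric flank, clipped to the sequence), for downstream
    structure prediction of just the putative interface."""
    seen: set[tuple[str, int, int]] = set()
    with open(path, "w") as fh:
        for c in candidates:
            for ref in (c.a, c.b):
                record = sequences.get(ref.protein)
                if record is None:
                    raise KeyError(f"no sequence supplied for {ref.protein}")
                start = max(1, ref.start - flank)
                end = min(len(record), ref.end + flank)
                key = (ref.protein, start, end)
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f">{ref.protein}_{start}-{end} {ref.kind}:{ref.id}\n")
                fh.write(record.sequence[start - 1:end] + "\n")
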