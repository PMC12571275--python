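"""Top-down interface validation on a 3D dimer model.

Candidate interfaces from the bottom-up stage are mapped onto the chains of
a dimer structure (e.g. AlphaFold-Multimer output) and filtered by the
minimum alpha-carbon (CA) distance between the two regions.  The CA is each
residue's representative point, following contact-map convention; the
recommended sweep runs the cutoff from 11 Å -- the interaction range of
coarse-grained CA elastic-network models -- down to 4 Å in 1 Å steps.

Region coordinates are annotation (sequence) coordinates; by default these
equal structure residue numbers, which holds for AlphaFold output, and a
per-chain integer offset accommodates renumbered experimental PDB entries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .pairing import InteractionCandidate

logger = logging.getLogger(__name__)

DEFAULT_SWEEP: tuple[float, ...] = tuple(float(c) for c in range(11, 3, -1))

_STANDARD_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL SEC PYL".split()
)


class StructureFormatError(ValueError):
    """Raised when a structure file has no usable coordinate records."""


class ChainNotFoundError(KeyError):
    """Raised when a requested chain is absent from the model."""


class UndefinedDistanceError(ValueError):
    """Raised when a region distance is requested for an empty selection.

    Distinct from a large distance: a region with no resolved residues has
    *no* distance, and must not be conflated with a failing candidate.
    """


class ChainMapError(ValueError):
    """Raised when the chain map does not resolve a candidate's proteins."""


@dataclass(frozen=True)
class Residue:
    number: int
    icode: str  # "" when absent
    aa: str  # 3-letter code
    ca: tuple[float, float, float] | None


@dataclass
class StructureModel:
    """Chains of residues with CA coordinates in Å (first model only)."""

    chains: dict[str, list[Residue]]
    source: str = ""

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ChainNotFoundError(
                f"chain {chain_id!r} not in model (has {sorted(self.chains)})"
            ) from None

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)


def parse_structure(path: str | Path) -> StructureModel:
    """Parse a PDB-format file into a CA-level model.

    Only the first model of a multi-model file is read.  Alternate locations
    are resolved to the highest-occupancy conformer (ties broken by altloc
    letter).  HETATM residues are ignored unless they are standard amino
    acids flagged as HETATM, which are kept.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no ATOM records / no model")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    n_ca = 0
    for chain in model:
        residues: list[Residue] = []
        seen: set[tuple[int, str]] = set()
        for res in chain:
            if res.het_flag == "H" and res.name not in _STANDARD_AA3:
                continue
            icode = res.seqid.icode.strip()
            key = (res.seqid.num, icode)
            if key in seen:
                logger.warning("%s: duplicate residue %s%s in chain %s; first kept",
                               path, res.seqid.num, icode, chain.name)
                continue
            cas = [a for a in res if a.name == "CA" and a.element.name != "Ca"]
            ca: tuple[float, float, float] | None = None
            if cas:
                # altloc resolution: highest occupancy, ties by altloc letter
                cas.sort(key=lambda a: (-a.occ, a.altloc or ""))
                best = cas[0]
                dup = [a for a in cas if (a.altloc or "") == (best.altloc or "")]
                if len(dup) > 1:
                    logger.warning("%s: duplicate CA in %s/%s%s; first kept",
                                   path, chain.name, res.seqid.num, icode)
                ca = (best.pos.x, best.pos.y, best.pos.z)
                n_ca += 1
            seen.add(key)
            residues.append(Residue(res.seqid.num, icode, res.name, ca))
        if residues:
            chains[chain.name] = residues
    if not chains or n_ca == 0:
        raise StructureFormatError(f"{path}: no amino-acid CA atoms found")
    return StructureModel(chains, source=str(path))


@dataclass
class ChainMap:
    """Maps the two proteins of a candidate pair onto model chains.

    ``offset_*`` converts annotation coordinates to structure numbering:
    structure residue number = annotation coordinate + offset.
    """

    protein_a: str
    chain_a: str
    protein_b: str
    chain_b: str
    offset_a: int = 0
    offset_b: int = 0

    def resolve(self, protein: str) -> tuple[str, int]:
        if protein == self.protein_a:
            return self.chain_a, self.offset_a
        if protein == self.protein_b:
            return self.chain_b, self.offset_b
        raise ChainMapError(f"chain map does not cover protein {protein!r}")

    @classmethod
    def first_two_chains(cls, model: StructureModel, protein_a: str,
                         protein_b: str) -> "ChainMap":
        """Default assignment: first two chains in file order -> A, B."""
        ids = model.chain_ids
        if len(ids) < 2:
            raise ChainMapError(f"model has {len(ids)} chain(s); need 2")
        return cls(protein_a, ids[0], protein_b, ids[1])


@dataclass
class Selection:
    """Residues of one chain inside a structure-numbering window, CA only.

    ``coverage`` is the fraction of the requested residue span that is
    resolved (has a CA) in the model.  Ranges select by residue number,
    ignoring insertion codes.
    """

    chain: str
    residues: list[Residue]
    start: int
    end: int

    @property
    def coverage(self) -> float:
        span = self.end - self.start + 1
        return len(self.residues) / span if span > 0 else 0.0

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.residues)


def select_region(model: StructureModel, chain: str, start: int, end: int) -> Selection:
    """All residues of ``chain`` with start <= number <= end that have a CA."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    residues = [
        r for r in model.chain(chain) if start <= r.number <= end and r.ca is not None
    ]
    return Selection(chain, residues, start, end)


def min_region_distance(sel_a: Selection, sel_b: Selection) -> float:
    """Minimum Euclidean CA-CA distance over the cross product of two
    selections (symmetric; raises :class:`UndefinedDistanceError` on empty
    selections)."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise UndefinedDistanceError(
            f"empty selection: {sel_a.chain}:{sel_a.start}-{sel_a.end} "
            f"({len(sel_a)} res) vs {sel_b.chain}:{sel_b.start}-{sel_b.end} "
            f"({len(sel_b)} res)"
        )
    xa, xb = sel_a.coords, sel_b.coords
    # same arithmetic as contact_residue_pairs, so pass/fail and contact
    # labeling can never disagree at an exact cutoff boundary
    dmat = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2))
    return float(dmat.min())


@dataclass(frozen=True)
class ContactPair:
    """One CA pair within the cutoff, labeled for reporting."""

    chain_a: str
    number_a: int
    aa_a: str
    chain_b: str
    number_b: int
    aa_b: str
    distance: float


def contact_residue_pairs(
    sel_a: Selection,
    sel_b: Selection,
    cutoff: float,
    use_kdtree: bool = False,
) -> list[ContactPair]:
    """Every CA pair with distance <= cutoff, sorted by distance ascending.

    ``use_kdtree`` prunes the pair search with a k-d tree for large regions;
    pass/fail is identical to the dense path because retained distances are
    recomputed with the same arithmetic.
    """
    if len(sel_a) == 0 or len(sel_b) == 0:
        return []
    xa, xb = sel_a.coords, sel_b.coords
    if use_kdtree:
        # inflate the tree radius slightly, then re-filter with the exact
        # arithmetic so pass/fail matches the dense path bit for bit
        neighbor_lists = cKDTree(xa).query_ball_tree(cKDTree(xb), cutoff + 1e-9)
        idx_pairs = [(i, j) for i, js in enumerate(neighbor_lists) for j in js]
        if not idx_pairs:
            return []
        ii = np.array([p[0] for p in idx_pairs])
        jj = np.array([p[1] for p in idx_pairs])
        dists = np.sqrt(((xa[ii] - xb[jj]) ** 2).sum(axis=1))
        keep = dists <= cutoff
        ii, jj, dists = ii[keep], jj[keep], dists[keep]
        triples = list(zip(ii.tolist(), jj.tolist(), dists.tolist()))
    else:
        dmat = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2))
        ii, jj = np.nonzero(dmat <= cutoff)
        triples = [(int(i), int(j), float(dmat[i, j])) for i, j in zip(ii, jj)]
    pairs = [
        ContactPair(
            sel_a.chain, sel_a.residues[i].number, sel_a.residues[i].aa,
            sel_b.chain, sel_b.residues[j].number, sel_b.residues[j].aa,
            d,
        )
        for i, j, d in triples
    ]
    pairs.sort(key=lambda p: (p.distance, p.number_a, p.number_b))
    return pairs


@dataclass
class ContactReport:
    """Distance evaluation of one candidate on the model."""

    candidate: InteractionCandidate
    min_distance: float
    contact_pairs: list[ContactPair]
    coverage_a: float
    coverage_b: float


@dataclass
class DistanceFilterResult:
    """Outcome of distance filtering: candidates that pass the cutoff, those
    that fail it, and candidates that could not be evaluated because a
    region has no resolved residues (a third category, never silently folded
    into pass or fail)."""

    cutoff: float
    passed: list[ContactReport]
    failed: list[ContactReport]
    unevaluable: list[InteractionCandidate]


def _candidate_selections(
    candidate: InteractionCandidate, model: StructureModel, chain_map: ChainMap
) -> tuple[Selection, Selection]:
    chain_a, off_a = chain_map.resolve(candidate.a.protein)
    chain_b, off_b = chain_map.resolve(candidate.b.protein)
    sel_a = select_region(model, chain_a, candidate.a.start + off_a,
                          candidate.a.end + off_a)
    sel_b = select_region(model, chain_b, candidate.b.start + off_b,
                          candidate.b.end + off_b)
    return sel_a, sel_b


def evaluate_candidate(
    candidate: InteractionCandidate,
    model: StructureModel,
    chain_map: ChainMap,
    cutoff: float,
    label_contacts: bool = True,
) -> ContactReport | None:
    """ContactReport for one candidate, or None when unevaluable."""
    sel_a, sel_b = _candidate_selections(candidate, model, chain_map)
    if len(sel_a) == 0 or len(sel_b) == 0:
        return None
    md = min_region_distance(sel_a, sel_b)
    pairs = contact_residue_pairs(sel_a, sel_b, cutoff) if label_contacts else []
    return ContactReport(candidate, md, pairs, sel_a.coverage, sel_b.coverage)


def filter_by_distance(
    candidates: Sequence[InteractionCandidate],
    model: StructureModel,
    chain_map: ChainMap,
    cutoff: float,
    label_contacts: bool = True,
) -> DistanceFilterResult:
    """Partition candidates by whether their minimum CA-CA distance is
    within ``cutoff`` (comparison is <=, full double precision, no epsilon)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive: {cutoff}")
    passed: list[ContactReport] = []
    failed: list[ContactReport] = []
    unevaluable: list[InteractionCandidate] = []
    for cand in candidates:
        report = evaluate_candidate(cand, model, chain_map, cutoff, label_contacts)
        if report is None:
            unevaluable.append(cand)
        elif report.min_distance <= cutoff:
            passed.append(report)
        else:
            failed.append(report)
    return DistanceFilterResult(cutoff, passed, failed, unevaluable)


@dataclass
class SweepResult:
    """Per-cutoff pass sets plus each candidate's detection distance: the
    smallest swept cutoff at which it passes (None if it passes none, i.e.
    beyond the largest cutoff)."""

    cutoffs: list[float]
    min_distances: dict[InteractionCandidate, float]
    unevaluable: list[InteractionCandidate]

    def pass_set(self, cutoff: float) -> set[InteractionCandidate]:
        return {c for c, d in self.min_distances.items() if d <= cutoff}

    @property
    def detection_distance(self) -> dict[InteractionCandidate, float | None]:
        out: dict[InteractionCandidate, float | None] = {}
        for cand, d in self.min_distances.items():
            passing = [c for c in self.cutoffs if d <= c]
            out[cand] = min(passing) if passing else None
        return out


def distance_sweep(
    candidates: Sequence[InteractionCandidate],
    model: StructureModel,
    chain_map: ChainMap,
    cutoffs: Sequence[float] = DEFAULT_SWEEP,
) -> SweepResult:
    """Sweep the contact cutoff (default 11 Å down to 4 Å in 1 Å steps).

    Each candidate's minimum distance is computed once, so pass sets are
    nested by construction: pass(d1) ⊆ pass(d2) whenever d1 <= d2.
    """
    if any(c <= 0 for c in cutoffs):
        raise ValueError("cutoffs must be positive")
    min_distances: dict[InteractionCandidate, float] = {}
    unevaluable: list[InteractionCandidate] = []
    for cand in candidates:
        sel_a, sel_b = _candidate_selections(cand, model, chain_map)
        if len(sel_a) == 0 or len(sel_b) == 0:
            unevaluable.append(cand)
        else:
            min_distances[cand] = min_region_distance(sel_a, sel_b)
    return SweepResult(sorted(float(c) for c in cutoffs), min_distances, unevaluable)


# ---------------------------------------------------------------------------
# Report writers


def _candidate_cells(c: InteractionCandidate) -> list[str]:
    return [
        c.a.protein, c.a.kind, c.a.id, str(c.a.start), str(c.a.end),
        c.b.protein, c.b.kind, c.b.id, str(c.b.start), str(c.b.end),
        c.interaction_kind, c.catalog_key,
    ]


_REPORT_HEADER = (
    "protein_a\tkind_a\tid_a\tstart_a\tend_a\t"
    "protein_b\tkind_b\tid_b\tstart_b\tend_b\t"
    "interaction_kind\tcatalog_key\tstatus\tmin_distance\tn_contacts\t"
    "coverage_a\tcoverage_b\n"
)


def write_contact_reports_tsv(result: DistanceFilterResult, path: str | Path) -> None:
    """TSV report: one row per candidate with status pass/fail/unevaluable.

    Å values are formatted to 3 decimals (internal comparisons always use
    full precision)."""
    with open(path, "w") as fh:
        fh.write(_REPORT_HEADER)
        for status, reports in (("pass", result.passed), ("fail", result.failed)):
            for r in reports:
                fh.write("\t".join(
                    _candidate_cells(r.candidate)
                    + [status, f"{r.min_distance:.3f}", str(len(r.contact_pairs)),
                       f"{r.coverage_a:.3f}", f"{r.coverage_b:.3f}"]
                ) + "\n")
        for cand in result.unevaluable:
            fh.write("\t".join(_candidate_cells(cand)
                               + ["unevaluable", "", "0", "0.000", "0.000"]) + "\n")


def write_contact_reports_json(result: DistanceFilterResult, path: str | Path) -> None:
    """JSON report including the full labeled contact-pair lists."""
    def report_obj(r: ContactReport, status: str) -> dict:
        return {
            "candidate": dict(zip(
                ["protein_a", "kind_a", "id_a", "start_a", "end_a",
                 "protein_b", "kind_b", "id_b", "start_b", "end_b",
                 "interaction_kind", "catalog_key"],
                _candidate_cells(r.candidate))),
            "status": status,
            "min_distance": round(r.min_distance, 3),
            "coverage_a": round(r.coverage_a, 3),
            "coverage_b": round(r.coverage_b, 3),
            "contacts": [
                {"chain_a": p.chain_a, "residue_a": p.number_a, "aa_a": p.aa_a,
                 "chain_b": p.chain_b, "residue_b": p.number_b, "aa_b": p.aa_b,
                 "distance": round(p.distance, 3)}
                for p in r.contact_pairs
            ],
        }

    payload = {
        "cutoff": result.cutoff,
        "reports": [report_obj(r, "pass") for r in result.passed]
        + [report_obj(r, "fail") for r in result.failed],
        "unevaluable": [dict(zip(
            ["protein_a", "kind_a", "id_a", "start_a", "end_a",
             "protein_b", "kind_b", "id_b", "start_b", "end_b",
             "interaction_kind", "catalog_key"], _candidate_cells(c)))
            for c in result.unevaluable],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_sweep_tsv(sweep: SweepResult, path: str | Path) -> None:
    """Candidate x cutoff pass matrix plus per-candidate detection distance."""
    with open(path, "w") as fh:
        header = ["protein_a", "id_a", "start_a", "protein_b", "id_b", "start_b",
                  "interaction_kind", "min_distance"]
        header += [f"pass_{c:g}A" for c in sweep.cutoffs]
        header.append("detection_distance")
        fh.write("\t".join(header) + "\n")
        detection = sweep.detection_distance
        for cand in sorted(sweep.min_distances,
                           key=lambda c: (c.interaction_kind, c.a.start, c.b.start)):
            d = sweep.min_distances[cand]
            det = detection[cand]
            row = [cand.a.protein, cand.a.id, str(cand.a.start),
                   cand.b.protein, cand.b.id, str(cand.b.start),
                   cand.interaction_kind, f"{d:.3f}"]
            row += ["1" if d <= c else "0" for c in sweep.cutoffs]
            row.append(f"{det:g}" if det is not None else f">{max(sweep.cutoffs):g}")
            fh.write("\t".join(row) + "\n")
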