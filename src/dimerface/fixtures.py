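"""Deterministic synthetic fixtures: dimer structures with planted interfaces.

The generator lays each candidate region out as a straight run of CA atoms
(3.8 Å consecutive-CA spacing, the trans-peptide value) on chain A and
chain B of a two-chain PDB file.  A *planted* pair puts the two runs on
parallel segments separated exactly by the target distance, so the minimum
CA-CA distance is realized by construction; a *decoy* pair is separated by
at least a stated floor (default 20 Å, far outside any biologically
meaningful contact cutoff).  Pairs occupy well-separated slots along x so
cross-pair distances are always large.

Matching toy annotations and catalogs are generated so that the bottom-up
stage emits exactly the planted + decoy candidates and the top-down filter
at a mid-range cutoff (e.g. 6 Å) keeps exactly the planted ones.  This
emulates what the pipeline must get right -- catalog matching and geometry
-- not the messiness of real data: no unresolved residues, no numbering
offsets, no near-threshold ambiguity unless explicitly planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import DomainHit, MotifHit, write_elm_predict_tsv, write_interproscan_tsv
from .interaction_db import DDICatalog, DMICatalog, DMIRecord
from .pairing import ProteinAnnotations

CA_SPACING = 3.8  # Å between consecutive CA atoms along a region
SLOT_SPACING = 200.0  # Å between pair slots along x

_AA_CYCLE = ("GLY", "ALA", "SER", "LEU", "LYS", "GLU", "VAL", "THR")

PROTEIN_A = "PROT_A"
PROTEIN_B = "PROT_B"


class FixtureGeometryError(ValueError):
    """Raised when a fixture spec requests infeasible geometry."""


@dataclass(frozen=True)
class Region:
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FixtureGeometryError(f"bad region {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PlantedPair:
    """One region pair with a constructed minimum CA-CA distance."""

    kind: str  # "DDI" or "DMI"
    region_a: Region
    region_b: Region
    target_distance: float
    decoy: bool = False


@dataclass
class FixtureSpec:
    seed: int
    pairs: list[PlantedPair]
    n_chains: int = 2
    residues_per_chain: int = 0  # informational; regions define the residues
    decoy_floor: float = 20.0

    def __post_init__(self) -> None:
        if self.n_chains != 2:
            raise FixtureGeometryError("only two-chain dimers are generated")
        for p in self.pairs:
            if p.target_distance <= 0:
                raise FixtureGeometryError(f"non-positive distance {p.target_distance}")
            if p.decoy and p.target_distance < self.decoy_floor:
                raise FixtureGeometryError(
                    f"decoy at {p.target_distance} Å below floor {self.decoy_floor}"
                )
        for chain_regions in (
            [p.region_a for p in self.pairs], [p.region_b for p in self.pairs]
        ):
            spans = sorted((r.start, r.end) for r in chain_regions)
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise FixtureGeometryError("overlapping regions on one chain")

    @property
    def planted(self) -> list[PlantedPair]:
        return [p for p in self.pairs if not p.decoy]

    @property
    def decoys(self) -> list[PlantedPair]:
        return [p for p in self.pairs if p.decoy]


def default_fixture_spec(seed: int) -> FixtureSpec:
    """The standard study condition: 3 planted pairs (2 DDI + 1 DMI) at
    4.5-5.5 Å and 2 decoy pairs (1 DDI + 1 DMI) at 20-40 Å."""
    rng = np.random.default_rng(seed)
    layout = [("DDI", False), ("DDI", False), ("DMI", False),
              ("DDI", True), ("DMI", True)]
    pairs = []
    for i, (kind, decoy) in enumerate(layout):
        lo, hi = (20.0, 40.0) if decoy else (4.5, 5.5)
        d = round(float(rng.uniform(lo, hi)), 3)
        length_a = int(rng.integers(4, 9))
        length_b = int(rng.integers(4, 9)) if kind == "DDI" else int(rng.integers(4, 7))
        start = 20 * i + 1
        pairs.append(PlantedPair(kind, Region(start, start + length_a - 1),
                                 Region(start, start + length_b - 1), d, decoy))
    return FixtureSpec(seed=seed, pairs=pairs)


# ---------------------------------------------------------------------------
# Structure generation


def _region_coords(spec: FixtureSpec) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """CA coordinates per pair index, chain A and chain B, rounded to PDB
    precision (3 decimals) so the written file realizes them exactly."""
    coords_a: dict[int, np.ndarray] = {}
    coords_b: dict[int, np.ndarray] = {}
    for i, pair in enumerate(spec.pairs):
        x0 = SLOT_SPACING * i
        xs_a = x0 + CA_SPACING * np.arange(len(pair.region_a))
        xs_b = x0 + CA_SPACING * np.arange(len(pair.region_b))
        a = np.column_stack([xs_a, np.zeros_like(xs_a), np.zeros_like(xs_a)])
        b = np.column_stack([xs_b, np.full_like(xs_b, pair.target_distance),
                             np.zeros_like(xs_b)])
        coords_a[i] = np.round(a, 3)
        coords_b[i] = np.round(b, 3)
    return coords_a, coords_b


def _pdb_atom_line(serial: int, resname: str, chain: str, resseq: int,
                   xyz: np.ndarray) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  CA  {resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
    )


@dataclass
class GroundTruthEntry:
    pair_index: int
    kind: str
    decoy: bool
    region_a: Region
    region_b: Region
    min_distance: float  # achieved, from the written coordinates


@dataclass
class ToyStructure:
    pdb_text: str
    ground_truth: list[GroundTruthEntry]
    cross_distances: dict[tuple[int, int], float] = field(default_factory=dict)


def make_toy_structure(spec: FixtureSpec) -> ToyStructure:
    """Emit a valid PDB file realizing the spec's planted minimum distances.

    Byte-deterministic for a given spec.  The ground truth records every
    (chain A region i, chain B region j) pair's true minimum CA-CA distance
    as computed from the written (3-decimal) coordinates.
    """
    coords_a, coords_b = _region_coords(spec)
    rng = np.random.default_rng(spec.seed)
    lines: list[str] = ["HEADER    SYNTHETIC PLANTED-INTERFACE DIMER FIXTURE"]
    serial = 0
    for chain, coords, region_of in (
        ("A", coords_a, lambda p: p.region_a),
        ("B", coords_b, lambda p: p.region_b),
    ):
        for i, pair in enumerate(spec.pairs):
            region = region_of(pair)
            for k, resseq in enumerate(range(region.start, region.end + 1)):
                serial += 1
                resname = _AA_CYCLE[int(rng.integers(len(_AA_CYCLE)))]
                lines.append(_pdb_atom_line(serial, resname, chain, resseq,
                                            coords[i][k]))
        lines.append(f"TER   {serial + 1:5d}")
        serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    truth = []
    cross: dict[tuple[int, int], float] = {}
    for i in range(len(spec.pairs)):
        for j in range(len(spec.pairs)):
            diff = coords_a[i][:, None, :] - coords_b[j][None, :, :]
            d = float(np.sqrt((diff ** 2).sum(axis=2)).min())
            cross[(i, j)] = d
    for i, pair in enumerate(spec.pairs):
        achieved = cross[(i, i)]
        if abs(achieved - pair.target_distance) > 1e-3:
            raise FixtureGeometryError(
                f"pair {i}: achieved {achieved} vs target {pair.target_distance}"
            )
        truth.append(GroundTruthEntry(i, pair.kind, pair.decoy, pair.region_a,
                                      pair.region_b, achieved))
    return ToyStructure(pdb_text, truth, cross)


# ---------------------------------------------------------------------------
# Annotation + catalog generation


def _pair_ids(i: int, kind: str) -> tuple[str, str]:
    """Catalog identifiers for pair i: (id on protein A, id on protein B)."""
    if kind == "DDI":
        return f"PF9{i:02d}01", f"PF9{i:02d}02"
    return f"PF9{i:02d}03", f"LIG_SYN_{i + 1}"


@dataclass
class ToyAnnotations:
    annot_a: ProteinAnnotations
    annot_b: ProteinAnnotations
    ddi_catalog: DDICatalog
    dmi_catalog: DMICatalog
    expected_keys: dict[str, bool]  # catalog_key -> is_planted


def make_toy_annotations(spec: FixtureSpec) -> ToyAnnotations:
    """Annotations and catalogs whose catalogued pairs correspond exactly to
    the structural pairs of ``spec``: each pair gets its own private Pfam /
    ELM identifiers, so bottom-up prediction emits exactly one candidate per
    planted or decoy pair."""
    ddi = DDICatalog()
    dmi = DMICatalog()
    domains_a: list[DomainHit] = []
    domains_b: list[DomainHit] = []
    motifs_b: list[MotifHit] = []
    expected: dict[str, bool] = {}
    for i, pair in enumerate(spec.pairs):
        id_a, id_b = _pair_ids(i, pair.kind)
        domains_a.append(DomainHit(PROTEIN_A, id_a, pair.region_a.start,
                                   pair.region_a.end, f"toy domain {i}"))
        if pair.kind == "DDI":
            ddi.add(id_a, id_b, source="toy")
            domains_b.append(DomainHit(PROTEIN_B, id_b, pair.region_b.start,
                                       pair.region_b.end, f"toy domain {i}"))
            expected["--".join(sorted((id_a, id_b)))] = not pair.decoy
        else:
            dmi.add(DMIRecord(id_b, id_a))
            motifs_b.append(MotifHit(PROTEIN_B, id_b, pair.region_b.start,
                                     pair.region_b.end))
            expected[f"{id_b}--{id_a}"] = not pair.decoy
    return ToyAnnotations(
        ProteinAnnotations(PROTEIN_A, domains=domains_a),
        ProteinAnnotations(PROTEIN_B, domains=domains_b, motifs=motifs_b),
        ddi, dmi, expected,
    )


def write_fixture_files(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize a complete offline test workspace: PDB model, per-protein
    InterProScan-dialect domain TSVs, ELM-Predict-dialect motif TSV, and
    serialized DDI/DMI catalogs.  Returns the paths by role."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = make_toy_structure(spec)
    annotations = make_toy_annotations(spec)
    paths = {
        "pdb": outdir / "model.pdb",
        "a_domains": outdir / "protein_a.interproscan.tsv",
        "b_domains": outdir / "protein_b.interproscan.tsv",
        "b_motifs": outdir / "protein_b.elm_predict.tsv",
        "ddi": outdir / "ddi_catalog.tsv",
        "dmi": outdir / "dmi_catalog.tsv",
    }
    paths["pdb"].write_text(structure.pdb_text)
    write_interproscan_tsv(annotations.annot_a.domains, paths["a_domains"])
    write_interproscan_tsv(annotations.annot_b.domains, paths["b_domains"])
    write_elm_predict_tsv(annotations.annot_b.motifs, paths["b_motifs"])
    annotations.ddi_catalog.write(paths["ddi"])
    with open(paths["dmi"], "w") as fh:
        fh.write("ELM identifier\tInteraction Domain Id\n")
        for rec in annotations.dmi_catalog.records:
            fh.write(f"{rec.elm_id}\t{rec.domain}\n")
    return paths
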