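"""dimerface: candidate protein-protein interfaces from domain/motif
catalogs (bottom-up) and alpha-carbon contact-distance validation on dimer
models (top-down)."""

from .interaction_db import (
    DDICatalog,
    DMICatalog,
    DMIRecord,
    DdiSource,
    MotifClass,
    PfamIdError,
    compile_ddi_catalog,
    ddi_source_3did,
    ddi_source_domine,
    dmi_domains_for_motif,
    dmi_motifs_for_domain,
    has_ddi,
    load_dmi_catalog,
    load_motif_classes,
    normalize_pfam,
    read_ddi_catalog,
)
from .annotation import (
    DomainHit,
    MotifHit,
    NetworkDisabledError,
    ProteinRecord,
    fetch_domains,
    fetch_sequence,
    parse_elm_predict_tsv,
    parse_interproscan_tsv,
    read_fasta,
    scan_slims,
    write_elm_predict_tsv,
    write_interproscan_tsv,
)
from .pairing import (
    InteractionCandidate,
    MotifMotifError,
    ProteinAnnotations,
    RegionRef,
    count_candidate_pairings,
    predict_ddis,
    predict_dmis,
    predict_interactions,
    read_candidates_tsv,
    write_candidates_tsv,
    write_cropped_fasta,
)
from .structure_contacts import (
    ChainMap,
    ContactPair,
    ContactReport,
    DistanceFilterResult,
    StructureModel,
    UndefinedDistanceError,
    contact_residue_pairs,
    distance_sweep,
    filter_by_distance,
    min_region_distance,
    parse_structure,
    select_region,
)
from .fixtures import (
    FixtureSpec,
    PlantedPair,
    Region,
    default_fixture_spec,
    make_toy_annotations,
    make_toy_structure,
    write_fixture_files,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def toy_catalog_path(name: str):
    """Path to a bundled toy catalog table (ships in the package so every
    test and example runs offline).  Known names: toy_ddi_3did.tsv,
    toy_ddi_domine.tsv, toy_dmi_elm.tsv, toy_elm_classes.tsv."""
    from importlib.resources import files

    return files("dimerface").joinpath("data", name)
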