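"""Structure parsing and contact-distance geometry against brute-force oracles."""

import math
import random

import numpy as np
import pytest

from dimerface import (
    ChainMap,
    InteractionCandidate,
    RegionRef,
    contact_residue_pairs,
    distance_sweep,
    filter_by_distance,
    min_region_distance,
    parse_structure,
    predict_interactions,
    select_region,
)
from dimerface.structure_contacts import (
    ChainNotFoundError,
    Residue,
    Selection,
    StructureFormatError,
    StructureModel,
    UndefinedDistanceError,
    evaluate_candidate,
)


def _atom_line(serial, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ",
               record="ATOM  ", name=" CA "):
    return (
        f"{record}{serial:5d} {name}{altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}           C"
    )


def _write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def _selection(chain, coords, start=1):
    residues = [
        Residue(start + i, "", "GLY", tuple(c)) for i, c in enumerate(coords)
    ]
    return Selection(chain, residues, start, start + len(coords) - 1)


def _brute_min(coords_a, coords_b):
    return min(
        math.dist(p, q) for p in coords_a for q in coords_b
    )


class TestParseStructure:
    def test_two_chains_three_residues_each(self, tmp_path):
        lines = []
        serial = 0
        for chain in "AB":
            for i in range(3):
                serial += 1
                lines.append(_atom_line(serial, "ALA", chain, i + 1,
                                        float(i), 0.0, 0.0))
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        assert model.chain_ids == ["A", "B"]
        assert all(len(model.chain(c)) == 3 for c in "AB")
        assert all(r.ca is not None for c in "AB" for r in model.chain(c))

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        lines = [
            _atom_line(1, "SER", "A", 1, 1.0, 0.0, 0.0, occ=0.6, altloc="A"),
            _atom_line(2, "SER", "A", 1, 9.0, 0.0, 0.0, occ=0.4, altloc="B"),
        ]
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        assert model.chain("A")[0].ca == (1.0, 0.0, 0.0)

    def test_altloc_tie_broken_by_letter(self, tmp_path):
        lines = [
            _atom_line(1, "SER", "A", 1, 5.0, 0.0, 0.0, occ=0.5, altloc="B"),
            _atom_line(2, "SER", "A", 1, 1.0, 0.0, 0.0, occ=0.5, altloc="A"),
        ]
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        assert model.chain("A")[0].ca == (1.0, 0.0, 0.0)

    def test_hetatm_standard_amino_acid_kept_waters_dropped(self, tmp_path):
        lines = [
            _atom_line(1, "ALA", "A", 1, 0.0, 0.0, 0.0),
            _atom_line(2, "MET", "A", 2, 3.8, 0.0, 0.0, record="HETATM"),
            # water oxygen: must be ignored entirely
            f"HETATM    3  O   HOH A 100      0.000   0.000   9.000  1.00  0.00           O",
        ]
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        assert [r.aa for r in model.chain("A")] == ["ALA", "MET"]

    def test_only_first_model_of_multi_model_file(self, tmp_path):
        lines = (
            ["MODEL        1",
             _atom_line(1, "ALA", "A", 1, 0.0, 0.0, 0.0),
             "ENDMDL",
             "MODEL        2",
             _atom_line(1, "ALA", "A", 1, 99.0, 0.0, 0.0),
             "ENDMDL"]
        )
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        assert model.chain("A")[0].ca == (0.0, 0.0, 0.0)

    def test_no_atom_records_is_format_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(StructureFormatError):
            parse_structure(p)

    def test_toy_structure_round_trips_at_pdb_precision(self, toy_world):
        # every planted CA coordinate written by the generator must survive
        # write -> parse to 3 decimals
        model = toy_world["model"]
        spec = toy_world["spec"]
        for entry in toy_world["structure"].ground_truth:
            sel = select_region(model, "A", entry.region_a.start, entry.region_a.end)
            assert len(sel) == len(entry.region_a)
            xs = sel.coords[:, 0]
            assert np.allclose(np.diff(xs), 3.8, atol=1e-3)


class TestSelectRegion:
    def test_basic_window(self, tmp_path):
        lines = [_atom_line(i + 1, "GLY", "A", i + 1, float(i), 0.0, 0.0)
                 for i in range(3)]
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        sel = select_region(model, "A", 1, 2)
        assert [r.number for r in sel.residues] == [1, 2]
        assert sel.coverage == 1.0

    def test_window_beyond_chain_is_empty_with_zero_coverage(self, tmp_path):
        lines = [_atom_line(i + 1, "GLY", "A", i + 1, float(i), 0.0, 0.0)
                 for i in range(5)]
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        sel = select_region(model, "A", 10, 20)
        assert len(sel) == 0 and sel.coverage == 0.0

    def test_absent_chain_is_lookup_error(self, tmp_path):
        lines = [_atom_line(1, "GLY", "A", 1, 0.0, 0.0, 0.0)]
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        with pytest.raises(ChainNotFoundError):
            select_region(model, "Z", 1, 5)

    def test_gapped_chain_matches_list_filter_oracle(self, tmp_path):
        rng = random.Random(21)
        numbers = sorted(rng.sample(range(1, 120), 40))
        lines = [_atom_line(i + 1, "GLY", "A", n, float(i), 0.0, 0.0)
                 for i, n in enumerate(numbers)]
        model = parse_structure(_write_pdb(tmp_path / "m.pdb", lines))
        for _ in range(25):
            start = rng.randrange(1, 110)
            end = start + rng.randrange(0, 30)
            sel = select_region(model, "A", start, end)
            oracle = [n for n in numbers if start <= n <= end]
            assert [r.number for r in sel.residues] == oracle


class TestMinRegionDistance:
    def test_analytic_distance(self):
        a = _selection("A", [(0.0, 0.0, 0.0)])
        b = _selection("B", [(6.0, 0.0, 0.0)])
        assert min_region_distance(a, b) == 6.0

    def test_identical_selection_is_zero(self):
        a = _selection("A", [(1.5, 2.5, 3.5)])
        assert min_region_distance(a, a) == 0.0

    def test_empty_selection_is_undefined_not_large(self):
        a = _selection("A", [(0.0, 0.0, 0.0)])
        empty = Selection("B", [], 10, 20)
        with pytest.raises(UndefinedDistanceError):
            min_region_distance(a, empty)

    def test_seeded_random_selections_match_double_loop(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            ca = rng.uniform(-40, 40, size=(15, 3)).round(3)
            cb = rng.uniform(-40, 40, size=(15, 3)).round(3)
            sa, sb = _selection("A", ca), _selection("B", cb)
            expected = _brute_min(ca, cb)
            assert min_region_distance(sa, sb) == pytest.approx(expected, abs=1e-12)
            assert min_region_distance(sa, sb) == min_region_distance(sb, sa)

    def test_rigid_transform_changes_no_distance(self):
        rng = np.random.default_rng(12)
        ca = rng.uniform(-20, 20, size=(10, 3))
        cb = rng.uniform(-20, 20, size=(12, 3))
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-50, 50, size=3)
        d0 = min_region_distance(_selection("A", ca), _selection("B", cb))
        d1 = min_region_distance(_selection("A", ca @ q.T + t),
                                 _selection("B", cb @ q.T + t))
        assert abs(d0 - d1) < 1e-6


class TestContactResiduePairs:
    def test_constructed_three_pairs_under_cutoff(self):
        a = _selection("A", [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0)])
        # exactly three cross pairs fall under 5 Å: (1,1)=4.0, (2,2)=4.0,
        # (2,3)=4.5; the diagonals sit at sqrt(3.8^2+4^2)=5.52 and 5.89
        b = _selection("B", [(0.0, 4.0, 0.0), (3.8, 4.0, 0.0), (3.8, -4.5, 0.0)])
        pairs = contact_residue_pairs(a, b, cutoff=5.0)
        assert {(p.number_a, p.number_b) for p in pairs} == {(1, 1), (2, 2), (2, 3)}
        assert pairs[0].distance <= pairs[-1].distance == 4.5

    def test_cutoff_below_minimum_gives_empty_list(self):
        a = _selection("A", [(0.0, 0.0, 0.0)])
        b = _selection("B", [(0.0, 6.0, 0.0)])
        assert contact_residue_pairs(a, b, cutoff=5.9) == []

    def test_matches_enumeration_oracle_and_kdtree_parity(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            ca = rng.uniform(-15, 15, size=(20, 3)).round(3)
            cb = rng.uniform(-15, 15, size=(20, 3)).round(3)
            sa, sb = _selection("A", ca), _selection("B", cb)
            cutoff = float(rng.uniform(4, 12))
            pairs = contact_residue_pairs(sa, sb, cutoff)
            oracle = {
                (i + 1, j + 1)
                for i, p in enumerate(ca)
                for j, q in enumerate(cb)
                if math.dist(p, q) <= cutoff
            }
            assert {(p.number_a, p.number_b) for p in pairs} == oracle
            kd = contact_residue_pairs(sa, sb, cutoff, use_kdtree=True)
            assert [(p.number_a, p.number_b, p.distance) for p in kd] == [
                (p.number_a, p.number_b, p.distance) for p in pairs
            ]

    def test_labels_carry_chain_residue_and_amino_acid(self):
        a = Selection("A", [Residue(7, "", "TRP", (0.0, 0.0, 0.0))], 7, 7)
        b = Selection("B", [Residue(9, "", "HIS", (3.0, 0.0, 0.0))], 9, 9)
        (pair,) = contact_residue_pairs(a, b, cutoff=4.0)
        assert (pair.chain_a, pair.number_a, pair.aa_a) == ("A", 7, "TRP")
        assert (pair.chain_b, pair.number_b, pair.aa_b) == ("B", 9, "HIS")
        assert pair.distance == 3.0


def _toy_candidates(world):
    ann = world["annotations"]
    return predict_interactions(ann.annot_a, ann.annot_b,
                                ann.ddi_catalog, ann.dmi_catalog)


class TestFilterByDistance:
    def test_planted_pass_and_decoys_fail_at_six_angstroms(self, toy_world):
        cands = _toy_candidates(toy_world)
        result = filter_by_distance(cands, toy_world["model"],
                                    toy_world["chain_map"], cutoff=6.0)
        expected = toy_world["annotations"].expected_keys
        assert {r.candidate.catalog_key for r in result.passed} == {
            k for k, planted in expected.items() if planted
        }
        assert {r.candidate.catalog_key for r in result.failed} == {
            k for k, planted in expected.items() if not planted
        }
        assert result.unevaluable == []

    def test_cutoff_four_on_same_fixture_passes_nothing(self, toy_world):
        # planted distances are drawn from 4.5-5.5 Å, all above 4
        cands = _toy_candidates(toy_world)
        result = filter_by_distance(cands, toy_world["model"],
                                    toy_world["chain_map"], cutoff=4.0)
        assert result.passed == []

    def test_exact_boundary_distance_passes(self):
        # comparison is <= with no epsilon
        a = _selection("A", [(0.0, 0.0, 0.0)])
        b = _selection("B", [(6.0, 0.0, 0.0)])
        assert min_region_distance(a, b) == 6.0
        assert len(contact_residue_pairs(a, b, cutoff=6.0)) == 1

    def test_random_candidates_match_brute_force_recomputation(self, toy_world):
        rng = random.Random(13)
        model = toy_world["model"]
        spans_a = [(r.number, r.number) for r in model.chain("A")]
        cands = []
        for i in range(20):
            sa = rng.choice(spans_a)
            sb = rng.choice([(r.number, r.number) for r in model.chain("B")])
            cands.append(InteractionCandidate(
                RegionRef("PROT_A", "domain", f"PF{i:05d}", sa[0], sa[1]),
                RegionRef("PROT_B", "domain", f"PF{i + 50:05d}", sb[0], sb[1]),
                "DDI", f"PF{i:05d}--PF{i + 50:05d}"))
            # make each candidate's pair catalogued-looking; geometry is what's tested
        cutoff = 25.0
        result = filter_by_distance(cands, model, toy_world["chain_map"], cutoff)
        reported = {id(r.candidate): r.min_distance
                    for r in result.passed + result.failed}
        for cand in cands:
            sel_a = select_region(model, "A", cand.a.start, cand.a.end)
            sel_b = select_region(model, "B", cand.b.start, cand.b.end)
            expected = _brute_min([r.ca for r in sel_a.residues],
                                  [r.ca for r in sel_b.residues])
            assert reported[id(cand)] == pytest.approx(expected, abs=1e-12)

    def test_unresolved_region_is_unevaluable_not_fail(self, toy_world):
        cand = InteractionCandidate(
            RegionRef("PROT_A", "domain", "PF88888", 5000, 5010),
            RegionRef("PROT_B", "domain", "PF88889", 1, 8),
            "DDI", "PF88888--PF88889")
        result = filter_by_distance([cand], toy_world["model"],
                                    toy_world["chain_map"], cutoff=50.0)
        assert result.passed == [] and result.failed == []
        assert result.unevaluable == [cand]

    def test_missing_protein_in_chain_map_is_configuration_error(self, toy_world):
        from dimerface.structure_contacts import ChainMapError

        cand = _toy_candidates(toy_world)[0]
        bad_map = ChainMap("OTHER_A", "A", "OTHER_B", "B")
        with pytest.raises(ChainMapError):
            filter_by_distance([cand], toy_world["model"], bad_map, cutoff=6.0)

    def test_nonpositive_cutoff_rejected(self, toy_world):
        with pytest.raises(ValueError):
            filter_by_distance([], toy_world["model"], toy_world["chain_map"], 0.0)

    def test_pass_iff_contact_pairs_nonempty(self, toy_world):
        cands = _toy_candidates(toy_world)
        for cutoff in (4.0, 5.0, 6.0, 11.0, 30.0):
            result = filter_by_distance(cands, toy_world["model"],
                                        toy_world["chain_map"], cutoff)
            for r in result.passed:
                assert r.contact_pairs, "passing candidate must have contacts"
                assert all(p.distance <= cutoff for p in r.contact_pairs)
            for r in result.failed:
                assert r.contact_pairs == []


class TestDistanceSweep:
    def test_detection_distance_is_ceiling_of_min_distance(self, toy_world):
        cand = InteractionCandidate(
            RegionRef("PROT_A", "domain", "PF77777", 1, 8),
            RegionRef("PROT_B", "domain", "PF77778", 1, 8),
            "DDI", "PF77777--PF77778")
        sweep = distance_sweep([cand], toy_world["model"], toy_world["chain_map"])
        md = sweep.min_distances[cand]
        det = sweep.detection_distance[cand]
        assert det == float(math.ceil(md))

    def test_candidate_beyond_largest_cutoff_detected_nowhere(self, toy_world):
        # decoys sit at >= 20 Å: no default cutoff (11..4) can detect them
        cands = _toy_candidates(toy_world)
        sweep = distance_sweep(cands, toy_world["model"], toy_world["chain_map"])
        expected = toy_world["annotations"].expected_keys
        for cand, det in sweep.detection_distance.items():
            if not expected[cand.catalog_key]:
                assert det is None

    def test_pass_sets_are_nested_across_the_sweep(self, toy_world):
        cands = _toy_candidates(toy_world)
        sweep = distance_sweep(cands, toy_world["model"], toy_world["chain_map"])
        cutoffs = sweep.cutoffs
        for c1, c2 in zip(cutoffs, cutoffs[1:]):
            assert sweep.pass_set(c1) <= sweep.pass_set(c2)

    def test_sweep_agrees_with_filter_at_each_cutoff(self, toy_world):
        cands = _toy_candidates(toy_world)
        sweep = distance_sweep(cands, toy_world["model"], toy_world["chain_map"])
        for cutoff in sweep.cutoffs:
            result = filter_by_distance(cands, toy_world["model"],
                                        toy_world["chain_map"], cutoff,
                                        label_contacts=False)
            assert {r.candidate for r in result.passed} == sweep.pass_set(cutoff)
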