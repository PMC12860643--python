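"""Triad enumeration: surface scan, pair search, acid extension, gates."""

import numpy as np
import pytest

from triadscan.fixtures import make_pssm, make_scaffold
from triadscan.geometry import evaluate_triad_geometry, is_competent, stage_thresholds
from triadscan.model import TriadCandidate, TriadSpec
from triadscan.rotamers import apply_placement
from triadscan.search import (
    SearchParams,
    dedupe_and_rank,
    design_triads,
    exclusion_gate,
    extend_with_acid,
    find_ser_his_pairs,
    min_substitutions,
    pssm_gate,
    surface_positions,
)


class TestSurfacePositions:
    def test_all_residues_of_extended_peptide_are_surface(self):
        strand = make_scaffold(8, "strand")
        assert surface_positions(strand, 0.2) == list(range(1, 9))

    def test_buried_residue_excluded(self, cage):
        assert 1 not in surface_positions(cage, 0.2)

    def test_impossible_threshold_gives_empty_list(self, helix8):
        assert surface_positions(helix8, 1.1) == []


class TestPairSearch:
    def test_planted_pair_is_found(self, planted8):
        structure, spec = planted8
        pairs = find_ser_his_pairs(structure, [spec.ser_pos, spec.his_pos])
        assert any(
            p.ser.position == spec.ser_pos and p.his.position == spec.his_pos
            for p in pairs
        )

    def test_distant_positions_give_no_pairs(self, planted8):
        structure, _ = planted8
        long_strand = make_scaffold(12, "strand")
        # ends of an extended strand are far beyond the 4 A window
        assert find_ser_his_pairs(long_strand, [1, 12]) == []

    def test_every_returned_pair_passes_independent_recheck(self, planted8):
        structure, spec = planted8
        params = SearchParams()
        pairs = find_ser_his_pairs(structure, [spec.ser_pos, spec.his_pos], params)
        assert pairs
        for p in pairs[:: max(1, len(pairs) // 25)]:
            og = next(a.coords for a in p.ser.atoms if a.name == "OG")
            n = next(a.coords for a in p.his.atoms if a.name == p.tautomer)
            assert np.linalg.norm(og - n) <= params.d_ser_his_max + 1e-9
            assert params.ang_min <= p.ang_ser <= params.ang_max
            # the reported HG placement realises the reported angle
            hg = p.hg.coords
            u, v = og - hg, n - hg
            ang = np.degrees(
                np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
            )
            assert ang == pytest.approx(p.ang_ser, abs=1e-6)


class TestAcidExtension:
    def test_planted_acid_recovered_with_matching_kind(self, planted8):
        """Some geometry-compatible Ser/His pair extends to the planted acid
        position with the planted kind (extensibility depends on the His
        rotamer, so pairs are tried in order of distance match)."""
        structure, spec = planted8
        pairs = find_ser_his_pairs(structure, [spec.ser_pos, spec.his_pos])
        assert pairs
        found = False
        for pair in sorted(pairs, key=lambda p: abs(p.d_ser_his - 3.0)):
            cands = extend_with_acid(structure, pair)
            if any(
                c.spec.acid_pos == spec.acid_pos
                and c.spec.acid_kind == spec.acid_kind
                for c in cands
            ):
                found = True
                break
        assert found

    def test_isolated_his_gets_no_acid(self, planted8):
        structure, spec = planted8
        pairs = find_ser_his_pairs(structure, [spec.ser_pos, spec.his_pos])
        cands = extend_with_acid(structure, pairs[0], acid_positions=[])
        assert cands == []

    def test_both_kinds_can_coexist_at_one_position(self, design8):
        by_pos = {}
        for c in design8.candidates:
            by_pos.setdefault((c.spec.ser_pos, c.spec.his_pos, c.spec.acid_pos), set()).add(
                c.spec.acid_kind
            )
        assert any(kinds == {"ASP", "GLU"} for kinds in by_pos.values())


class TestGates:
    def test_pssm_gate_keeps_exactly_tolerant_candidates(self, planted8, design8):
        structure, spec = planted8
        tolerant = {spec.ser_pos, spec.his_pos, spec.acid_pos}
        pssm = make_pssm(structure.sequence(), tolerant_positions=tolerant, seed=3)
        kept = pssm_gate(design8.candidates, pssm, min_score=0)
        for c in design8.candidates:
            subs = {pl.position for pl in c.placements
                    if structure.residue(pl.position).aa != pl.aa}
            assert (c in kept) == subs.issubset(tolerant)

    def test_pssm_gate_passthrough_at_very_low_threshold(self, planted8, design8):
        structure, _ = planted8
        pssm = make_pssm(structure.sequence(), tolerant_positions=[], seed=3)
        assert len(pssm_gate(design8.candidates, pssm, min_score=-100)) == len(
            design8.candidates
        )

    def test_pssm_gate_missing_position_is_an_error(self, planted8, design8):
        structure, _ = planted8
        pssm = make_pssm(structure.sequence()[:4], tolerant_positions=[1], seed=0)
        with pytest.raises(KeyError):
            pssm_gate(design8.candidates, pssm, min_score=0)

    def test_exclusion_gate_empty_sites_is_identity(self, planted8, design8):
        structure, _ = planted8
        assert exclusion_gate(structure, design8.candidates, []) == list(design8.candidates)

    def test_exclusion_gate_drops_by_heavy_atom_distance(self, planted8, design8):
        structure, _ = planted8
        cands = design8.candidates
        site = 4
        kept = exclusion_gate(structure, cands, [site], min_dist=6.0)
        native_pts = np.array(
            [a.coords for a in structure.residue(site).atoms if a.element != "H"]
        )
        for c in cands:
            pts = [a.coords for pl in c.placements for a in pl.atoms if a.element != "H"]
            for pl in c.placements:
                res = structure.residue(pl.position)
                pts.extend(a.coords for a in res.atoms if a.name in ("N", "CA", "C", "O"))
            dmin = np.min(
                np.linalg.norm(np.array(pts)[:, None] - native_pts[None], axis=2)
            )
            assert (c in kept) == (dmin >= 6.0)

    def test_monotone_gate_sizes(self, planted8, design8):
        structure, spec = planted8
        pssm = make_pssm(
            structure.sequence(), tolerant_positions=[spec.ser_pos, spec.his_pos, spec.acid_pos],
            seed=1,
        )
        after_pssm = pssm_gate(design8.candidates, pssm)
        after_excl = exclusion_gate(structure, after_pssm, [2], min_dist=6.0)
        assert len(after_pssm) <= len(design8.candidates)
        assert len(after_excl) <= len(after_pssm)


class TestDedupe:
    def _cand(self, design8, clash):
        c = design8.candidates[0]
        return TriadCandidate(
            spec=c.spec, placements=c.placements, metrics=c.metrics,
            total_clash=clash, n_substitutions=c.n_substitutions,
        )

    def test_lowest_clash_representative_kept(self, design8):
        a, b = self._cand(design8, 0.1), self._cand(design8, 0.5)
        out = dedupe_and_rank([b, a])
        assert len(out) == 1 and out[0].total_clash == 0.1

    def test_disjoint_specs_all_kept_sorted_by_clash(self, design8):
        cands = design8.candidates[:4]
        out = dedupe_and_rank(cands)
        assert len(out) == len({c.spec.identity() for c in cands})
        clashes = [c.total_clash for c in out]
        assert clashes == sorted(clashes)

    def test_exact_tie_is_deterministic(self, design8):
        a, b = self._cand(design8, 0.3), self._cand(design8, 0.3)
        assert dedupe_and_rank([a, b]) == dedupe_and_rank([b, a])


class TestMinSubstitutions:
    def test_structure_source(self, planted8):
        structure, spec = planted8
        assert min_substitutions(structure, spec) == 0  # triad already installed

    def test_sequence_and_mapping_sources(self):
        spec = TriadSpec(2, 4, 6, "ASP")
        assert min_substitutions("ASAQAD", spec) == 1  # Q4H needed
        assert min_substitutions({2: "S", 4: "H", 6: "N"}, spec) == 1

    def test_all_native_matches_give_zero(self):
        assert min_substitutions("ASHDA", TriadSpec(2, 3, 4, "ASP")) == 0

    def test_missing_position_is_an_error(self):
        with pytest.raises(KeyError):
            min_substitutions("ASH", TriadSpec(2, 3, 9, "ASP"))


class TestDesignStage:
    def test_every_candidate_passes_independent_geometry_recheck(self, planted8, design8):
        structure, _ = planted8
        thresholds = stage_thresholds("design")
        assert design8.candidates
        for c in design8.candidates:
            mutated = structure
            for pl in c.placements:
                mutated = apply_placement(mutated, pl)
            m = evaluate_triad_geometry(mutated, c.spec)
            assert is_competent(m, thresholds), c.spec.key
            assert m.d_ser_his == pytest.approx(c.metrics.d_ser_his, abs=1e-6)
            assert m.d_his_acid == pytest.approx(c.metrics.d_his_acid, abs=1e-6)

    def test_design_is_deterministic(self, planted8, design8):
        structure, _ = planted8
        again = design_triads(structure)
        assert again.counts == design8.counts
        assert [c.spec.key for c in again.candidates] == [
            c.spec.key for c in design8.candidates
        ]
        assert [c.total_clash for c in again.candidates] == [
            c.total_clash for c in design8.candidates
        ]
        assert [tuple(pl.chis for pl in c.placements) for c in again.candidates] == [
            tuple(pl.chis for pl in c.placements) for c in design8.candidates
        ]

    def test_n_substitutions_counts_changed_positions(self, planted8, design8):
        structure, _ = planted8
        for c in design8.candidates[:20]:
            expected = sum(
                1 for pl in c.placements
                if structure.residue(pl.position).aa != pl.aa
            )
            assert c.n_substitutions == expected

    def test_counts_are_monotone_through_the_pipeline(self, design8):
        assert design8.counts["unique_triads"] <= design8.counts["triads_enumerated"]
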