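"""Independent oracles used by the test suite.

The enumeration oracle re-derives the set of installable triads by dense
brute force over position triples and full chi grids, with no spatial
indexing, no prefilters and no cache decomposition — only the shared
low-level primitives (grid side-chain coordinates, ring-H construction,
soft-sphere clash formula) are reused.
"""

from __future__ import annotations

import numpy as np

from triadscan.geometry import ACID_OXYGENS, HG_ANGLE, O_H_BOND, place_atom_vec
from triadscan.geometry import _HIS_N_NEIGHBOURS, ring_h_position
from triadscan.model import Structure
from triadscan.rotamers import environment_arrays, grid_clash_scores, grid_side_chain_coords
from triadscan.search import SearchParams, surface_positions


def _pair_ok_j(structure, pos_s, pos_h, tautomer, params):
    """Boolean over His rotamers j: some Ser rotamer forms a valid pair."""
    _, ser_coords = grid_side_chain_coords(structure, pos_s, "SER", params.grid_step)
    _, his_coords = grid_side_chain_coords(structure, pos_h, "HIS", params.grid_step)
    og = ser_coords["OG"]
    n_face = his_coords[tautomer]
    ser_res = structure.residue(pos_s)
    ca = ser_res.atom("CA").coords
    cb = ser_coords["CB"][0]
    hg = place_atom_vec(
        ca, cb, og[:, None, :], O_H_BOND, HG_ANGLE,
        np.arange(0.0, 360.0, params.grid_step)[None, :],
    )  # (ns, n_hg, 3)

    env_c, env_r = environment_arrays(structure, {pos_s, pos_h})
    ser_clash = grid_clash_scores("SER", ser_coords, env_c, env_r)
    his_clash = grid_clash_scores("HIS", his_coords, env_c, env_r)

    ok_j = np.zeros(len(n_face), dtype=bool)
    for i in range(len(og)):
        if ser_clash[i] > params.clash_cutoff:
            continue
        d = np.linalg.norm(n_face - og[i], axis=1)
        u = og[i] - hg[i]  # (n_hg, 3)
        for j in np.where((d <= params.d_ser_his_max)
                          & (his_clash <= params.clash_cutoff))[0]:
            v = n_face[j] - hg[i]
            cosang = np.sum(u * v, axis=1) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if np.any((ang >= params.ang_min) & (ang <= params.ang_max)):
                ok_j[j] = True
    return ok_j


def _acid_ok_j(structure, pos_h, tautomer, pos_a, kind, params):
    """Boolean over His rotamers j: some acid rotamer satisfies the
    His-H...O distance and angle windows and the clash cutoff."""
    _, his_coords = grid_side_chain_coords(structure, pos_h, "HIS", params.grid_step)
    _, acid_coords = grid_side_chain_coords(structure, pos_a, kind, params.grid_step)
    n_name = "ND1" if tautomer == "NE2" else "NE2"
    nb1, nb2 = _HIS_N_NEIGHBOURS[n_name]
    n = his_coords[n_name]
    h = ring_h_position(n, his_coords[nb1], his_coords[nb2])

    o1, o2 = (acid_coords[nm] for nm in ACID_OXYGENS[kind])
    env_c, env_r = environment_arrays(structure, {pos_h, pos_a})
    acid_clash = grid_clash_scores(kind, acid_coords, env_c, env_r)
    k_ok = acid_clash <= params.clash_cutoff

    ok_j = np.zeros(len(n), dtype=bool)
    for j in range(len(n)):
        d1 = np.linalg.norm(o1 - h[j], axis=1)
        d2 = np.linalg.norm(o2 - h[j], axis=1)
        dmin = np.minimum(d1, d2)
        o_near = np.where((d1 <= d2)[:, None], o1, o2)
        v = o_near - h[j]
        u = n[j] - h[j]
        cosang = (v @ u) / (np.linalg.norm(u) * np.linalg.norm(v, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        good = (
            (dmin <= params.d_his_acid_max)
            & (ang >= params.ang_min)
            & (ang <= params.ang_max)
            & k_ok
        )
        if good.any():
            ok_j[j] = True
    return ok_j


def brute_force_triads(
    structure: Structure, params: SearchParams = SearchParams()
) -> set[tuple[int, int, int, str]]:
    """Every installable (ser, his, acid, kind) by dense enumeration."""
    surf = surface_positions(
        structure, params.rel_sasa_min, params.sasa_points, params.probe_radius
    )
    pair_cache: dict = {}
    acid_cache: dict = {}
    found = set()
    for pos_h in surf:
        for tautomer in ("NE2", "ND1"):
            for pos_s in surf:
                if pos_s == pos_h:
                    continue
                key_p = (pos_s, pos_h, tautomer)
                if key_p not in pair_cache:
                    pair_cache[key_p] = _pair_ok_j(
                        structure, pos_s, pos_h, tautomer, params
                    )
                pair_j = pair_cache[key_p]
                if not pair_j.any():
                    continue
                for pos_a in surf:
                    if pos_a in (pos_s, pos_h):
                        continue
                    for kind in ("ASP", "GLU"):
                        key_a = (pos_h, tautomer, pos_a, kind)
                        if key_a not in acid_cache:
                            acid_cache[key_a] = _acid_ok_j(
                                structure, pos_h, tautomer, pos_a, kind, params
                            )
                        if np.any(pair_j & acid_cache[key_a]):
                            found.add((pos_s, pos_h, pos_a, kind))
    return found
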