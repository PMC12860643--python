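"""Exhaustive surface scan for installable Ser-His-Asp/Glu catalytic triads.

The design stage enumerates Ser/His rotamer pairs on the chi grid over all
surface-exposed position pairs, keeps pairs satisfying the hydrogen-bond
distance and angle windows, extends each with Asp and Glu at neighbouring
positions under the analogous His-H to acid-O constraints, and then filters
by evolutionary tolerance (PSSM), distance to native catalytic sites, and
steric feasibility, deduplicating rotamer combinations into unique triads.

The enumeration is exhaustive but organised for speed: Ser/His pairs are
scanned with vectorised distance/angle tests, and because the acid-side
constraints depend only on the His rotamer, acid extensions are computed
once per His rotamer (with a KD-tree over carboxylate oxygen positions)
and joined to the Ser/His pairs afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    ACID_OXYGENS,
    HG_ANGLE,
    HIS_RING_ATOMS,
    O_H_BOND,
    _HIS_N_NEIGHBOURS,
    angle,
    fit_plane,
    place_atom_vec,
    ring_h_position,
    sasa,
)
from .model import (
    Atom,
    GeometryMetrics,
    PSSM,
    RotamerPlacement,
    Structure,
    TriadCandidate,
    TriadSpec,
)
from .rotamers import (
    environment_arrays,
    grid_clash_scores,
    grid_side_chain_coords,
    ideal_cb,
    placement_from_grid,
)

ROLE_AA1 = {"SER": "S", "HIS": "H", "ASP": "D", "GLU": "E"}

#: farthest carboxylate oxygen reach from CB (A), used only to prune
#: position pairs that cannot possibly satisfy the distance window
_ACID_REACH = {"ASP": 3.9, "GLU": 5.2}
_HIS_H_REACH = 6.0  # CB to ring-nitrogen H upper bound


@dataclass
class SearchParams:
    """Design-stage knobs: chi grid, geometry windows, steric cutoff."""

    grid_step: float = 20.0
    d_ser_his_max: float = 4.0
    d_his_acid_max: float = 4.0
    ang_min: float = 100.0
    ang_max: float = 180.0
    clash_cutoff: float = 2.0
    cb_prefilter: float = 12.0
    rel_sasa_min: float = 0.2
    sasa_points: int = 960
    probe_radius: float = 1.4


@dataclass
class SerHisPair:
    """A geometry-compatible Ser/His rotamer pair from the scan."""

    ser: RotamerPlacement
    his: RotamerPlacement
    tautomer: str  # His nitrogen facing Ser: NE2 | ND1
    d_ser_his: float
    ang_ser: float
    hg: Atom  # best-window Ser hydroxyl H placement


@dataclass(frozen=True)
class _PairRec:
    """Lightweight scan record; placements are materialised on demand."""

    pos_s: int
    pos_h: int
    tautomer: str
    i: int  # Ser rotamer grid index
    j: int  # His rotamer grid index
    d_ser_his: float
    ang_ser: float
    hg: tuple[float, float, float]
    clash_s: float
    clash_h: float


class _GridCache:
    """Per-call cache of rotamer grids, environments and clash vectors.

    Clash vectors for an exclusion set are assembled as the base score
    (environment = everything but the rotamer's own residue) minus the
    per-residue contributions of the other excluded positions; the soft-
    sphere score is a sum over environment atoms, so the decomposition is
    exact and keeps the cache small.
    """

    def __init__(self, structure: Structure, step: float):
        self.structure = structure
        self.step = step
        self._grids: dict = {}
        self._base: dict = {}
        self._vs_res: dict = {}
        self._clashes: dict = {}

    def grid(self, position: int, aa: str):
        key = (position, aa)
        if key not in self._grids:
            self._grids[key] = grid_side_chain_coords(
                self.structure, position, aa, self.step
            )
        return self._grids[key]

    def _clash_base(self, position: int, aa: str) -> np.ndarray:
        key = (position, aa)
        if key not in self._base:
            _, coords = self.grid(position, aa)
            env_coords, env_radii = environment_arrays(self.structure, {position})
            self._base[key] = grid_clash_scores(aa, coords, env_coords, env_radii)
        return self._base[key]

    def _clash_vs_residue(self, position: int, aa: str, other: int) -> np.ndarray:
        key = (position, aa, other)
        if key not in self._vs_res:
            _, coords = self.grid(position, aa)
            res = self.structure.residue(other)
            pts = [a.coords for a in res.atoms if a.element.upper() != "H"]
            from .geometry import vdw_radius
            radii = np.array(
                [vdw_radius(a.element) for a in res.atoms if a.element.upper() != "H"]
            )
            self._vs_res[key] = grid_clash_scores(
                aa, coords, np.array(pts), radii
            )
        return self._vs_res[key]

    def clash(self, position: int, aa: str, exclusion: frozenset) -> np.ndarray:
        exclusion = frozenset(exclusion) | {position}
        key = (position, aa, exclusion)
        if key not in self._clashes:
            total = self._clash_base(position, aa).copy()
            for other in sorted(exclusion - {position}):
                total -= self._clash_vs_residue(position, aa, other)
            np.maximum(total, 0.0, out=total)  # guard float cancellation
            self._clashes[key] = total
        return self._clashes[key]


def _cb_coord(structure: Structure, position: int) -> np.ndarray:
    res = structure.residue(position)
    if res.has_atom("CB"):
        return res.atom("CB").coords
    return ideal_cb(res.atom("N").coords, res.atom("CA").coords, res.atom("C").coords)


def surface_positions(
    structure: Structure,
    rel_sasa_min: float = 0.2,
    n_points: int = 960,
    probe_radius: float = 1.4,
) -> list[int]:
    """Positions whose relative (side-chain-inclusive) SASA meets the
    threshold, sorted by author number."""
    result = sasa(structure, probe_radius=probe_radius, n_points=n_points)
    return sorted(pos for pos, rel in result.relative.items() if rel >= rel_sasa_min)


# ---------------------------------------------------------------------------
# Ser/His pair scan
# ---------------------------------------------------------------------------


def _scan_pairs(
    structure: Structure,
    positions: Sequence[int],
    params: SearchParams,
    cache: _GridCache,
) -> list[_PairRec]:
    cbs = {p: _cb_coord(structure, p) for p in positions}
    hg_dihedrals = np.arange(0.0, 360.0, params.grid_step)
    records: list[_PairRec] = []

    for pos_s in positions:
        ser_chis, ser_coords = cache.grid(pos_s, "SER")
        og = ser_coords["OG"]
        ser_res = structure.residue(pos_s)
        ca = ser_res.atom("CA").coords
        cb = ser_coords["CB"][0]
        hg_all = None  # computed lazily per Ser position
        for pos_h in positions:
            if pos_h == pos_s:
                continue
            if np.linalg.norm(cbs[pos_s] - cbs[pos_h]) > params.cb_prefilter:
                continue
            his_chis, his_coords = cache.grid(pos_h, "HIS")
            exclusion = frozenset({pos_s, pos_h})
            ser_clash = cache.clash(pos_s, "SER", exclusion)
            his_clash = cache.clash(pos_h, "HIS", exclusion)

            for tautomer in ("NE2", "ND1"):
                n_face = his_coords[tautomer]
                dmat = np.linalg.norm(og[:, None, :] - n_face[None, :, :], axis=2)
                ii, jj = np.where(dmat <= params.d_ser_his_max)
                if len(ii) == 0:
                    continue
                if hg_all is None:
                    hg_all = place_atom_vec(
                        ca, cb, og[:, None, :], O_H_BOND, HG_ANGLE,
                        hg_dihedrals[None, :],
                    )
                u = og[ii][:, None, :] - hg_all[ii]
                v = n_face[jj][:, None, :] - hg_all[ii]
                cosang = np.sum(u * v, axis=2) / (
                    np.linalg.norm(u, axis=2) * np.linalg.norm(v, axis=2)
                )
                angs = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                in_window = (angs >= params.ang_min) & (angs <= params.ang_max)
                ok = (
                    in_window.any(axis=1)
                    & (ser_clash[ii] <= params.clash_cutoff)
                    & (his_clash[jj] <= params.clash_cutoff)
                )
                masked = np.where(in_window, angs, -1.0)
                g_best = np.argmax(masked, axis=1)
                for k in np.where(ok)[0]:
                    i, j = int(ii[k]), int(jj[k])
                    g = int(g_best[k])
                    records.append(
                        _PairRec(
                            pos_s=pos_s, pos_h=pos_h, tautomer=tautomer,
                            i=i, j=j,
                            d_ser_his=float(dmat[i, j]),
                            ang_ser=float(angs[k, g]),
                            hg=tuple(hg_all[i, g]),
                            clash_s=float(ser_clash[i]),
                            clash_h=float(his_clash[j]),
                        )
                    )
    return records


def _materialise_pair(
    structure: Structure, rec: _PairRec, cache: _GridCache
) -> SerHisPair:
    ser_chis, ser_coords = cache.grid(rec.pos_s, "SER")
    his_chis, his_coords = cache.grid(rec.pos_h, "HIS")
    ser_pl = placement_from_grid(rec.pos_s, "SER", ser_chis[rec.i], ser_coords, rec.i)
    ser_pl.clash_score = rec.clash_s
    his_pl = placement_from_grid(rec.pos_h, "HIS", his_chis[rec.j], his_coords, rec.j)
    his_pl.clash_score = rec.clash_h
    return SerHisPair(
        ser=ser_pl, his=his_pl, tautomer=rec.tautomer,
        d_ser_his=rec.d_ser_his, ang_ser=rec.ang_ser,
        hg=Atom("HG", "H", np.array(rec.hg)),
    )


def find_ser_his_pairs(
    structure: Structure,
    positions: Sequence[int],
    params: SearchParams = SearchParams(),
    cache: Optional[_GridCache] = None,
) -> list[SerHisPair]:
    """Scan all position pairs for Ser/His rotamer pairs with catalytic
    geometry: d(Ser OG, His NE2/ND1) within the distance window and some
    hydroxyl-H placement giving a Ser OG-HG-N angle inside the angular
    window, with both placements below the clash cutoff. Both tautomers
    (NE2- or ND1-facing) are searched as separate branches.
    """
    cache = cache or _GridCache(structure, params.grid_step)
    return [
        _materialise_pair(structure, rec, cache)
        for rec in _scan_pairs(structure, positions, params, cache)
    ]


# ---------------------------------------------------------------------------
# acid extension
# ---------------------------------------------------------------------------


@dataclass
class _AcidHit:
    """Best satisfying acid rotamer at one (position, kind) for a given
    His rotamer; independent of the Ser rotamer."""

    position: int
    aa: str
    grid_index: int
    chis: tuple[float, ...]
    d_his_acid: float
    ang_his: float
    clash: float
    o_pair: np.ndarray


def _placement_atom(placement: RotamerPlacement, name: str) -> np.ndarray:
    for a in placement.atoms:
        if a.name == name:
            return a.coords
    raise KeyError(name)


def _his_h_arrays(
    his_coords: dict[str, np.ndarray], tautomer: str, j_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(H, N_acid) positions for the selected His rotamers."""
    n_acid_name = "ND1" if tautomer == "NE2" else "NE2"
    nb1, nb2 = _HIS_N_NEIGHBOURS[n_acid_name]
    n = his_coords[n_acid_name][j_idx]
    h = ring_h_position(n, his_coords[nb1][j_idx], his_coords[nb2][j_idx])
    return h, n


def _acid_targets(
    structure: Structure,
    pos_h: int,
    acid_positions: Sequence[int],
    params: SearchParams,
) -> list[tuple[int, str]]:
    """(position, kind) combinations whose carboxylate could conceivably
    reach the His polar hydrogen (CB-distance triage only)."""
    his_cb = _cb_coord(structure, pos_h)
    out = []
    for pos_a in acid_positions:
        if pos_a == pos_h:
            continue
        cb_dist = np.linalg.norm(_cb_coord(structure, pos_a) - his_cb)
        if cb_dist > params.cb_prefilter:
            continue
        for aa in ("ASP", "GLU"):
            if cb_dist <= _ACID_REACH[aa] + _HIS_H_REACH + params.d_his_acid_max:
                out.append((pos_a, aa))
    return out


def _acid_ok_map(
    structure: Structure,
    pos_h: int,
    tautomer: str,
    j_idx: np.ndarray,
    acid_positions: Sequence[int],
    params: SearchParams,
    cache: _GridCache,
) -> dict[tuple[int, str], np.ndarray]:
    """For one His position/tautomer and a batch of His rotamers, decide
    per (acid position, kind) which rotamers admit at least one acid
    rotamer satisfying the distance window, the His N-H...O angular window
    and the clash cutoff. Returns boolean masks aligned with ``j_idx``.

    The (His rotamer x acid rotamer) candidate pairs come from a KD-tree
    fixed-radius query over carboxylate oxygen positions and are then
    checked in bulk.
    """
    _, his_coords = cache.grid(pos_h, "HIS")
    h_pts, n_pts = _his_h_arrays(his_coords, tautomer, j_idx)
    u = n_pts - h_pts
    u_norm = np.linalg.norm(u, axis=1)
    ok_map: dict[tuple[int, str], np.ndarray] = {}

    for pos_a, aa in _acid_targets(structure, pos_h, acid_positions, params):
        ok = np.zeros(len(j_idx), dtype=bool)
        cb_a = _cb_coord(structure, pos_a)
        rows = np.where(
            np.linalg.norm(h_pts - cb_a, axis=1)
            <= _ACID_REACH[aa] + params.d_his_acid_max
        )[0]
        if len(rows):
            chis, coords = cache.grid(pos_a, aa)
            o1, o2 = (coords[n] for n in ACID_OXYGENS[aa])
            # clash-failing rotamers can never yield a hit: prune them
            # before the spatial query
            clash = cache.clash(pos_a, aa, frozenset({pos_h, pos_a}))
            kmap = np.where(clash <= params.clash_cutoff)[0]
            if len(kmap):
                nk_ok = len(kmap)
                tree_h = cKDTree(h_pts[rows])
                tree_o = cKDTree(np.concatenate([o1[kmap], o2[kmap]]))
                flat = tree_h.sparse_distance_matrix(
                    tree_o, params.d_his_acid_max, output_type="ndarray"
                )
            else:
                flat = []
            if len(flat):
                jrow = rows[flat["i"]]
                k = kmap[flat["j"] % nk_ok]
                # a (j, k) combination may enter via either oxygen; each
                # entry is evaluated with the nearest-oxygen convention, so
                # duplicates agree and no dedup is needed
                d1 = np.linalg.norm(o1[k] - h_pts[jrow], axis=1)
                d2 = np.linalg.norm(o2[k] - h_pts[jrow], axis=1)
                dmin = np.minimum(d1, d2)
                o_near = np.where((d1 <= d2)[:, None], o1[k], o2[k])
                v = o_near - h_pts[jrow]
                cosang = np.sum(v * u[jrow], axis=1) / (
                    u_norm[jrow] * np.linalg.norm(v, axis=1)
                )
                ang_his = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                good = (
                    (dmin <= params.d_his_acid_max)
                    & (ang_his >= params.ang_min)
                    & (ang_his <= params.ang_max)
                )
                ok[jrow[good]] = True
        ok_map[(pos_a, aa)] = ok
    return ok_map


def _best_hit_for_j(
    structure: Structure,
    pos_h: int,
    tautomer: str,
    j: int,
    pos_a: int,
    aa: str,
    params: SearchParams,
    cache: _GridCache,
) -> Optional[_AcidHit]:
    """Exact best acid rotamer (min clash, then distance, then chis) at one
    (position, kind) for a single His rotamer."""
    _, his_coords = cache.grid(pos_h, "HIS")
    h_arr, n_arr = _his_h_arrays(his_coords, tautomer, np.array([j]))
    h, n = h_arr[0], n_arr[0]
    u = n - h
    u_norm = np.linalg.norm(u)

    chis, coords = cache.grid(pos_a, aa)
    o1, o2 = (coords[name] for name in ACID_OXYGENS[aa])
    o_stack = np.stack([o1, o2], axis=1)
    d_os = np.linalg.norm(o_stack - h, axis=2)
    nearest = np.argmin(d_os, axis=1)
    rows = np.arange(len(o1))
    dmin = d_os[rows, nearest]
    o_near = o_stack[rows, nearest]
    v = o_near - h
    cosang = (v @ u) / (u_norm * np.linalg.norm(v, axis=1))
    ang_his = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    clash = cache.clash(pos_a, aa, frozenset({pos_h, pos_a}))
    mask = (
        (dmin <= params.d_his_acid_max)
        & (ang_his >= params.ang_min)
        & (ang_his <= params.ang_max)
        & (clash <= params.clash_cutoff)
    )
    if not mask.any():
        return None
    idx = np.where(mask)[0]
    best = int(min(idx, key=lambda i: (clash[i], dmin[i], tuple(chis[i]))))
    return _AcidHit(
        position=pos_a, aa=aa, grid_index=best,
        chis=tuple(float(c) for c in chis[best]),
        d_his_acid=float(dmin[best]),
        ang_his=float(ang_his[best]),
        clash=float(clash[best]),
        o_pair=o_stack[best],
    )


def extend_with_acid(
    structure: Structure,
    pair: SerHisPair,
    params: SearchParams = SearchParams(),
    acid_positions: Optional[Sequence[int]] = None,
    cache: Optional[_GridCache] = None,
) -> list[TriadCandidate]:
    """Extend a Ser/His pair with Asp and Glu at neighbouring positions;
    one candidate per satisfiable (position, acid kind).

    Both acids are always tried; the constraint atoms are the His polar
    hydrogen (on the nitrogen facing away from Ser) and the nearest
    carboxylate oxygen, with the His N-H...O angle in the angular window.
    """
    cache = cache or _GridCache(structure, params.grid_step)
    if acid_positions is None:
        acid_positions = [r.number for r in structure.residues]
    acid_positions = [p for p in acid_positions if p != pair.ser.position]

    his_chis, _ = cache.grid(pair.his.position, "HIS")
    j = int(np.argmin(np.abs(his_chis - np.array(pair.his.chis)).sum(axis=1)))
    candidates = []
    for pos_a, aa in _acid_targets(structure, pair.his.position, acid_positions, params):
        hit = _best_hit_for_j(
            structure, pair.his.position, pair.tautomer, j, pos_a, aa, params, cache
        )
        if hit is not None:
            candidates.append(_candidate_from_hit(structure, pair, hit, cache))
    return candidates


def _candidate_from_hit(
    structure: Structure, pair: SerHisPair, hit: _AcidHit, cache: _GridCache
) -> TriadCandidate:
    chis, coords = cache.grid(hit.position, hit.aa)
    acid_pl = placement_from_grid(
        hit.position, hit.aa, chis[hit.grid_index], coords, hit.grid_index
    )
    acid_pl.clash_score = hit.clash
    spec = TriadSpec(
        ser_pos=pair.ser.position,
        his_pos=pair.his.position,
        acid_pos=hit.position,
        acid_kind=hit.aa,
        his_n_ser_side=pair.tautomer,
    )
    og = _placement_atom(pair.ser, "OG")
    nd1 = _placement_atom(pair.his, "ND1")
    ne2 = _placement_atom(pair.his, "NE2")
    six = np.vstack([og, pair.hg.coords, nd1, ne2, hit.o_pair])
    _, _, coplanarity = fit_plane(six)
    ring = np.array([_placement_atom(pair.his, n) for n in HIS_RING_ATOMS])
    collinearity = angle(og, ring.mean(axis=0), hit.o_pair.mean(axis=0))
    metrics = GeometryMetrics(
        d_ser_his=pair.d_ser_his,
        d_his_acid=hit.d_his_acid,
        ang_ser=pair.ang_ser,
        ang_his=hit.ang_his,
        coplanarity=coplanarity,
        collinearity=collinearity,
        his_n_ser_side=pair.tautomer,
    )
    needs_sub = {
        pl.position: None
        for pl in (pair.ser, pair.his, acid_pl)
        if structure.residue(pl.position).aa != pl.aa
    }
    return TriadCandidate(
        spec=spec,
        placements=(pair.ser, pair.his, acid_pl),
        metrics=metrics,
        total_clash=float(hit.clash + pair.ser.clash_score + pair.his.clash_score),
        pssm_scores=dict(needs_sub),
        n_substitutions=len(needs_sub),
    )


# ---------------------------------------------------------------------------
# gates
# ---------------------------------------------------------------------------


def pssm_gate(
    candidates: Sequence[TriadCandidate],
    pssm: PSSM,
    min_score: int = 0,
) -> list[TriadCandidate]:
    """Keep candidates whose every required substitution is evolutionarily
    tolerated: score(introduced aa) >= min_score at each mutated position.
    Positions whose native residue already matches the triad role are exempt.
    """
    kept = []
    for cand in candidates:
        role_by_pos = {pl.position: ROLE_AA1[pl.aa] for pl in cand.placements}
        scores = {pos: pssm.score(pos, role_by_pos[pos]) for pos in cand.pssm_scores}
        cand.pssm_scores = scores
        if all(s >= min_score for s in scores.values()):
            kept.append(cand)
    return kept


def exclusion_gate(
    structure: Structure,
    candidates: Sequence[TriadCandidate],
    native_sites: Sequence[int],
    min_dist: float = 6.0,
) -> list[TriadCandidate]:
    """Drop candidates with any triad heavy atom within ``min_dist`` of any
    heavy atom of a flagged native catalytic residue."""
    if not native_sites:
        return list(candidates)
    native_pts = []
    for pos in native_sites:
        res = structure.residue(pos)
        native_pts.extend(a.coords for a in res.atoms if a.element.upper() != "H")
    native_pts = np.array(native_pts)

    kept = []
    for cand in candidates:
        pts = []
        for pl in cand.placements:
            res = structure.residue(pl.position)
            pts.extend(
                a.coords for a in res.atoms
                if a.name in ("N", "CA", "C", "O")
            )
            pts.extend(a.coords for a in pl.atoms if a.element.upper() != "H")
        pts = np.array(pts)
        dmin = np.min(np.linalg.norm(pts[:, None, :] - native_pts[None, :, :], axis=2))
        if dmin >= min_dist:
            kept.append(cand)
    return kept


def dedupe_and_rank(candidates: Sequence[TriadCandidate]) -> list[TriadCandidate]:
    """One candidate per unique (ser, his, acid, kind): the lowest-clash
    representative, ties broken by smaller d_ser_his then lexicographic chi
    tuples; output sorted by total clash ascending (deterministically)."""
    def rep_key(c: TriadCandidate):
        all_chis = tuple(chi for pl in c.placements for chi in pl.chis)
        return (c.total_clash, c.metrics.d_ser_his, all_chis)

    best: dict[tuple, TriadCandidate] = {}
    for cand in candidates:
        ident = cand.spec.identity()
        if ident not in best or rep_key(cand) < rep_key(best[ident]):
            best[ident] = cand
    return sorted(
        best.values(),
        key=lambda c: (c.total_clash, c.metrics.d_ser_his, c.spec.key),
    )


# ---------------------------------------------------------------------------
# substitution counting
# ---------------------------------------------------------------------------

SequenceLike = Union[Structure, str, Mapping[int, str]]


def min_substitutions(source: SequenceLike, spec: TriadSpec) -> int:
    """Count triad positions whose wild-type residue differs from the triad
    role (Ser/His/Asp-or-Glu). ``source`` may be a Structure, a plain
    1-indexed sequence string, or a mapping from author position to
    one-letter code."""
    targets = {
        spec.ser_pos: "S",
        spec.his_pos: "H",
        spec.acid_pos: ROLE_AA1[spec.acid_kind],
    }
    count = 0
    for pos, target in targets.items():
        if _native_aa1(source, pos).upper() != target:
            count += 1
    return count


def _native_aa1(source: SequenceLike, pos: int) -> str:
    if isinstance(source, Structure):
        return source.residue(pos).one_letter
    if isinstance(source, str):
        if not (1 <= pos <= len(source)):
            raise KeyError(f"position {pos} outside sequence of length {len(source)}")
        return source[pos - 1]
    return source[pos]


# ---------------------------------------------------------------------------
# design-stage driver
# ---------------------------------------------------------------------------


@dataclass
class DesignResult:
    """Design-stage output with per-filter funnel counts."""

    candidates: list[TriadCandidate]
    counts: dict[str, int] = field(default_factory=dict)


def design_triads(
    structure: Structure,
    params: SearchParams = SearchParams(),
    pssm: Optional[PSSM] = None,
    native_sites: Sequence[int] = (),
    pssm_min: int = 0,
    exclusion_dist: float = 6.0,
) -> DesignResult:
    """Run the full design stage: surface scan, pair enumeration, acid
    extension, PSSM and exclusion gates, dedup and ranking."""
    cache = _GridCache(structure, params.grid_step)
    surf = surface_positions(
        structure, params.rel_sasa_min, params.sasa_points, params.probe_radius
    )
    records = _scan_pairs(structure, surf, params, cache)

    # group records by (pos_h, tautomer); decide acid-extendability once
    # per distinct His rotamer, then join back to the Ser side
    groups: dict[tuple[int, str], list[int]] = {}
    for rec in records:
        groups.setdefault((rec.pos_h, rec.tautomer), [])
    for key in groups:
        js = sorted({rec.j for rec in records
                     if (rec.pos_h, rec.tautomer) == key})
        groups[key] = js
    ok_tables: dict[tuple[int, str], dict[tuple[int, str], np.ndarray]] = {}
    j_rows: dict[tuple[int, str], dict[int, int]] = {}
    for (pos_h, tautomer), js in groups.items():
        ok_tables[(pos_h, tautomer)] = _acid_ok_map(
            structure, pos_h, tautomer, np.array(js), surf, params, cache
        )
        j_rows[(pos_h, tautomer)] = {j: row for row, j in enumerate(js)}

    # representative per unique triad: the lowest-clash Ser/His pair (ties:
    # smaller d_ser_his, then chi tuples); its acid rotamer is chosen by
    # the same ordering afterwards
    best: dict[tuple, tuple[tuple, _PairRec, tuple[int, str]]] = {}
    n_enumerated = 0
    for rec in records:
        group = (rec.pos_h, rec.tautomer)
        row = j_rows[group][rec.j]
        ser_chis, _ = cache.grid(rec.pos_s, "SER")
        his_chis, _ = cache.grid(rec.pos_h, "HIS")
        for (pos_a, aa), ok in ok_tables[group].items():
            if not ok[row] or pos_a == rec.pos_s:
                continue
            n_enumerated += 1
            ident = (rec.pos_s, rec.pos_h, pos_a, aa)
            rank = (
                rec.clash_s + rec.clash_h,
                rec.d_ser_his,
                tuple(ser_chis[rec.i]) + tuple(his_chis[rec.j]),
            )
            if ident not in best or rank < best[ident][0]:
                best[ident] = (rank, rec, (pos_a, aa))

    hit_memo: dict[tuple, Optional[_AcidHit]] = {}
    raw = []
    for _, rec, (pos_a, aa) in best.values():
        memo_key = (rec.pos_h, rec.tautomer, rec.j, pos_a, aa)
        if memo_key not in hit_memo:
            hit_memo[memo_key] = _best_hit_for_j(
                structure, rec.pos_h, rec.tautomer, rec.j, pos_a, aa, params, cache
            )
        hit = hit_memo[memo_key]
        assert hit is not None  # ok-map guarantees satisfiability
        raw.append(
            _candidate_from_hit(
                structure, _materialise_pair(structure, rec, cache), hit, cache
            )
        )
    counts = {
        "surface_positions": len(surf),
        "ser_his_pairs": len(records),
        "triads_enumerated": n_enumerated,
    }
    cands = raw
    if pssm is not None:
        cands = pssm_gate(cands, pssm, pssm_min)
        counts["after_pssm_gate"] = len(cands)
    if native_sites:
        cands = exclusion_gate(structure, cands, native_sites, exclusion_dist)
        counts["after_exclusion_gate"] = len(cands)
    unique = dedupe_and_rank(cands)
    counts["unique_triads"] = len(unique)
    return DesignResult(candidates=unique, counts=counts)
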