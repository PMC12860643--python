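"""Side-chain construction on discrete chi grids.

Ser/His/Asp/Glu (and Ala) side chains are built from the existing backbone
using idealised internal coordinates (Engh-Huber bond lengths and angles),
not a statistical rotamer library: the design scan samples a uniform chi
grid anchored at 0 deg. Steric feasibility is scored with a soft-sphere
clash penalty.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np

from .geometry import place_atom, place_atom_vec, vdw_radius
from .model import Atom, Residue, RotamerPlacement, Structure, TriadscanError

#: Number of chi angles per supported residue type.
N_CHI = {"SER": 1, "HIS": 2, "ASP": 2, "GLU": 3, "ALA": 0}

# Each entry: atom name, element, (ref1, ref2, ref3), bond, angle, dihedral.
# A dihedral given as ("chi", k, offset) is chis[k] + offset.
_SIDE_CHAIN_ZMAT = {
    "SER": [
        ("OG", "O", ("N", "CA", "CB"), 1.417, 111.1, ("chi", 0, 0.0)),
    ],
    "HIS": [
        ("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 0, 0.0)),
        ("ND1", "N", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 1, 0.0)),
        ("CD2", "C", ("CA", "CB", "CG"), 1.354, 131.2, ("chi", 1, 180.0)),
        ("CE1", "C", ("CB", "CG", "ND1"), 1.321, 109.3, ("fix", 180.0)),
        ("NE2", "N", ("CG", "ND1", "CE1"), 1.321, 111.7, ("fix", 0.0)),
    ],
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 0, 0.0)),
        ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 1, 0.0)),
        ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 1, 180.0)),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 0, 0.0)),
        ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ALA": [],
}

# CB from backbone: bonded to CA, referenced off C and N (L-configuration).
_CB_BOND = 1.530
_CB_ANGLE = 110.5  # N-CA-CB
_CB_DIHEDRAL = 122.6  # C-N-CA-CB improper (L-configuration)


def enumerate_chi_grid(aa: str, step: float = 20.0) -> list[tuple[float, ...]]:
    """All chi tuples on the uniform grid [0, 360) per chi; (360/step)^n_chi."""
    aa = aa.upper()
    if aa not in N_CHI:
        raise TriadscanError(f"unsupported residue type {aa!r} for rotamer grid")
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError("grid step must divide 360")
    values = [float(v) for v in np.arange(0.0, 360.0, step)]
    return [tuple(c) for c in itertools.product(values, repeat=N_CHI[aa])]


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB position for an L-amino acid backbone."""
    return place_atom(c, n, ca, _CB_BOND, _CB_ANGLE, _CB_DIHEDRAL)


def build_side_chain(
    structure: Structure,
    position: int,
    aa: str,
    chis: Sequence[float],
) -> RotamerPlacement:
    """Replace the side chain at ``position`` with an idealised ``aa`` rotamer.

    The existing backbone (N, CA, C) is kept; CB is reused when present and
    synthesised at the ideal tetrahedral position otherwise (Gly backbones
    included). The returned placement carries the constructed side-chain
    atoms, CB included.
    """
    aa = aa.upper()
    if aa not in _SIDE_CHAIN_ZMAT:
        raise TriadscanError(f"unsupported residue type {aa!r}")
    chis = tuple(float(c) for c in chis)
    if len(chis) != N_CHI[aa]:
        raise ValueError(f"{aa} needs {N_CHI[aa]} chi angles, got {len(chis)}")

    res = structure.residue(position)
    for bb in ("N", "CA", "C"):
        if not res.has_atom(bb):
            raise TriadscanError(
                f"residue {position} lacks backbone atom {bb}; cannot build side chain"
            )
    coords = {bb: res.atom(bb).coords for bb in ("N", "CA", "C")}
    if res.has_atom("CB"):
        coords["CB"] = res.atom("CB").coords
    else:
        coords["CB"] = ideal_cb(coords["N"], coords["CA"], coords["C"])

    atoms = [Atom("CB", "C", coords["CB"])]
    for name, element, refs, bond, ang, dih_spec in _SIDE_CHAIN_ZMAT[aa]:
        if dih_spec[0] == "chi":
            dih = chis[dih_spec[1]] + dih_spec[2]
        else:
            dih = dih_spec[1]
        pos = place_atom(coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, ang, dih)
        coords[name] = pos
        atoms.append(Atom(name, element, pos))

    return RotamerPlacement(position=position, aa=aa, chis=chis, atoms=atoms)


def apply_placement(structure: Structure, placement: RotamerPlacement) -> Structure:
    """Return a structure copy with the placement's residue swapped in."""
    old = structure.residue(placement.position)
    backbone = [a for a in old.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    new = Residue(
        chain_id=old.chain_id,
        number=old.number,
        aa=placement.aa,
        atoms=backbone + list(placement.atoms),
    )
    return structure.replace_residue(new)


def grid_side_chain_coords(
    structure: Structure, position: int, aa: str, step: float = 20.0
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Side-chain coordinates for every chi tuple on the grid, vectorised.

    Returns ``(chis, coords)`` where ``chis`` has shape (n_rot, n_chi) in the
    order of :func:`enumerate_chi_grid`, and ``coords`` maps each side-chain
    atom name (CB included) to an (n_rot, 3) array. Exactly equivalent to
    calling :func:`build_side_chain` per tuple.
    """
    aa = aa.upper()
    chi_tuples = enumerate_chi_grid(aa, step)
    n = len(chi_tuples)
    chis = np.array(chi_tuples, dtype=float).reshape(n, N_CHI[aa])

    res = structure.residue(position)
    for bb in ("N", "CA", "C"):
        if not res.has_atom(bb):
            raise TriadscanError(
                f"residue {position} lacks backbone atom {bb}; cannot build side chain"
            )
    base = {bb: res.atom(bb).coords for bb in ("N", "CA", "C")}
    if res.has_atom("CB"):
        base["CB"] = res.atom("CB").coords
    else:
        base["CB"] = ideal_cb(base["N"], base["CA"], base["C"])

    coords = {name: np.broadcast_to(xyz, (n, 3)) for name, xyz in base.items()}
    for name, _element, refs, bond, ang, dih_spec in _SIDE_CHAIN_ZMAT[aa]:
        if dih_spec[0] == "chi":
            dih = chis[:, dih_spec[1]] + dih_spec[2]
        else:
            dih = np.full(n, dih_spec[1])
        coords[name] = place_atom_vec(
            coords[refs[0]], coords[refs[1]], coords[refs[2]], bond, ang, dih
        )
    out = {"CB": np.array(coords["CB"])}
    out.update({e[0]: coords[e[0]] for e in _SIDE_CHAIN_ZMAT[aa]})
    return chis, out


def placement_from_grid(
    position: int, aa: str, chis: Sequence[float], coords: dict[str, np.ndarray], i: int
) -> RotamerPlacement:
    """Materialise one grid rotamer as a :class:`RotamerPlacement`."""
    aa = aa.upper()
    elements = {"CB": "C"}
    elements.update({e[0]: e[1] for e in _SIDE_CHAIN_ZMAT[aa]})
    atoms = [Atom(name, elements[name], coords[name][i]) for name in elements]
    return RotamerPlacement(
        position=position, aa=aa, chis=tuple(float(c) for c in chis), atoms=atoms
    )


SOFT_SPHERE_FACTOR = 0.8


def clash_score(
    structure: Structure,
    placement: RotamerPlacement,
    exclusion: Optional[set[int]] = None,
    env_coords: Optional[np.ndarray] = None,
    env_radii: Optional[np.ndarray] = None,
) -> float:
    """Soft-sphere steric penalty of a placement against its environment.

    sum over atom pairs of max(0, (0.8*(ri+rj) - d) / (ri+rj))^2, where the
    environment is every heavy protein atom outside the placement's own
    residue and the excluded positions. 0 means clash-free; the score grows
    monotonically as environment atoms approach.
    """
    excl = set(exclusion or ())
    excl.add(placement.position)
    if env_coords is None:
        env = [
            (a.coords, vdw_radius(a.element))
            for r in structure.residues
            if r.number not in excl
            for a in r.atoms
            if a.element.upper() != "H"
        ]
        if not env:
            return 0.0
        env_coords = np.array([e[0] for e in env])
        env_radii = np.array([e[1] for e in env])
    elif len(env_coords) == 0:
        return 0.0

    total = 0.0
    for a in placement.atoms:
        if a.element.upper() == "H":
            continue
        ri = vdw_radius(a.element)
        d = np.linalg.norm(env_coords - a.coords, axis=1)
        rsum = env_radii + ri
        overlap = np.maximum(0.0, (SOFT_SPHERE_FACTOR * rsum - d) / rsum)
        total += float(np.sum(overlap**2))
    return total


def environment_arrays(
    structure: Structure, exclusion: set[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Heavy-atom coordinates and radii outside the excluded positions."""
    env = [
        (a.coords, vdw_radius(a.element))
        for r in structure.residues
        if r.number not in exclusion
        for a in r.atoms
        if a.element.upper() != "H"
    ]
    if not env:
        return np.empty((0, 3)), np.empty((0,))
    return np.array([e[0] for e in env]), np.array([e[1] for e in env])


def grid_clash_scores(
    aa: str,
    coords: dict[str, np.ndarray],
    env_coords: np.ndarray,
    env_radii: np.ndarray,
    indices: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Soft-sphere clash score of grid rotamers against a fixed environment;
    identical formula to :func:`clash_score`, vectorised. ``indices``
    restricts evaluation to a rotamer subset (scores returned in that
    order)."""
    aa = aa.upper()
    names = ["CB"] + [e[0] for e in _SIDE_CHAIN_ZMAT[aa]]
    elements = {"CB": "C"}
    elements.update({e[0]: e[1] for e in _SIDE_CHAIN_ZMAT[aa]})
    n = len(coords[names[0]]) if indices is None else len(indices)
    total = np.zeros(n)
    if len(env_coords) == 0:
        return total
    for name in names:
        ri = vdw_radius(elements[name])
        pts = coords[name] if indices is None else coords[name][indices]
        d = np.linalg.norm(pts[:, None, :] - env_coords[None, :, :], axis=2)
        rsum = env_radii[None, :] + ri
        overlap = np.maximum(0.0, (SOFT_SPHERE_FACTOR * rsum - d) / rsum)
        total += np.sum(overlap**2, axis=1)
    return total
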