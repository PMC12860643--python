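"""Geometric primitives for catalytic-triad evaluation.

Distances, angles, dihedrals, internal-coordinate atom placement (NeRF),
polar-hydrogen construction, a deterministic Shrake-Rupley SASA, and the
triad-geometry evaluator with its stage-specific competence predicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .model import (
    Atom,
    GeometryMetrics,
    SasaResult,
    Structure,
    TriadSpec,
    TriadscanError,
)

# ---------------------------------------------------------------------------
# vector primitives
# ---------------------------------------------------------------------------


def angle(a, b, c) -> float:
    """Interior angle at vertex ``b`` in degrees, in [0, 180]."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("angle() requires non-coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Signed dihedral a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom_vec(a, b, c, bond, ang, dih) -> np.ndarray:
    """NeRF placement, broadcasting over leading axes.

    ``a``, ``b``, ``c`` are (..., 3) reference coordinates; ``bond``, ``ang``
    (deg) and ``dih`` (deg) broadcast against them. Returns the new atom
    position(s) with ``angle(b, c, new) = ang`` and
    ``dihedral(a, b, c, new) = dih``.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    a, b, c = np.broadcast_arrays(a, b, c)
    shape = np.broadcast_shapes(
        a.shape[:-1], np.shape(bond), np.shape(ang), np.shape(dih)
    )
    a = np.broadcast_to(a, shape + (3,))
    b = np.broadcast_to(b, shape + (3,))
    c = np.broadcast_to(c, shape + (3,))
    bond = np.broadcast_to(np.asarray(bond, dtype=float), shape)[..., None]
    ang_r = np.radians(np.broadcast_to(np.asarray(ang, dtype=float), shape))[..., None]
    dih_r = np.radians(np.broadcast_to(np.asarray(dih, dtype=float), shape))[..., None]

    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    return (
        c
        - bond * np.cos(ang_r) * bc
        + bond * np.sin(ang_r) * np.cos(dih_r) * m
        - bond * np.sin(ang_r) * np.sin(dih_r) * n
    )


def place_atom(a, b, c, bond: float, ang: float, dih: float) -> np.ndarray:
    """Scalar NeRF placement (see :func:`place_atom_vec`)."""
    return place_atom_vec(a, b, c, bond, ang, dih)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through points: (centroid, unit normal, RMS dist)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vh = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9 or (len(s) > 1 and s[1] < 1e-9):
        # degenerate (collinear or coincident) point set: any containing plane
        return centroid, vh[-1], 0.0
    normal = vh[-1]
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, rms


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere lattice (golden-spiral)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


# ---------------------------------------------------------------------------
# radii and reference areas
# ---------------------------------------------------------------------------

#: van der Waals radii (A) by element.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

#: Theoretical maximum accessible surface area per residue (A^2),
#: Tien et al. 2013 (theoretical column), used to normalise relative SASA.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

REL_SASA_CAP = 1.5


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise TriadscanError(f"no van der Waals radius for element {element!r}") from None


# ---------------------------------------------------------------------------
# stage thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """Stage-specific competence windows (distances in A, angles in deg).

    ``d_ser_lig_max`` is only checked when a Ser-ligand distance is available;
    angle windows apply only where ``apply_angles`` is set (the design scan).
    """

    d_ser_his_max: float = 4.0
    d_his_acid_max: float = 4.0
    d_ser_lig_max: Optional[float] = None
    ang_min: float = 100.0
    ang_max: float = 180.0
    apply_angles: bool = False


#: Default windows per pipeline stage.
STAGE_THRESHOLDS = {
    "design": Thresholds(4.0, 4.0, None, 100.0, 180.0, apply_angles=True),
    "relax": Thresholds(4.0, 4.0, None, apply_angles=False),
    "md": Thresholds(3.5, 3.5, 5.0, apply_angles=False),
    "pele_md": Thresholds(3.5, 3.5, 5.0, apply_angles=False),
}


def stage_thresholds(stage: str) -> Thresholds:
    try:
        return STAGE_THRESHOLDS[stage]
    except KeyError:
        raise TriadscanError(f"unknown stage {stage!r}") from None


def is_competent(metrics: GeometryMetrics, thresholds: Thresholds) -> bool:
    """True iff every enabled criterion of the stage window passes."""
    if metrics.d_ser_his > thresholds.d_ser_his_max:
        return False
    if metrics.d_his_acid > thresholds.d_his_acid_max:
        return False
    if (
        thresholds.d_ser_lig_max is not None
        and metrics.d_ser_lig is not None
        and metrics.d_ser_lig > thresholds.d_ser_lig_max
    ):
        return False
    if thresholds.apply_angles:
        for ang in (metrics.ang_ser, metrics.ang_his):
            if not (thresholds.ang_min <= ang <= thresholds.ang_max):
                return False
    return True


# ---------------------------------------------------------------------------
# polar hydrogens
# ---------------------------------------------------------------------------

HIS_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")
#: ring neighbours of each imidazole nitrogen, used to build its in-plane H
_HIS_N_NEIGHBOURS = {"ND1": ("CG", "CE1"), "NE2": ("CD2", "CE1")}
ACID_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

N_H_BOND = 1.01
O_H_BOND = 0.96
HG_ANGLE = 109.5  # CB-OG-HG


class PolarHydrogens(NamedTuple):
    """Constructed polar hydrogens for one triad."""

    his_h: Atom  # HD1 or HE2 on the acid-facing nitrogen, in the ring plane
    hg_candidates: list[Atom]  # Ser HG sampled on the hydroxyl dihedral grid


def ring_h_position(n: np.ndarray, nb1: np.ndarray, nb2: np.ndarray) -> np.ndarray:
    """H on a ring nitrogen ``n`` along the external bisector of its two
    ring neighbours, in the ring plane by construction (broadcasts over
    leading axes)."""
    u1 = nb1 - n
    u2 = nb2 - n
    u1 = u1 / np.linalg.norm(u1, axis=-1, keepdims=True)
    u2 = u2 / np.linalg.norm(u2, axis=-1, keepdims=True)
    direction = -(u1 + u2)
    direction = direction / np.linalg.norm(direction, axis=-1, keepdims=True)
    return n + N_H_BOND * direction


def his_ring_h(his, nitrogen: str) -> Atom:
    """In-plane H on an imidazole nitrogen of a His residue."""
    n1, n2 = _HIS_N_NEIGHBOURS[nitrogen]
    pos = ring_h_position(
        his.atom(nitrogen).coords, his.atom(n1).coords, his.atom(n2).coords
    )
    name = "HD1" if nitrogen == "ND1" else "HE2"
    return Atom(name, "H", pos)


def ser_hg_grid(ser, grid_step: float) -> list[Atom]:
    """Ser HG placements on the rotatable CA-CB-OG-HG dihedral grid."""
    ca, cb, og = (ser.atom(n).coords for n in ("CA", "CB", "OG"))
    out = []
    for dih in np.arange(0.0, 360.0, grid_step):
        out.append(Atom("HG", "H", place_atom(ca, cb, og, O_H_BOND, HG_ANGLE, dih)))
    return out


def place_polar_hydrogens(
    structure: Structure, triad: TriadSpec, grid_step: float = 20.0
) -> PolarHydrogens:
    """Build the triad's polar hydrogens without mutating the structure.

    The His ring H goes on the nitrogen opposite ``triad.his_n_ser_side``;
    the Ser hydroxyl H is returned at every grid placement so that callers
    can apply "any placement satisfies" semantics.
    """
    ser = structure.residue(triad.ser_pos)
    his = structure.residue(triad.his_pos)
    for atom_name in ("CA", "CB", "OG"):
        if not ser.has_atom(atom_name):
            raise TriadscanError(
                f"Ser {triad.ser_pos} lacks atom {atom_name} needed for HG placement"
            )
    for atom_name in HIS_RING_ATOMS:
        if not his.has_atom(atom_name):
            raise TriadscanError(
                f"His {triad.his_pos} lacks ring atom {atom_name} needed for H placement"
            )
    return PolarHydrogens(
        his_h=his_ring_h(his, triad.his_n_acid_side),
        hg_candidates=ser_hg_grid(ser, grid_step),
    )


# ---------------------------------------------------------------------------
# triad geometry
# ---------------------------------------------------------------------------


def ser_lig_distance(
    structure: Structure,
    spec: TriadSpec,
    carbonyl_names: Optional[Sequence[str]] = None,
) -> Optional[float]:
    """Min distance Ser OG to a substrate carbonyl carbon, if a ligand exists.

    Substrates may carry several carbonyl groups; the minimum over all of
    them is reported. Without an explicit atom-name list every hetero carbon
    is considered a candidate carbonyl carbon.
    """
    og = structure.residue(spec.ser_pos).atom("OG").coords
    pts = []
    for het in structure.hetero_residues:
        for a in het.atoms:
            if a.element.upper() != "C":
                continue
            if carbonyl_names is not None and a.name not in carbonyl_names:
                continue
            pts.append(a.coords)
    if not pts:
        return None
    return float(np.min(np.linalg.norm(np.array(pts) - og, axis=1)))


def evaluate_triad_geometry(
    structure: Structure,
    triad: TriadSpec,
    grid_step: float = 20.0,
    carbonyl_names: Optional[Sequence[str]] = None,
) -> GeometryMetrics:
    """Measure the hydrogen-bond network geometry of a triad in place.

    Reports the Ser OG to His nitrogen distance on the tautomer stated by
    the spec, the His-H to nearest acid oxygen distance (minimum over the
    symmetric carboxylate pair), and the two hydrogen-bond angles. The Ser
    hydroxyl dihedral is free: the placement best satisfying the angular
    window (largest Ser OG-HG-N angle on the grid) is reported.
    """
    ser = structure.residue(triad.ser_pos)
    his = structure.residue(triad.his_pos)
    acid = structure.residue(triad.acid_pos)
    if ser.aa != "SER":
        raise TriadscanError(f"position {triad.ser_pos} is {ser.aa}, expected SER")
    if his.aa != "HIS":
        raise TriadscanError(f"position {triad.his_pos} is {his.aa}, expected HIS")
    if acid.aa != triad.acid_kind:
        raise TriadscanError(
            f"position {triad.acid_pos} is {acid.aa}, expected {triad.acid_kind}"
        )

    hydrogens = place_polar_hydrogens(structure, triad, grid_step)
    og = ser.atom("OG").coords
    n_face = his.atom(triad.his_n_ser_side).coords
    d_ser_his = float(np.linalg.norm(og - n_face))

    h = hydrogens.his_h.coords
    o_names = ACID_OXYGENS[triad.acid_kind]
    o_coords = acid.coords(o_names)
    d_to_os = np.linalg.norm(o_coords - h, axis=1)
    nearest = int(np.argmin(d_to_os))
    d_his_acid = float(d_to_os[nearest])
    n_acid = his.atom(triad.his_n_acid_side).coords
    ang_his = angle(n_acid, h, o_coords[nearest])

    hg_positions = np.array([a.coords for a in hydrogens.hg_candidates])
    angles = _angles_at_vertices(og, hg_positions, n_face)
    best = int(np.argmax(angles))
    ang_ser = float(angles[best])
    hg = hg_positions[best]

    plane_atoms = np.vstack(
        [og, hg, his.atom("ND1").coords, his.atom("NE2").coords, o_coords]
    )
    _, _, coplanarity = fit_plane(plane_atoms)
    ring_centroid = his.coords(HIS_RING_ATOMS).mean(axis=0)
    carboxylate_mid = o_coords.mean(axis=0)
    collinearity = angle(og, ring_centroid, carboxylate_mid)

    return GeometryMetrics(
        d_ser_his=d_ser_his,
        d_his_acid=d_his_acid,
        ang_ser=ang_ser,
        ang_his=ang_his,
        coplanarity=coplanarity,
        collinearity=collinearity,
        d_ser_lig=ser_lig_distance(structure, triad, carbonyl_names),
        his_n_ser_side=triad.his_n_ser_side,
    )


def _angles_at_vertices(a: np.ndarray, vertices: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised interior angle a-v-c for each vertex v (degrees)."""
    u = a - vertices
    v = c - vertices
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def coplanarity_collinearity(
    structure: Structure, triad: TriadSpec, grid_step: float = 20.0
) -> tuple[float, float]:
    """(RMS deviation of the six constraint atoms from their best plane in A,
    Ser OG - His ring centroid - carboxylate midpoint angle in degrees)."""
    m = evaluate_triad_geometry(structure, triad, grid_step=grid_step)
    return m.coplanarity, m.collinearity


# ---------------------------------------------------------------------------
# solvent accessible surface area
# ---------------------------------------------------------------------------


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA with a deterministic Fibonacci point lattice.

    Per-residue areas sum the residue's atoms (side chain inclusive);
    relative SASA divides by the Tien et al. theoretical maximum for the
    residue type (capped at 1.5 for reporting).
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if n_points < 92:
        raise ValueError("n_points must be >= 92")

    atoms: list[tuple[int, str, str, np.ndarray]] = []
    for res in structure.residues:
        for a in res.atoms:
            if not include_hydrogens and a.element.upper() == "H":
                continue
            atoms.append((res.number, a.name, a.element, a.coords))
    if not atoms:
        return SasaResult({}, {}, {})

    centers = np.array([a[3] for a in atoms])
    radii = np.array([vdw_radius(a[2]) + probe_radius for a in atoms])
    sphere = fibonacci_sphere(n_points)

    per_atom: dict[tuple[int, str], float] = {}
    n = len(atoms)
    for i in range(n):
        ri = radii[i]
        pts = centers[i] + ri * sphere
        d_centers = np.linalg.norm(centers - centers[i], axis=1)
        neighbours = np.where((d_centers < ri + radii) & (np.arange(n) != i))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            accessible &= (
                np.linalg.norm(pts - centers[j], axis=1) >= radii[j]
            )
            if not accessible.any():
                break
        frac = accessible.mean()
        per_atom[(atoms[i][0], atoms[i][1])] = float(frac * 4.0 * np.pi * ri**2)

    per_residue: dict[int, float] = {}
    for (resnum, _), area in per_atom.items():
        per_residue[resnum] = per_residue.get(resnum, 0.0) + area

    relative: dict[int, float] = {}
    for res in structure.residues:
        total = per_residue.get(res.number, 0.0)
        ref = MAX_ASA.get(res.aa)
        if ref:
            relative[res.number] = min(total / ref, REL_SASA_CAP)
    return SasaResult(per_atom, per_residue, relative)
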