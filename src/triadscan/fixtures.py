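"""Synthetic structures, ensembles, pose tables and PSSMs with known truth.

Every generator is fully determined by its parameters plus a single integer
seed, so tests can plant a triad with prescribed geometry, an ensemble with
a prescribed persistence fraction, or a pose table with a closed-form
Boltzmann average, and assert exact recovery. The generated data emulate
the shapes of relaxation trajectories, MD frames and Monte Carlo pose
reports, not their physics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    ACID_OXYGENS,
    Thresholds,
    evaluate_triad_geometry,
    is_competent,
    place_atom,
    ring_h_position,
    stage_thresholds,
)
from .geometry import _HIS_N_NEIGHBOURS
from .model import (
    Atom,
    Ensemble,
    PoseRecord,
    PSSM,
    PSSM_ALPHABET,
    Residue,
    Structure,
    TriadSpec,
    TriadscanError,
)
from .rotamers import N_CHI, build_side_chain, apply_placement, clash_score, ideal_cb


class InfeasibleTriadError(TriadscanError):
    """Raised when no side-chain conformation can realise the target geometry."""


@dataclass
class FixtureSpec:
    """Declarative description of one synthetic fixture.

    ``kind`` is one of scaffold | planted_triad | ensemble | pose_table |
    pssm; ``parameters`` are forwarded to the corresponding maker. The seed
    is mandatory: parameters plus seed fully determine the output.
    """

    kind: str
    seed: int
    parameters: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# backbone scaffolds
# ---------------------------------------------------------------------------

# backbone internal coordinates (A / degrees)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_C_N_CA, _ANG_N_CA_C, _ANG_CA_C_N, _ANG_CA_C_O = 121.7, 111.2, 116.2, 120.8
_OMEGA = 180.0

PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}


def make_scaffold(
    n_residues: int, geometry: str = "helix", seed: int = 0, chain_id: str = "A"
) -> Structure:
    """Ideal poly-Ala backbone with uniform (phi, psi); deterministic."""
    if n_residues < 5:
        raise ValueError("scaffold needs at least 5 residues")
    try:
        phi, psi = PHI_PSI[geometry]
    except KeyError:
        raise ValueError(f"geometry must be one of {sorted(PHI_PSI)}") from None

    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    c = ca + _CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    backbone = [(n, ca, c)]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = place_atom(n_prev, ca_prev, c_prev, _C_N, _ANG_CA_C_N, psi)
        ca_next = place_atom(ca_prev, c_prev, n_next, _N_CA, _ANG_C_N_CA, _OMEGA)
        c_next = place_atom(c_prev, n_next, ca_next, _CA_C, _ANG_N_CA_C, phi)
        backbone.append((n_next, ca_next, c_next))

    residues = []
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        o_i = place_atom(n_i, ca_i, c_i, _C_O, _ANG_CA_C_O, psi + 180.0)
        cb_i = ideal_cb(n_i, ca_i, c_i)
        residues.append(
            Residue(
                chain_id=chain_id,
                number=i + 1,
                aa="ALA",
                atoms=[
                    Atom("N", "N", n_i),
                    Atom("CA", "C", ca_i),
                    Atom("C", "C", c_i),
                    Atom("O", "O", o_i),
                    Atom("CB", "C", cb_i),
                ],
            )
        )
    return Structure(residues=residues, model_id=1)


# ---------------------------------------------------------------------------
# planting triads with prescribed geometry
# ---------------------------------------------------------------------------


def _triad_geometry_from_chis(
    structure: Structure,
    positions: tuple[int, int, int],
    acid_kind: str,
    tautomer: str,
    chis: np.ndarray,
) -> tuple[dict, tuple]:
    """Build the three side chains at continuous chis and measure the
    hydrogen-bond geometry directly (no structure mutation)."""
    pos_s, pos_h, pos_a = positions
    n_acid_chis = N_CHI[acid_kind]
    ser_pl = build_side_chain(structure, pos_s, "SER", chis[:1])
    his_pl = build_side_chain(structure, pos_h, "HIS", chis[1:3])
    acid_pl = build_side_chain(structure, pos_a, acid_kind, chis[3:3 + n_acid_chis])

    def coord(pl, name):
        for a in pl.atoms:
            if a.name == name:
                return a.coords
        raise KeyError(name)

    og = coord(ser_pl, "OG")
    n_face = coord(his_pl, tautomer)
    n_acid_name = "ND1" if tautomer == "NE2" else "NE2"
    nb1, nb2 = _HIS_N_NEIGHBOURS[n_acid_name]
    h = ring_h_position(
        coord(his_pl, n_acid_name), coord(his_pl, nb1), coord(his_pl, nb2)
    )
    o_names = ACID_OXYGENS[acid_kind]
    o_pair = np.array([coord(acid_pl, o_names[0]), coord(acid_pl, o_names[1])])
    d_os = np.linalg.norm(o_pair - h, axis=1)

    geom = {
        "d_ser_his": float(np.linalg.norm(og - n_face)),
        "d_his_acid": float(d_os.min()),
    }
    return geom, (ser_pl, his_pl, acid_pl)


def plant_triad(
    scaffold: Structure,
    positions: tuple[int, int, int],
    target: Optional[dict] = None,
    acid_kind: str = "ASP",
    tautomer: str = "NE2",
    seed: int = 0,
    tol_d: float = 0.05,
    max_clash: float = 2.0,
) -> tuple[Structure, TriadSpec]:
    """Install Ser/His/acid side chains realising a target geometry.

    ``target`` may prescribe ``d_ser_his`` and ``d_his_acid`` (A, default
    3.0 each). Side-chain chi angles are optimised continuously (coarse
    grid scan then simplex refinement) until the measured geometry matches
    the target within ``tol_d`` / 2 deg and the hydrogen-bond angles sit in
    the design window; infeasible targets raise, never silently degrade.
    """
    target = dict(target or {})
    t_sh = float(target.get("d_ser_his", 3.0))
    t_ha = float(target.get("d_his_acid", 3.0))
    acid_kind = acid_kind.upper()
    pos_s, pos_h, pos_a = positions
    for pos in positions:
        if not scaffold.has_residue(pos):
            raise KeyError(f"scaffold has no residue {pos}")

    cb = {p: scaffold.residue(p).atom("CB").coords for p in positions}
    # quick reachability triage before any optimisation
    if np.linalg.norm(cb[pos_s] - cb[pos_h]) > t_sh + 9.0:
        raise InfeasibleTriadError(
            f"Ser {pos_s} and His {pos_h} backbones too far apart for "
            f"d_ser_his = {t_sh:.2f}"
        )
    if np.linalg.norm(cb[pos_h] - cb[pos_a]) > t_ha + 11.0:
        raise InfeasibleTriadError(
            f"His {pos_h} and acid {pos_a} backbones too far apart for "
            f"d_his_acid = {t_ha:.2f}"
        )

    n_chis = 3 + N_CHI[acid_kind]
    rng = np.random.default_rng(seed)

    def objective(chis: np.ndarray) -> float:
        geom, placements = _triad_geometry_from_chis(
            scaffold, positions, acid_kind, tautomer, chis
        )
        cost = (geom["d_ser_his"] - t_sh) ** 2 + (geom["d_his_acid"] - t_ha) ** 2
        excl = set(positions)
        for pl in placements:
            cost += 0.05 * clash_score(scaffold, pl, exclusion=excl)
        return cost

    # coarse seeded starts plus grid-aligned starts
    starts = [rng.uniform(0.0, 360.0, n_chis) for _ in range(12)]
    starts += [np.array(c, dtype=float)
               for c in itertools.islice(
                   itertools.product([60.0, 180.0, 300.0], repeat=n_chis), 27)]
    starts.sort(key=lambda s: objective(s))

    spec = TriadSpec(pos_s, pos_h, pos_a, acid_kind, his_n_ser_side=tautomer)
    best_struct = None
    for start in starts[:8]:
        res = minimize(
            objective, start, method="Nelder-Mead",
            options={"xatol": 0.01, "fatol": 1e-8, "maxiter": 2000},
        )
        _, placements = _triad_geometry_from_chis(
            scaffold, positions, acid_kind, tautomer, res.x
        )
        planted = scaffold
        for pl in placements:
            planted = apply_placement(planted, pl)
        metrics = evaluate_triad_geometry(planted, spec)
        if (
            abs(metrics.d_ser_his - t_sh) <= tol_d
            and abs(metrics.d_his_acid - t_ha) <= tol_d
            and 100.0 - 2.0 <= metrics.ang_ser <= 180.0
            and 100.0 - 2.0 <= metrics.ang_his <= 180.0
            and sum(pl.clash_score for pl in placements) <= max_clash
        ):
            best_struct = planted
            break
    if best_struct is None:
        raise InfeasibleTriadError(
            f"no side-chain conformation reaches d_ser_his={t_sh:.2f}, "
            f"d_his_acid={t_ha:.2f} at positions {positions}"
        )
    return best_struct, spec


# ---------------------------------------------------------------------------
# ensembles with prescribed persistence
# ---------------------------------------------------------------------------


def _displace_side_chain(res: Residue, shift: np.ndarray) -> Residue:
    """Rigidly translate the side chain beyond CB."""
    moved = []
    for a in res.atoms:
        if a.name in ("N", "CA", "C", "O", "CB"):
            moved.append(a)
        else:
            moved.append(Atom(a.name, a.element, a.coords + shift))
    return Residue(res.chain_id, res.number, res.aa, moved, res.hetero)


def _jitter_side_chain(res: Residue, sigma: float, rng) -> Residue:
    moved = []
    for a in res.atoms:
        if a.name in ("N", "CA", "C", "O"):
            moved.append(a)
        else:
            moved.append(Atom(a.name, a.element, a.coords + rng.normal(0.0, sigma, 3)))
    return Residue(res.chain_id, res.number, res.aa, moved, res.hetero)


def make_ensemble(
    structure: Structure,
    spec: TriadSpec,
    n_frames: int,
    competent_fraction: float,
    sigma: float = 0.05,
    seed: int = 0,
    stage: str = "relax",
    thresholds: Optional[Thresholds] = None,
) -> Ensemble:
    """Ensemble in which exactly round(n_frames * fraction) frames keep the
    triad competent at the stage thresholds.

    Competent frames carry a small verified side-chain jitter; incompetent
    frames have the acid side chain rigidly displaced past the distance
    threshold by at least 0.5 A. Frame order is shuffled by the seed.
    """
    if not (0.0 <= competent_fraction <= 1.0):
        raise ValueError("competent_fraction must be in [0, 1]")
    thr = thresholds if thresholds is not None else stage_thresholds(stage)
    rng = np.random.default_rng(seed)
    n_comp = int(round(n_frames * competent_fraction))

    base_metrics = evaluate_triad_geometry(structure, spec)
    if not is_competent(base_metrics, thr):
        raise TriadscanError("base structure is not competent at the stage thresholds")

    flags = np.array([True] * n_comp + [False] * (n_frames - n_comp))
    flags = flags[rng.permutation(n_frames)]

    frames = []
    for idx, competent in enumerate(flags):
        if competent:
            frame = _competent_frame(structure, spec, thr, sigma, rng)
        else:
            frame = _incompetent_frame(structure, spec, thr, rng)
        frame = Structure(
            residues=frame.residues,
            hetero_residues=frame.hetero_residues,
            model_id=idx + 1,
        )
        frames.append(frame)
    return Ensemble(frames=frames)


def _competent_frame(structure, spec, thr, sigma, rng) -> Structure:
    for _ in range(25):
        frame = structure
        for pos in (spec.ser_pos, spec.his_pos, spec.acid_pos):
            frame = frame.replace_residue(
                _jitter_side_chain(frame.residue(pos), sigma, rng)
            )
        if is_competent(evaluate_triad_geometry(frame, spec), thr):
            return frame
    return structure  # zero-jitter frame is competent by construction


def _incompetent_frame(structure, spec, thr, rng) -> Structure:
    metrics = evaluate_triad_geometry(structure, spec)
    his = structure.residue(spec.his_pos)
    h = ring_h_position(
        his.atom(spec.his_n_acid_side).coords,
        *(his.atom(n).coords for n in _HIS_N_NEIGHBOURS[spec.his_n_acid_side]),
    )
    acid = structure.residue(spec.acid_pos)
    o_coords = acid.coords(ACID_OXYGENS[spec.acid_kind])
    nearest = o_coords[np.argmin(np.linalg.norm(o_coords - h, axis=1))]
    direction = nearest - h
    direction = direction / np.linalg.norm(direction)

    delta = (thr.d_his_acid_max - metrics.d_his_acid) + 0.5 + rng.uniform(0.05, 0.4)
    for _ in range(12):
        frame = structure.replace_residue(
            _displace_side_chain(acid, delta * direction)
        )
        m = evaluate_triad_geometry(frame, spec)
        if m.d_his_acid >= thr.d_his_acid_max + 0.5 - 1e-9:
            return frame
        delta += 0.5
    raise TriadscanError("could not displace acid side chain past the threshold")


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

Law = Union[tuple, Sequence[float]]


def _draw(law: Law, n: int, rng) -> np.ndarray:
    if isinstance(law, tuple) and law and isinstance(law[0], str):
        kind = law[0]
        if kind == "constant":
            return np.full(n, float(law[1]))
        if kind == "uniform":
            return rng.uniform(float(law[1]), float(law[2]), n)
        if kind == "normal":
            return rng.normal(float(law[1]), float(law[2]), n)
        raise ValueError(f"unknown law {kind!r}")
    values = np.asarray(law, dtype=float)
    if len(values) != n:
        raise ValueError(f"explicit law needs {n} values, got {len(values)}")
    return values


def make_pose_table(
    n: int,
    energy_law: Law = ("uniform", 0.0, 5.0),
    binding_law: Law = ("uniform", -10.0, -1.0),
    catalytic_flags: Union[None, float, Sequence[bool]] = None,
    seed: int = 0,
) -> list[PoseRecord]:
    """Pose records with prescribed energy laws and catalytic-flag pattern.

    Distance columns are set to satisfy or violate the catalytic-pose
    predicate exactly as flagged (violations pick one distance at random).
    """
    if n < 1:
        raise ValueError("need at least one pose")
    rng = np.random.default_rng(seed)
    e_tot = _draw(energy_law, n, rng)
    e_bind = _draw(binding_law, n, rng)
    if catalytic_flags is None:
        flags = np.ones(n, dtype=bool)
    elif isinstance(catalytic_flags, float):
        k = int(round(n * catalytic_flags))
        flags = np.array([True] * k + [False] * (n - k))
        flags = flags[rng.permutation(n)]
    else:
        flags = np.asarray(catalytic_flags, dtype=bool)
        if len(flags) != n:
            raise ValueError("catalytic_flags length must equal n")

    poses = []
    for i in range(n):
        if flags[i]:
            d = (
                rng.uniform(3.5, 4.9),
                rng.uniform(2.9, 3.4),
                rng.uniform(2.9, 3.4),
            )
        else:
            which = rng.integers(0, 3)
            d = [
                rng.uniform(3.5, 4.9),
                rng.uniform(2.9, 3.4),
                rng.uniform(2.9, 3.4),
            ]
            d[which] = (5.1, 3.6, 3.6)[which] + rng.uniform(0.0, 1.0)
            d = tuple(d)
        poses.append(
            PoseRecord(
                pose_id=f"pose{i + 1}",
                E_total=float(e_tot[i]),
                E_bind=float(e_bind[i]),
                d_ser_lig=float(d[0]),
                d_ser_his=float(d[1]),
                d_his_acid=float(d[2]),
            )
        )
    return poses


# ---------------------------------------------------------------------------
# PSSMs
# ---------------------------------------------------------------------------

_TRIAD_AAS = "SHDE"


def make_pssm(
    sequence: str,
    tolerant_positions: Sequence[int] = (),
    seed: int = 0,
) -> PSSM:
    """Synthetic PSSM: the triad residue types (S/H/D/E) score non-negative
    at the listed positions and strongly negative elsewhere; the wild-type
    residue always scores high."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    tolerant = set(tolerant_positions)
    positions, wildtype, scores = [], [], []
    for i, aa1 in enumerate(sequence.upper(), start=1):
        row = {aa: int(rng.integers(-5, 2)) for aa in PSSM_ALPHABET}
        if i in tolerant:
            for aa in _TRIAD_AAS:
                row[aa] = int(rng.integers(0, 6))
        else:
            for aa in _TRIAD_AAS:
                row[aa] = int(rng.integers(-9, -3))
        if aa1 in row:
            row[aa1] = max(row[aa1], 6)
        positions.append(i)
        wildtype.append(aa1 if aa1 in PSSM_ALPHABET else "A")
        scores.append(row)
    return PSSM(positions=positions, wildtype=wildtype, scores=scores)


# ---------------------------------------------------------------------------
# demo fixture set
# ---------------------------------------------------------------------------


def write_demo_fixtures(
    outdir: Union[str, Path],
    seed: int = 0,
    n_residues: int = 12,
    positions: tuple[int, int, int] = (3, 7, 10),
) -> dict:
    """Emit a complete, self-consistent demo input set for the funnel CLI.

    Returns the paths plus the planted TriadSpec for reference.
    """
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scaffold = make_scaffold(n_residues, "helix", seed=seed)
    planted, spec = plant_triad(
        scaffold, positions, {"d_ser_his": 3.0, "d_his_acid": 3.0}, seed=seed
    )
    pssm = make_pssm(planted.sequence(), tolerant_positions=list(positions), seed=seed)
    relax = make_ensemble(planted, spec, 30, 0.8, seed=seed + 1, stage="relax")
    md = make_ensemble(planted, spec, 100, 0.6, seed=seed + 2, stage="md")
    poses = make_pose_table(
        50, ("normal", 0.0, 2.0), ("normal", -8.0, 2.0), 0.7, seed=seed + 3
    )

    paths = {
        "structure": outdir / "planted.pdb",
        "pssm": outdir / "profile.pssm",
        "relax_ensemble": outdir / "relax.pdb",
        "md_ensemble": outdir / "md.pdb",
        "pose_table": outdir / "poses.csv",
    }
    tio.write_structure(planted, paths["structure"])
    tio.write_pssm(pssm, paths["pssm"])
    tio.write_ensemble(relax, paths["relax_ensemble"])
    tio.write_ensemble(md, paths["md_ensemble"])
    tio.write_pose_table(poses, paths["pose_table"])

    config = {
        "structure": str(paths["structure"]),
        "pssm": str(paths["pssm"]),
        "native_sites": [],
        "ensembles": {spec.key: str(paths["relax_ensemble"])},
        "md_ensembles": {spec.key: str(paths["md_ensemble"])},
        "pose_tables": {spec.key: str(paths["pose_table"])},
    }
    import yaml

    config_path = outdir / "funnel.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return {"spec": spec, "config": config_path, **paths}
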