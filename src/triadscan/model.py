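"""Domain types shared across the triad-design pipeline.

All coordinates are in Angstrom, all residue numbers are author numbers
taken verbatim from the input file (1-based full-length UniProt numbering
for AlphaFold models), and all energies are in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: Three-letter -> one-letter codes for the 20 standard amino acids.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Column order of PSI-BLAST ASCII PSSM files.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})


class TriadscanError(Exception):
    """Base class for all package errors."""


class FormatError(TriadscanError):
    """Raised when an input file cannot be parsed."""


class TopologyError(TriadscanError):
    """Raised when ensemble frames disagree on residue topology."""


@dataclass(frozen=True)
class Atom:
    """A single atom: PDB-convention name, element, and coordinates (A)."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)


@dataclass
class Residue:
    """One residue with author numbering and its atoms."""

    chain_id: str
    number: int
    aa: str  # three-letter code, upper case
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    def __post_init__(self) -> None:
        self.aa = self.aa.upper()
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"residue {self.chain_id}{self.number}: duplicate atom names {dup}"
            )
        if not self.hetero and self.aa not in AA3_TO_1:
            raise ValueError(
                f"residue {self.chain_id}{self.number}: non-standard aa "
                f"{self.aa!r} must be flagged hetero"
            )

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.aa, "X")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"residue {self.chain_id}{self.number} ({self.aa}) has no atom {name!r}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        atoms = self.atoms if names is None else [self.atom(n) for n in names]
        return np.array([a.coords for a in atoms], dtype=float)

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]


@dataclass
class Structure:
    """An ordered set of residues from one model of a PDB file.

    Hetero/ligand residues are retained separately in ``hetero_residues``
    so that protein iteration never mixes them in.
    """

    residues: list[Residue] = field(default_factory=list)
    hetero_residues: list[Residue] = field(default_factory=list)
    model_id: int = 1

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.number) for r in self.residues]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (chain, number) residues: {dup}")
        self._index = {k: r for k, r in zip(keys, self.residues)}

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int, chain_id: Optional[str] = None) -> Residue:
        """Look up a residue by author number (and chain when ambiguous)."""
        if chain_id is not None:
            try:
                return self._index[(chain_id, number)]
            except KeyError:
                raise KeyError(f"no residue {chain_id}{number}") from None
        hits = [r for r in self.residues if r.number == number]
        if not hits:
            raise KeyError(f"no residue numbered {number}")
        if len(hits) > 1:
            raise KeyError(f"residue number {number} ambiguous across chains")
        return hits[0]

    def has_residue(self, number: int) -> bool:
        return any(r.number == number for r in self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def replace_residue(self, new: Residue) -> "Structure":
        """Return a copy with one residue swapped (same chain/number)."""
        res = [new if (r.chain_id, r.number) == (new.chain_id, new.number) else r
               for r in self.residues]
        return Structure(res, list(self.hetero_residues), self.model_id)

    def heavy_coords(self, exclude_positions: Sequence[int] = ()) -> np.ndarray:
        """Coordinates of all non-hydrogen protein atoms outside excluded positions."""
        excl = set(exclude_positions)
        pts = [a.coords for r in self.residues if r.number not in excl
               for a in r.atoms if a.element != "H"]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))


@dataclass
class Ensemble:
    """Ordered frames sharing an identical residue topology."""

    frames: list[Structure]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        ref = [(r.chain_id, r.number, r.aa) for r in self.frames[0].residues]
        for i, frame in enumerate(self.frames[1:], start=2):
            topo = [(r.chain_id, r.number, r.aa) for r in frame.residues]
            if topo != ref:
                bad = _first_topology_mismatch(ref, topo)
                raise TopologyError(
                    f"frame {i} topology differs from frame 1 at {bad}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)


def _first_topology_mismatch(ref: list, other: list) -> str:
    for a, b in zip(ref, other):
        if a != b:
            return f"residue {a} vs {b}"
    return f"length {len(ref)} vs {len(other)}"


@dataclass
class PSSM:
    """Position-specific scoring matrix: per-position log-odds scores.

    ``positions`` are author residue numbers; ``scores[i]`` maps each of the
    20 one-letter amino acid codes to an integer log-odds score.
    """

    positions: list[int]
    wildtype: list[str]
    scores: list[dict[str, int]]

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.wildtype) == len(self.scores)):
            raise ValueError("positions, wildtype and scores must align")
        for pos, row in zip(self.positions, self.scores):
            if sorted(row) != sorted(PSSM_ALPHABET):
                raise ValueError(f"position {pos}: needs exactly 20 aa scores")
        self._by_pos = dict(zip(self.positions, self.scores))

    def score(self, position: int, aa1: str) -> int:
        try:
            return self._by_pos[position][aa1.upper()]
        except KeyError:
            raise KeyError(f"position {position} absent from PSSM") from None

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class TriadSpec:
    """The identity of one candidate triad: three positions plus chemistry.

    ``his_n_ser_side`` names the His imidazole nitrogen that faces Ser
    (accepts the Ser hydroxyl hydrogen bond); the opposite nitrogen carries
    the proton that hydrogen-bonds to the acid.
    """

    ser_pos: int
    his_pos: int
    acid_pos: int
    acid_kind: str = "ASP"  # ASP | GLU
    his_n_ser_side: str = "NE2"  # NE2 | ND1

    def __post_init__(self) -> None:
        self.acid_kind = self.acid_kind.upper()
        if self.acid_kind not in ("ASP", "GLU"):
            raise ValueError("acid_kind must be ASP or GLU")
        if self.his_n_ser_side not in ("NE2", "ND1"):
            raise ValueError("his_n_ser_side must be NE2 or ND1")
        if len({self.ser_pos, self.his_pos, self.acid_pos}) != 3:
            raise ValueError("triad positions must be distinct")

    @property
    def his_n_acid_side(self) -> str:
        return "ND1" if self.his_n_ser_side == "NE2" else "NE2"

    @property
    def key(self) -> str:
        return (f"S{self.ser_pos}-H{self.his_pos}-"
                f"{'D' if self.acid_kind == 'ASP' else 'E'}{self.acid_pos}")

    def identity(self) -> tuple:
        """Dedup key: tautomer choice is folded into one unique triad."""
        return (self.ser_pos, self.his_pos, self.acid_pos, self.acid_kind)


@dataclass
class PoseRecord:
    """One sampled protein-ligand pose with energies and catalytic distances."""

    pose_id: str
    E_total: float
    E_bind: float
    d_ser_lig: Optional[float] = None
    d_ser_his: Optional[float] = None
    d_his_acid: Optional[float] = None
    score: Optional[float] = None  # docking score when present

    def __post_init__(self) -> None:
        if not (math.isfinite(self.E_total) and math.isfinite(self.E_bind)):
            raise ValueError(f"pose {self.pose_id}: energies must be finite")
        for name in ("d_ser_lig", "d_ser_his", "d_his_acid"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"pose {self.pose_id}: {name} must be >= 0")


@dataclass
class GeometryMetrics:
    """Measured triad geometry (distances in A, angles in degrees)."""

    d_ser_his: float
    d_his_acid: float
    ang_ser: float
    ang_his: float
    coplanarity: float = float("nan")
    collinearity: float = float("nan")
    d_ser_lig: Optional[float] = None
    his_n_ser_side: str = "NE2"

    def __post_init__(self) -> None:
        if self.d_ser_his < 0 or self.d_his_acid < 0:
            raise ValueError("distances must be >= 0")
        for ang in (self.ang_ser, self.ang_his):
            if not (0.0 <= ang <= 180.0 + 1e-9):
                raise ValueError("angles must lie in [0, 180]")


@dataclass
class SasaResult:
    """Shrake-Rupley solvent accessible surface areas."""

    per_atom: dict[tuple[int, str], float]
    per_residue: dict[int, float]
    relative: dict[int, float]

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.per_atom.values()):
            raise ValueError("SASA values must be >= 0")


@dataclass
class RotamerPlacement:
    """A constructed side chain at one position on the chi grid."""

    position: int
    aa: str
    chis: tuple[float, ...]
    atoms: list[Atom]
    clash_score: float = 0.0


@dataclass
class TriadCandidate:
    """One surviving triad candidate with full provenance."""

    spec: TriadSpec
    placements: tuple[RotamerPlacement, RotamerPlacement, RotamerPlacement]
    metrics: GeometryMetrics
    total_clash: float
    pssm_scores: dict[int, Optional[int]] = field(default_factory=dict)
    n_substitutions: int = 0


@dataclass
class EnsembleReport:
    """Per-frame triad competence over a structural ensemble."""

    n_frames: int
    mask: list[bool]
    stage: str  # "relax" | "md"

    def __post_init__(self) -> None:
        if len(self.mask) != self.n_frames:
            raise ValueError("mask length must equal n_frames")
        if self.stage not in ("relax", "md"):
            raise ValueError("stage must be 'relax' or 'md'")

    @property
    def fraction(self) -> float:
        return float(np.mean(self.mask)) if self.mask else 0.0


@dataclass
class CatalyticScore:
    """Boltzmann-weighted catalytic binding free energy over a pose ensemble.

    ``e_cat`` is <Eb> = sum over catalytic poses of Pi * Eib, with the pose
    probabilities Pi normalised over ALL poses. When no pose is catalytic the
    score is undefined: ``e_cat`` is NaN and ``defined`` is False.
    """

    kT: float
    Q: float
    weights: np.ndarray
    e_cat: float
    n_catalytic: int
    n_poses: int

    @property
    def defined(self) -> bool:
        return self.n_catalytic > 0
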