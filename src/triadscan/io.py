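"""Readers and writers for the pipeline's on-disk formats.

PDB (single- and multi-model) via biotite, PSI-BLAST ASCII PSSMs, CSV pose
tables via pandas, YAML/JSON configuration, FASTA sequence export, and the
packaged table of engineered-variant triad sites.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .model import (
    Atom,
    Ensemble,
    FormatError,
    PoseRecord,
    PSSM,
    PSSM_ALPHABET,
    Residue,
    Structure,
    TriadSpec,
)

PathLike = Union[str, Path]

# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def _atom_array_to_structure(array: "struc.AtomArray", model_id: int) -> Structure:
    residues: list[Residue] = []
    hetero: list[Residue] = []
    seen: set[tuple] = set()

    current_key = None
    current: Optional[Residue] = None
    for i in range(array.array_length()):
        ins = str(array.ins_code[i]).strip()
        if ins:
            raise FormatError(
                f"insertion code {ins!r} at residue "
                f"{array.chain_id[i]}{array.res_id[i]} is not supported"
            )
        is_het = bool(array.hetero[i])
        key = (str(array.chain_id[i]), int(array.res_id[i]), is_het,
               str(array.res_name[i]))
        if key != current_key:
            if current is not None:
                (hetero if current.hetero else residues).append(current)
            if key[:3] in seen:
                raise FormatError(
                    f"duplicate residue {key[0]}{key[1]} within one model"
                )
            seen.add(key[:3])
            current_key = key
            current = Residue(
                chain_id=key[0], number=key[1],
                aa=key[3], atoms=[], hetero=is_het,
            )
        element = str(array.element[i]) or "C"
        current.atoms.append(Atom(str(array.atom_name[i]), element, array.coord[i]))
    if current is not None:
        (hetero if current.hetero else residues).append(current)
    # re-validate atom-name uniqueness now that atoms are attached
    try:
        for res in residues + hetero:
            Residue(res.chain_id, res.number, res.aa, res.atoms, res.hetero)
        return Structure(residues=residues, hetero_residues=hetero, model_id=model_id)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def read_structure(path: PathLike) -> Structure:
    """Read the first model of a PDB file, author numbering preserved."""
    try:
        pdb = PDBFile.read(str(path))
        array = pdb.get_structure(model=1)
    except FormatError:
        raise
    except Exception as exc:  # biotite parse failure
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    return _atom_array_to_structure(array, model_id=1)


def read_ensemble(path: PathLike) -> Ensemble:
    """Read a multi-model PDB as an ensemble; frame order = MODEL order."""
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        frames = [
            _atom_array_to_structure(pdb.get_structure(model=m), model_id=m)
            for m in range(1, n_models + 1)
        ]
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    return Ensemble(frames=frames)


def _structure_to_atom_array(structure: Structure) -> "struc.AtomArray":
    records = []
    for res in list(structure.residues) + list(structure.hetero_residues):
        for a in res.atoms:
            records.append((res, a))
    array = struc.AtomArray(len(records))
    for i, (res, a) in enumerate(records):
        array.chain_id[i] = res.chain_id
        array.res_id[i] = res.number
        array.res_name[i] = res.aa
        array.atom_name[i] = a.name
        array.element[i] = a.element
        array.hetero[i] = res.hetero
        array.coord[i] = a.coords
    return array


def write_structure(structure: Structure, path: PathLike) -> None:
    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(str(path))


def write_ensemble(ensemble: Ensemble, path: PathLike) -> None:
    """Write frames as MODEL blocks; all frames must share the atom layout."""
    arrays = [_structure_to_atom_array(f) for f in ensemble.frames]
    ref = arrays[0]
    stack = struc.AtomArrayStack(len(arrays), ref.array_length())
    for cat in ref.get_annotation_categories():
        stack.set_annotation(cat, ref.get_annotation(cat))
    for i, arr in enumerate(arrays):
        if arr.array_length() != ref.array_length():
            raise FormatError(f"frame {i + 1} atom count differs; cannot write stack")
        stack.coord[i] = arr.coord
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_fasta(structure: Structure, path: PathLike, name: str = "structure") -> None:
    seq = structure.sequence()
    lines = [f">{name}"]
    lines += [seq[i:i + 60] for i in range(0, len(seq), 60)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------


def read_pssm(path: PathLike) -> PSSM:
    """Parse the `-out_ascii_pssm` dialect: the first 20 integer columns of
    each position row are the log-odds scores (the percentage block and the
    trailing statistics are ignored)."""
    lines = Path(path).read_text().splitlines()
    header_order: Optional[list[str]] = None
    positions: list[int] = []
    wildtype: list[str] = []
    scores: list[dict[str, int]] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if header_order is None:
            if len(tokens) >= 20 and all(t in PSSM_ALPHABET and len(t) == 1 for t in tokens[:20]):
                header_order = tokens[:20]
            continue
        if not tokens[0].lstrip("-").isdigit():
            continue  # footer statistics
        if len(tokens) < 2 or tokens[1] not in PSSM_ALPHABET:
            continue
        values = tokens[2:2 + 20]
        try:
            ints = [int(v) for v in values]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer log-odds column") from exc
        if len(ints) != 20:
            raise FormatError(
                f"{path}:{lineno}: expected 20 log-odds columns, got {len(ints)}"
            )
        positions.append(int(tokens[0]))
        wildtype.append(tokens[1])
        scores.append(dict(zip(header_order, ints)))
    if header_order is None or not positions:
        raise FormatError(f"{path}: not a PSI-BLAST ASCII PSSM")
    return PSSM(positions=positions, wildtype=wildtype, scores=scores)


def write_pssm(pssm: PSSM, path: PathLike) -> None:
    """Emit the PSI-BLAST ASCII dialect (log-odds block plus a zeroed
    percentage block, as psiblast prints)."""
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(PSSM_ALPHABET) + "   " + "   ".join(PSSM_ALPHABET),
    ]
    for pos, wt, row in zip(pssm.positions, pssm.wildtype, pssm.scores):
        logodds = " ".join(f"{row[aa]:3d}" for aa in PSSM_ALPHABET)
        pct = " ".join(f"{0:3d}" for _ in PSSM_ALPHABET)
        out.append(f"{pos:5d} {wt}  {logodds}  {pct}  0.00 0.00")
    out.append("")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# pose tables
# ---------------------------------------------------------------------------

_POSE_OPTIONAL = ("d_ser_lig", "d_ser_his", "d_his_acid", "score")


def read_pose_table(path: PathLike) -> list[PoseRecord]:
    """Read a CSV pose table; row order preserved, optional distance/score
    columns absent in the file stay absent (None), never zero-filled."""
    df = pd.read_csv(path)
    for col in ("pose_id", "E_total", "E_bind"):
        if col not in df.columns:
            raise FormatError(f"{path}: pose table missing column {col!r}")
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col in ("E_total", "E_bind"):
            value = pd.to_numeric(pd.Series([row[col]]), errors="coerce").iloc[0]
            if pd.isna(value):
                raise FormatError(
                    f"{path}: non-numeric {col} {row[col]!r} in data row {idx + 1}"
                )
            kwargs[col] = float(value)
        for col in _POSE_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = float(row[col])
        records.append(PoseRecord(pose_id=str(row["pose_id"]), **kwargs))
    return records


def write_pose_table(poses: list[PoseRecord], path: PathLike) -> None:
    rows = []
    for p in poses:
        row = {"pose_id": p.pose_id, "E_total": p.E_total, "E_bind": p.E_bind}
        for col in _POSE_OPTIONAL:
            value = getattr(p, col)
            if value is not None:
                row[col] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def read_config(path: PathLike) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return data


# ---------------------------------------------------------------------------
# packaged engineered-variant site table
# ---------------------------------------------------------------------------


def load_variant_sites() -> dict[str, dict]:
    """Triad sites of published engineered E. coli PETase variants.

    Returns per protein the UniProt accession, the TriadSpec (full-length
    AlphaFold/UniProt numbering) and the wild-type residue identities at the
    three triad positions (one-letter codes).
    """
    text = resources.files("triadscan.data").joinpath("variant_sites.tsv").read_text()
    table: dict[str, dict] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, acc, ser, his, acid, kind, wt_ser, wt_his, wt_acid = line.split("\t")
        spec = TriadSpec(
            ser_pos=int(ser), his_pos=int(his), acid_pos=int(acid), acid_kind=kind
        )
        table[name] = {
            "uniprot": acc,
            "spec": spec,
            "native": {int(ser): wt_ser, int(his): wt_his, int(acid): wt_acid},
        }
    return table
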