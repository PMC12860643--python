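"""Geometry-persistence gates over structural ensembles plus the final
oxyanion-hole and serine-accessibility filters.

The relax gate consumes one structure per relaxation trajectory and keeps a
triad only when at least 50% of trajectories preserve competent geometry
(Ser-His and His-acid hydrogen bonds within 4.0 A). The MD gate keeps a
triad only when competent geometry persists in at least 37% of simulation
frames (3.5 A windows, plus the Ser-ligand distance when a ligand is
present in the frames). Both bounds are inclusive by default; strict (>)
variants are available for the published stricter readings.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .geometry import (
    Thresholds,
    evaluate_triad_geometry,
    is_competent,
    sasa,
    stage_thresholds,
)
from .model import Ensemble, EnsembleReport, Structure, TriadSpec, TriadscanError

RELAX_MIN_FRACTION = 0.5
MD_MIN_FRACTION = 0.37


def persistence(
    ensemble: Ensemble,
    spec: TriadSpec,
    stage: str,
    thresholds: Thresholds | None = None,
    grid_step: float = 20.0,
) -> EnsembleReport:
    """Per-frame triad competence mask and its persistence fraction."""
    if stage not in ("relax", "md"):
        raise TriadscanError(f"stage must be 'relax' or 'md', got {stage!r}")
    thr = thresholds if thresholds is not None else stage_thresholds(stage)
    mask = []
    for i, frame in enumerate(ensemble.frames, start=1):
        try:
            metrics = evaluate_triad_geometry(frame, spec, grid_step=grid_step)
        except (KeyError, TriadscanError) as exc:
            raise TriadscanError(f"frame {i}: {exc}") from exc
        mask.append(is_competent(metrics, thr))
    return EnsembleReport(n_frames=len(ensemble), mask=mask, stage=stage)


def relax_gate(
    report: EnsembleReport, min_fraction: float = RELAX_MIN_FRACTION, strict: bool = False
) -> bool:
    """True iff the relax persistence fraction reaches ``min_fraction``
    (inclusive: a triad competent in exactly half the trajectories passes)."""
    if report.stage != "relax":
        raise TriadscanError(f"relax_gate needs a relax-stage report, got {report.stage!r}")
    return report.fraction > min_fraction if strict else report.fraction >= min_fraction


def md_gate(
    report: EnsembleReport, min_fraction: float = MD_MIN_FRACTION, strict: bool = False
) -> bool:
    """True iff competent geometry persists for at least ``min_fraction`` of
    the simulation frames (inclusive by default; strict mode uses >)."""
    if report.stage != "md":
        raise TriadscanError(f"md_gate needs an md-stage report, got {report.stage!r}")
    return report.fraction > min_fraction if strict else report.fraction >= min_fraction


#: Side-chain amide nitrogens able to donate an oxyanion-stabilising H-bond.
_SIDE_CHAIN_DONORS = {"ASN": ("ND2",), "GLN": ("NE2",)}


def oxyanion_scan(
    structure: Structure, spec: TriadSpec, cutoff: float = 4.0
) -> list[tuple[int, str]]:
    """Potential oxyanion-hole donors near the catalytic serine.

    Backbone amide nitrogens plus Asn/Gln side-chain amide nitrogens within
    ``cutoff`` of Ser OG, excluding the triad His. An empty list means the
    candidate has no oxyanion hole and fails this filter.
    """
    og = structure.residue(spec.ser_pos).atom("OG").coords
    donors = []
    for res in structure.residues:
        if res.number == spec.his_pos:
            continue
        names = ["N"] + list(_SIDE_CHAIN_DONORS.get(res.aa, ()))
        for name in names:
            if not res.has_atom(name):
                continue
            if np.linalg.norm(res.atom(name).coords - og) <= cutoff:
                donors.append((res.number, name))
    return donors


def ser_accessibility_gate(
    structure: Structure,
    spec: TriadSpec,
    min_rel_sasa: float = 0.2,
    n_points: int = 960,
    probe_radius: float = 1.4,
) -> bool:
    """True iff the catalytic serine is not buried: its relative SASA
    reaches ``min_rel_sasa``."""
    result = sasa(structure, probe_radius=probe_radius, n_points=n_points)
    return result.relative.get(spec.ser_pos, 0.0) >= min_rel_sasa


def concat_reports(reports: Sequence[EnsembleReport]) -> EnsembleReport:
    """Concatenate per-ensemble reports; the fraction becomes the
    frame-count-weighted mean of the parts."""
    if not reports:
        raise ValueError("need at least one report")
    stages = {r.stage for r in reports}
    if len(stages) != 1:
        raise TriadscanError("cannot concatenate reports from different stages")
    mask = [m for r in reports for m in r.mask]
    return EnsembleReport(n_frames=len(mask), mask=mask, stage=reports[0].stage)
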