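"""Staged design funnel: design scan, relax gate, pose scoring, MD gate,
and the final oxyanion-hole / serine-accessibility filters.

Stages run in a fixed order and are individually skippable when their
inputs (relax/MD ensembles, pose tables) are absent, since those come from
external sampling engines. The report records, per stage, the input and
surviving candidate counts (monotone non-increasing), the parameters used,
and the first failing criterion of every dropped candidate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import io as tio
from .gates import (
    MD_MIN_FRACTION,
    RELAX_MIN_FRACTION,
    md_gate,
    oxyanion_scan,
    persistence,
    relax_gate,
    ser_accessibility_gate,
)
from .model import TriadCandidate, TriadscanError
from .rotamers import apply_placement
from .scoring import KT_298, catalytic_binding_energy
from .search import SearchParams, design_triads

STAGE_ORDER = ("design", "relax_gate", "pose_scoring", "md_gate", "final_filters")


@dataclass
class StageReport:
    name: str
    ran: bool
    n_in: int
    n_out: int
    params: dict = field(default_factory=dict)


@dataclass
class FunnelReport:
    stages: list[StageReport]
    candidates: list[dict]
    dropped: list[dict]
    design_counts: dict = field(default_factory=dict)

    def validate_monotone(self) -> None:
        ran = [s for s in self.stages if s.ran]
        for s in ran:
            if s.n_out > s.n_in:
                raise TriadscanError(f"stage {s.name}: surviving > input")
        for prev, cur in zip(ran, ran[1:]):
            if cur.n_in > prev.n_out:
                raise TriadscanError(
                    f"stage {cur.name}: input exceeds previous stage output"
                )

    def to_dict(self) -> dict:
        return {
            "stages": [asdict(s) for s in self.stages],
            "design_counts": dict(self.design_counts),
            "candidates": self.candidates,
            "dropped": self.dropped,
        }


def _candidate_row(cand: TriadCandidate) -> dict:
    m = cand.metrics
    return {
        "triad": cand.spec.key,
        "ser_pos": cand.spec.ser_pos,
        "his_pos": cand.spec.his_pos,
        "acid_pos": cand.spec.acid_pos,
        "acid_kind": cand.spec.acid_kind,
        "tautomer": cand.spec.his_n_ser_side,
        "chis": [list(pl.chis) for pl in cand.placements],
        "d_ser_his": round(m.d_ser_his, 4),
        "d_his_acid": round(m.d_his_acid, 4),
        "ang_ser": round(m.ang_ser, 2),
        "ang_his": round(m.ang_his, 2),
        "coplanarity": round(m.coplanarity, 4),
        "collinearity": round(m.collinearity, 2),
        "total_clash": round(cand.total_clash, 6),
        "n_substitutions": cand.n_substitutions,
        "pssm_scores": {str(k): v for k, v in cand.pssm_scores.items()},
    }


def run_funnel(config: dict) -> FunnelReport:
    """Execute the staged funnel described by a configuration mapping.

    Required: ``structure`` (PDB path). Optional: ``pssm``, ``native_sites``,
    ``search`` (SearchParams overrides), ``ensembles`` / ``md_ensembles`` /
    ``pose_tables`` (mappings from triad key, e.g. ``S3-H7-D10``, to paths),
    threshold overrides, and ``references`` (reference catalytic binding
    energies for ranking context).
    """
    if "structure" not in config:
        raise TriadscanError("config error: 'structure' is mandatory")
    for key in ("structure", "pssm"):
        if key in config and config[key] and not Path(config[key]).exists():
            raise TriadscanError(f"config error: {key} file {config[key]} not found")

    structure = tio.read_structure(config["structure"])
    pssm = tio.read_pssm(config["pssm"]) if config.get("pssm") else None
    native_sites = list(config.get("native_sites", []) or [])
    params = SearchParams(**config.get("search", {}))
    stages: list[StageReport] = []
    dropped: list[dict] = []

    # -- stage 1: design ----------------------------------------------------
    design = design_triads(
        structure,
        params,
        pssm=pssm,
        native_sites=native_sites,
        pssm_min=int(config.get("pssm_min", 0)),
        exclusion_dist=float(config.get("exclusion_dist", 6.0)),
    )
    survivors = design.candidates
    stages.append(
        StageReport(
            "design", True,
            n_in=design.counts.get("triads_enumerated", len(survivors)),
            n_out=len(survivors),
            params={"grid_step": params.grid_step,
                    "d_ser_his_max": params.d_ser_his_max,
                    "d_his_acid_max": params.d_his_acid_max,
                    "ang_window": [params.ang_min, params.ang_max],
                    "pssm_min": int(config.get("pssm_min", 0)),
                    "exclusion_dist": float(config.get("exclusion_dist", 6.0))},
        )
    )

    rows = {c.spec.key: _candidate_row(c) for c in survivors}
    by_key = {c.spec.key: c for c in survivors}

    # -- stage 2: relax gate ------------------------------------------------
    relax_paths = config.get("ensembles") or {}
    min_relax = float(config.get("relax_min_fraction", RELAX_MIN_FRACTION))
    if relax_paths:
        survivors, stage = _ensemble_stage(
            survivors, by_key, rows, dropped, relax_paths,
            stage_name="relax_gate", ensemble_stage="relax",
            gate=lambda rep: relax_gate(rep, min_relax),
            fraction_field="relax_fraction",
            params={"min_fraction": min_relax},
        )
        stages.append(stage)
    else:
        stages.append(StageReport("relax_gate", False, len(survivors), len(survivors)))

    # -- stage 3: pose scoring ----------------------------------------------
    pose_paths = config.get("pose_tables") or {}
    kt = float(config.get("kt", KT_298))
    if pose_paths:
        n_in = len(survivors)
        kept = []
        for cand in survivors:
            key = cand.spec.key
            if key not in pose_paths:
                dropped.append({"triad": key, "stage": "pose_scoring",
                                "reason": "no pose table provided"})
                continue
            poses = tio.read_pose_table(pose_paths[key])
            score = catalytic_binding_energy(poses, kT=kt)
            rows[key]["e_cat"] = None if not score.defined else round(score.e_cat, 6)
            rows[key]["n_catalytic_poses"] = score.n_catalytic
            if not score.defined:
                dropped.append({"triad": key, "stage": "pose_scoring",
                                "reason": "no catalytic pose in ensemble"})
                continue
            references = list(config.get("references", []) or [])
            if references:
                rows[key]["beats_references"] = sum(
                    1 for ref in references if score.e_cat < ref
                )
            kept.append(cand)
        kept.sort(key=lambda c: rows[c.spec.key]["e_cat"])
        survivors = kept
        stages.append(StageReport("pose_scoring", True, n_in, len(survivors),
                                  params={"kt": kt}))
    else:
        stages.append(StageReport("pose_scoring", False, len(survivors), len(survivors)))

    # -- stage 4: MD gate ---------------------------------------------------
    md_paths = config.get("md_ensembles") or {}
    min_md = float(config.get("md_min_fraction", MD_MIN_FRACTION))
    if md_paths:
        survivors, stage = _ensemble_stage(
            survivors, by_key, rows, dropped, md_paths,
            stage_name="md_gate", ensemble_stage="md",
            gate=lambda rep: md_gate(rep, min_md),
            fraction_field="md_fraction",
            params={"min_fraction": min_md},
        )
        stages.append(stage)
    else:
        stages.append(StageReport("md_gate", False, len(survivors), len(survivors)))

    # -- stage 5: final filters ---------------------------------------------
    oxy_cutoff = float(config.get("oxyanion_cutoff", 4.0))
    min_rel = float(config.get("ser_rel_sasa_min", config.get("rel_sasa_min", 0.2)))
    n_in = len(survivors)
    kept = []
    for cand in survivors:
        key = cand.spec.key
        mutated = structure
        for pl in cand.placements:
            mutated = apply_placement(mutated, pl)
        donors = oxyanion_scan(mutated, cand.spec, cutoff=oxy_cutoff)
        rows[key]["oxyanion_donors"] = len(donors)
        if not donors:
            dropped.append({"triad": key, "stage": "final_filters",
                            "reason": "no oxyanion-hole donor near Ser OG"})
            continue
        accessible = ser_accessibility_gate(mutated, cand.spec, min_rel)
        rows[key]["ser_accessible"] = bool(accessible)
        if not accessible:
            dropped.append({"triad": key, "stage": "final_filters",
                            "reason": "catalytic Ser buried"})
            continue
        kept.append(cand)
    survivors = kept
    stages.append(StageReport(
        "final_filters", True, n_in, len(survivors),
        params={"oxyanion_cutoff": oxy_cutoff, "ser_rel_sasa_min": min_rel},
    ))

    report = FunnelReport(
        stages=stages,
        candidates=[rows[c.spec.key] for c in survivors],
        dropped=dropped,
        design_counts=design.counts,
    )
    report.validate_monotone()
    return report


def _ensemble_stage(
    survivors, by_key, rows, dropped, paths, stage_name, ensemble_stage,
    gate, fraction_field, params,
):
    n_in = len(survivors)
    kept = []
    for cand in survivors:
        key = cand.spec.key
        if key not in paths:
            dropped.append({"triad": key, "stage": stage_name,
                            "reason": "no ensemble provided"})
            continue
        ensemble = tio.read_ensemble(paths[key])
        report = persistence(ensemble, cand.spec, stage=ensemble_stage)
        rows[key][fraction_field] = round(report.fraction, 6)
        if gate(report):
            kept.append(cand)
        else:
            dropped.append({
                "triad": key, "stage": stage_name,
                "reason": f"persistence {report.fraction:.3f} below "
                          f"{params['min_fraction']}",
            })
    return kept, StageReport(stage_name, True, n_in, len(kept), params=params)


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------


def write_report(report: FunnelReport, path) -> tuple[Path, Path]:
    """Write the machine-readable JSON and a human-readable stage table.

    ``path`` names the JSON file; the text table goes next to it with a
    ``.txt`` suffix. Rerunning on identical inputs produces byte-identical
    files (no timestamps, sorted keys).
    """
    json_path = Path(path)
    txt_path = json_path.with_suffix(".txt")
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    lines = [
        f"{'stage':<16}{'ran':<6}{'in':>6}{'out':>6}  parameters",
        "-" * 72,
    ]
    for s in report.stages:
        params = ", ".join(f"{k}={v}" for k, v in sorted(s.params.items()))
        lines.append(f"{s.name:<16}{str(s.ran):<6}{s.n_in:>6}{s.n_out:>6}  {params}")
    lines.append("")
    lines.append(f"final candidates: {len(report.candidates)}")
    for row in report.candidates:
        extras = []
        for field_name in ("relax_fraction", "e_cat", "md_fraction"):
            if field_name in row and row[field_name] is not None:
                extras.append(f"{field_name}={row[field_name]}")
        lines.append(
            f"  {row['triad']:<16} clash={row['total_clash']:<10} "
            f"d_sh={row['d_ser_his']} d_ha={row['d_his_acid']} "
            + " ".join(extras)
        )
    txt_path.write_text("\n".join(lines) + "\n")
    return json_path, txt_path
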