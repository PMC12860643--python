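"""Boltzmann-weighted catalytic binding free energy of pose ensembles.

Each sampled pose i carries a total energy Ei and a binding energy Eib.
Pose probabilities follow a Boltzmann distribution over ALL poses,

    Pi = exp(-Ei / kT) / Q,      Q = sum_i exp(-Ei / kT),

and the catalytic binding free energy is the probability-weighted sum of
binding energies restricted to catalytically posed members,

    <Eb> = sum_{i catalytic} Pi * Eib.

The weights are deliberately NOT renormalised over the catalytic subset:
an ensemble that rarely visits catalytic poses is penalised through the
missing weight. A renormalised variant is available for sensitivity
analysis. The evaluation is shift-stabilised (energies offset by their
minimum) and exactly invariant to adding a constant to all Ei.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import CatalyticScore, PoseRecord, TriadscanError

#: Thermal energy at 298.15 K in kcal/mol.
KT_298 = 0.593


def is_catalytic_pose(
    pose: PoseRecord,
    d_ser_lig_max: float = 5.0,
    d_ser_his_max: float = 3.5,
    d_his_acid_max: float = 3.5,
    inclusive: bool = False,
) -> bool:
    """Catalytic-pose predicate on the three mechanism distances.

    Default bounds are strict (<), matching how sampled poses are
    classified; ``inclusive`` switches the two hydrogen-bond distances to
    <=, the reading used when validating docking poses.
    """
    for name in ("d_ser_lig", "d_ser_his", "d_his_acid"):
        if getattr(pose, name) is None:
            raise TriadscanError(f"pose {pose.pose_id}: missing distance {name}")
    if inclusive:
        return (
            pose.d_ser_lig < d_ser_lig_max
            and pose.d_ser_his <= d_ser_his_max
            and pose.d_his_acid <= d_his_acid_max
        )
    return (
        pose.d_ser_lig < d_ser_lig_max
        and pose.d_ser_his < d_ser_his_max
        and pose.d_his_acid < d_his_acid_max
    )


def boltzmann_weights(energies: Sequence[float], kT: float = KT_298) -> np.ndarray:
    """Normalised Boltzmann probabilities, shift-stabilised by min(E)."""
    if len(energies) == 0:
        raise TriadscanError("boltzmann_weights needs at least one pose")
    if kT <= 0:
        raise ValueError("kT must be > 0")
    e = np.asarray(energies, dtype=float)
    shifted = np.exp(-(e - e.min()) / kT)
    return shifted / shifted.sum()


def catalytic_binding_energy(
    poses: Sequence[PoseRecord],
    kT: float = KT_298,
    d_ser_lig_max: float = 5.0,
    d_ser_his_max: float = 3.5,
    d_his_acid_max: float = 3.5,
    renormalize: bool = False,
) -> CatalyticScore:
    """<Eb> over a pose ensemble.

    Weights are computed over all poses; the sum runs over catalytic poses
    only. With no catalytic pose the score is undefined (NaN, flagged via
    ``CatalyticScore.defined``), never 0 — an ensemble that never reaches a
    catalytic arrangement carries no binding-energy information.
    """
    if not poses:
        raise TriadscanError("catalytic_binding_energy needs at least one pose")
    weights = boltzmann_weights([p.E_total for p in poses], kT)
    catalytic = np.array(
        [
            is_catalytic_pose(p, d_ser_lig_max, d_ser_his_max, d_his_acid_max)
            for p in poses
        ]
    )
    e = np.asarray([p.E_total for p in poses], dtype=float)
    q = float(np.sum(np.exp(-(e - e.min()) / kT)))
    n_cat = int(catalytic.sum())
    if n_cat == 0:
        e_cat = float("nan")
    else:
        w = weights[catalytic]
        eb = np.array([p.E_bind for p in poses])[catalytic]
        if renormalize:
            w = w / w.sum()
        e_cat = float(np.sum(w * eb))
    return CatalyticScore(
        kT=kT, Q=q, weights=weights, e_cat=e_cat,
        n_catalytic=n_cat, n_poses=len(poses),
    )


def select_best_docking_pose(
    poses: Sequence[PoseRecord],
    d_ser_lig_max: float = 5.0,
    d_ser_his_max: float = 3.5,
    d_his_acid_max: float = 3.5,
) -> Optional[PoseRecord]:
    """Best-scoring docking pose that fulfils the catalytic distances
    (Ser-His and His-acid <= 3.5 A, Ser-ligand < 5 A); ties broken by the
    smaller Ser-ligand distance. Returns None when no pose qualifies."""
    valid = []
    for p in poses:
        if p.score is None:
            raise TriadscanError(f"pose {p.pose_id}: missing docking score")
        if is_catalytic_pose(
            p, d_ser_lig_max, d_ser_his_max, d_his_acid_max, inclusive=True
        ):
            valid.append(p)
    if not valid:
        return None
    return min(valid, key=lambda p: (p.score, p.d_ser_lig))


def rank_candidates(
    scored: Sequence[tuple[object, CatalyticScore]],
    references: Sequence[float] = (),
) -> list[tuple[object, CatalyticScore, int]]:
    """Sort candidates by <Eb> ascending (most favourable first) and
    annotate each with the number of reference energies it beats.

    Undefined scores (no catalytic poses) sort last. The sort is stable:
    equal scores keep input order.
    """
    def sort_key(item):
        _, score = item
        return (not score.defined, score.e_cat if score.defined else 0.0)

    ranked = sorted(scored, key=sort_key)
    out = []
    for cand, score in ranked:
        beats = (
            sum(1 for ref in references if score.e_cat < ref) if score.defined else 0
        )
        out.append((cand, score, beats))
    return out
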