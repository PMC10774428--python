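"""Framework-aligned backbone RMSD between a model and a reference Fv.

The superposition is fitted by least squares (Kabsch) on the backbone
atoms (N, CA, C, O) of the framework residues common to both structures
for the investigated chain; region RMSDs (FR, CDR1, CDR2, CDR3) are then
evaluated under that single transform without re-fitting, so CDR values
measure loop displacement in the framework frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import BACKBONE_ATOMS, FvStructure
from .regions import assign_regions

logger = logging.getLogger(__name__)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # 3x3, det +1
    translation: np.ndarray       # 3-vector, Å
    per_region_rmsd: dict[str, float]
    n_atoms: dict[str, int] = field(default_factory=dict)


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) minimising |R·moving + t − fixed|.

    Proper rotation enforced (det +1) via sign correction of the smallest
    singular vector.
    """
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("need matching (n, 3) coordinate arrays")
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    h = (moving - mu_m).T @ (fixed - mu_f)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_f - rot @ mu_m
    return rot, trans


def _region_backbone(model: FvStructure, reference: FvStructure,
                     chain: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Paired backbone coordinates per region, matched by IMGT identity."""
    regions_m = assign_regions(model)
    ref_by_key = {r.key: r for r in reference.chain(chain)}
    paired: dict[str, tuple[list, list]] = {}
    for res in model.chain(chain):
        ref = ref_by_key.get(res.key)
        if ref is None:
            continue
        atoms_m = [res.get_atom(n) for n in BACKBONE_ATOMS]
        atoms_r = [ref.get_atom(n) for n in BACKBONE_ATOMS]
        if any(a is None for a in atoms_m + atoms_r):
            logger.warning("skipping %s: missing backbone atoms", res.key)
            continue
        region = regions_m.per_residue_region[res.key]
        bucket = paired.setdefault(region, ([], []))
        bucket[0].extend(a.coord for a in atoms_m)
        bucket[1].extend(a.coord for a in atoms_r)
    return {k: (np.asarray(v[0]), np.asarray(v[1])) for k, v in paired.items()}


def framework_align_region_rmsd(
    model: FvStructure, reference: FvStructure, chain: str,
) -> SuperpositionResult:
    """Superpose on framework backbone; report per-region backbone RMSDs."""
    if chain not in ("H", "L"):
        raise ValueError("chain must be 'H' or 'L'")
    paired = _region_backbone(model, reference, chain)
    if "FR" not in paired or len(paired["FR"][0]) < 3 * len(BACKBONE_ATOMS):
        raise ValueError("fewer than 3 common framework residues")
    rot, trans = kabsch(paired["FR"][0], paired["FR"][1])
    per_region: dict[str, float] = {}
    n_atoms: dict[str, int] = {}
    for region, (m_xyz, r_xyz) in paired.items():
        moved = m_xyz @ rot.T + trans
        per_region[region] = float(np.sqrt(((moved - r_xyz) ** 2).sum(axis=1).mean()))
        n_atoms[region] = len(m_xyz)
    return SuperpositionResult(rotation=rot, translation=trans,
                               per_region_rmsd=per_region, n_atoms=n_atoms)
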