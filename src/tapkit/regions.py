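"""IMGT region assignment, total CDR length and the CDR vicinity.

IMGT position ranges (both chains): CDR1 27-38, CDR2 56-65, CDR3 105-117;
everything else is framework.  Insertion-coded residues inside a range
count as CDR.  The CDR vicinity is the anchor set (CDR residues plus two
sequence flanks on each side, counted in chain order) united with every
surface-exposed residue whose minimum heavy-atom distance to an anchor is
within the cutoff (default 4.5 Å); the expansion is a single pass — the
shell does not grow transitively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_model import FvStructure, Residue, ResidueKey

CDR_BOUNDS: dict[str, tuple[int, int]] = {
    "CDR1": (27, 38),
    "CDR2": (56, 65),
    "CDR3": (105, 117),
}


@dataclass
class RegionMap:
    per_residue_region: dict[ResidueKey, str]   # FR | CDR1 | CDR2 | CDR3

    def region_of(self, res: Residue) -> str:
        return self.per_residue_region[res.key]

    def cdr_label(self, res: Residue) -> str | None:
        """e.g. "CDRH3" for a heavy-chain CDR3 residue, None for framework."""
        region = self.per_residue_region[res.key]
        if region == "FR":
            return None
        return f"CDR{res.chain_id}{region[-1]}"


def region_for_number(imgt_number: int) -> str:
    for name, (lo, hi) in CDR_BOUNDS.items():
        if lo <= imgt_number <= hi:
            return name
    return "FR"


def assign_regions(structure: FvStructure) -> RegionMap:
    """Label every residue FR/CDR1/CDR2/CDR3 by its IMGT number."""
    return RegionMap(per_residue_region={
        res.key: region_for_number(res.imgt_number) for res in structure.residues()
    })


def cdr_residues(structure: FvStructure, regions: RegionMap,
                 chain_id: str | None = None, cdr: str | None = None) -> list[Residue]:
    out = []
    for res in structure.residues():
        if chain_id is not None and res.chain_id != chain_id:
            continue
        region = regions.per_residue_region[res.key]
        if region == "FR":
            continue
        if cdr is not None and region != cdr:
            continue
        out.append(res)
    return out


def total_cdr_length(structure: FvStructure, regions: RegionMap) -> int:
    """Residue count over all six CDRs (insertion codes included)."""
    return len(cdr_residues(structure, regions))


def cdr_lengths(structure: FvStructure, regions: RegionMap) -> dict[str, int]:
    """Per-loop lengths keyed CDRH1..CDRL3 (missing loops count 0)."""
    lengths = {f"CDR{c}{i}": 0 for c in "HL" for i in (1, 2, 3)}
    for res in structure.residues():
        label = regions.cdr_label(res)
        if label is not None:
            lengths[label] += 1
    return lengths


def build_anchor_set(structure: FvStructure, regions: RegionMap,
                     flank: int = 2) -> list[Residue]:
    """CDR residues plus ``flank`` preceding/following residues per segment.

    Flanks are taken in chain order (seq_index), not by IMGT arithmetic, so
    numbering gaps still yield two flank residues; segments abutting a
    terminus are truncated silently.  The result is deduplicated and kept
    in chain order (heavy then light).
    """
    anchors: list[Residue] = []
    seen: set[ResidueKey] = set()
    for chain_id in ("H", "L"):
        chain = structure.chain(chain_id)
        n = len(chain)
        take = [False] * n
        for i, res in enumerate(chain):
            if regions.per_residue_region[res.key] != "FR":
                for j in range(max(0, i - flank), min(n, i + flank + 1)):
                    take[j] = True
        for i, res in enumerate(chain):
            if take[i] and res.key not in seen:
                seen.add(res.key)
                anchors.append(res)
    return anchors


@dataclass
class CdrVicinity:
    anchors: list[Residue]
    members: list[Residue]
    distance_cutoff: float

    def member_keys(self) -> set[ResidueKey]:
        return {r.key for r in self.members}


def min_heavy_atom_distance(res_a: Residue, res_b: Residue) -> float:
    diff = res_a.coords()[:, None, :] - res_b.coords()[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2).min()))


def build_cdr_vicinity(
    structure: FvStructure,
    anchors: list[Residue],
    exposure: dict[ResidueKey, bool],
    cutoff: float = 4.5,
) -> CdrVicinity:
    """Anchors plus exposed residues within ``cutoff`` Å of any anchor.

    Distance is the minimum over heavy-atom pairs (inclusive bound).
    Anchor residues are members regardless of exposure; exposure gating of
    anchors happens at metric time.
    """
    anchor_keys = {r.key for r in anchors}
    anchor_xyz = np.concatenate([r.coords() for r in anchors]) if anchors else np.empty((0, 3))
    members: list[Residue] = list(anchors)
    if len(anchor_xyz):
        tree = cKDTree(anchor_xyz)
        for res in structure.residues():
            if res.key in anchor_keys or not exposure.get(res.key, False):
                continue
            d, _ = tree.query(res.coords(), k=1)
            if float(np.min(d)) <= cutoff:
                members.append(res)
    return CdrVicinity(anchors=list(anchors), members=members, distance_cutoff=cutoff)
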