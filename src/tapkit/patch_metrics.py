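"""The five developability metrics and the pairwise patch decomposition.

Three patch scores are sums over unordered pairs of exposed CDR-vicinity
residues within a distance cutoff:

    score = sum_{i<j, d_ij <= cutoff} w_i * w_j / d_ij^e        (e = 2)

with residue weights w given by the normalised Kyte–Doolittle
hydrophobicity (PSH), the magnitude of positive formal charge (PPC) or of
negative formal charge (PNC).  Distances are minimum heavy-atom distances
by default.  Each score carries its full list of pair components, which is
what makes the metrics decomposable: the components of a profile sum back
to the score exactly, and ranking them surfaces the residue pairs that
drive an extreme value.

The two remaining metrics are the total IMGT CDR length (L_tot) and the
structural Fv charge symmetry parameter (SFvCSP): the product of the net
formal charge of the exposed heavy-chain residues and that of the exposed
light-chain residues — large negative values mean strongly opposite net
chain charges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .config import RunConfig
from .core_model import FvStructure, Residue, ResidueKey
from .regions import (CdrVicinity, RegionMap, assign_regions, build_anchor_set,
                      build_cdr_vicinity, cdr_lengths, total_cdr_length)
from .surface import MaxSasaTable, run_sasa_pipeline

# raw Kyte–Doolittle hydropathy
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Kyte–Doolittle values affinely rescaled onto a strictly positive range.

    The affine map preserves the ordering of the raw scale, and positive
    weights keep every pair contribution non-negative (hence rankable).
    """
    per_aa: dict[str, float]
    normalized: dict[str, float]

    @classmethod
    def kyte_doolittle(cls, low: float = 1.0, high: float = 2.0) -> "HydrophobicityScale":
        if not 0 < low < high:
            raise ValueError("need 0 < low < high for a strictly positive scale")
        raw = dict(KYTE_DOOLITTLE)
        lo, hi = min(raw.values()), max(raw.values())
        normalized = {aa: low + (v - lo) * (high - low) / (hi - lo)
                      for aa, v in raw.items()}
        return cls(per_aa=raw, normalized=normalized)


@dataclass(frozen=True)
class ChargeAssignment:
    """Formal residue charges: R/K +1, D/E -1, His a configurable fraction."""
    per_aa: dict[str, float]
    h_his: float = 0.1

    @classmethod
    def default(cls, h_his: float = 0.1) -> "ChargeAssignment":
        per_aa = {aa: 0.0 for aa in KYTE_DOOLITTLE}
        per_aa.update({"R": 1.0, "K": 1.0, "H": h_his, "D": -1.0, "E": -1.0})
        return cls(per_aa=per_aa, h_his=h_his)


@dataclass
class PairComponent:
    res_i: ResidueKey
    res_j: ResidueKey
    aa_i: str
    aa_j: str
    seq_i: int
    seq_j: int
    distance: float
    contribution: float
    adjacent: bool      # same chain and consecutive in sequence

    def positions(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.res_i[0], self.res_i[1]), (self.res_j[0], self.res_j[1]))


@dataclass
class TapProfile:
    id: str
    l_tot: int
    psh: float
    ppc: float
    pnc: float
    sfvcsp: float
    psh_components: list[PairComponent] = field(default_factory=list)
    ppc_components: list[PairComponent] = field(default_factory=list)
    pnc_components: list[PairComponent] = field(default_factory=list)
    cdr_lengths: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def metric(self, name: str) -> float:
        return {"l_tot": float(self.l_tot), "psh": self.psh, "ppc": self.ppc,
                "pnc": self.pnc, "sfvcsp": self.sfvcsp}[name]


METRICS = ("l_tot", "psh", "ppc", "pnc", "sfvcsp")


def _pair_distance(res_a: Residue, res_b: Residue, mode: str) -> float:
    if mode == "min_heavy":
        diff = res_a.coords()[:, None, :] - res_b.coords()[None, :, :]
        return float(np.sqrt((diff ** 2).sum(axis=2).min()))
    if mode == "cb":
        def anchor_atom(r: Residue):
            return r.get_atom("CB") or r.get_atom("CA")
        a, b = anchor_atom(res_a), anchor_atom(res_b)
        return float(np.linalg.norm(a.coord - b.coord))
    raise ValueError(f"unknown distance mode {mode!r}")


def patch_score(
    vicinity: CdrVicinity,
    exposure: dict[ResidueKey, bool],
    weights: Callable[[Residue], float],
    pair_cutoff: float = 7.5,
    exponent: int = 2,
    distance_mode: str = "min_heavy",
) -> tuple[float, list[PairComponent]]:
    """Pairwise patch kernel over exposed, positively weighted vicinity members.

    Returns the score and every contributing pair; an empty vicinity (or one
    with no eligible pair) yields (0.0, []).
    """
    eligible = [(r, weights(r)) for r in vicinity.members
                if exposure.get(r.key, False)]
    eligible = [(r, w) for r, w in eligible if w > 0]
    components: list[PairComponent] = []
    score = 0.0
    for (ra, wa), (rb, wb) in itertools.combinations(eligible, 2):
        d = _pair_distance(ra, rb, distance_mode)
        if d > pair_cutoff or d <= 0.0:
            continue
        contrib = wa * wb / d ** exponent
        score += contrib
        adjacent = ra.chain_id == rb.chain_id and abs(ra.seq_index - rb.seq_index) == 1
        components.append(PairComponent(
            res_i=ra.key, res_j=rb.key, aa_i=ra.aa, aa_j=rb.aa,
            seq_i=ra.seq_index, seq_j=rb.seq_index,
            distance=d, contribution=contrib, adjacent=adjacent,
        ))
    return score, components


def psh(vicinity: CdrVicinity, exposure: dict[ResidueKey, bool],
        scale: Optional[HydrophobicityScale] = None,
        config: Optional[RunConfig] = None) -> tuple[float, list[PairComponent]]:
    """Patches of Surface Hydrophobicity over the CDR vicinity."""
    config = config or RunConfig()
    scale = scale or HydrophobicityScale.kyte_doolittle(*config.hydrophobicity_norm)
    return patch_score(vicinity, exposure, lambda r: scale.normalized[r.aa],
                       pair_cutoff=config.pair_cutoff,
                       exponent=config.distance_exponent,
                       distance_mode=config.distance_mode)


def ppc(vicinity: CdrVicinity, exposure: dict[ResidueKey, bool],
        charges: Optional[ChargeAssignment] = None,
        config: Optional[RunConfig] = None) -> tuple[float, list[PairComponent]]:
    """Patches of Surface Positive Charge (weights |q| for q > 0)."""
    config = config or RunConfig()
    charges = charges or ChargeAssignment.default(config.his_charge)
    return patch_score(vicinity, exposure,
                       lambda r: max(charges.per_aa[r.aa], 0.0),
                       pair_cutoff=config.pair_cutoff,
                       exponent=config.distance_exponent,
                       distance_mode=config.distance_mode)


def pnc(vicinity: CdrVicinity, exposure: dict[ResidueKey, bool],
        charges: Optional[ChargeAssignment] = None,
        config: Optional[RunConfig] = None) -> tuple[float, list[PairComponent]]:
    """Patches of Surface Negative Charge (weights |q| for q < 0)."""
    config = config or RunConfig()
    charges = charges or ChargeAssignment.default(config.his_charge)
    return patch_score(vicinity, exposure,
                       lambda r: max(-charges.per_aa[r.aa], 0.0),
                       pair_cutoff=config.pair_cutoff,
                       exponent=config.distance_exponent,
                       distance_mode=config.distance_mode)


def sfvcsp(structure: FvStructure, exposure: dict[ResidueKey, bool],
           charges: Optional[ChargeAssignment] = None,
           scope: str = "domain",
           vicinity: Optional[CdrVicinity] = None) -> float:
    """Structural Fv charge symmetry: (net exposed VH charge) x (net exposed VL charge)."""
    charges = charges or ChargeAssignment.default()
    if scope == "domain":
        allowed = None
    elif scope == "vicinity":
        if vicinity is None:
            raise ValueError("vicinity scope requires a vicinity")
        allowed = vicinity.member_keys()
    else:
        raise ValueError(f"unknown sfvcsp scope {scope!r}")

    def net(chain: list[Residue]) -> float:
        total = 0.0
        for res in chain:
            if not exposure.get(res.key, False):
                continue
            if allowed is not None and res.key not in allowed:
                continue
            total += charges.per_aa[res.aa]
        return total

    return net(structure.heavy) * net(structure.light)


def compute_profile(
    structure: FvStructure,
    config: Optional[RunConfig] = None,
    max_sasa_table: Optional[MaxSasaTable] = None,
) -> TapProfile:
    """Full pipeline: SASA -> exposure -> regions -> vicinity -> five metrics."""
    config = config or RunConfig()
    sasa, exposure = run_sasa_pipeline(structure, config, max_sasa_table)
    regions = assign_regions(structure)
    anchors = build_anchor_set(structure, regions)
    vicinity = build_cdr_vicinity(structure, anchors, exposure,
                                  cutoff=config.vicinity_cutoff)
    scale = HydrophobicityScale.kyte_doolittle(*config.hydrophobicity_norm)
    charges = ChargeAssignment.default(config.his_charge)
    psh_score, psh_comp = psh(vicinity, exposure, scale, config)
    ppc_score, ppc_comp = ppc(vicinity, exposure, charges, config)
    pnc_score, pnc_comp = pnc(vicinity, exposure, charges, config)
    csp = sfvcsp(structure, exposure, charges,
                 scope=config.sfvcsp_scope, vicinity=vicinity)
    return TapProfile(
        id=structure.id,
        l_tot=total_cdr_length(structure, regions),
        psh=psh_score, ppc=ppc_score, pnc=pnc_score, sfvcsp=csp,
        psh_components=psh_comp, ppc_components=ppc_comp, pnc_components=pnc_comp,
        cdr_lengths=cdr_lengths(structure, regions),
        metadata={"light_locus": structure.light_locus, **structure.metadata},
    )


def _component_sort_key(c: PairComponent):
    return (-c.contribution, c.res_i[0], c.seq_i, c.res_j[0], c.seq_j)


def top_components(components: list[PairComponent], k: int = 20,
                   adjacency: Optional[str] = None) -> list[PairComponent]:
    """Largest-contribution components, optionally restricted by adjacency.

    adjacency: "adjacent", "non_adjacent" or None (all).  Ties are broken
    lexicographically on residue identity for reproducible reports.
    """
    if adjacency == "adjacent":
        pool = [c for c in components if c.adjacent]
    elif adjacency == "non_adjacent":
        pool = [c for c in components if not c.adjacent]
    elif adjacency is None:
        pool = list(components)
    else:
        raise ValueError(f"unknown adjacency class {adjacency!r}")
    return sorted(pool, key=_component_sort_key)[:k]


def position_contribution_table(
    profiles: list[TapProfile], k: int = 20,
    component_attr: str = "psh_components",
) -> dict[tuple[str, int], int]:
    """Aggregate (chain, IMGT position) counts over per-antibody top components.

    For each profile the top-k adjacent and top-k non-adjacent components
    are taken; both partners of every selected pair increment their
    position's count.
    """
    counts: dict[tuple[str, int], int] = {}
    for profile in profiles:
        components = getattr(profile, component_attr)
        selected = (top_components(components, k, "adjacent")
                    + top_components(components, k, "non_adjacent"))
        for comp in selected:
            for pos in comp.positions():
                counts[pos] = counts.get(pos, 0) + 1
    return counts
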