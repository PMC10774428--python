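"""Solvent-accessible surface area (Shrake–Rupley) and residue exposure.

SASA is computed by placing a deterministic golden-spiral lattice of test
points on each atom's probe-expanded sphere and counting the points not
occluded by any neighbouring expanded sphere:

    SASA_i = (accessible points / n_points) * 4 pi (r_vdw,i + r_probe)^2

A residue X is classified *exposed* when its SASA is at least a fixed
fraction (default 7.5 %, inclusive) of the theoretical maximum SASA of X,
defined as the residue SASA of X in an extended open-chain Ala-X-Ala
tripeptide computed with the same routine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .config import RunConfig
from .core_model import CANONICAL_AA, FvStructure, ResidueKey


@dataclass
class SasaResult:
    per_atom: dict[tuple[ResidueKey, str], float]   # (residue key, atom name) -> Å^2
    per_residue: dict[ResidueKey, float]            # residue key -> Å^2
    probe_radius: float
    n_sphere_points: int

    def total(self) -> float:
        return float(sum(self.per_residue.values()))


@dataclass
class MaxSasaTable:
    per_aa: dict[str, float]    # one-letter code -> Å^2
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.per_aa) != CANONICAL_AA:
            missing = CANONICAL_AA - set(self.per_aa)
            raise ValueError(f"max-SASA table must cover all 20 amino acids; missing {sorted(missing)}")
        if any(v <= 0 for v in self.per_aa.values()):
            raise ValueError("max-SASA values must be positive")


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (Fibonacci spiral)."""
    if n < 16:
        raise ValueError("need at least 16 sphere points")
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(
    structure: FvStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Per-atom and per-residue SASA of the whole (paired-chain) Fv.

    The neighbour search is pruned to atoms whose expanded spheres can
    intersect (centre distance below r_i + r_j + 2*probe).
    """
    atom_keys: list[tuple[ResidueKey, str]] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    res_of_atom: list[ResidueKey] = []
    for res in structure.residues():
        for atom in res.atoms:
            atom_keys.append((res.key, atom.name))
            coords.append(atom.coord)
            radii.append(atom.vdw_radius)
            res_of_atom.append(res.key)
    if not coords:
        raise ValueError("structure has no atoms")

    xyz = np.asarray(coords)
    expanded = np.asarray(radii) + probe_radius
    unit = golden_spiral_points(n_points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * expanded.max()
    pairs = tree.query_ball_point(xyz, r=max_reach)

    per_atom: dict[tuple[ResidueKey, str], float] = {}
    per_residue: dict[ResidueKey, float] = {}
    for i in range(len(xyz)):
        neigh = [j for j in pairs[i]
                 if j != i
                 and np.dot(xyz[j] - xyz[i], xyz[j] - xyz[i])
                 < (expanded[i] + expanded[j]) ** 2]
        pts = xyz[i] + expanded[i] * unit          # (n, 3)
        if neigh:
            nxyz = xyz[neigh]                      # (m, 3)
            nrad = expanded[neigh]                 # (m,)
            d2 = ((pts[:, None, :] - nxyz[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= (nrad ** 2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        area = float(frac * 4.0 * np.pi * expanded[i] ** 2)
        per_atom[atom_keys[i]] = area
        rk = res_of_atom[i]
        per_residue[rk] = per_residue.get(rk, 0.0) + area

    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      probe_radius=probe_radius, n_sphere_points=n_points)


# ---------------------------------------------------------------------------
# theoretical maximum SASA (open-chain Ala-X-Ala)

_TABLE_RESOURCE = "max_sasa.csv"


def build_max_sasa_table(
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> MaxSasaTable:
    """Recompute the maximum-SASA reference from extended Ala-X-Ala tripeptides.

    For each amino acid X an ideal-geometry extended tripeptide is generated
    and the central residue's SASA taken as the theoretical maximum.  The
    shipped table (``data/max_sasa.csv``) was produced by exactly this call;
    see ``scripts/regenerate_max_sasa.py``.
    """
    from .fixtures import make_tripeptide_host

    per_aa: dict[str, float] = {}
    for aa in sorted(CANONICAL_AA):
        tri = make_tripeptide_host(aa)
        sasa = shrake_rupley(tri, probe_radius=probe_radius, n_points=n_points)
        central = tri.heavy[1]
        per_aa[aa] = sasa.per_residue[central.key]
    return MaxSasaTable(
        per_aa=per_aa,
        provenance=(f"extended Ala-X-Ala (phi=-120, psi=+120), "
                    f"probe {probe_radius} Å, {n_points} points"),
    )


def load_max_sasa_table(path: Optional[str | Path] = None) -> MaxSasaTable:
    """Load the shipped (or a user-supplied) max-SASA table."""
    if path is None:
        ref = resources.files("tapkit").joinpath("data").joinpath(_TABLE_RESOURCE)
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    per_aa: dict[str, float] = {}
    provenance = ""
    for row in csv.reader(line for line in text.splitlines() if line.strip()):
        if row[0].startswith("#"):
            provenance = row[0].lstrip("# ")
            continue
        if row[0] == "aa":
            continue
        per_aa[row[0]] = float(row[1])
    return MaxSasaTable(per_aa=per_aa, provenance=provenance)


def save_max_sasa_table(table: MaxSasaTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {table.provenance}\n")
        fh.write("aa,max_sasa\n")
        for aa in sorted(table.per_aa):
            fh.write(f"{aa},{table.per_aa[aa]:.4f}\n")


def classify_exposure(
    structure: FvStructure,
    sasa: SasaResult,
    table: MaxSasaTable,
    fraction: float = 0.075,
) -> dict[ResidueKey, bool]:
    """Map residue key -> True (exposed) / False (buried); inclusive bound."""
    exposure: dict[ResidueKey, bool] = {}
    for res in structure.residues():
        if res.aa not in table.per_aa:
            raise KeyError(f"no max-SASA entry for {res.aa}")
        exposure[res.key] = sasa.per_residue[res.key] >= fraction * table.per_aa[res.aa]
    return exposure


def run_sasa_pipeline(
    structure: FvStructure, config: Optional[RunConfig] = None,
    table: Optional[MaxSasaTable] = None,
) -> tuple[SasaResult, dict[ResidueKey, bool]]:
    """Convenience: SASA on the paired Fv plus exposure calls."""
    config = config or RunConfig()
    table = table or load_max_sasa_table()
    sasa = shrake_rupley(structure, probe_radius=config.probe_radius,
                         n_points=config.n_sphere_points)
    exposure = classify_exposure(structure, sasa, table, fraction=config.exposure_fraction)
    return sasa, exposure
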