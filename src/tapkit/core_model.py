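"""Domain model and PDB I/O for IMGT-numbered antibody Fv structures.

An Fv is the paired variable domain (VH + VL) of an antibody.  Ingestion
normalises the structure for surface work: hydrogens, waters and hetero
records are dropped, one alternate-location conformer is kept, and van der
Waals radii are assigned per element.  When the B-factor column carries a
per-residue backbone predicted error (as in ABodyBuilder2 deposits), the
mean over the backbone atoms N/CA/C/O is stored as ``predicted_error``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

from .config import RunConfig

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_AA = set(ONE_TO_THREE)
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: residue identity within a structure: (chain_id, imgt_number, insertion_code)
ResidueKey = tuple[str, int, str]


class PdbIngestError(ValueError):
    """Raised when a PDB file cannot be interpreted as a clean Fv."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray          # shape (3,), Å
    vdw_radius: float          # Å
    bfactor: float = 0.0
    occupancy_rank: int = 0    # 0 for altloc '' or 'A'

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be a finite 3-vector")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")
        if self.element.upper() in ("H", "D"):
            raise ValueError("hydrogen atoms are not permitted after ingestion")


@dataclass
class Residue:
    chain_id: str              # "H" or "L"
    imgt_number: int
    insertion_code: str        # "" when absent
    aa: str                    # one-letter code, canonical 20
    seq_index: int             # 0-based position in chain order
    atoms: list[Atom] = field(default_factory=list)
    predicted_error: Optional[float] = None   # Å, backbone PE

    def __post_init__(self) -> None:
        if self.aa not in CANONICAL_AA:
            raise ValueError(f"non-canonical residue {self.aa!r}")
        if self.imgt_number <= 0:
            raise ValueError("imgt_number must be positive")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.imgt_number, self.insertion_code)

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates, shape (n_atoms, 3)."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class FvStructure:
    id: str
    heavy: list[Residue]
    light: list[Residue]
    light_locus: str = "unknown"            # kappa | lambda | unknown
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.heavy or not self.light:
            raise ValueError("both chains must be non-empty")
        for chain in (self.heavy, self.light):
            keys = [r.key for r in chain]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate residue identity in structure {self.id}")

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id == "H":
            return self.heavy
        if chain_id == "L":
            return self.light
        raise KeyError(f"unknown chain {chain_id!r}")

    def residues(self) -> Iterator[Residue]:
        yield from self.heavy
        yield from self.light

    def residue_by_key(self, key: ResidueKey) -> Residue:
        for r in self.chain(key[0]):
            if r.key == key:
                return r
        raise KeyError(key)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


def _vdw_radius(element: str, config: RunConfig) -> float:
    return config.vdw_radii.get(element.upper(), config.vdw_fallback)


def _keep_altloc(altloc: str) -> bool:
    return altloc in ("", "\x00", "A")


def read_fv_pdb(
    path: str | Path,
    chain_map: Optional[dict[str, str]] = None,
    config: Optional[RunConfig] = None,
    structure_id: Optional[str] = None,
) -> FvStructure:
    """Read an IMGT-numbered two-chain Fv from a PDB file.

    Parameters
    ----------
    path:
        PDB file with ATOM records for the heavy and light chains.
    chain_map:
        Maps file chain ids to "H"/"L"; defaults to the identity
        ``{"H": "H", "L": "L"}``.
    config:
        Controls vdW radii, the non-canonical-residue policy and whether
        B-factors are read as predicted error.

    Returns
    -------
    FvStructure with hydrogens, waters and hetero records removed and one
    altloc conformer per atom.
    """
    config = config or RunConfig()
    chain_map = chain_map or {"H": "H", "L": "L"}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise PdbIngestError(f"{path.name}: empty structure")
    model = st[0]

    chains: dict[str, list[Residue]] = {"H": [], "L": []}
    for file_id, fv_id in chain_map.items():
        chain = model.find_chain(file_id)
        if chain is None:
            raise PdbIngestError(f"{path.name}: chain not found: {file_id!r}")
        seq_index = 0
        for res in chain:
            if res.is_water() or res.het_flag != "A":
                continue
            aa = THREE_TO_ONE.get(res.name.upper())
            if aa is None:
                if config.noncanonical == "skip":
                    continue
                raise PdbIngestError(
                    f"{path.name}: non-canonical residue {res.name} "
                    f"{file_id}{res.seqid.num}"
                )
            atoms: list[Atom] = []
            seen_names: set[str] = set()
            for at in res:
                if at.element.name.upper() in ("H", "D"):
                    continue
                if not _keep_altloc(at.altloc):
                    continue
                if at.name in seen_names:
                    continue
                seen_names.add(at.name)
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name.upper(),
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw_radius=_vdw_radius(at.element.name, config),
                        bfactor=at.b_iso,
                    )
                )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residue = Residue(
                chain_id=fv_id,
                imgt_number=res.seqid.num,
                insertion_code=icode,
                aa=aa,
                seq_index=seq_index,
                atoms=atoms,
            )
            if config.read_predicted_error:
                bb = [residue.get_atom(n) for n in BACKBONE_ATOMS]
                if all(a is not None for a in bb):
                    residue.predicted_error = float(
                        np.mean([a.bfactor for a in bb])  # type: ignore[union-attr]
                    )
            chains[fv_id].append(residue)
            seq_index += 1

    if not chains["H"] and not chains["L"]:
        raise PdbIngestError(f"{path.name}: empty structure")
    for fv_id in ("H", "L"):
        if not chains[fv_id]:
            raise PdbIngestError(f"{path.name}: chain not found: no residues map to {fv_id}")

    return FvStructure(
        id=structure_id or path.stem,
        heavy=chains["H"],
        light=chains["L"],
    )


def write_fv_pdb(structure: FvStructure, path: str | Path) -> None:
    """Write the structure as standard PDB ATOM records (chains H and L).

    Coordinates are serialised at the PDB fixed precision (8.3), so a
    read/write round trip reproduces them to three decimals exactly.
    """
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain_id in ("H", "L"):
        chain = gemmi.Chain(chain_id)
        for res in structure.chain(chain_id):
            g_res = gemmi.Residue()
            g_res.name = ONE_TO_THREE[res.aa]
            g_res.seqid = gemmi.SeqId(res.imgt_number, res.insertion_code or " ")
            g_res.het_flag = "A"
            for atom in res.atoms:
                g_at = gemmi.Atom()
                g_at.name = atom.name
                g_at.element = gemmi.Element(atom.element)
                g_at.pos = gemmi.Position(*atom.coord)
                g_at.occ = 1.0
                g_at.b_iso = atom.bfactor
                g_res.add_atom(g_at)
            chain.add_residue(g_res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
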