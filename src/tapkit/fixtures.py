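"""Deterministic synthetic structures for testing and calibration.

Peptides are built with ideal backbone geometry (N–CA 1.46 Å, CA–C 1.52 Å,
C–N 1.33 Å, standard angles) at configurable φ/ψ, with simplified side
chains: heavy atoms laid out as an extended zig-zag from Cβ with correct
element types.  These are not physically realistic folds — they exist so
that surface, vicinity and patch-metric semantics can be exercised and
checked against brute-force oracles without any external download.

The Monte-Carlo SASA estimator here is an independent oracle: it shares no
code with :func:`tapkit.surface.shrake_rupley` (random sphere sampling and
an all-pairs occlusion scan instead of a spiral lattice and a k-d tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .config import RunConfig
from .core_model import Atom, FvStructure, Residue, ResidueKey

# heavy side-chain atoms beyond CB, in placement order: (name, element)
SIDE_CHAINS: dict[str, list[tuple[str, str]]] = {
    "G": [],
    "A": [],
    "S": [("OG", "O")],
    "C": [("SG", "S")],
    "T": [("OG1", "O"), ("CG2", "C")],
    "V": [("CG1", "C"), ("CG2", "C")],
    "P": [("CG", "C"), ("CD", "C")],
    "L": [("CG", "C"), ("CD1", "C"), ("CD2", "C")],
    "I": [("CG1", "C"), ("CG2", "C"), ("CD1", "C")],
    "M": [("CG", "C"), ("SD", "S"), ("CE", "C")],
    "D": [("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "N": [("CG", "C"), ("OD1", "O"), ("ND2", "N")],
    "E": [("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "Q": [("CG", "C"), ("CD", "C"), ("OE1", "O"), ("NE2", "N")],
    "K": [("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "R": [("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C"), ("NH1", "N"), ("NH2", "N")],
    "H": [("CG", "C"), ("ND1", "N"), ("CD2", "C"), ("CE1", "C"), ("NE2", "N")],
    "F": [("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("CE1", "C"), ("CE2", "C"), ("CZ", "C")],
    "Y": [("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("CE1", "C"), ("CE2", "C"), ("CZ", "C"), ("OH", "O")],
    "W": [("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("NE1", "N"), ("CE2", "C"),
          ("CE3", "C"), ("CZ2", "C"), ("CZ3", "C"), ("CH2", "C")],
}

_BOND = {"N-CA": 1.46, "CA-C": 1.52, "C-N": 1.33, "C-O": 1.23, "CA-CB": 1.53, "SC": 1.52}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural extension reference frame (NeRF) placement of atom d.

    Returns d such that |c-d| = bond, angle(b,c,d) = angle_deg and the
    dihedral a-b-c-d equals torsion_deg.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class PeptideFragment:
    """A single built chain; quacks enough like FvStructure for SASA."""
    id: str
    chain: list[Residue]

    @property
    def heavy(self) -> list[Residue]:
        return self.chain

    def residues(self) -> Iterator[Residue]:
        yield from self.chain

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.chain)


@dataclass
class FixtureSpec:
    """Recipe for a deterministic synthetic mini-Fv.

    CDR lengths drive the IMGT numbering plan; fr_lengths give the sizes of
    the four framework stretches flanking them.  ``seed`` fully determines
    the sequences (when not given explicitly) and any coordinate jitter.
    """
    heavy_seq: Optional[str] = None
    light_seq: Optional[str] = None
    heavy_cdr_lengths: tuple[int, int, int] = (8, 8, 10)
    light_cdr_lengths: tuple[int, int, int] = (6, 3, 9)
    fr_lengths: tuple[int, int, int, int] = (5, 6, 6, 4)
    phi: float = -120.0
    psi: float = 120.0
    seed: int = 0
    jitter: float = 0.0
    light_locus: str = "kappa"
    id: str = "mini_fv"
    metadata: dict = field(default_factory=dict)


def _vdw(element: str, config: RunConfig) -> float:
    return config.vdw_radii.get(element.upper(), config.vdw_fallback)


def make_peptide(
    sequence: str,
    chain_id: str = "H",
    numbering: Optional[Sequence[tuple[int, str]]] = None,
    phi: float = -120.0,
    psi: float = 120.0,
    seed: int = 0,
    jitter: float = 0.0,
    config: Optional[RunConfig] = None,
    structure_id: str = "peptide",
) -> PeptideFragment:
    """Ideal-geometry peptide with simplified side chains.

    numbering gives (imgt_number, insertion_code) per residue; default is
    sequential from 1.  jitter adds isotropic Gaussian noise (Å, seeded).
    """
    config = config or RunConfig()
    sequence = sequence.upper()
    bad = [aa for aa in sequence if aa not in SIDE_CHAINS]
    if bad:
        raise ValueError(f"invalid amino-acid letters: {bad}")
    n = len(sequence)
    if numbering is None:
        numbering = [(i + 1, "") for i in range(n)]
    if len(numbering) != n:
        raise ValueError("numbering length must match sequence length")

    # backbone trace
    coords_n = np.zeros((n, 3))
    coords_ca = np.zeros((n, 3))
    coords_c = np.zeros((n, 3))
    coords_n[0] = np.array([0.0, 0.0, 0.0])
    coords_ca[0] = np.array([_BOND["N-CA"], 0.0, 0.0])
    coords_c[0] = place_atom(np.array([0.0, 1.0, 0.0]), coords_n[0], coords_ca[0],
                             _BOND["CA-C"], 111.0, -60.0)
    for i in range(1, n):
        coords_n[i] = place_atom(coords_n[i - 1], coords_ca[i - 1], coords_c[i - 1],
                                 _BOND["C-N"], 116.0, psi)
        coords_ca[i] = place_atom(coords_ca[i - 1], coords_c[i - 1], coords_n[i],
                                  _BOND["N-CA"], 121.0, 180.0)   # omega trans
        coords_c[i] = place_atom(coords_c[i - 1], coords_n[i], coords_ca[i],
                                 _BOND["CA-C"], 111.0, phi)

    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    for i, aa in enumerate(sequence):
        atoms = [
            Atom("N", "N", coords_n[i].copy(), _vdw("N", config)),
            Atom("CA", "C", coords_ca[i].copy(), _vdw("C", config)),
            Atom("C", "C", coords_c[i].copy(), _vdw("C", config)),
        ]
        # carbonyl oxygen opposite the next amide nitrogen
        o = place_atom(coords_n[i], coords_ca[i], coords_c[i],
                       _BOND["C-O"], 121.0, psi + 180.0)
        atoms.append(Atom("O", "O", o, _vdw("O", config)))
        if aa != "G":
            cb = place_atom(coords_n[i], coords_c[i], coords_ca[i],
                            _BOND["CA-CB"], 110.5, 122.5)
            atoms.append(Atom("CB", "C", cb, _vdw("C", config)))
            prev3 = (coords_n[i], coords_ca[i], cb)
            for name, element in SIDE_CHAINS[aa]:
                pos = place_atom(*prev3, _BOND["SC"], 114.0, 180.0)
                atoms.append(Atom(name, element, pos, _vdw(element, config)))
                prev3 = (prev3[1], prev3[2], pos)
        num, icode = numbering[i]
        residues.append(Residue(chain_id=chain_id, imgt_number=num,
                                insertion_code=icode, aa=aa, seq_index=i,
                                atoms=atoms))
    if jitter > 0:
        for res in residues:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(0.0, jitter, size=3)
    return PeptideFragment(id=structure_id, chain=residues)


def make_tripeptide_host(aa: str, probe_config: Optional[RunConfig] = None) -> PeptideFragment:
    """Extended Ala-X-Ala host used for the theoretical maximum SASA of X."""
    return make_peptide("A" + aa + "A", structure_id=f"AXA_{aa}", config=probe_config)


# ---------------------------------------------------------------------------
# IMGT numbering plans

_CDR_RANGES = {1: (27, 38), 2: (56, 65), 3: (105, 117)}


def imgt_numbering_plan(
    cdr_lengths: tuple[int, int, int],
    fr_lengths: tuple[int, int, int, int] = (5, 6, 6, 4),
) -> tuple[list[tuple[int, str]], list[str]]:
    """IMGT numbers + regions for a chain with designed CDR lengths.

    CDR1/CDR2 must fit their ranges; CDR3 longer than 13 residues gains
    insertion codes at position 111 (111A, 111B, ...), as IMGT does.
    Returns (numbering, region labels) aligned to chain order.
    """
    l1, l2, l3 = cdr_lengths
    f1, f2, f3, f4 = fr_lengths
    if not (1 <= l1 <= 12):
        raise ValueError("CDR1 length must be 1..12 (IMGT 27-38)")
    if not (1 <= l2 <= 10):
        raise ValueError("CDR2 length must be 1..10 (IMGT 56-65)")
    if l3 < 1:
        raise ValueError("CDR3 length must be >= 1")
    if f1 > 26 or f3 > 10:
        raise ValueError("framework stretch too long for the numbering plan")

    numbering: list[tuple[int, str]] = []
    regions: list[str] = []

    def extend(nums: list[tuple[int, str]], label: str) -> None:
        numbering.extend(nums)
        regions.extend([label] * len(nums))

    extend([(n, "") for n in range(27 - f1, 27)], "FR")
    extend([(n, "") for n in range(27, 27 + l1)], "CDR1")
    extend([(n, "") for n in range(39, 39 + f2)], "FR")
    extend([(n, "") for n in range(56, 56 + l2)], "CDR2")
    extend([(n, "") for n in range(95, 95 + f3)], "FR")
    if l3 <= 13:
        extend([(n, "") for n in range(105, 105 + l3)], "CDR3")
    else:
        extra = l3 - 13
        extend([(n, "") for n in range(105, 112)], "CDR3")
        extend([(111, chr(ord("A") + k)) for k in range(extra)], "CDR3")
        extend([(n, "") for n in range(112, 118)], "CDR3")
    extend([(n, "") for n in range(118, 118 + f4)], "FR")
    return numbering, regions


_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA_ALPHABET), size=n))


def make_mini_fv(spec: FixtureSpec, config: Optional[RunConfig] = None) -> FvStructure:
    """Two-chain synthetic Fv with valid IMGT numbering.

    The light chain is rotated 180° about x and offset in z so the two
    extended chains run antiparallel with side chains in contact range,
    giving the CDR vicinity genuine cross-chain members.
    """
    config = config or RunConfig()
    h_numbering, _ = imgt_numbering_plan(spec.heavy_cdr_lengths, spec.fr_lengths)
    l_numbering, _ = imgt_numbering_plan(spec.light_cdr_lengths, spec.fr_lengths)
    rng = np.random.default_rng(spec.seed)
    heavy_seq = spec.heavy_seq or _random_sequence(len(h_numbering), rng)
    light_seq = spec.light_seq or _random_sequence(len(l_numbering), rng)
    if len(heavy_seq) != len(h_numbering) or len(light_seq) != len(l_numbering):
        raise ValueError("sequence length does not match the numbering plan")

    heavy = make_peptide(heavy_seq, chain_id="H", numbering=h_numbering,
                         phi=spec.phi, psi=spec.psi, config=config,
                         seed=spec.seed, jitter=spec.jitter,
                         structure_id=spec.id).chain
    light = make_peptide(light_seq, chain_id="L", numbering=l_numbering,
                         phi=spec.phi, psi=spec.psi, config=config,
                         seed=spec.seed + 1, jitter=spec.jitter,
                         structure_id=spec.id).chain

    # antiparallel placement of the light chain
    rot = np.diag([1.0, -1.0, -1.0])
    shift = np.array([0.0, 0.0, 4.2])   # inside the 4.5 Å vicinity shell, no clashes
    for res in light:
        for atom in res.atoms:
            atom.coord = rot @ atom.coord + shift

    return FvStructure(id=spec.id, heavy=heavy, light=light,
                       light_locus=spec.light_locus,
                       metadata=dict(spec.metadata))


# ---------------------------------------------------------------------------
# Monte-Carlo SASA oracle

def mc_sasa_oracle(
    structure,
    probe: float = 1.4,
    n_samples: int = 20000,
    seed: int = 0,
) -> dict[tuple[ResidueKey, str], tuple[float, float]]:
    """Monte-Carlo per-atom SASA estimate with its standard error.

    Uniform random points on each probe-expanded sphere are tested against
    every other expanded sphere by brute force.  Returns
    (residue key, atom name) -> (SASA estimate Å², standard error Å²).
    """
    if n_samples < 10_000:
        raise ValueError("need at least 1e4 samples per atom")
    rng = np.random.default_rng(seed)
    keys: list[tuple[ResidueKey, str]] = []
    coords: list[np.ndarray] = []
    radii: list[float] = []
    for res in structure.residues():
        for atom in res.atoms:
            keys.append((res.key, atom.name))
            coords.append(atom.coord)
            radii.append(atom.vdw_radius)
    xyz = np.asarray(coords)
    expanded = np.asarray(radii) + probe

    out: dict[tuple[ResidueKey, str], tuple[float, float]] = {}
    for i in range(len(xyz)):
        dirs = rng.normal(size=(n_samples, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = xyz[i] + expanded[i] * dirs
        occluded = np.zeros(n_samples, dtype=bool)
        for j in range(len(xyz)):
            if j == i:
                continue
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            occluded |= d2 < expanded[j] ** 2
        p = 1.0 - occluded.mean()
        area = 4.0 * np.pi * expanded[i] ** 2
        est = p * area
        se = area * np.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
        out[keys[i]] = (float(est), float(se))
    return out
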