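"""Run configuration: every numeric constant of the profiling protocol in one place.

The defaults mirror the published protocol: a 1.4 Å solvent probe, the 7.5 %
maximum-SASA exposure rule, a 4.5 Å CDR-vicinity shell, and a pairwise patch
kernel w_i*w_j/d^2 with a 7.5 Å pair cutoff.  All of them can be overridden
from a YAML file so that threshold calibration never requires a code change.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: van der Waals radii (Å) used for SASA; keyed by element symbol.
DEFAULT_VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW_FALLBACK: float = 1.70


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters for one profiling run.

    Attributes
    ----------
    probe_radius:
        Solvent probe radius in Å (water ~ 1.4 Å).
    n_sphere_points:
        Test points per atom for the Shrake–Rupley quadrature.
    exposure_fraction:
        A residue is surface exposed when SASA >= this fraction of its
        theoretical maximum (open-chain Ala-X-Ala value); inclusive bound.
    vicinity_cutoff:
        Å; exposed residues within this distance of a CDR anchor join the
        CDR vicinity.
    pair_cutoff:
        Å; residue pairs farther apart contribute nothing to patch scores.
    distance_exponent:
        Exponent of the 1/d term in the patch kernel.
    distance_mode:
        "min_heavy" (minimum over heavy-atom pairs) or "cb" (Cβ–Cβ, Cα
        for glycine).
    hydrophobicity_norm:
        (low, high) target range of the affine-rescaled Kyte–Doolittle scale;
        strictly positive so pair contributions stay non-negative.
    his_charge:
        Fractional formal charge assigned to histidine.
    sfvcsp_scope:
        "domain" sums charges over all exposed residues of each chain;
        "vicinity" restricts to CDR-vicinity members.
    percentile_method:
        numpy.percentile interpolation method for threshold fitting.
    sd_ddof:
        Delta degrees of freedom for cohort standard deviations (1 = sample).
    noncanonical:
        "error" or "skip" for non-canonical residues during PDB ingestion.
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    exposure_fraction: float = 0.075
    vicinity_cutoff: float = 4.5
    pair_cutoff: float = 7.5
    distance_exponent: int = 2
    distance_mode: str = "min_heavy"
    hydrophobicity_norm: tuple[float, float] = (1.0, 2.0)
    his_charge: float = 0.1
    sfvcsp_scope: str = "domain"
    percentile_method: str = "linear"
    sd_ddof: int = 1
    noncanonical: str = "error"
    read_predicted_error: bool = True
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    vdw_fallback: float = DEFAULT_VDW_FALLBACK

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["hydrophobicity_norm"] = list(self.hydrophobicity_norm)
        return d

    def config_hash(self) -> str:
        """Short stable digest of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "hydrophobicity_norm" in raw:
            raw = dict(raw)
            raw["hydrophobicity_norm"] = tuple(raw["hydrophobicity_norm"])
        return cls(**raw)
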