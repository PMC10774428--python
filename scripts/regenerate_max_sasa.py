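#!/usr/bin/env python
"""Regenerate the shipped theoretical maximum SASA table.

For every amino acid X, builds an extended (phi=-120, psi=+120)
ideal-geometry Ala-X-Ala tripeptide and records the SASA of the central
residue computed with the package's own Shrake-Rupley routine (1.4 Å
probe, 960 lattice points).  Writes src/tapkit/data/max_sasa.csv.
"""

from pathlib import Path

from tapkit.surface import build_max_sasa_table, save_max_sasa_table


def main() -> None:
    table = build_max_sasa_table(probe_radius=1.4, n_points=960)
    out = Path(__file__).resolve().parents[1] / "src" / "tapkit" / "data" / "max_sasa.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    save_max_sasa_table(table, out)
    print(f"wrote {out} ({len(table.per_aa)} entries)")


if __name__ == "__main__":
    main()
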