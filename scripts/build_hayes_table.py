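"""Regenerate the bundled finite-layer flat-punch correction table.

Writes ``src/cartispec/data/hayes_kappa.csv`` by solving the bonded-layer
contact problem (see ``cartispec._hayes``) on a grid of aspect ratios
a/h in [0, 2] and Poisson's ratios nu in [0, 0.5].  Run from the
repository root:

    python scripts/build_hayes_table.py
"""

from pathlib import Path

import numpy as np

from cartispec._hayes import build_table


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src" / "cartispec" / "data" / "hayes_kappa.csv"
    rows = build_table()
    header = "a_over_h,nu,kappa"
    np.savetxt(out, rows, delimiter=",", header=header, comments="", fmt=["%.4f", "%.3f", "%.10f"])
    print(f"wrote {out} ({rows.shape[0]} rows)")


if __name__ == "__main__":
    main()
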