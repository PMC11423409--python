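#!/usr/bin/env python
"""Generate the umbrella-sampling window set on the reference landscape.

Nine overdamped-Langevin windows (bias centers 0.30-0.62 nm, k = 5000
kJ/mol/nm^2, 2e5 production steps each, seed 42) on the three-mode
Ca2+-sulfur landscape.  Windows and a YAML manifest go to
scratch/windows/.
"""

from pathlib import Path

import glycopair as gp
from glycopair import io as gio

OUT = Path(__file__).resolve().parents[1] / "scratch" / "windows"
CENTERS = [round(0.30 + 0.04 * i, 2) for i in range(9)]
SEED = 42


def main() -> None:
    potential = gp.make_reference_potential("aimd_like")
    ex = potential.mode_extrema()
    print("reference landscape (analytic, relative to SSP):")
    u_ssp = ex["ssp"][1]
    for mode in ("bdp", "mdp", "barrier"):
        r, u = ex[mode]
        print(f"  {mode}: r = {r:.4f} nm, dU = {u - u_ssp:+.2f} kJ/mol")

    cfg = gp.LangevinConfig(n_steps=200_000, seed=SEED)
    windows = gp.generate_window_set(potential, CENTERS, 5000.0, cfg)
    manifest = gio.write_window_set(OUT, windows)
    for w in windows:
        print(
            f"  window r0={w.r0:.2f} nm: {w.n_samples} samples, "
            f"mean r = {w.samples.mean():.4f} nm"
        )
    print(f"wrote manifest {manifest}")


if __name__ == "__main__":
    main()
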