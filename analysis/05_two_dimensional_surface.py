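#!/usr/bin/env python
"""Two-dimensional free-energy surface for concurrent Ca2+ binding.

Surrogate for the adaptive-biasing analysis of a cation engaging two
sulfated molecules at once: a 5x5 grid of 2D umbrella windows over two
independent Ca2+-S distances on a single-well landscape, solved with 2D
WHAM, corrected by the sum of the two 1D volume-entropy terms, and
shifted to zero at the largest distances.  Writes results/surface2d.tsv.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np

import glycopair as gp
from glycopair import io as gio
from glycopair.synthetic import simulate_window_2d

ROOT = Path(__file__).resolve().parents[1] / "results"
CENTERS = [0.30, 0.38, 0.46, 0.54, 0.62]
K = 1500.0
SEED = 42


def main() -> None:
    pot = gp.make_reference_potential("single_well")
    thermo = gp.ThermoState(300.0)
    cfg = gp.LangevinConfig(n_steps=30_000, n_equil=5000, seed=SEED)
    windows = []
    for i, c1 in enumerate(CENTERS):
        for j, c2 in enumerate(CENTERS):
            wcfg = replace(cfg, seed=(SEED + 7919 * (5 * i + j + 1)) % 2**31)
            windows.append(simulate_window_2d(pot, pot, (c1, c2), (K, K), wcfg))
    edges = np.arange(0.26, 0.70 + 1e-12, 0.01)
    surface, solution = gp.solve_wham_2d(windows, (edges, edges), thermo)
    surface = gp.volume_entropy_correction_2d(surface, thermo)
    surface = gp.align_surface_tail(surface)
    gio.write_surface_tsv(ROOT / "surface2d.tsv", surface)

    occ = surface.occupied
    imin = np.unravel_index(np.nanargmin(np.where(occ, surface.G, np.inf)), surface.G.shape)
    print(
        f"2D WHAM {'converged' if solution.converged else 'NOT CONVERGED'}; "
        f"global minimum {np.nanmin(surface.G[occ]):.2f} kJ/mol at "
        f"(r1, r2) = ({surface.x_centers[imin[0]]:.2f}, "
        f"{surface.y_centers[imin[1]]:.2f}) nm"
    )
    print("the combined bound state sits at symmetric distances, as expected "
          "for a separable landscape")
    print(f"wrote {ROOT}/surface2d.tsv")


if __name__ == "__main__":
    main()
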