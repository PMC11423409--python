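"""Ion-pairing binding modes: BDP / MDP / SSP identification and energetics.

Calcium pairs with a sulfamate/sulfate group in three modes told apart
by how many anion oxygens (O_S) sit inside the cation's first solvation
shell: bidentate (BDP, >= 2 oxygens, ~0.32 nm Ca-S), monodentate (MDP,
1 oxygen, ~0.37 nm), and solvent-shared (SSP, 0 oxygens, hydration
shells intact, ~0.5-0.6 nm).  The first shell boundary is the first
minimum of the Ca-water RDF, 0.335 nm.

This module extracts mode positions, free-energy differences and the
MDP->SSP barrier from a free-energy profile, and classifies frames by
direct shell counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import FrameSet, minimum_image_distance
from .wham import FreeEnergyProfile

__all__ = [
    "ShellConfig",
    "ModeEnergetics",
    "DEFAULT_MODE_WINDOWS",
    "locate_mode_extrema",
    "count_shell_oxygens",
    "classify_frame_mode",
    "mode_fractions_along_windows",
]

#: Default search windows (nm) around the approximate mode positions.
DEFAULT_MODE_WINDOWS: dict[str, tuple[float, float]] = {
    "bdp": (0.28, 0.35),
    "mdp": (0.35, 0.45),
    "ssp": (0.45, 0.65),
}


@dataclass(frozen=True)
class ShellConfig:
    """First-solvation-shell definition for shell-occupancy counting."""

    first_shell_cutoff: float = 0.335  # nm; first min of the Ca-water RDF
    target_species: str = "O_S"
    center_species: str = "Ca"

    def __post_init__(self) -> None:
        if self.first_shell_cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class ModeEnergetics:
    """Mode minima positions, free-energy differences vs SSP, and barrier."""

    r_bdp: float | None
    r_mdp: float | None
    r_ssp: float | None
    dG_bdp_ssp: float | None
    dG_mdp_ssp: float | None
    barrier_mdp_ssp: float | None
    found: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if all(self.found.get(m) for m in ("bdp", "mdp", "ssp")):
            if not (self.r_bdp < self.r_mdp < self.r_ssp):
                raise ValueError("mode positions must be ordered r_bdp < r_mdp < r_ssp")


def _window_argmin(
    profile: FreeEnergyProfile, lo: float, hi: float
) -> tuple[float, float, bool]:
    """Bin-level argmin of G in [lo, hi]; found only if it is a genuine
    local minimum (not pinned to the window edge by a monotone profile)."""
    mask = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.occupied
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return math.nan, math.nan, False
    sub = profile.G[idx]
    j = int(np.argmin(sub))
    i = idx[j]
    r_min, g_min = float(profile.bin_centers[i]), float(profile.G[i])
    # a genuine local minimum must be bracketed by occupied bins on both
    # sides; a dip at the very edge of the sampled profile is not trusted
    have_left = i > 0 and np.isfinite(profile.G[i - 1])
    have_right = i + 1 < profile.G.size and np.isfinite(profile.G[i + 1])
    left = profile.G[i - 1] if have_left else np.inf
    right = profile.G[i + 1] if have_right else np.inf
    is_local = have_left and have_right and g_min <= left and g_min <= right
    # reject argmin pinned to a window edge with the profile still falling
    if j == 0 and np.isfinite(left) and left < g_min:
        is_local = False
    if j == sub.size - 1 and np.isfinite(right) and right < g_min:
        is_local = False
    return r_min, g_min, bool(is_local)


def locate_mode_extrema(
    profile: FreeEnergyProfile,
    windows: dict[str, tuple[float, float]] | None = None,
) -> ModeEnergetics:
    """Locate BDP/MDP/SSP minima and the MDP->SSP barrier on a profile.

    Bin-level extremum search with no smoothing (reproducibility over
    aesthetics).  A window whose argmin is not a local minimum (monotone
    stretch) is reported as not found.
    """
    wins = dict(DEFAULT_MODE_WINDOWS if windows is None else windows)
    order = sorted(wins, key=lambda m: wins[m][0])
    expected = ["bdp", "mdp", "ssp"]
    if sorted(wins) != sorted(expected):
        raise ValueError(f"windows must be exactly {expected}")
    bounds = [wins[m] for m in ("bdp", "mdp", "ssp")]
    for (lo, hi) in bounds:
        if lo >= hi:
            raise ValueError("each window must satisfy lo < hi")
    for (a_lo, a_hi), (b_lo, b_hi) in zip(bounds, bounds[1:]):
        if a_hi > b_lo:
            raise ValueError("mode windows must be sorted and non-overlapping")

    results = {m: _window_argmin(profile, *wins[m]) for m in expected}
    found = {m: results[m][2] for m in expected}

    r = {m: (results[m][0] if found[m] else None) for m in expected}
    g = {m: (results[m][1] if found[m] else None) for m in expected}

    dg_bdp = dg_mdp = barrier = None
    if found["ssp"]:
        if found["bdp"]:
            dg_bdp = g["bdp"] - g["ssp"]
        if found["mdp"]:
            dg_mdp = g["mdp"] - g["ssp"]
            mask = (
                (profile.bin_centers >= r["mdp"])
                & (profile.bin_centers <= r["ssp"])
                & profile.occupied
            )
            barrier = float(np.max(profile.G[mask]) - g["ssp"])
    return ModeEnergetics(
        r_bdp=r["bdp"],
        r_mdp=r["mdp"],
        r_ssp=r["ssp"],
        dG_bdp_ssp=dg_bdp,
        dG_mdp_ssp=dg_mdp,
        barrier_mdp_ssp=barrier,
        found=found,
    )


def count_shell_oxygens(
    frames: FrameSet, shell: ShellConfig, frame_index: int | None = None
) -> np.ndarray:
    """Number of target-species particles within the first shell of the
    (unique) center particle, minimum-image distances, per frame."""
    center_mask = frames.select(shell.center_species)
    if center_mask.sum() != 1:
        raise ValueError(
            f"expected exactly one {shell.center_species!r} center, "
            f"found {int(center_mask.sum())}"
        )
    target_mask = frames.select(shell.target_species)
    indices = list(range(frames.n_frames)) if frame_index is None else [frame_index]
    counts = np.empty(len(indices), dtype=int)
    for out_i, fi in enumerate(indices):
        center = frames.coords[fi][center_mask]
        targets = frames.coords[fi][target_mask]
        if targets.size == 0:
            counts[out_i] = 0
            continue
        d = minimum_image_distance(center, targets, frames.box)[0]
        counts[out_i] = int(np.sum(d < shell.first_shell_cutoff))
    return counts


def classify_frame_mode(count: int) -> str:
    """Map a shell oxygen count to a binding-mode label (2+ -> BDP,
    1 -> MDP, 0 -> SSP)."""
    if count < 0:
        raise ValueError("shell count cannot be negative")
    if count >= 2:
        return "BDP"
    if count == 1:
        return "MDP"
    return "SSP"


def mode_fractions_along_windows(
    framesets: dict[float, FrameSet],
    shell: ShellConfig,
    total_species: tuple[str, ...] = ("O_S", "O_W"),
) -> pd.DataFrame:
    """Per-window shell statistics along the umbrella ladder.

    For each window center: the mean fraction of O_S atoms inside the
    first shell, the mean O_S shell count, the mean total shell occupancy
    over ``total_species`` (water oxygens substitute for anion oxygens,
    so this total stays roughly constant), and the BDP/MDP/SSP frame
    fractions.
    """
    if not framesets:
        raise ValueError("framesets must be nonempty")
    rows = []
    for center in sorted(framesets):
        fs = framesets[center]
        if fs.n_frames == 0:
            raise ValueError(f"window at {center} nm has no frames")
        counts = count_shell_oxygens(fs, shell)
        n_os = int(fs.select(shell.target_species).sum())
        total = np.zeros(fs.n_frames)
        for sp in total_species:
            sp_shell = ShellConfig(
                first_shell_cutoff=shell.first_shell_cutoff,
                target_species=sp,
                center_species=shell.center_species,
            )
            total = total + count_shell_oxygens(fs, sp_shell)
        modes = np.array([classify_frame_mode(c) for c in counts])
        rows.append(
            {
                "window_center_nm": center,
                "os_fraction_in_shell": counts.mean() / n_os if n_os else 0.0,
                "os_shell_count": counts.mean(),
                "total_shell_occupancy": total.mean(),
                "frac_bdp": float(np.mean(modes == "BDP")),
                "frac_mdp": float(np.mean(modes == "MDP")),
                "frac_ssp": float(np.mean(modes == "SSP")),
            }
        )
    return pd.DataFrame(rows)
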