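"""Weighted histogram analysis method (WHAM) for umbrella sampling.

Umbrella sampling probes a reaction coordinate r (here the Ca2+-sulfur
distance) with a ladder of harmonic biases w_i(r) = k_i/2 (r - r0_i)^2.
WHAM recombines the biased histograms h_i(b) into one unbiased
probability P(b) by iterating the self-consistent equations

    P(b)            = sum_i h_i(b) / sum_i N_i exp(-beta (w_i(b) - F_i))
    exp(-beta F_i)  = sum_b P(b) exp(-beta w_i(b))

to a fixed point, after which G(b) = -kT ln P(b).  Because the
collective variable is a 3D distance, the raw profile carries a radial
Jacobian r^2; the volume-entropy correction +2 kT ln r removes it.
Profiles are aligned either to zero at the solvent-shared minimum
(for mode comparisons) or to zero at large distances (for absolute
binding energies).  Errors come from contiguous-segment splitting or
from within-window bootstrap resampling.

Bins that collect no samples are reported as NaN, never as silent
zeros.  Energies are kJ/mol, distances nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .constants import ThermoState

__all__ = [
    "UmbrellaWindow",
    "UmbrellaWindow2D",
    "FreeEnergyProfile",
    "Surface2D",
    "WHAMSolution",
    "WHAMConvergenceWarning",
    "solve_wham_1d",
    "solve_wham_2d",
    "volume_entropy_correction",
    "volume_entropy_correction_2d",
    "align_profile",
    "align_surface_tail",
    "segment_error",
    "bootstrap_error",
]

Alignment = Literal["none", "ssp_minimum", "large_distance"]

#: Default search range (nm) for the solvent-shared minimum, covering the
#: 5.0-6.0 Angstrom basin with margin for robustness.
SSP_SEARCH_RANGE = (0.45, 0.65)


class WHAMConvergenceWarning(UserWarning):
    """Issued when the WHAM iteration hits max_iter before the tolerance."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased sampling window: harmonic bias at r0 with force constant k.

    ``samples`` is the recorded distance series in nm; ``k`` is in
    kJ/mol/nm^2.
    """

    r0: float
    k: float
    samples: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("samples must be a nonempty 1D series")
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("samples must be finite and positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    def bias(self, r: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(r) - self.r0) ** 2


@dataclass(frozen=True)
class UmbrellaWindow2D:
    """Biased window over two distance coordinates with separable biases."""

    r0: tuple[float, float]
    k: tuple[float, float]
    samples: np.ndarray  # (n, 2)
    temperature: float = 300.0

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] == 0:
            raise ValueError("samples must be a nonempty (n, 2) array")
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("samples must be finite and positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    def bias(self, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
        return 0.5 * self.k[0] * (np.asarray(r1) - self.r0[0]) ** 2 + 0.5 * self.k[
            1
        ] * (np.asarray(r2) - self.r0[1]) ** 2


@dataclass(frozen=True)
class WHAMSolution:
    """Convergence metadata; window offsets are relative to the first window."""

    window_offsets: np.ndarray
    iterations: int
    final_change: float
    converged: bool


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Binned free energy G(r) with occupancy mask via NaN."""

    bin_centers: np.ndarray
    G: np.ndarray
    err: np.ndarray | None = None
    entropy_corrected: bool = False
    alignment: Alignment = "none"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))
        if self.bin_centers.shape != self.G.shape:
            raise ValueError("bin_centers and G must have the same shape")

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.G)


@dataclass(frozen=True)
class Surface2D:
    """Binned 2D free energy G(r1, r2)."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    G: np.ndarray
    entropy_corrected: bool = False
    alignment: str = "none"
    metadata: dict = field(default_factory=dict)

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.G)

    def transpose(self) -> "Surface2D":
        return Surface2D(
            x_centers=self.y_centers,
            y_centers=self.x_centers,
            G=self.G.T,
            entropy_corrected=self.entropy_corrected,
            alignment=self.alignment,
            metadata=dict(self.metadata),
        )


# --------------------------------------------------------------------------
# core fixed-point iteration (shared by 1D and 2D)

def _wham_fixed_point(
    hist: np.ndarray,  # (n_win, n_bins) counts
    bias: np.ndarray,  # (n_win, n_bins) bias energies at bin centers
    beta: float,
    tolerance: float,
    max_iter: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, WHAMSolution]:
    """Return (P over bins with NaN on empty bins, occupied mask, solution)."""
    n_win, n_bins = hist.shape
    counts_total = hist.sum(axis=0)
    occupied = counts_total > 0
    n_i = hist.sum(axis=1)

    expw = np.exp(-beta * bias)  # (n_win, n_bins)
    f = np.zeros(n_win) if f_init is None else np.array(f_init, dtype=float)
    change = np.inf
    it = 0
    kT = 1.0 / beta
    for it in range(1, max_iter + 1):
        weight = n_i * np.exp(beta * f)  # (n_win,)
        denom = weight @ expw  # (n_bins,)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied, counts_total / denom, 0.0)
        p_sum = p.sum()
        p /= p_sum
        z = expw @ p  # (n_win,)
        f_new = -kT * np.log(z)
        f_new -= f_new[0]
        change = float(np.max(np.abs(f_new - f)))
        f = f_new
        if change < tolerance:
            break
    converged = change < tolerance
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last change {change:.3e} kJ/mol)",
            WHAMConvergenceWarning,
            stacklevel=3,
        )
    p_out = np.where(occupied, p, np.nan)
    solution = WHAMSolution(
        window_offsets=f, iterations=it, final_change=change, converged=converged
    )
    return p_out, occupied, solution


def _shared_temperature(windows: Sequence, thermo: ThermoState | None) -> ThermoState:
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"windows at different temperatures: {sorted(temps)}")
    if thermo is None:
        return ThermoState(temperature=temps.pop())
    if temps and abs(thermo.temperature - temps.pop()) > 1e-9:
        raise ValueError("thermo temperature disagrees with window temperature")
    return thermo


# --------------------------------------------------------------------------
# 1D

def solve_wham_1d(
    windows: Sequence[UmbrellaWindow],
    bin_edges: np.ndarray,
    thermo: ThermoState | None = None,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[FreeEnergyProfile, WHAMSolution]:
    """Reconstruct G(r) from umbrella windows on a shared bin grid.

    Samples outside the grid are counted and reported in the profile
    metadata rather than silently dropped.  Unoccupied bins are NaN.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    thermo = _shared_temperature(windows, thermo)
    bin_edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    n_bins = centers.size

    hist = np.empty((len(windows), n_bins))
    n_out = 0
    for i, w in enumerate(windows):
        h, _ = np.histogram(w.samples, bins=bin_edges)
        hist[i] = h
        n_out += w.n_samples - int(h.sum())
    bias = np.stack([w.bias(centers) for w in windows])

    p, occupied, solution = _wham_fixed_point(
        hist, bias, thermo.beta, tolerance, max_iter
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        g = -thermo.kT * np.log(p)
    profile = FreeEnergyProfile(
        bin_centers=centers,
        G=g,
        metadata={
            "temperature_K": thermo.temperature,
            "n_windows": len(windows),
            "n_out_of_range": n_out,
            "converged": solution.converged,
            "iterations": solution.iterations,
            "final_change_kJ_per_mol": solution.final_change,
            "bin_width_nm": float(np.mean(np.diff(bin_edges))),
        },
    )
    return profile, solution


def volume_entropy_correction(
    profile: FreeEnergyProfile, thermo: ThermoState
) -> FreeEnergyProfile:
    """Add the +2 kT ln r volume-entropy term, removing the radial Jacobian."""
    if profile.entropy_corrected:
        raise ValueError("profile is already entropy-corrected")
    g = profile.G + 2.0 * thermo.kT * np.log(profile.bin_centers)
    return replace(profile, G=g, entropy_corrected=True)


def align_profile(
    profile: FreeEnergyProfile,
    convention: Alignment,
    ssp_search_range: tuple[float, float] = SSP_SEARCH_RANGE,
    n_tail: int = 3,
) -> FreeEnergyProfile:
    """Shift the profile to zero per the chosen convention.

    ``ssp_minimum`` zeroes the minimum within the solvent-shared search
    range; ``large_distance`` zeroes the mean of the last ``n_tail``
    occupied bins (where the cation no longer interacts).
    """
    if convention == "ssp_minimum":
        lo, hi = ssp_search_range
        mask = (
            (profile.bin_centers >= lo)
            & (profile.bin_centers <= hi)
            & profile.occupied
        )
        if not mask.any():
            raise ValueError(
                f"no occupied bin in the SSP search range [{lo}, {hi}] nm"
            )
        shift = np.nanmin(profile.G[mask])
    elif convention == "large_distance":
        occ_idx = np.flatnonzero(profile.occupied)
        if occ_idx.size == 0:
            raise ValueError("profile has no occupied bins")
        tail = occ_idx[-n_tail:]
        shift = float(np.mean(profile.G[tail]))
    else:
        raise ValueError(f"unknown alignment convention {convention!r}")
    return replace(profile, G=profile.G - shift, alignment=convention)


# --------------------------------------------------------------------------
# error estimation

def _profile_from_windows(
    windows: Sequence[UmbrellaWindow],
    bin_edges: np.ndarray,
    thermo: ThermoState,
    tolerance: float,
    max_iter: int,
    entropy_correction: bool,
    align: Alignment | None,
    ssp_search_range: tuple[float, float],
    n_tail: int,
) -> FreeEnergyProfile:
    prof, _ = solve_wham_1d(windows, bin_edges, thermo, tolerance, max_iter)
    if entropy_correction:
        prof = volume_entropy_correction(prof, thermo)
    if align is not None and align != "none":
        prof = align_profile(prof, align, ssp_search_range, n_tail)
    return prof


def _nan_std(stack: np.ndarray) -> np.ndarray:
    """Per-bin std over replicate profiles; NaN where < 2 replicates cover."""
    covered = np.isfinite(stack).sum(axis=0)
    out = np.full(stack.shape[1], np.nan)
    ok = covered >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out[ok] = np.nanstd(stack[:, ok], axis=0, ddof=1)
    return out


def segment_error(
    windows: Sequence[UmbrellaWindow],
    bin_edges: np.ndarray,
    thermo: ThermoState | None = None,
    n_segments: int = 5,
    entropy_correction: bool = True,
    align: Alignment = "ssp_minimum",
    ssp_search_range: tuple[float, float] = SSP_SEARCH_RANGE,
    n_tail: int = 3,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Per-bin standard deviation of G over contiguous equal-length segments.

    Each window's series is cut into ``n_segments`` contiguous blocks;
    a full WHAM profile (corrected and aligned as requested) is built per
    block index, and the per-bin std across those profiles is returned.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be at least 2")
    thermo = _shared_temperature(windows, thermo)
    profiles = []
    for s in range(n_segments):
        seg_windows = []
        for w in windows:
            blocks = np.array_split(w.samples, n_segments)
            seg_windows.append(replace(w, samples=blocks[s]))
        profiles.append(
            _profile_from_windows(
                seg_windows, bin_edges, thermo, tolerance, max_iter,
                entropy_correction, align, ssp_search_range, n_tail,
            )
        )
    return _nan_std(np.stack([p.G for p in profiles]))


def bootstrap_error(
    windows: Sequence[UmbrellaWindow],
    bin_edges: np.ndarray,
    thermo: ThermoState | None = None,
    n_boot: int = 100,
    seed: int = 0,
    entropy_correction: bool = True,
    align: Alignment = "ssp_minimum",
    ssp_search_range: tuple[float, float] = SSP_SEARCH_RANGE,
    n_tail: int = 3,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Per-bin standard deviation of G over bootstrap replicates.

    Within-window resampling with replacement (same length per window);
    a full WHAM profile is built per replicate.  Seeded and reproducible.
    """
    thermo = _shared_temperature(windows, thermo)
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_boot):
        boot_windows = [
            replace(w, samples=rng.choice(w.samples, size=w.n_samples, replace=True))
            for w in windows
        ]
        profiles.append(
            _profile_from_windows(
                boot_windows, bin_edges, thermo, tolerance, max_iter,
                entropy_correction, align, ssp_search_range, n_tail,
            )
        )
    return _nan_std(np.stack([p.G for p in profiles]))


# --------------------------------------------------------------------------
# 2D

def solve_wham_2d(
    windows: Sequence[UmbrellaWindow2D],
    bin_edges_pair: tuple[np.ndarray, np.ndarray],
    thermo: ThermoState | None = None,
    tolerance: float = 1e-7,
    max_iter: int = 100_000,
) -> tuple[Surface2D, WHAMSolution]:
    """Reconstruct G(r1, r2) from 2D umbrella windows with separable biases."""
    if len(windows) == 0:
        raise ValueError("need at least one window")
    thermo = _shared_temperature(windows, thermo)
    ex = np.asarray(bin_edges_pair[0], dtype=float)
    ey = np.asarray(bin_edges_pair[1], dtype=float)
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    nx, ny = cx.size, cy.size

    hist = np.empty((len(windows), nx * ny))
    n_out = 0
    for i, w in enumerate(windows):
        h, _, _ = np.histogram2d(w.samples[:, 0], w.samples[:, 1], bins=(ex, ey))
        hist[i] = h.ravel()
        n_out += w.n_samples - int(h.sum())
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    bias = np.stack([w.bias(gx, gy).ravel() for w in windows])

    p, occupied, solution = _wham_fixed_point(
        hist, bias, thermo.beta, tolerance, max_iter
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (-thermo.kT * np.log(p)).reshape(nx, ny)
    surface = Surface2D(
        x_centers=cx,
        y_centers=cy,
        G=g,
        metadata={
            "temperature_K": thermo.temperature,
            "n_windows": len(windows),
            "n_out_of_range": n_out,
            "converged": solution.converged,
            "iterations": solution.iterations,
        },
    )
    return surface, solution


def volume_entropy_correction_2d(surface: Surface2D, thermo: ThermoState) -> Surface2D:
    """Sum of the two independent 1D volume-entropy corrections."""
    if surface.entropy_corrected:
        raise ValueError("surface is already entropy-corrected")
    corr = 2.0 * thermo.kT * (
        np.log(surface.x_centers)[:, None] + np.log(surface.y_centers)[None, :]
    )
    return replace(surface, G=surface.G + corr, entropy_corrected=True)


def align_surface_tail(surface: Surface2D, n_tail: int = 3) -> Surface2D:
    """Zero the surface at the largest-distance corner (no interaction)."""
    occ = surface.occupied
    if not occ.any():
        raise ValueError("no occupied bins in the surface")
    # occupied cells farthest out in r1 + r2 (the sampled grid may stop
    # short of the nominal corner)
    ii, jj = np.nonzero(occ)
    reach = surface.x_centers[ii] + surface.y_centers[jj]
    order = np.argsort(-reach)[: n_tail * n_tail]
    shift = float(np.mean(surface.G[ii[order], jj[order]]))
    return replace(surface, G=surface.G - shift, alignment="large_distance")
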