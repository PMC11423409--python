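"""Solution-structure observables: RDFs, coordination numbers, clusters.

All pair distances honor the minimum-image convention in an orthorhombic
periodic box.  The RDF normalization uses exact spherical-shell volumes
(4 pi / 3)(r+^3 - r-^3), so an ideal gas gives g = 1 bin by bin.  The
largest-cluster-size distribution mirrors the aggregation analysis of
sulfated disaccharide solutions: molecules are in contact when any
inter-molecule particle pair is closer than the contact cutoff (0.35 nm,
i.e. 3.5 Angstrom, by default), and cluster sizes are connected-component
sizes of the resulting contact graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .frames import FrameSet, minimum_image_distance

__all__ = [
    "RDFResult",
    "ClusterDistribution",
    "compute_rdf",
    "coordination_number",
    "cluster_size_distribution",
]


@dataclass(frozen=True)
class RDFResult:
    """Radial distribution function g(r) with its normalization context."""

    bin_centers: np.ndarray
    g: np.ndarray
    pair: tuple[str, str]
    target_density: float  # nm^-3, density of species b used in normalization
    bin_edges: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) cannot be negative")


@dataclass(frozen=True)
class ClusterDistribution:
    """Probability distribution of the largest cluster size over frames."""

    sizes: np.ndarray  # 1..n_molecules
    probabilities: np.ndarray
    contact_cutoff: float

    def __post_init__(self) -> None:
        total = self.probabilities.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {total}")

    def probability_of(self, size: int) -> float:
        idx = np.flatnonzero(self.sizes == size)
        return float(self.probabilities[idx[0]]) if idx.size else 0.0

    @property
    def mean_size(self) -> float:
        return float(np.sum(self.sizes * self.probabilities))


def compute_rdf(
    frames: FrameSet,
    sel_a: str,
    sel_b: str,
    bin_width: float = 0.002,
    r_max: float | None = None,
) -> RDFResult:
    """RDF of species b around species a with minimum-image distances.

    ``r_max`` defaults to min(box)/2 and may not exceed it (beyond that
    the minimum-image shell volume is no longer spherical).  For a
    same-species RDF the self pair is excluded and the target density is
    (N-1)/V, keeping the ideal-gas baseline at exactly 1.
    """
    half_box = float(frames.box.min()) / 2.0
    if r_max is None:
        r_max = half_box
    if r_max > half_box + 1e-12:
        raise ValueError(
            f"r_max={r_max} nm exceeds half the smallest box edge ({half_box} nm)"
        )
    mask_a = frames.select(sel_a)
    mask_b = frames.select(sel_b)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"empty selection: {sel_a!r} has {n_a}, {sel_b!r} has {n_b}")
    same = sel_a == sel_b
    if same and n_b < 2:
        raise ValueError("same-species RDF needs at least two particles")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(edges.size - 1)
    for fi in range(frames.n_frames):
        a = frames.coords[fi][mask_a]
        b = frames.coords[fi][mask_b]
        d = minimum_image_distance(a, b, frames.box)
        if same:
            iu = np.triu_indices(n_a, k=1)
            dvals = d[iu]
            h, _ = np.histogram(dvals, bins=edges)
            counts += 2 * h  # count ordered pairs for the standard normalization
        else:
            h, _ = np.histogram(d.ravel(), bins=edges)
            counts += h

    volume = frames.volume
    rho_b = ((n_b - 1) if same else n_b) / volume
    shell = (4.0 * np.pi / 3.0) * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = frames.n_frames * n_a * rho_b * shell
    g = counts / norm
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(
        bin_centers=centers,
        g=g,
        pair=(sel_a, sel_b),
        target_density=rho_b,
        bin_edges=edges,
    )


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """Running coordination number 4 pi rho int_0^{r_cut} g r^2 dr
    (trapezoid on the RDF grid)."""
    if r_cut <= 0 or r_cut > rdf.bin_centers[-1] + 1e-12:
        raise ValueError(
            f"r_cut={r_cut} nm outside the RDF grid "
            f"(0, {rdf.bin_centers[-1]:.4f}] nm"
        )
    mask = rdf.bin_centers <= r_cut
    # close the integral at 0 and at r_cut (interpolated) so no partial
    # shell is dropped
    r = np.concatenate([[0.0], rdf.bin_centers[mask], [r_cut]])
    g_cut = float(np.interp(r_cut, rdf.bin_centers, rdf.g))
    gvals = np.concatenate([[rdf.g[0]], rdf.g[mask], [g_cut]])
    integrand = gvals * r**2
    return float(4.0 * np.pi * rdf.target_density * np.trapezoid(integrand, r))


def cluster_size_distribution(
    frames: FrameSet,
    contact_cutoff: float = 0.35,
    exclude_species: tuple[str, ...] = ("Ca",),
    species_subset: tuple[str, ...] | None = None,
) -> ClusterDistribution:
    """Distribution of the largest molecular cluster size over frames.

    Two molecules are in contact when any pair of their particles is
    within ``contact_cutoff`` (minimum image).  Cations listed in
    ``exclude_species`` do not contribute to connectivity (the cluster
    is defined over saccharide-saccharide contacts); pass an empty tuple
    for a bridging-inclusive analysis.  ``species_subset`` restricts the
    contact search to given particle species (e.g. heavy atoms only).
    """
    keep = np.array(
        [
            s not in exclude_species
            and (species_subset is None or s in species_subset)
            for s in frames.species
        ],
        dtype=bool,
    )
    sub = frames.subset(keep)
    mol_ids = np.unique(sub.mol_ids)
    n_mol = mol_ids.size
    if n_mol == 0:
        raise ValueError("no molecules left after species filtering")
    if n_mol == 1:
        warnings.warn("single molecule: degenerate distribution {1: 1.0}", UserWarning)
        return ClusterDistribution(
            sizes=np.array([1]), probabilities=np.array([1.0]),
            contact_cutoff=contact_cutoff,
        )
    mol_index = {m: i for i, m in enumerate(mol_ids)}
    per_particle = np.array([mol_index[m] for m in sub.mol_ids])

    largest = np.empty(frames.n_frames, dtype=int)
    for fi in range(frames.n_frames):
        pos = sub.coords[fi]
        d = minimum_image_distance(pos, pos, sub.box)
        contact = d < contact_cutoff
        ii, jj = np.nonzero(contact)
        different = per_particle[ii] != per_particle[jj]
        rows = per_particle[ii[different]]
        cols = per_particle[jj[different]]
        adj = coo_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n_mol, n_mol)
        )
        n_comp, labels = connected_components(adj, directed=False)
        largest[fi] = int(np.bincount(labels).max()) if n_mol else 0

    sizes = np.arange(1, n_mol + 1)
    probs = np.array(
        [(largest == s).mean() for s in sizes], dtype=float
    )
    return ClusterDistribution(
        sizes=sizes, probabilities=probs, contact_cutoff=contact_cutoff
    )
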