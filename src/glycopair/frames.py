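"""Particle-frame container with an orthorhombic periodic box.

A :class:`FrameSet` holds a fixed set of particles (species label and
molecule id per particle) over one or more frames, mirroring what a
GRO/XYZ trajectory of a small solution box would provide.  All
coordinates are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSet", "minimum_image_displacement", "minimum_image_distance"]


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances between point sets a (n,3) and b (m,3)."""
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image_displacement(d, box)
    return np.sqrt((d * d).sum(axis=-1))


@dataclass(frozen=True)
class FrameSet:
    """Trajectory frames with constant topology.

    Attributes
    ----------
    coords
        Array (n_frames, n_particles, 3), nm.
    species
        Label per particle, e.g. ``Ca``, ``O_S``, ``O_W``, ``H_w``.
    mol_ids
        Integer molecule id per particle.
    box
        Orthorhombic box edge lengths (3,), nm.
    """

    coords: np.ndarray
    species: tuple[str, ...]
    mol_ids: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        box = np.asarray(self.box, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "mol_ids", np.asarray(self.mol_ids, dtype=int))
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_particles, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if box.shape != (3,) or np.any(box <= 0):
            raise ValueError("box must be three positive edge lengths")
        n = coords.shape[1]
        if len(self.species) != n or self.mol_ids.shape != (n,):
            raise ValueError("species/mol_ids length must match particle count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @classmethod
    def from_mdanalysis(cls, universe, species_attr: str = "names") -> "FrameSet":
        """Build a FrameSet from an MDAnalysis Universe (optional dependency).

        Coordinates are converted from Angstrom to nm; species labels come
        from the atom attribute named by ``species_attr`` and molecule ids
        from residue indices.  Requires an orthorhombic box.
        """
        ts_coords = []
        box = None
        for ts in universe.trajectory:
            if box is None:
                dims = ts.dimensions
                if dims is None or not np.allclose(dims[3:6], 90.0):
                    raise ValueError("only orthorhombic boxes are supported")
                box = np.asarray(dims[:3], dtype=float) / 10.0
            ts_coords.append(universe.atoms.positions / 10.0)
        species = tuple(str(s) for s in getattr(universe.atoms, species_attr))
        return cls(
            coords=np.stack(ts_coords),
            species=species,
            mol_ids=universe.atoms.resindices.copy(),
            box=box,
        )

    def select(self, species: str) -> np.ndarray:
        """Boolean mask of particles with the given species label."""
        return np.array([s == species for s in self.species], dtype=bool)

    def subset(self, mask: np.ndarray) -> "FrameSet":
        """New FrameSet restricted to particles where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return FrameSet(
            coords=self.coords[:, mask, :],
            species=tuple(s for s, m in zip(self.species, mask) if m),
            mol_ids=self.mol_ids[mask],
            box=self.box,
        )
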