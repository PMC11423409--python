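"""Text I/O: window series, manifests, frames, and result tables.

Window series are two-column text files (time ps, distance nm) in the
style of GROMACS pull-coordinate output, tied together by a YAML
manifest recording (r0, k, T, seed) per file.  Frames are written as
XYZ-with-box text: the XYZ comment line carries ``box = bx by bz nm``
and each atom line is ``species mol_id x y z`` (nm).  Distances tagged
``angstrom`` in manifests are converted on read.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import nm_from
from .frames import FrameSet
from .wham import FreeEnergyProfile, Surface2D, UmbrellaWindow

__all__ = [
    "write_window",
    "read_window_series",
    "write_window_set",
    "read_window_set",
    "write_frames",
    "read_frames",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_surface_tsv",
]


def write_window(path: str | Path, window: UmbrellaWindow, timestep_ps: float = 1.0) -> None:
    """Write one window as two-column text (time ps, distance nm)."""
    t = np.arange(window.n_samples) * timestep_ps
    np.savetxt(
        path,
        np.column_stack([t, window.samples]),
        header="time_ps distance_nm",
        fmt="%.6f %.8f",
    )


def read_window_series(path: str | Path, unit: str = "nm") -> np.ndarray:
    """Read the distance column of a two-column series file."""
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, distance)")
    r = data[:, 1]
    return np.array([nm_from(v, unit) for v in r])


def write_window_set(
    directory: str | Path,
    windows: Sequence[UmbrellaWindow],
    seeds: Sequence[int] | None = None,
) -> Path:
    """Write windows plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.xvg"
        write_window(directory / fname, w)
        entry = {
            "file": fname,
            "r0": float(w.r0),
            "k": float(w.k),
            "temperature": float(w.temperature),
            "n_samples": int(w.n_samples),
            "unit": "nm",
        }
        if seeds is not None:
            entry["seed"] = int(seeds[i])
        entries.append(entry)
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"windows": entries}, fh, sort_keys=False)
    return manifest


def read_window_set(manifest_path: str | Path) -> list[UmbrellaWindow]:
    """Load windows described by a YAML manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    windows = []
    for entry in manifest["windows"]:
        unit = entry.get("unit", "nm")
        samples = read_window_series(manifest_path.parent / entry["file"], unit=unit)
        windows.append(
            UmbrellaWindow(
                r0=nm_from(entry["r0"], unit),
                k=float(entry["k"]),
                samples=samples,
                temperature=float(entry.get("temperature", 300.0)),
            )
        )
    return windows


def write_frames(path: str | Path, frames: FrameSet) -> None:
    """Write a FrameSet as XYZ-with-box text."""
    with open(path, "w") as fh:
        for fi in range(frames.n_frames):
            fh.write(f"{frames.n_particles}\n")
            bx, by, bz = frames.box
            fh.write(f"box = {bx:.6f} {by:.6f} {bz:.6f} nm\n")
            for s, m, (x, y, z) in zip(
                frames.species, frames.mol_ids, frames.coords[fi]
            ):
                fh.write(f"{s} {m} {x:.6f} {y:.6f} {z:.6f}\n")


def read_frames(path: str | Path) -> FrameSet:
    """Read XYZ-with-box text back into a FrameSet."""
    coords_all: list[np.ndarray] = []
    species: list[str] = []
    mol_ids: list[int] = []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        header = lines[i + 1].split()
        if len(header) < 5 or header[0] != "box":
            raise ValueError(f"{path}: malformed box line {lines[i + 1]!r}")
        box = np.array([float(v) for v in header[2:5]])
        frame = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if first:
                species.append(parts[0])
                mol_ids.append(int(parts[1]))
            frame[j] = [float(v) for v in parts[2:5]]
        coords_all.append(frame)
        first = False
        i += 2 + n
    if box is None:
        raise ValueError(f"{path}: no frames found")
    return FrameSet(
        coords=np.stack(coords_all),
        species=tuple(species),
        mol_ids=np.array(mol_ids),
        box=box,
    )


def write_profile_tsv(path: str | Path, profile: FreeEnergyProfile) -> None:
    """Profile as TSV (bin_center_nm, G_kJ_per_mol[, err]) plus YAML sidecar."""
    df = pd.DataFrame(
        {"bin_center_nm": profile.bin_centers, "G_kJ_per_mol": profile.G}
    )
    if profile.err is not None:
        df["err_kJ_per_mol"] = profile.err
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = dict(profile.metadata)
    meta["entropy_corrected"] = bool(profile.entropy_corrected)
    meta["alignment"] = profile.alignment
    with open(str(path) + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_profile_tsv(path: str | Path) -> FreeEnergyProfile:
    df = pd.read_csv(path, sep="\t")
    err = df["err_kJ_per_mol"].to_numpy() if "err_kJ_per_mol" in df else None
    meta_path = str(path) + ".yaml"
    entropy_corrected = False
    alignment = "none"
    metadata: dict = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            metadata = yaml.safe_load(fh) or {}
        entropy_corrected = bool(metadata.pop("entropy_corrected", False))
        alignment = metadata.pop("alignment", "none")
    return FreeEnergyProfile(
        bin_centers=df["bin_center_nm"].to_numpy(),
        G=df["G_kJ_per_mol"].to_numpy(),
        err=err,
        entropy_corrected=entropy_corrected,
        alignment=alignment,
        metadata=metadata,
    )


def write_surface_tsv(path: str | Path, surface: Surface2D) -> None:
    """Long-format TSV (r1_nm, r2_nm, G_kJ_per_mol) for a 2D surface."""
    gx, gy = np.meshgrid(surface.x_centers, surface.y_centers, indexing="ij")
    df = pd.DataFrame(
        {
            "r1_nm": gx.ravel(),
            "r2_nm": gy.ravel(),
            "G_kJ_per_mol": surface.G.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
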