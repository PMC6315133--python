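"""A minimal 3-D statistic-volume container with plain-text persistence.

Volumes hold voxel grids of t statistics, p values or contrast values on an
isotropic lattice.  Coordinates follow the convention: voxel indices are
0-based and the mm coordinate of voxel (i, j, k) is origin + index *
voxel_size.  Persistence is deliberately plain text — a whitespace-separated
flat array plus a small JSON sidecar header (dims, voxel size, origin) — so
runs remain inspectable without neuroimaging tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["StatVolume", "save_volume", "load_volume"]


@dataclass
class StatVolume:
    """A 3-D grid of statistics (t, p or contrast values)."""

    data: np.ndarray
    voxel_size: float = 2.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "stat"  # "t", "p", "r", "contrast", ...

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a 3-D grid with all dims >= 1")
        if self.kind == "p":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValueError("p-volumes must lie in [0, 1]")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "StatVolume") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.origin, other.origin)
        )

    def index_to_mm(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * self.voxel_size

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center mm coordinates."""
        grids = np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij")
        idx = np.stack(grids, axis=-1).astype(float)
        return np.asarray(self.origin) + idx * self.voxel_size


def save_volume(vol: StatVolume, path) -> None:
    """Write a volume as a flat text array with a JSON sidecar header."""
    path = Path(path)
    np.savetxt(path, vol.data.ravel()[None, :], fmt="%.10g")
    sidecar = {
        "shape": list(vol.shape),
        "voxel_size": vol.voxel_size,
        "origin": list(vol.origin),
        "kind": vol.kind,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_volume(path) -> StatVolume:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    flat = np.loadtxt(path)
    data = np.asarray(flat, dtype=float).reshape(sidecar["shape"])
    return StatVolume(
        data,
        voxel_size=sidecar["voxel_size"],
        origin=tuple(sidecar["origin"]),
        kind=sidecar.get("kind", "stat"),
    )
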