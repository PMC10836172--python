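"""Bi-hemispheric spherical parcel atlas.

Each hemisphere lives on its own unit sphere (the convention of
surface-based neuroimaging, where left and right cortices are registered to
separate spheres).  A parcel is represented by its spherical centroid, a
hemisphere label, and one or more per-parcel gradient values.  Right-
hemisphere centroids mirror the left (x -> -x), so homotopic parcels have
"folded" coordinates that coincide, which is what the spatial covariance
kernels and the mirrored spin rotations rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ParcelAtlas"]

_REQUIRED = ("parcel_id", "hemisphere", "x", "y", "z", "gradient")


@dataclass
class ParcelAtlas:
    """Parcel table: id, hemisphere ('L'/'R'), unit-sphere centroid, gradient."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        norms = np.linalg.norm(self.table[["x", "y", "z"]].to_numpy(float), axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-6)
        if bad.size:
            raise ValueError(f"non-unit centroid at atlas row {bad[0]} (norm={norms[bad[0]]:.6f})")
        if not set(self.table["hemisphere"]) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")
        if self.table["parcel_id"].duplicated().any():
            raise ValueError("duplicate parcel ids")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def gradient(self) -> np.ndarray:
        return self.table["gradient"].to_numpy(float)

    def centroids(self, hemi: str | None = None) -> np.ndarray:
        t = self.table if hemi is None else self.table[self.table["hemisphere"] == hemi]
        return t[["x", "y", "z"]].to_numpy(float)

    def hemi_index(self, hemi: str) -> np.ndarray:
        """Row positions of the given hemisphere's parcels."""
        return np.flatnonzero((self.table["hemisphere"] == hemi).to_numpy())

    def folded_centroids(self) -> np.ndarray:
        """Centroids with right-hemisphere x mirrored onto the left sphere.

        Homotopic parcels coincide in this representation; spatial kernels
        computed on folded coordinates produce approximately bilaterally
        symmetric fields.
        """
        xyz = self.centroids().copy()
        right = self.hemispheres == "R"
        xyz[right, 0] *= -1.0
        return xyz

    def hemi_sign(self) -> np.ndarray:
        """Centred hemisphere coding: L -> -0.5, R -> +0.5."""
        return np.where(self.hemispheres == "R", 0.5, -0.5)
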