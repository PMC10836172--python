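"""Spin-permutation null for parcellated brain maps.

Spatial-autocorrelation-preserving permutations of a parcel map: each
permutation applies one uniformly random 3-D rotation to the left
hemisphere's spherical centroids and its x-mirror conjugate to the right
hemisphere's, then reassigns parcels by one-to-one nearest-neighbour
matching within hemisphere.  Because the assignment is a bijection, every
permuted map has exactly the original per-hemisphere value multiset, which
makes the null exchangeable.  Observed statistics are converted to
permutation p-values with the standard +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .atlas import ParcelAtlas

__all__ = [
    "SpinSet",
    "generate_spins",
    "spin_pvalue",
    "p_floor",
    "format_spin_p",
    "random_rotation",
    "match_rotation",
]

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # x-flip between hemispheres


@dataclass
class SpinSet:
    """Bijective within-hemisphere parcel permutations from mirrored rotations."""

    perms: np.ndarray  # (n_perm, n_parcels) int; permuted[i] = values[perms[k, i]]
    seed: int
    quaternions: np.ndarray  # (n_perm, 4), generating rotations
    n_parcels: int

    @property
    def n_perm(self) -> int:
        return self.perms.shape[0]

    def apply(self, values: np.ndarray, k: int) -> np.ndarray:
        return np.asarray(values)[self.perms[k]]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix drawn uniformly from SO(3) via a normalised quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return _quat_to_mat(q), q


def _quat_to_mat(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _greedy_match(orig: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """One-to-one nearest-neighbour assignment, greedy over globally sorted pairs.

    Returns `assign` with assign[target] = source: the parcel whose rotated
    centroid lands nearest the target's original location, subject to each
    source being used once.  Unlike independent nearest-neighbour matching,
    this is a bijection, so permuted maps keep the original value multiset.
    """
    n = len(orig)
    dist = 1.0 - orig @ rotated.T  # monotone in chordal distance
    order = np.argsort(dist, axis=None)
    targets, sources = np.unravel_index(order, (n, n))
    assign = np.full(n, -1, dtype=int)
    src_used = np.zeros(n, dtype=bool)
    remaining = n
    for t, s in zip(targets, sources):
        if assign[t] < 0 and not src_used[s]:
            assign[t] = s
            src_used[s] = True
            remaining -= 1
            if remaining == 0:
                break
    return assign


def match_rotation(atlas: ParcelAtlas, rotation: np.ndarray) -> np.ndarray:
    """Within-hemisphere bijection induced by one rotation (mirrored on the right)."""
    perm = np.empty(atlas.n_parcels, dtype=int)
    for hemi, rot in (("L", rotation), ("R", _MIRROR @ rotation @ _MIRROR)):
        idx = atlas.hemi_index(hemi)
        cent = atlas.centroids(hemi)
        assign = _greedy_match(cent, cent @ rot.T)
        perm[idx] = idx[assign]
    return perm


def generate_spins(atlas: ParcelAtlas, n_perm: int, seed: int) -> SpinSet:
    """Seed-deterministic set of spin permutations for one atlas.

    One SpinSet is generated per atlas and shared across all parameters,
    windows and contrasts, mirroring a single set of permuted gradient maps.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = substream(seed, "spin")
    perms = np.empty((n_perm, atlas.n_parcels), dtype=int)
    quats = np.empty((n_perm, 4))
    for k in range(n_perm):
        rot, q = random_rotation(rng)
        perms[k] = match_rotation(atlas, rot)
        quats[k] = q
    return SpinSet(perms=perms, seed=seed, quaternions=quats, n_parcels=atlas.n_parcels)


# ---------------------------------------------------------------------------
# permutation p-values


def spin_pvalue(stat_obs: float, stat_null: np.ndarray, sided: str = "two") -> float:
    """Permutation p-value with the +1 correction.

    two-sided: p = min(1, 2 * min(r+ + 1, r- + 1) / (n + 1)) where
    r+ = #{null >= obs}, r- = #{null <= obs}; one-sided: (r+ + 1) / (n + 1).
    """
    null = np.asarray(stat_null, float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if not np.isfinite(stat_obs):
        raise ValueError("observed statistic is not finite")
    null = null[np.isfinite(null)]
    n = null.size
    r_plus = int((null >= stat_obs).sum())
    if sided == "one":
        return (r_plus + 1) / (n + 1)
    if sided == "two":
        r_minus = int((null <= stat_obs).sum())
        return min(1.0, 2.0 * min(r_plus + 1, r_minus + 1) / (n + 1))
    raise ValueError(f"unknown sidedness {sided!r}")


def p_floor(n_perm: int, sided: str = "two") -> float:
    """Smallest attainable p for the given permutation count."""
    return (2.0 if sided == "two" else 1.0) / (n_perm + 1)


def format_spin_p(p: float, n_perm: int, sided: str = "two") -> str:
    """Render a spin p-value, using the '< floor' convention at the floor."""
    floor = p_floor(n_perm, sided)
    if p <= floor:
        return f"< {floor:.2g}".replace("0.", ".")
    return f"{p:.2g}".replace("0.", ".")
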