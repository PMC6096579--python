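"""Eroded-volume-fraction (EVF) radial analysis.

The EVF of a point inside a nucleus is the fraction of nuclear volume lying
between that point and the nuclear membrane: 0 at the periphery, 1 at the
centre.  Its key property is shape universality — for points uniformly
distributed in the nucleus the EVF is uniform on [0, 1] whatever the nuclear
shape — which makes the radial position of a signal directly comparable
across nuclei.

On a voxel grid we realise the EVF as the (mid-)rank of the voxel's depth
(anisotropic Euclidean distance to the background) among all mask voxels,
divided by the mask voxel count.  The nucleus is then divided into ``F``
fractions of identical volume ordered periphery -> centre, the per-fraction
signal proportions give a cumulative radial distribution, and the deviation
from uniformity is summarised by ``d_max``: the signed difference of largest
magnitude between that cumulative curve and the uniform diagonal.  Positive
d_max means a peripheral bias, negative a central one, |d_max| <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .image import ImageStack

__all__ = [
    "EVFMap",
    "RadialProfile",
    "evf_map",
    "equal_volume_fractions",
    "radial_profile",
    "dmax",
    "spot_evf",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class EVFMap:
    """EVF values over a nuclear mask.

    ``values`` is a full-grid float array, NaN outside the mask; ``mask``
    is the boolean nucleus mask; ``depth`` the distance-to-background map
    the ranks were computed from.
    """

    values: np.ndarray
    mask: np.ndarray
    depth: np.ndarray
    spacing: tuple[float, float, float]
    convention: str = "midrank"
    nucleus_id: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RadialProfile:
    """Radial signal distribution over equal-volume fractions.

    ``p[k]`` is the proportion of total nuclear signal in fraction ``k+1``
    (fraction 1 at the periphery, fraction F at the centre); ``cumulative``
    its running sum.  The uniform reference for fraction k is k/F.
    """

    p: np.ndarray
    mode: str
    spacing: tuple[float, float, float]
    nucleus_id: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        total = self.p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"fraction proportions must sum to 1, got {total}")

    @property
    def F(self) -> int:
        return self.p.size

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.p)

    @property
    def d_max(self) -> float:
        return dmax(self)


def evf_map(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    convention: str = "midrank",
    nucleus_id: int = 0,
) -> EVFMap:
    """Compute the EVF of every voxel of a single-component nuclear mask.

    Depth is the Euclidean distance to the background computed with the
    physical voxel spacing (anisotropy-aware).  EVF(x) is the fraction of
    mask voxels strictly shallower than x plus, under the default mid-rank
    convention, half the voxels at equal depth:

        EVF(x) = (#{y : d(y) < d(x)} + 0.5 * #{y : d(y) = d(x)}) / N

    On a discrete grid the raw EDT is heavily tied (every voxel whose
    nearest background lies across a face shares the same depth; the
    largest plateau holds several percent of the nucleus), which alone
    breaks the uniform-points property at the 0.03-KS level.  Depth ties
    are therefore sub-ranked by a secondary key — the lightly smoothed EDT
    (Gaussian, 1 voxel), which orders voxels within a plateau by the depth
    of their neighbourhood.  The raw depth stays the primary sort key, so
    d(x) < d(y) still implies EVF(x) <= EVF(y) exactly; residual exact ties
    (symmetry copies) keep the mid-rank.  ``convention`` may also be
    ``"strict"`` or ``"inclusive"`` (lower / upper rank of the same key).
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    _, n_comp = ndimage.label(mask, structure=_STRUCT6)
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected component, found {n_comp}")
    depth = ndimage.distance_transform_edt(mask, sampling=spacing)
    smooth = ndimage.gaussian_filter(depth, sigma=1.0)
    # complex lexicographic key: real part (raw depth) dominates, imaginary
    # part (smoothed depth) breaks plateaus
    key = depth[mask] + 1j * smooth[mask]
    if convention == "midrank":
        ranks = stats.rankdata(key, method="average")
        evf = (ranks - 0.5) / n
    elif convention == "strict":
        evf = (stats.rankdata(key, method="min") - 1.0) / n
    elif convention == "inclusive":
        evf = stats.rankdata(key, method="max") / n
    else:
        raise ValueError(f"unknown EVF convention {convention!r}")
    values = np.full(mask.shape, np.nan)
    values[mask] = evf
    return EVFMap(values, mask, depth, tuple(spacing), convention, nucleus_id)


def equal_volume_fractions(evf: EVFMap, F: int = 1000) -> np.ndarray:
    """Partition the nucleus into F fractions of (near-)identical volume.

    Returns an integer grid: 0 outside the mask, fraction index 1..F inside,
    fraction 1 at the periphery.  Voxels are ordered by EVF (ties broken by
    scan order); fraction k takes ranks in ((k-1)N/F, kN/F], so sizes differ
    by at most one voxel.  F > N is clamped to N with a warning.
    """
    if F < 2:
        raise ValueError("need at least 2 fractions")
    n = evf.n_voxels
    if F > n:
        warnings.warn(f"F={F} exceeds mask voxel count {n}; clamping to {n}")
        F = n
    order = np.argsort(evf.values[evf.mask], kind="stable")
    bounds = (np.arange(1, F + 1) * n) // F
    sizes = np.diff(np.concatenate([[0], bounds]))
    frac_of_sorted = np.repeat(np.arange(1, F + 1), sizes)
    frac_flat = np.empty(n, dtype=np.int32)
    frac_flat[order] = frac_of_sorted
    labels = np.zeros(evf.mask.shape, dtype=np.int32)
    labels[evf.mask] = frac_flat
    return labels


def radial_profile(
    fractions: np.ndarray,
    signal: ImageStack | np.ndarray,
    mode: str = "intensity",
    spacing: tuple[float, float, float] | None = None,
    nucleus_id: int = 0,
    channel: str = "",
) -> RadialProfile:
    """Per-fraction signal proportions and cumulative radial distribution.

    ``mode="intensity"`` weights each voxel by its raw intensity (the
    default: it needs no segmentation of the signal); ``mode="spots"``
    weights by membership of a binary/labelled spot mask.
    """
    if isinstance(signal, ImageStack):
        values = signal.values
        spacing = signal.spacing
        channel = channel or signal.channel
    else:
        values = np.asarray(signal)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
    if values.shape != fractions.shape:
        raise ValueError("signal grid does not match fraction grid")
    inside = fractions > 0
    if mode == "intensity":
        weights = values[inside].astype(float)
    elif mode == "spots":
        weights = (values[inside] > 0).astype(float)
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    F = int(fractions.max())
    sums = np.bincount(fractions[inside] - 1, weights=weights, minlength=F)
    total = sums.sum()
    if total <= 0:
        raise ValueError("total signal in nucleus is zero")
    return RadialProfile(sums / total, mode, tuple(spacing), nucleus_id, channel)


def dmax(profile: RadialProfile, rule: str = "max_abs") -> float:
    """Signed largest deviation of the radial cumulative curve from uniform.

    D_k = C_k - k/F; returns D at the k maximising |D_k| (ties -> smallest
    k).  ``rule="max_signed"`` returns max_k D_k instead — an alternative
    reading of "largest signed difference"; max-|D| is the default.
    """
    F = profile.F
    D = profile.cumulative - np.arange(1, F + 1) / F
    if rule == "max_abs":
        return float(D[np.argmax(np.abs(D))])
    if rule == "max_signed":
        return float(D.max())
    raise ValueError(f"unknown d_max rule {rule!r}")


def spot_evf(evf: EVFMap, centroids_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """EVF at the voxel nearest each spot centroid (physical um coords, zyx).

    Centroids falling outside the mask are mapped to the nearest mask voxel
    and flagged.  Returns ``(evf_values, outside_flags)``.
    """
    centroids = np.atleast_2d(np.asarray(centroids_um, dtype=float))
    spacing = np.asarray(evf.spacing)
    idx = np.rint(centroids / spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(evf.mask.shape) - 1)
    outside = ~evf.mask[tuple(idx.T)]
    if outside.any():
        # nearest in-mask voxel via EDT feature transform
        _, nearest = ndimage.distance_transform_edt(
            ~evf.mask, sampling=evf.spacing, return_indices=True
        )
        out_idx = idx[outside]
        idx[outside] = nearest[(slice(None),) + tuple(out_idx.T)].T
    return evf.values[tuple(idx.T)], outside
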