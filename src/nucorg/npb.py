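"""Nucleolar precursor body (NPB) detection and heterochromatin association.

NPBs appear as round, compact bodies darker than the surrounding
nucleoplasm in the DNA counterstain.  The detector inverts the in-mask
intensities, smooths, thresholds with Otsu on the inverted histogram, and
keeps components that are large and round enough (sphericity filter).  The
association step flags each NPB that has at least one spot voxel within a
small gap of its surface and reports the associated/total ratio per channel.

Note this automated detector is a reconstruction of what is usually a
visual count; all thresholds are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .image import ImageStack
from .spotseg import SpotSet

__all__ = ["NPBSet", "segment_npbs", "associate", "sphericity"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class NPBSet:
    """Labelled NPBs with per-body geometry and association flags.

    ``table`` columns: npb_id, center_z/y/x_um, volume_um3, sphericity, and
    one boolean ``assoc_<channel>`` column per associated channel.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    table: pd.DataFrame
    nucleus_id: int = 0

    @property
    def n_npb(self) -> int:
        return len(self.table)

    def n_associated(self, channel: str = "any") -> int:
        cols = [c for c in self.table.columns if c.startswith("assoc_")]
        if not cols:
            return 0
        if channel == "any":
            return int(self.table[cols].any(axis=1).sum())
        col = f"assoc_{channel}"
        if col not in self.table.columns:
            raise KeyError(f"no association flags for channel {channel!r}")
        return int(self.table[col].sum())

    def ratio(self, channel: str = "any") -> float:
        """Associated / total NPBs; 0 when there are no NPBs."""
        return self.n_associated(channel) / self.n_npb if self.n_npb else 0.0


def sphericity(comp: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """pi^(1/3) (6V)^(2/3) / A with A from a marching-cubes surface mesh.

    Returns 0 for components too thin to mesh.
    """
    comp = np.asarray(comp, dtype=bool)
    nvox = int(comp.sum())
    if nvox == 0:
        return 0.0
    voxvol = float(np.prod(spacing))
    V = nvox * voxvol
    padded = np.pad(comp.astype(float), 1)
    try:
        verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=spacing)
        A = skmeasure.mesh_surface_area(verts, faces)
    except (ValueError, RuntimeError):
        return 0.0
    if A <= 0:
        return 0.0
    return float(np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / A)


def segment_npbs(
    dna: ImageStack,
    nucleus: np.ndarray,
    min_volume_um3: float = 1.0,
    min_sphericity: float = 0.6,
    smooth_sigma_um: float = 0.3,
    min_depth: float = 10.0,
    nucleus_id: int = 0,
) -> NPBSet:
    """Detect dark round bodies in the DNA channel within the nucleus.

    ``min_depth`` is the minimum intensity contrast (in-mask max - min)
    required to attempt detection at all: a flat nucleoplasm has no voids.
    """
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise ValueError("empty nuclear mask")
    values = dna.values.astype(float)
    in_vals = values[nucleus]
    spacing = np.asarray(dna.spacing)
    empty = NPBSet(np.zeros(values.shape, np.int32), dna.spacing, _empty_table(), nucleus_id)
    if in_vals.max() - in_vals.min() < min_depth:
        return empty
    inverted = np.zeros_like(values)
    inverted[nucleus] = in_vals.max() - values[nucleus]
    if smooth_sigma_um > 0:
        inverted = ndimage.gaussian_filter(inverted, sigma=smooth_sigma_um / spacing)
    from .nucseg import compute_threshold  # local import avoids cycle at module load

    try:
        t = compute_threshold(inverted, method="otsu", roi=nucleus)
    except ValueError:
        return empty
    dark = nucleus & (inverted > t)
    # neighbouring bodies can fuse into one dark component; split on the
    # distance map before filtering
    from .nucseg import split_touching

    # h at half the minimum body radius: deep enough to ignore ridge noise
    # along elongated streaks, shallow enough to cut the saddle between
    # near-touching spheres
    split = split_touching(dark, tuple(dna.spacing), h_um=0.6)
    labels, n = split.labels, split.n_labels
    voxvol = dna.voxel_volume
    out = np.zeros(labels.shape, dtype=np.int32)
    rows = []
    next_id = 0
    for lab in range(1, n + 1):
        comp = labels == lab
        vol = comp.sum() * voxvol
        if vol < min_volume_um3:
            continue
        sph = sphericity(comp, dna.spacing)
        if sph < min_sphericity:
            continue
        next_id += 1
        out[comp] = next_id
        center = np.argwhere(comp).mean(axis=0) * spacing
        rows.append((next_id, *center, vol, sph))
    table = pd.DataFrame(rows, columns=_empty_table().columns) if rows else _empty_table()
    return NPBSet(out, dna.spacing, table, nucleus_id)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["npb_id", "center_z_um", "center_y_um", "center_x_um",
                 "volume_um3", "sphericity"]
    )


def associate(npbs: NPBSet, spots: SpotSet | np.ndarray, gap_um: float = 0.5,
              channel: str | None = None) -> NPBSet:
    """Flag NPBs with >= 1 spot voxel within ``gap_um`` of their surface.

    The test is anisotropy-aware: for each NPB the Euclidean distance to the
    body is computed with the physical spacing, and any overlapping or
    sufficiently close spot voxel triggers the flag.  Returns a new NPBSet
    with an ``assoc_<channel>`` column filled in.
    """
    if isinstance(spots, SpotSet):
        spot_mask = spots.binary()
        channel = channel or spots.channel or "spots"
    else:
        spot_mask = np.asarray(spots) > 0
        channel = channel or "spots"
    if spot_mask.shape != npbs.labels.shape:
        raise ValueError("spot grid does not match NPB grid")
    spacing = np.asarray(npbs.spacing)
    pad = np.ceil(gap_um / spacing).astype(int) + 1
    flags = []
    table = npbs.table.copy()
    for _, row in table.iterrows():
        lab = int(row["npb_id"])
        comp = npbs.labels == lab
        idx = np.argwhere(comp)
        lo = np.maximum(idx.min(axis=0) - pad, 0)
        hi = np.minimum(idx.max(axis=0) + pad + 1, comp.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        dist = ndimage.distance_transform_edt(~comp[sl], sampling=npbs.spacing)
        flags.append(bool((spot_mask[sl] & (dist <= gap_um)).any()))
    table[f"assoc_{channel}"] = flags
    return NPBSet(npbs.labels, npbs.spacing, table, npbs.nucleus_id)
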