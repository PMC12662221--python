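"""3D nucleus segmentation and per-nucleus intensity quantification.

The pipeline mirrors a classic immunofluorescence workflow: the DNA
(DAPI) channel of a multi-channel z-stack is smoothed slice-by-slice with a
small 2D Gaussian, a single Otsu threshold is computed for the whole stack,
per-slice 8-connected components are linked across adjacent slices into 3D
nuclei, and mean intensities of the *raw* channels are measured per
nucleus.  Everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .stats import pearson_with_p

__all__ = [
    "ImageStack",
    "NucleusRecord",
    "gaussian_smooth",
    "otsu_threshold",
    "label_and_stitch",
    "quantify_nuclei",
    "channel_correlation",
    "records_frame",
    "segment_stack",
]


@dataclass
class ImageStack:
    """Voxel data indexed (z, y, x, channel) with channel names.

    ``dna_channel`` designates the channel used for segmentation.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    dna_channel: str = "dapi"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("stack must be 4D (z, y, x, channel)")
        if self.data.shape[3] != len(self.channels):
            raise ValueError("channel axis length does not match channel names")
        if self.data.shape[0] < 1 or self.data.shape[3] < 1:
            raise ValueError("stack needs >=1 slice and >=1 channel")
        if (self.data < 0).any():
            raise ValueError("voxel intensities must be non-negative")
        if self.dna_channel not in self.channels:
            raise ValueError(f"DNA channel {self.dna_channel!r} not in {self.channels}")

    def channel(self, name: str) -> np.ndarray:
        return self.data[..., self.channels.index(name)]


@dataclass(frozen=True)
class NucleusRecord:
    nucleus_id: int
    voxel_count: int
    centroid: tuple[float, float, float]   # (z, y, x)
    slice_span: tuple[int, int]            # first and last slice, inclusive
    channel_means: dict


def gaussian_smooth(
    stack: ImageStack, channel: str | None = None, size: int = 9, sigma: float = 5.0
) -> np.ndarray:
    """Per-slice 2D Gaussian smoothing of one channel.

    The kernel is a ``size`` x ``size`` truncated Gaussian renormalized to
    sum 1, applied with reflective boundaries; slices are never mixed.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    chan = stack.dna_channel if channel is None else channel
    img = stack.channel(chan)
    radius = (size - 1) // 2
    ax = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    out = np.empty_like(img)
    for z in range(img.shape[0]):
        # symmetric kernel: correlation == convolution
        out[z] = ndimage.convolve(img[z], kernel, mode="reflect")
    return out


def otsu_threshold(smoothed: np.ndarray, nbins: int = 256) -> tuple[float, np.ndarray]:
    """Single Otsu threshold over all voxels of the stack, plus the mask
    ``smoothed > threshold``.

    The threshold maximizes between-class variance over an ``nbins``-bin
    histogram of the full stack.
    """
    arr = np.asarray(smoothed, dtype=float)
    if np.ptp(arr) == 0:
        raise ValueError("constant stack: no Otsu threshold exists")
    thr = float(threshold_otsu(arr, nbins=nbins))
    return thr, arr > thr


def label_and_stitch(
    mask: np.ndarray, link_overlap: float = 0.5, min_volume: int = 50
) -> tuple[np.ndarray, int]:
    """Stitch per-slice 8-connected components into 3D nuclei.

    Components A (slice z) and B (slice z+1) are linked iff
    ``|A & B| / min(|A|, |B|) >= link_overlap``.  Many-to-many candidates
    are resolved greedily by decreasing overlap (ties by label ids), each
    component accepting at most one link per direction; linked chains form
    one nucleus.  Nuclei with fewer than ``min_volume`` voxels total are
    discarded.  Returns the labeled volume (0 = background, nuclei numbered
    1..n in scan order) and the nucleus count.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    nz = mask.shape[0]
    slice_labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = [0]
    for z in range(nz):
        lab = cc_label(mask[z], connectivity=2)
        slice_labels[z] = np.where(lab > 0, lab + offsets[-1], 0)
        offsets.append(offsets[-1] + lab.max())
    n_comp = offsets[-1]
    parent = np.arange(n_comp + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comp_sizes = np.bincount(slice_labels.ravel(), minlength=n_comp + 1)
    for z in range(nz - 1):
        a = slice_labels[z].ravel()
        b = slice_labels[z + 1].ravel()
        both = (a > 0) & (b > 0)
        if not both.any():
            continue
        pairs, counts = np.unique(
            np.stack([a[both], b[both]]), axis=1, return_counts=True
        )
        cand = []
        for (ca, cb), inter in zip(pairs.T, counts):
            frac = inter / min(comp_sizes[ca], comp_sizes[cb])
            if frac >= link_overlap:
                cand.append((frac, int(ca), int(cb)))
        # greedy: largest overlap fraction first, deterministic tie-break
        cand.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, ca, cb in cand:
            if ca in used_a or cb in used_b:
                continue
            used_a.add(ca)
            used_b.add(cb)
            parent[find(ca)] = find(cb)

    roots = np.array([find(i) for i in range(n_comp + 1)])
    nucleus_sizes = np.bincount(roots[slice_labels.ravel()], minlength=n_comp + 1)
    nucleus_sizes[0] = 0
    keep_roots = np.nonzero(nucleus_sizes >= min_volume)[0]
    # renumber kept nuclei 1..n in order of first appearance in scan order
    root_vol = roots[slice_labels]
    remap = np.zeros(n_comp + 1, dtype=np.int32)
    flat = root_vol.ravel()
    first_pos = {}
    for pos in np.nonzero(flat)[0]:
        r = flat[pos]
        if r not in first_pos:
            first_pos[r] = pos
    next_id = 1
    for r in sorted(keep_roots, key=lambda r: first_pos.get(r, np.inf)):
        if r in first_pos:
            remap[r] = next_id
            next_id += 1
    labeled = remap[root_vol]
    return labeled, next_id - 1


def quantify_nuclei(labels: np.ndarray, stack: ImageStack) -> list[NucleusRecord]:
    """Per-nucleus voxel count, centroid and mean raw intensity per channel.

    Intensities are measured on the unsmoothed channels; the centroid is
    the unweighted mean of member voxel coordinates.
    """
    if labels.shape != stack.data.shape[:3]:
        raise ValueError("label volume does not align with the stack")
    n = int(labels.max())
    records = []
    idx = np.arange(1, n + 1)
    if n == 0:
        return records
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, idx)
    counts = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, idx)
    z_any = [np.nonzero((labels == i).any(axis=(1, 2)))[0] for i in idx]
    means = {
        ch: ndimage.mean(stack.channel(ch), labels, idx) for ch in stack.channels
    }
    for j, i in enumerate(idx):
        records.append(
            NucleusRecord(
                nucleus_id=int(i),
                voxel_count=int(counts[j]),
                centroid=tuple(float(c) for c in centroids[j]),
                slice_span=(int(z_any[j][0]), int(z_any[j][-1])),
                channel_means={ch: float(means[ch][j]) for ch in stack.channels},
            )
        )
    return records


def records_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "nucleus": r.nucleus_id,
            "voxels": r.voxel_count,
            "z": r.centroid[0],
            "y": r.centroid[1],
            "x": r.centroid[2],
            "z_first": r.slice_span[0],
            "z_last": r.slice_span[1],
        }
        row.update({f"mean_{ch}": v for ch, v in r.channel_means.items()})
        rows.append(row)
    cols = ["nucleus", "voxels", "z", "y", "x", "z_first", "z_last"]
    if records:
        cols += [f"mean_{ch}" for ch in records[0].channel_means]
    return pd.DataFrame(rows, columns=cols)


def channel_correlation(
    records: Sequence[NucleusRecord], channel_a: str, channel_b: str
) -> tuple[float, float]:
    """Pearson correlation of per-nucleus mean intensities between two
    channels, with the exact two-sided t-transform p (n-2 df)."""
    if len(records) < 3:
        raise ValueError("need at least 3 nuclei")
    a = np.array([r.channel_means[channel_a] for r in records])
    b = np.array([r.channel_means[channel_b] for r in records])
    return pearson_with_p(a, b)


def segment_stack(
    stack: ImageStack,
    size: int = 9,
    sigma: float = 5.0,
    link_overlap: float = 0.5,
    min_volume: int = 50,
) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Full pipeline: smooth DNA channel, Otsu-threshold, stitch, quantify."""
    smoothed = gaussian_smooth(stack, stack.dna_channel, size=size, sigma=sigma)
    _, mask = otsu_threshold(smoothed)
    labels, _ = label_and_stitch(mask, link_overlap=link_overlap, min_volume=min_volume)
    return labels, quantify_nuclei(labels, stack)
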