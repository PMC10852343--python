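"""Independent brute-force oracles and small test utilities.

The oracles deliberately avoid the imaging-library code paths the package
uses: erosion/dilation are recomputed from the Euclidean-distance
definition over explicit offset sets, and puncta detection is a pure-python
pixel-by-pixel reimplementation (sorted-list median, BFS components).
"""

from __future__ import annotations

import math

import numpy as np


def disc_offsets(k: int) -> list[tuple[int, int]]:
    """All integer offsets within Euclidean distance k of the origin."""
    return [(dr, dc)
            for dr in range(-k, k + 1)
            for dc in range(-k, k + 1)
            if dr * dr + dc * dc <= k * k]


def erode_oracle(mask: np.ndarray, k: int) -> np.ndarray:
    """{p : every pixel within distance <= k of p is in the mask}.

    Pixels outside the frame count as background, so anything within k of
    the border is removed when the mask reaches it.
    """
    padded = np.pad(mask.astype(bool), k, constant_values=False)
    out = np.ones_like(mask, dtype=bool)
    h, w = mask.shape
    for dr, dc in disc_offsets(k):
        out &= padded[k + dr:k + dr + h, k + dc:k + dc + w]
    return out & mask.astype(bool)


def shrink_oracle(labels: np.ndarray, k: int) -> np.ndarray:
    """Per-instance erosion oracle (instances eroded independently)."""
    out = np.zeros_like(labels)
    for idx in np.unique(labels[labels > 0]):
        out[erode_oracle(labels == idx, k)] = idx
    return out


def grow_oracle(labels: np.ndarray, k: int) -> np.ndarray:
    """Nearest-seed dilation oracle.

    Every pixel within distance k of some instance joins the nearest
    instance; exact distance ties go to the smallest label.  Distances are
    compared as exact squared integers.
    """
    fg = np.argwhere(labels > 0)
    out = np.zeros_like(labels)
    if fg.size == 0:
        return out
    fg_labels = labels[fg[:, 0], fg[:, 1]]
    order = np.argsort(fg_labels, kind="stable")
    fg, fg_labels = fg[order], fg_labels[order]
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            d2 = (fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2
            i = int(np.argmin(d2))  # first minimum = smallest label (sorted)
            if d2[i] <= k * k:
                out[r, c] = fg_labels[i]
    return out


def puncta_pixels_oracle(channel, mask, delta_afu: float, min_area_px: float):
    """Library-free puncta detection on one neuron.

    Returns the set of detected components, each a frozenset of (row, col)
    pixels: median background over the mask, per-pixel threshold
    background + delta (comparator >=), BFS 8-connected components, integer
    area gate ceil(min_area_px).
    """
    pixels = sorted((r, c) for r, c in np.argwhere(np.asarray(mask)))
    values = sorted(float(channel[r][c]) for r, c in pixels)
    n = len(values)
    if n % 2 == 1:
        background = values[n // 2]
    else:
        background = 0.5 * (values[n // 2 - 1] + values[n // 2])
    threshold = background + delta_afu
    supra = {(r, c) for r, c in pixels if float(channel[r][c]) >= threshold}
    min_area = math.ceil(min_area_px)
    components = []
    remaining = set(supra)
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q in remaining:
                        remaining.discard(q)
                        comp.add(q)
                        frontier.append(q)
        if len(comp) >= min_area:
            components.append(frozenset(comp))
    return set(components)


def random_blob_labels(rng, shape=(40, 40), threshold=1.0):
    """Random labelled blobs: smoothed noise thresholded, then labelled."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=3.0)
    mask = field > threshold * field.std()
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), int))
    return labels.astype(np.int32)


def truth_to_label(truth_row, labels: np.ndarray) -> int:
    """Pipeline label under a truth object's centroid (0 if missed)."""
    r = int(round(truth_row.centroid_row))
    c = int(round(truth_row.centroid_col))
    return int(labels[r, c])
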