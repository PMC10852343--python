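"""QC overlays and summary plots (PNG, headless backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .image_io import ImageStack, LabelMap  # noqa: E402
from .morphometry import DiameterFit  # noqa: E402


def qc_overlay(stack: ImageStack, neurons: LabelMap, puncta_sets=None,
               channel: str = "PGP9.5", path: str | Path = "qc.png") -> Path:
    """Neuron outlines (and puncta markers) over one channel, for visual audit."""
    path = Path(path)
    img = stack.channel(channel)
    fig, ax = plt.subplots(figsize=(8, 8))
    ax.imshow(img, cmap="gray", interpolation="nearest")
    ax.contour(neurons.binary(), levels=[0.5], colors="cyan", linewidths=0.6)
    if puncta_sets:
        pts = [(c.centroid[1], c.centroid[0])
               for ps in puncta_sets for c in ps.components]
        if pts:
            xs, ys = zip(*pts)
            ax.plot(xs, ys, "r.", markersize=3)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def diameter_histogram_plot(diameters, fit: DiameterFit | None = None,
                            path: str | Path = "diameters.png",
                            bin_width_um: float = 2.0) -> Path:
    """Pooled-neuron diameter histogram with an optional Gaussian overlay."""
    path = Path(path)
    d = np.asarray(list(diameters), dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if d.size:
        edges = np.arange(0.0, d.max() + bin_width_um, bin_width_um)
        ax.hist(d, bins=edges, color="#888", edgecolor="white")
        if fit is not None:
            x = np.linspace(edges[0], edges[-1], 200)
            pdf = (np.exp(-0.5 * ((x - fit.mean_um) / fit.sd_um) ** 2)
                   / (fit.sd_um * np.sqrt(2 * np.pi)))
            ax.plot(x, pdf * d.size * bin_width_um, "k-",
                    label=f"Gaussian fit: μ={fit.mean_um:.1f} μm")
            ax.legend()
    ax.set_xlabel("soma diameter (μm)")
    ax.set_ylabel("neurons")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
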