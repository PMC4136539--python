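"""Static figure export: ethogram rasters and dust maps.

Presentation-only helpers; nothing here is used by the quantitative
pipeline.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .dustmaps import DustMap
from .ethogram import Ethogram
from .model import LEG_LABELS, SimulationResult

__all__ = ["plot_ethogram", "plot_dust_map"]


def plot_ethogram(
    source: Union[SimulationResult, Ethogram, Sequence[str]],
    ax: Optional[plt.Axes] = None,
    labels: Optional[Sequence[str]] = None,
):
    """Raster plot with one row per behavior and a tick per active timestep."""
    if isinstance(source, SimulationResult):
        seq = source.ethogram.labels
        if labels is None:
            labels = list(source.config.labels) + (
                list(LEG_LABELS) if source.config.legs_enabled else []
            )
    elif isinstance(source, Ethogram):
        seq = source.labels
    else:
        seq = tuple(str(x) for x in source)
    if labels is None:
        labels = list(dict.fromkeys(seq))
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.4 * len(labels) + 1))
    raster = np.zeros((len(labels), len(seq)))
    index = {lab: i for i, lab in enumerate(labels)}
    for t, lab in enumerate(seq):
        if lab in index:
            raster[index[lab], t] = 1.0
    ax.imshow(raster, aspect="auto", cmap="Greys", interpolation="none")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("iteration")
    return ax


def plot_dust_map(dust_map: DustMap, ax: Optional[plt.Axes] = None):
    """Grayscale rendering of a groomogram (white = all subjects dusted)."""
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(dust_map.fractions, cmap="gray", vmin=0.0, vmax=1.0)
    ax.figure.colorbar(im, ax=ax, label="fraction of subjects dusted")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
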