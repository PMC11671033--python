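"""Length-distribution histograms: above/below side, linear and log scale.

Binning: unit-width integer bins when the length range spans at most 100
distinct values (readable at peptide scale, 40-100 aa), otherwise 50
equal-width bins (readable at transcript scale, hundreds to tens of
thousands of bp).  "Log scale" means a logarithmic count axis over a linear
length axis, the usual view for heavy-tailed length distributions.

Rendering is headless-safe: unless interactive display is requested the
figure is drawn straight onto an off-screen Agg canvas, so pipeline runs
never need a display regardless of the configured backend.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

__all__ = [
    "HistogramSpec",
    "PlotBackendError",
    "build_histogram",
    "render_plot",
    "plot_file_name",
]

logger = logging.getLogger(__name__)

SIDES = ("above", "below")
SCALES = ("linear", "log")

#: Widest length range still drawn with unit-width integer bins.
INTEGER_BIN_SPAN = 100
#: Number of equal-width bins for wider ranges.
WIDE_RANGE_BINS = 50


class PlotBackendError(ValueError):
    """Raised for a plotting backend identifier matplotlib does not know."""


@dataclass
class HistogramSpec:
    """Binned length counts plus the metadata needed to draw one panel."""

    bin_edges: np.ndarray
    bin_counts: np.ndarray
    scale: str
    side: str
    unit: str
    cutoff: int
    title: str = ""
    xlabel: str = ""
    ylabel: str = ""
    n_sequences: int = 0

    @property
    def renderable(self) -> bool:
        """False for the empty-side spec, which produces no file."""
        return self.n_sequences > 0


def _side_label(side: str, cutoff: int, unit: str) -> str:
    boundary = cutoff - 1 if side == "above" else cutoff
    return f"{side} {boundary} {unit}"


def build_histogram(
    lengths: Iterable[int],
    scale: str,
    side: str,
    unit: str,
    cutoff: int,
) -> HistogramSpec:
    """Bin *lengths* into a :class:`HistogramSpec` for one plot panel.

    Bins cover [min(lengths), max(lengths)] and the bin counts sum to the
    number of sequences.  Empty input yields a spec flagged not-renderable.
    """
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    arr = np.asarray(list(lengths), dtype=float)
    label = _side_label(side, cutoff, unit)
    title = f"Sequence length distribution {label}"
    if scale == "log":
        title += " (log scale)"
    spec = HistogramSpec(
        bin_edges=np.empty(0),
        bin_counts=np.empty(0, dtype=int),
        scale=scale,
        side=side,
        unit=unit,
        cutoff=cutoff,
        title=title,
        xlabel=f"Sequence length ({unit})",
        ylabel="Number of sequences",
        n_sequences=arr.size,
    )
    if arr.size == 0:
        return spec
    lo, hi = int(arr.min()), int(arr.max())
    if hi - lo + 1 <= INTEGER_BIN_SPAN:
        # half-integer edges center each unit-width bin on its length value
        edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    else:
        edges = np.linspace(lo, hi, WIDE_RANGE_BINS + 1)
    counts, edges = np.histogram(arr, bins=edges)
    spec.bin_edges = edges
    spec.bin_counts = counts.astype(int)
    return spec


def _validate_backend(backend: str) -> None:
    from matplotlib.backends.registry import backend_registry

    known = {name.lower() for name in backend_registry.list_all()}
    if backend.lower() not in known:
        raise PlotBackendError(f"unknown plotting backend: {backend!r}")


def render_plot(
    spec: HistogramSpec,
    out_path: Union[str, os.PathLike],
    show: bool = False,
    backend: str = "TkAgg",
) -> Optional[Path]:
    """Render *spec* to a PNG at *out_path*; return the path, or ``None``.

    A not-renderable (empty-side) spec is skipped with a logged warning and
    no file is produced.  With ``show=False`` the figure is drawn off
    screen; with ``show=True`` it is additionally displayed through
    *backend*, which must be a backend matplotlib recognises.
    """
    out_path = Path(out_path)
    if not spec.renderable:
        logger.warning(
            "no sequences on the %s side: skipping plot %s", spec.side, out_path
        )
        return None
    _validate_backend(backend)

    if show:  # pragma: no cover - needs a display
        import matplotlib

        matplotlib.use(backend, force=True)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 5))
    else:
        from matplotlib.backends.backend_agg import FigureCanvasAgg
        from matplotlib.figure import Figure

        fig = Figure(figsize=(8, 5))
        FigureCanvasAgg(fig)
        ax = fig.add_subplot(111)

    widths = np.diff(spec.bin_edges)
    ax.bar(
        spec.bin_edges[:-1],
        spec.bin_counts,
        width=widths,
        align="edge",
        color="steelblue",
        edgecolor="none",
    )
    if spec.scale == "log":
        ax.set_yscale("log")
    ax.set_title(spec.title)
    ax.set_xlabel(spec.xlabel)
    ax.set_ylabel(spec.ylabel)
    fig.tight_layout()
    fig.savefig(out_path, format="png", dpi=100)
    if show:  # pragma: no cover
        import matplotlib.pyplot as plt

        plt.show()
        plt.close(fig)
    return out_path


def plot_file_name(side: str, scale: str, cutoff: int, unit: str) -> str:
    """PNG file name for one panel.

    The below/log panel carries a ``seqs_`` prefix while the other three
    use ``seq_``; the asymmetry reproduces the published inventory
    verbatim.
    """
    boundary = cutoff - 1 if side == "above" else cutoff
    prefix = "seqs" if (side, scale) == ("below", "log") else "seq"
    suffix = "_log" if scale == "log" else ""
    return f"{prefix}_length_distribution_{side}{boundary}{unit}{suffix}.png"
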