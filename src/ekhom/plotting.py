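"""Static plot helpers: barcodes and Poincare-polynomial surfaces."""

from __future__ import annotations

from typing import Sequence, Tuple

from .ekh import Barcode
from .laurent import TwoVarPolynomial

__all__ = ["plot_barcode", "plot_poincare_surface"]


def plot_barcode(bc: Barcode, ax=None, by_height: bool = True):
    """Horizontal bars over the filtration parameter, one row per bar.

    Arrows are not drawn; remember that classes emerge from the more
    smoothed stages and persist toward the original link.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    bars = sorted(bc.bars, key=lambda b: (b.height, b.stage_lo))
    for row, b in enumerate(bars):
        lo, hi = sorted((b.param_lo, b.param_hi))
        ax.hlines(row, lo, hi, lw=3)
        ax.plot([lo, hi], [row, row], "k|", ms=6)
        if by_height:
            ax.annotate(f"k={b.height}", (hi, row), textcoords="offset points",
                        xytext=(4, -3), fontsize=7)
    ax.set_xlabel("filtration parameter")
    ax.set_ylabel("bar")
    ax.set_yticks([])
    return ax


def plot_poincare_surface(stages: Sequence[Tuple[float, TwoVarPolynomial]],
                          ax=None):
    """Stem summary of the graded Poincare polynomial per stage:
    for each filtration parameter, total dimension by q-degree."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    for a, poly in stages:
        for (t, q), c in sorted(poly.coeffs.items()):
            ax.plot([a, a], [q, q], [0, float(c)], "b-", lw=1)
            ax.plot([a], [q], [float(c)], "bo", ms=3)
    ax.set_xlabel("parameter")
    ax.set_ylabel("q-degree")
    ax.set_zlabel("dimension")
    return ax
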