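"""Phase-portrait rendering.

Marker convention: filled black = locally stable, filled red = unstable,
hollow = saddle; separatrices dashed; vector field drawn as arrows whose
angle gives the direction of density change and whose color the magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import models as M
from .dynamics import default_box, find_equilibria, nullclines

__all__ = ["PortraitStyle", "render_portrait"]


@dataclass(frozen=True)
class PortraitStyle:
    arrow_density: int = 18
    cmap: str = "viridis"
    stable_color: str = "black"
    unstable_color: str = "tab:red"
    saddle_face: str = "white"
    separatrix_style: str = "--"
    nullcline_colors: tuple[str, str] = ("tab:blue", "tab:orange")


def render_portrait(model, params, box=None, path=None,
                    style: PortraitStyle | None = None,
                    equilibria=None, separatrices=(), ax=None):
    """Draw vector field, nullclines, equilibria and separatrices.

    Returns the matplotlib figure; writes to ``path`` when given.
    """
    spec = M.get_model(model)
    style = style or PortraitStyle()
    if box is None:
        box = default_box(spec, params)
    L = float(box[1])
    if L <= (box[0] or 0.0):
        raise ValueError("box must have positive area")
    if equilibria is None:
        equilibria = find_equilibria(spec, params, box=(0.0, L))

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(5.2, 5.0))
    else:
        fig = ax.figure

    xs = np.linspace(L / style.arrow_density / 2, L, style.arrow_density)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    mask = M.valid_mask(spec, params, X, Y)
    F = M.rhs(spec, params, (X, Y), check=False)
    U = np.where(mask & np.isfinite(F[0]), F[0], np.nan)
    V = np.where(mask & np.isfinite(F[1]), F[1], np.nan)
    mag = np.hypot(U, V)
    with np.errstate(invalid="ignore", divide="ignore"):
        Un, Vn = U / mag, V / mag
    ax.quiver(X, Y, Un, Vn, np.log10(mag + 1e-12), cmap=style.cmap,
              angles="xy", pivot="mid", alpha=0.75, width=0.004)

    ncs = nullclines(spec, params, box=(0.0, L), resolution=201)
    for c in ncs.curves:
        color = style.nullcline_colors[c.species - 1]
        lw = 1.0 if c.kind == "trivial" else 1.8
        ax.plot(c.points[:, 0], c.points[:, 1], color=color, lw=lw,
                label=None)

    for sep in separatrices:
        for branch in sep.branches:
            ax.plot(branch[:, 0], branch[:, 1], style.separatrix_style,
                    color="tab:red", lw=1.4)

    for e in equilibria:
        x, y = e.location
        if e.is_saddle or e.local_type == "nonhyperbolic":
            ax.plot(x, y, "o", mfc=style.saddle_face, mec="black", ms=8, mew=1.4)
        elif e.is_attractor:
            ax.plot(x, y, "o", color=style.stable_color, ms=8)
        else:
            ax.plot(x, y, "o", color=style.unstable_color, ms=8)

    ax.set_xlim(0, L)
    ax.set_ylim(0, L)
    ax.set_xlabel("$N_1$")
    ax.set_ylabel("$N_2$")
    ax.set_title(spec.id)
    if own_fig:
        fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path))
        if own_fig:
            plt.close(fig)
    return fig
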