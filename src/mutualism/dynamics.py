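"""Equilibrium finding, local stability typing, and nullcline extraction.

The static phase-plane skeleton: fixed points of the two-species flow with
their Jacobian eigenvalues and local type, and the zero-growth curves
(nullclines) whose crossings those fixed points are.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from contourpy import contour_generator
from scipy import optimize

from . import models as M

__all__ = [
    "Equilibrium",
    "NullclineSet",
    "NullclineCurve",
    "DynamicsSettings",
    "default_box",
    "find_equilibria",
    "classify_equilibrium",
    "nullclines",
    "single_species_equilibrium",
]

LOCAL_TYPES = (
    "stable_node", "stable_spiral", "unstable_node", "unstable_spiral",
    "saddle", "nonhyperbolic",
)


@dataclass(frozen=True)
class DynamicsSettings:
    """Numerical tolerances for the static phase-plane analysis."""

    grid_n: int = 64            # sign-change scan resolution per axis
    newton_tol: float = 1e-10   # relative residual for accepted roots
    dedupe_rel: float = 1e-5    # merge radius, relative to box scale
    tol_hyp: float = 1e-6       # |Re| below this (scaled) is nonhyperbolic
    axis_scan_n: int = 400      # 1-D scan resolution on each axis


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with its local linearization."""

    location: tuple[float, float]
    residual: float
    eigenvalues: tuple[complex, complex]
    local_type: str
    position_class: str  # origin | axis_1 | axis_2 | interior

    @property
    def is_attractor(self) -> bool:
        return self.local_type in ("stable_node", "stable_spiral")

    @property
    def is_saddle(self) -> bool:
        return self.local_type == "saddle"


@dataclass(frozen=True)
class NullclineCurve:
    species: int                    # whose growth is zero on the curve
    kind: str                       # "trivial" (axis) or "nontrivial"
    points: np.ndarray              # (n, 2) polyline
    geometry: tuple[str, str] = ("", "")  # (monotonicity, curvature)


@dataclass(frozen=True)
class NullclineSet:
    curves: tuple[NullclineCurve, ...]
    box: tuple[float, float]
    clipped: bool = False           # True when validity clipping occurred

    def nontrivial(self, species: int) -> list[NullclineCurve]:
        return [c for c in self.curves
                if c.species == species and c.kind == "nontrivial"]


def default_box(model, params) -> tuple[float, float]:
    """Analysis box ``[0, L]^2``.

    ``L`` is ten times the largest of the single-species equilibria, the
    half-saturation constants in the schema, and 1 — saturating benefits are
    bounded, so finite equilibria fall well inside.
    """
    spec = M.get_model(model)
    scale = 1.0
    for i in (1, 2):
        try:
            scale = max(scale, single_species_equilibrium(spec, params, i))
        except M.DomainError:
            pass
    values = params.values if isinstance(params, M.ParameterSet) else params
    for d in spec.schema:
        if d.symbol.startswith(("h", "D", "e", "K", "S")) and d.symbol not in ("D",):
            scale = max(scale, abs(float(values[d.symbol])))
        if d.symbol == "D":
            scale = max(scale, float(values[d.symbol]))
    return (0.0, 10.0 * scale)


def classify_equilibrium(eigenvalues, tol_hyp: float = 1e-6) -> str:
    """Map a pair of Jacobian eigenvalues to a local-type label.

    Both real parts negative -> stable (node if real, spiral if complex);
    both positive -> unstable likewise; opposite signs -> saddle; any real
    part within ``tol_hyp * max(1, |lambda|)`` of zero -> nonhyperbolic
    (eigenvalues alone cannot decide, e.g. a candidate center).
    """
    lam = [complex(v) for v in eigenvalues]
    if any(not np.isfinite([v.real, v.imag]).all() for v in lam):
        raise ValueError("non-finite eigenvalues")
    scale = max(1.0, max(abs(v) for v in lam))
    re = [v.real for v in lam]
    if any(abs(x) < tol_hyp * scale for x in re):
        return "nonhyperbolic"
    has_im = any(abs(v.imag) > tol_hyp * scale for v in lam)
    if all(x < 0 for x in re):
        return "stable_spiral" if has_im else "stable_node"
    if all(x > 0 for x in re):
        return "unstable_spiral" if has_im else "unstable_node"
    return "saddle"


def _make_equilibrium(spec, params, x, y, L, settings) -> Equilibrium:
    f = M.rhs(spec, params, (x, y), check=False)
    resid = float(np.max(np.abs(f)))
    jac = M.jacobian(spec, params, (x, y), check=False)
    eig = np.linalg.eigvals(jac)
    tol = settings.dedupe_rel * L
    if abs(x) < tol and abs(y) < tol:
        pos = "origin"
    elif abs(y) < tol:
        pos = "axis_1"
    elif abs(x) < tol:
        pos = "axis_2"
    else:
        pos = "interior"
    return Equilibrium(
        location=(float(x), float(y)),
        residual=resid,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        local_type=classify_equilibrium(eig, settings.tol_hyp),
        position_class=pos,
    )


def _axis_roots(spec, params, species: int, L: float, settings) -> list[float]:
    """Positive roots of the per-capita growth of ``species`` on its own axis."""
    xs = np.linspace(0.0, L, settings.axis_scan_n + 1)[1:]
    state = (xs, np.zeros_like(xs)) if species == 1 else (np.zeros_like(xs), xs)
    mask = M.valid_mask(spec, params, state[0], state[1])
    g = M.per_capita(spec, params, state, check=False)[species - 1]
    g = np.where(mask, g, np.nan)

    def g_scalar(x):
        st = (x, 0.0) if species == 1 else (0.0, x)
        return float(M.per_capita(spec, params, st, check=False)[species - 1])

    roots = []
    for k in range(len(xs) - 1):
        a, b = g[k], g[k + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(float(xs[k]))
        elif a * b < 0:
            roots.append(float(optimize.brentq(g_scalar, xs[k], xs[k + 1],
                                               xtol=1e-14, rtol=1e-14)))
    if np.isfinite(g[-1]) and g[-1] == 0.0:
        roots.append(float(xs[-1]))
    return roots


def single_species_equilibrium(model, params, species: int) -> float:
    """Density a species settles to alone (its carrying capacity), 0 if none.

    The largest nonnegative root of the per-capita growth rate on the
    species' own axis; obligate species return 0.
    """
    spec = M.get_model(model)
    settings = DynamicsSettings()
    # scan box from parameter magnitudes only (avoid recursion into default_box)
    values = params.values if isinstance(params, M.ParameterSet) else params
    scale = max([1.0] + [abs(float(v)) for v in values.values()])
    roots = _axis_roots(spec, params, species, 20.0 * scale, settings)
    return max(roots) if roots else 0.0


def _newton_polish(spec, params, x0, L, settings):
    def fun(z):
        return M.rhs(spec, params, z, check=False)

    def jac(z):
        return M.jacobian(spec, params, z, check=False)

    sol = optimize.root(fun, x0, jac=jac, method="hybr",
                        options={"xtol": 1e-13})
    if not sol.success:
        return None
    z = sol.x
    scale = max(1.0, L)
    fz = fun(z)
    if not np.all(np.isfinite(fz)) or np.max(np.abs(fz)) > settings.newton_tol * scale:
        return None
    return z


def find_equilibria(model, params, box=None,
                    settings: DynamicsSettings | None = None) -> list[Equilibrium]:
    """All fixed points inside the axis-aligned box with origin corner (0, 0).

    The origin and axis equilibria come from 1-D root scans of the per-capita
    growth rates; interior candidates from sign-change cells of both rhs
    components on a dense grid, polished by Newton's method and deduplicated.
    Sorted by (position class, N1).
    """
    spec = M.get_model(model)
    settings = settings or DynamicsSettings()
    if box is None:
        box = default_box(spec, params)
    L = float(box[1])
    if L <= 0:
        raise ValueError("box must have positive extent")

    found: list[np.ndarray] = []

    def push(z):
        z = np.asarray(z, float)
        if not np.all(np.isfinite(z)):
            return
        if z[0] < -settings.dedupe_rel * L or z[1] < -settings.dedupe_rel * L:
            return
        if z[0] > L * (1 + 1e-9) or z[1] > L * (1 + 1e-9):
            return
        z = np.maximum(z, 0.0)
        for w in found:
            if np.hypot(*(z - w)) < settings.dedupe_rel * L:
                return
        found.append(z)

    # origin (when invariant axes make it a fixed point)
    f0 = M.rhs(spec, params, (0.0, 0.0), check=False)
    if np.all(np.isfinite(f0)) and np.max(np.abs(f0)) < settings.newton_tol * max(1.0, L):
        push((0.0, 0.0))

    for sp_i in (1, 2):
        for r in _axis_roots(spec, params, sp_i, L, settings):
            z = (r, 0.0) if sp_i == 1 else (0.0, r)
            # only a fixed point if the partner axis is also at rest there
            fz = M.rhs(spec, params, z, check=False)
            if np.all(np.isfinite(fz)) and np.max(np.abs(fz)) < 1e-8 * max(1.0, L):
                push(z)

    # interior: sign-change cells of both components
    n = settings.grid_n
    xs = np.linspace(0.0, L, n + 1)[1:]
    ys = np.linspace(0.0, L, n + 1)[1:]
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    mask = M.valid_mask(spec, params, X, Y)
    F = M.rhs(spec, params, (X, Y), check=False)
    F = np.where(mask & np.isfinite(F), F, np.nan)

    def sign_change(A):
        s = np.sign(A)
        c = np.zeros((n - 1, n - 1), bool)
        for (sl1, sl2) in (((slice(None, -1), slice(None, -1)), (slice(1, None), slice(None, -1))),
                           ((slice(None, -1), slice(None, -1)), (slice(None, -1), slice(1, None))),
                           ((slice(1, None), slice(None, -1)), (slice(1, None), slice(1, None))),
                           ((slice(None, -1), slice(1, None)), (slice(1, None), slice(1, None)))):
            a, b = s[sl1], s[sl2]
            c |= (a * b <= 0) & np.isfinite(A[sl1]) & np.isfinite(A[sl2])
        return c

    cells = sign_change(F[0]) & sign_change(F[1])
    ii, jj = np.nonzero(cells)
    for i, j in zip(ii, jj):
        x0 = (0.5 * (xs[i] + xs[i + 1]), 0.5 * (ys[j] + ys[j + 1]))
        z = _newton_polish(spec, params, x0, L, settings)
        if z is not None:
            push(z)

    eqs = [_make_equilibrium(spec, params, z[0], z[1], L, settings) for z in found]
    order = {"origin": 0, "axis_1": 1, "axis_2": 2, "interior": 3}
    eqs.sort(key=lambda e: (order[e.position_class], e.location[0], e.location[1]))
    return eqs


# ---------------------------------------------------------------------------
# Nullclines
# ---------------------------------------------------------------------------

def _geometry_summary(points: np.ndarray, L: float) -> tuple[str, str]:
    """Vote-based (monotonicity, curvature) labels for one polyline.

    Monotonicity is the sign consistency of dN2/dN1 along the curve;
    curvature the sign consistency of its change.  Closed or back-bending
    curves (the lobe shape produced by saturating costs) are tagged "lobe".
    """
    pts = points
    if len(pts) < 3:
        return ("flat", "linear")
    closed = np.hypot(*(pts[0] - pts[-1])) < 1e-3 * L
    d = np.diff(pts, axis=0)
    keep = np.hypot(d[:, 0], d[:, 1]) > 1e-12 * L
    d = d[keep]
    if len(d) < 2:
        return ("flat", "linear")
    # back-bending: direction of travel along N1 reverses substantially
    dx_sign = np.sign(d[:, 0])
    nz = dx_sign[np.abs(d[:, 0]) > 1e-9 * L]
    frac_fwd = np.mean(nz > 0) if len(nz) else 0.5
    if closed or (len(nz) > 10 and 0.05 < frac_fwd < 0.95):
        return ("non-monotonic", "lobe")

    # orient by increasing N1 where possible, else treat as vertical line
    if len(nz) == 0:
        return ("increasing", "linear") if np.std(pts[:, 0]) < 1e-9 * L else ("flat", "linear")
    order = np.argsort(pts[:, 0])
    x, y = pts[order, 0], pts[order, 1]
    # resample coarsely so contour-extraction jitter cannot flip the
    # slope/curvature votes
    if len(x) > 30:
        idx = np.unique(np.linspace(0, len(x) - 1, 30).astype(int))
        x, y = x[idx], y[idx]
    dx = np.diff(x)
    ok = dx > 1e-9 * L
    slopes = np.diff(y)[ok] / dx[ok]
    if len(slopes) < 2:
        return ("flat", "linear")
    pos = np.mean(slopes > 0)
    if pos >= 0.95:
        mono = "increasing"
    elif pos <= 0.05:
        mono = "decreasing"
    else:
        mono = "non-monotonic"
    ds = np.diff(slopes)
    span = np.ptp(slopes)
    scale = max(abs(np.median(slopes)), span, 1e-12)
    if span < 0.02 * max(1.0, abs(np.median(slopes))):
        curv = "linear"
    else:
        up = np.mean(ds > 0)
        if up >= 0.95:
            curv = "concave_up"
        elif up <= 0.05:
            curv = "concave_down"
        else:
            curv = "non-monotonic"
    return (mono, curv)


def nullclines(model, params, box=None, resolution: int = 401,
               settings: DynamicsSettings | None = None) -> NullclineSet:
    """Zero-growth curves of both species inside the box.

    Nontrivial curves are zero-contours of the per-capita growth rate
    ``g_i`` (of the full rhs for models whose axes are not invariant); the
    axes themselves are returned as trivial curves where they are invariant.
    """
    spec = M.get_model(model)
    settings = settings or DynamicsSettings()
    if box is None:
        box = default_box(spec, params)
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    L = float(box[1])
    xs = np.linspace(0.0, L, resolution)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    mask = M.valid_mask(spec, params, X, Y)
    inv = M.axis_invariant(spec, params)
    G = M.per_capita(spec, params, (X, Y), check=False)
    F = M.rhs(spec, params, (X, Y), check=False)
    clipped = bool(~np.all(mask))

    curves: list[NullclineCurve] = []
    for i in (1, 2):
        Z = G[i - 1] if inv[i - 1] else F[i - 1]
        Z = np.where(mask & np.isfinite(Z), Z, np.nan)
        gen = contour_generator(x=X, y=Y, z=Z)
        for line in gen.lines(0.0):
            pts = np.asarray(line)
            if len(pts) < 2:
                continue
            curves.append(NullclineCurve(
                species=i, kind="nontrivial", points=pts,
                geometry=_geometry_summary(pts, L),
            ))
        if inv[i - 1]:
            axis_pts = (np.column_stack([np.zeros(2), [0.0, L]]) if i == 1
                        else np.column_stack([[0.0, L], np.zeros(2)]))
            curves.append(NullclineCurve(species=i, kind="trivial",
                                         points=axis_pts,
                                         geometry=("flat", "linear")))
    return NullclineSet(curves=tuple(curves), box=(0.0, L), clipped=clipped)
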