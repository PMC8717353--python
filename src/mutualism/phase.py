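"""Time integration, basins of attraction, separatrices, oscillations.

Single trajectories are integrated with scipy's adaptive solvers (stiff
fallback included) and terminated by ecological events: convergence onto an
attractor, extinction (a density crossing a floor while declining), or
unbounded growth (the finite-time surrogate for divergence).  Basin maps
integrate a whole grid of initial conditions at once with a vectorized
embedded Runge-Kutta scheme whose step size adapts per trajectory.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from . import models as M
from .dynamics import DynamicsSettings, Equilibrium, default_box, find_equilibria

__all__ = [
    "PhaseSettings",
    "Trajectory",
    "BasinMap",
    "Separatrix",
    "integrate",
    "basin_map",
    "separatrix",
    "separatrix_consistency",
    "detect_oscillation",
]


@dataclass(frozen=True)
class PhaseSettings:
    """Integration tolerances and event thresholds (scaled by box size L)."""

    rtol: float = 1e-8
    atol_rel: float = 1e-10        # atol = atol_rel * L (single trajectories)
    batch_rtol: float = 1e-6
    batch_atol_rel: float = 1e-9
    blowup_factor: float = 1e3     # unbounded when any density > factor * L
    eps_ext_rel: float = 1e-6      # extinction floor = eps_ext_rel * L
    conv_tol_rel: float = 1e-5     # |rhs| floor for convergence
    dt_conv: float = 5.0           # time the |rhs| floor must be sustained
    t_max: float = 400.0
    match_rel: float = 5e-3        # endpoint-to-equilibrium match radius
    cycle_return_rel: float = 1e-3 # Poincare-style recurrence radius
    max_batch_iters: int = 60_000


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    y: np.ndarray                   # (2, n) state series
    terminal_event: str             # converged | extinct | unbounded | horizon | domain
    event_time: float
    extinct_species: tuple[int, ...] = ()
    attractor: tuple[float, float] | None = None

    @property
    def final_state(self) -> np.ndarray:
        return self.y[:, -1]


@dataclass(frozen=True)
class BasinMap:
    x0_grid: tuple[np.ndarray, np.ndarray]   # 1-D coordinate vectors
    labels: np.ndarray                       # (n, n) object array, row-major, origin (0,0)
    attractors: tuple[dict, ...]
    equilibria: tuple[Equilibrium, ...]
    counts: dict
    grid_n: int
    t_max: float
    box: tuple[float, float]


@dataclass(frozen=True)
class Separatrix:
    saddle: tuple[float, float]
    branches: tuple[np.ndarray, np.ndarray]  # stable-manifold polylines
    truncation: tuple[str, str]              # box_exit | origin | horizon per branch


# ---------------------------------------------------------------------------
# Single trajectories
# ---------------------------------------------------------------------------

def integrate(model, params, x0, t_max: float | None = None,
              settings: PhaseSettings | None = None,
              box=None) -> Trajectory:
    """Integrate one orbit until an ecological terminal event.

    Events: *unbounded* (density exceeds ``blowup_factor * L``), *extinct*
    (density below the extinction floor while declining), *converged*
    (``|rhs|`` below the convergence floor, sustained for ``dt_conv``),
    else *horizon*.  Tiny negative densities are projected to zero.
    """
    spec = M.get_model(model)
    st = settings or PhaseSettings()
    if box is None:
        box = default_box(spec, params)
    L = float(box[1])
    t_max = float(t_max if t_max is not None else st.t_max)
    eps_ext = st.eps_ext_rel * L
    conv_tol = st.conv_tol_rel * max(1.0, L)
    blowup = st.blowup_factor * L

    if not np.all(M.valid_mask(spec, params, x0[0], x0[1])):
        raise M.DomainError(f"initial state outside validity domain: {spec.validity_text}")

    def f(t, y):
        out = M.rhs(spec, params, y, check=False)
        return np.where(np.isfinite(out), out, 0.0)

    def ev_blow(t, y):
        return max(y) - blowup
    ev_blow.terminal = True
    ev_blow.direction = 1

    def ev_e1(t, y):
        return y[0] - eps_ext
    ev_e1.terminal = True
    ev_e1.direction = -1

    def ev_e2(t, y):
        return y[1] - eps_ext
    ev_e2.terminal = True
    ev_e2.direction = -1

    def ev_conv(t, y):
        return float(np.max(np.abs(f(t, y)))) - conv_tol
    ev_conv.terminal = True
    ev_conv.direction = -1

    ts, ys = [np.array([0.0])], [np.asarray(x0, float).reshape(2, 1)]
    t0 = 0.0
    y0 = np.asarray(x0, float)
    event = "horizon"
    event_time = t_max
    extinct: tuple[int, ...] = ()
    attractor = None

    for _ in range(50):
        events = [ev_blow, ev_conv]
        if y0[0] > eps_ext:
            events.append(ev_e1)
        if y0[1] > eps_ext:
            events.append(ev_e2)
        sol = solve_ivp(f, (t0, t_max), y0, method="RK45", rtol=st.rtol,
                        atol=st.atol_rel * L, events=events, dense_output=False)
        if sol.status == -1:  # stiff fallback
            sol = solve_ivp(f, (t0, t_max), y0, method="LSODA", rtol=st.rtol,
                            atol=st.atol_rel * L, events=events)
        ts.append(sol.t[1:])
        ys.append(sol.y[:, 1:])
        t0 = float(sol.t[-1])
        y0 = np.maximum(sol.y[:, -1], 0.0)
        if not np.all(M.valid_mask(spec, params, y0[0], y0[1])):
            event, event_time = "domain", t0
            break
        if sol.status == 0:
            event, event_time = "horizon", t_max
            break
        hit = [k for k, te in enumerate(sol.t_events) if len(te)]
        which = events[hit[0]] if hit else None
        if which is ev_blow:
            event, event_time = "unbounded", t0
            break
        if which in (ev_e1, ev_e2):
            g = f(t0, y0)
            i = 0 if which is ev_e1 else 1
            if g[i] < 0:
                dead = [i + 1]
                if y0[1 - i] <= eps_ext:
                    dead = [1, 2]
                event, event_time, extinct = "extinct", t0, tuple(dead)
                y0[i] = 0.0
                break
            y0[i] = eps_ext * 1.001  # transient dip with nonnegative growth
            continue
        if which is ev_conv:
            # sustain check: hold for dt_conv beyond the crossing
            sol2 = solve_ivp(f, (t0, min(t0 + st.dt_conv, t_max)), y0,
                             method="RK45", rtol=st.rtol, atol=st.atol_rel * L)
            yend = np.maximum(sol2.y[:, -1], 0.0)
            still = float(np.max(np.abs(f(0.0, yend)))) < 10 * conv_tol
            ts.append(sol2.t[1:])
            ys.append(sol2.y[:, 1:])
            t0 = float(sol2.t[-1])
            y0 = yend
            if still:
                g_end = f(0.0, yend)
                dying = (yend < 100 * eps_ext) & (g_end <= 0)
                if dying.any():
                    event, event_time = "extinct", t0
                    extinct = tuple(int(i) + 1 for i in np.nonzero(dying)[0])
                    break
                event, event_time = "converged", t0
                attractor = (float(yend[0]), float(yend[1]))
                break
            if t0 >= t_max:
                event, event_time = "horizon", t_max
                break
            continue
        event, event_time = "horizon", t_max
        break

    t = np.concatenate(ts)
    y = np.maximum(np.concatenate(ys, axis=1), 0.0)
    return Trajectory(t=t, y=y, terminal_event=event, event_time=event_time,
                      extinct_species=extinct, attractor=attractor)


# ---------------------------------------------------------------------------
# Vectorized batch integration (Cash-Karp RK with per-trajectory steps)
# ---------------------------------------------------------------------------

_CK_A = [
    (),
    (1 / 5,),
    (3 / 40, 9 / 40),
    (3 / 10, -9 / 10, 6 / 5),
    (-11 / 54, 5 / 2, -70 / 27, 35 / 27),
    (1631 / 55296, 175 / 512, 575 / 13824, 44275 / 110592, 253 / 4096),
]
_CK_B5 = (37 / 378, 0, 250 / 621, 125 / 594, 0, 512 / 1771)
_CK_B4 = (2825 / 27648, 0, 18575 / 48384, 13525 / 55296, 277 / 14336, 1 / 4)

ACTIVE, CONVERGED, EXTINCT, UNBOUNDED, HORIZON, DOMAIN = range(6)


def _batch_integrate(fvec, x0s: np.ndarray, t_max: float, L: float,
                     st: PhaseSettings):
    """Integrate many 2-D orbits at once; returns (y, t, status, extinct_mask).

    ``fvec`` maps two (m,) arrays to two (m,) derivative arrays.  Each
    trajectory carries its own adaptive step; finished trajectories are
    frozen in place.
    """
    m = x0s.shape[0]
    y = x0s.astype(float).copy()
    t = np.zeros(m)
    h = np.full(m, min(0.05, t_max / 100))
    status = np.full(m, ACTIVE, dtype=np.int8)
    conv_since = np.full(m, np.nan)  # time the |rhs| floor was first met
    extinct_mask = np.zeros((m, 2), bool)

    eps_ext = st.eps_ext_rel * L
    conv_tol = st.conv_tol_rel * max(1.0, L)
    blowup = st.blowup_factor * L
    atol = st.batch_atol_rel * L
    hmin = 1e-11 * t_max

    def F(yy):
        with np.errstate(all="ignore"):
            f1, f2 = fvec(yy[:, 0], yy[:, 1])
        return np.stack([np.asarray(f1, float), np.asarray(f2, float)], axis=1)

    for _ in range(st.max_batch_iters):
        act = status == ACTIVE
        if not act.any():
            break
        ya = y[act]
        ha = h[act]
        ks = [F(ya)]
        for row in _CK_A[1:]:
            yi = ya + ha[:, None] * sum(c * k for c, k in zip(row, ks))
            ks.append(F(yi))
        y5 = ya + ha[:, None] * sum(b * k for b, k in zip(_CK_B5, ks))
        y4 = ya + ha[:, None] * sum(b * k for b, k in zip(_CK_B4, ks))
        bad = ~np.all(np.isfinite(y5), axis=1)
        sc = atol + st.batch_rtol * np.maximum(np.abs(ya), np.abs(y5)).max(axis=1)
        with np.errstate(all="ignore"):
            err = np.abs(y5 - y4).max(axis=1) / sc
        err = np.where(np.isfinite(err), err, np.inf)
        accept = (err <= 1.0) | (ha <= hmin)
        # diverging stages: treat as unbounded if already huge, else shrink
        huge = bad & (np.abs(ya).max(axis=1) > 0.5 * blowup)
        accept &= ~bad

        idx = np.nonzero(act)[0]
        ia = idx[accept]
        y[ia] = np.maximum(y5[accept], 0.0)
        t[ia] = t[ia] + ha[accept]
        status[idx[huge]] = UNBOUNDED

        with np.errstate(all="ignore"):
            grow = np.where(err > 0, 0.9 * err ** -0.2, 5.0)
            grow = np.clip(np.where(np.isfinite(grow), grow, 5.0), 0.1, 5.0)
            shrink = np.where(err > 0, 0.9 * err ** -0.25, 1.0)
            shrink = np.clip(np.where(np.isfinite(shrink), shrink, 0.1), 0.1, 1.0)
        hnew = np.where(accept, ha * grow, ha * shrink)
        hnew = np.minimum(np.maximum(hnew, hmin), t_max - t[idx] + 1e-12)
        h[idx] = np.maximum(hnew, hmin)

        if len(ia) == 0:
            continue
        # events at accepted points
        yn = y[ia]
        fn = F(yn)
        fin = np.all(np.isfinite(fn), axis=1) & np.all(np.isfinite(yn), axis=1)
        over = yn.max(axis=1) > blowup
        status[ia[over | ~fin]] = np.where(
            yn[over | ~fin].max(axis=1) > blowup, UNBOUNDED, DOMAIN)
        dead = (yn < eps_ext) & (fn < 0)
        any_dead = dead.any(axis=1)
        extinct_mask[ia[any_dead]] |= dead[any_dead] | (yn[any_dead] < eps_ext)
        status[ia[any_dead & (status[ia] == ACTIVE)]] = EXTINCT

        small = np.abs(fn).max(axis=1) < conv_tol
        first = np.isnan(conv_since[ia]) & small
        conv_since[ia[first]] = t[ia[first]]
        conv_since[ia[~small]] = np.nan
        held = small & (t[ia] - conv_since[ia] >= st.dt_conv)
        # an orbit creeping toward an axis/origin rest point is an
        # extinction, not a coexistence convergence
        dying = (yn < 100 * eps_ext) & (fn <= 0)
        to_ext = held & dying.any(axis=1)
        sel = ia[to_ext]
        extinct_mask[sel] |= dying[to_ext]
        status[sel[status[sel] == ACTIVE]] = EXTINCT
        sel = ia[held & ~dying.any(axis=1)]
        status[sel[status[sel] == ACTIVE]] = CONVERGED

        tmo = t[ia] >= t_max * (1 - 1e-12)
        sel = ia[tmo]
        status[sel[status[sel] == ACTIVE]] = HORIZON
    status[status == ACTIVE] = HORIZON
    return y, t, status, extinct_mask


# ---------------------------------------------------------------------------
# Basin mapping
# ---------------------------------------------------------------------------

def _label_extinct(mask_row) -> str:
    if mask_row[0] and mask_row[1]:
        return "extinct:both"
    return "extinct:1" if mask_row[0] else "extinct:2"


def basin_map(model, params, box=None, grid_n: int = 101,
              t_max: float | None = None,
              settings: PhaseSettings | None = None,
              equilibria: list[Equilibrium] | None = None,
              dyn_settings: DynamicsSettings | None = None) -> BasinMap:
    """Label a grid of initial conditions by their terminal behavior.

    Grids are row-major with inclusive endpoints and origin at (0, 0).
    Converged endpoints are matched to known equilibria; bounded recurrent
    orbits that never settle are registered as cycle attractors.
    """
    spec = M.get_model(model)
    st = settings or PhaseSettings()
    if grid_n < 11:
        raise ValueError("grid_n must be >= 11")
    if box is None:
        box = default_box(spec, params)
    L = float(box[1])
    t_max = float(t_max if t_max is not None else st.t_max)
    if equilibria is None:
        equilibria = find_equilibria(spec, params, box=(0.0, L),
                                     settings=dyn_settings)

    xs = np.linspace(0.0, L, grid_n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    valid0 = M.valid_mask(spec, params, pts[:, 0], pts[:, 1])

    comp = M._compiled(spec.id)
    vals = M._vals(spec, params)

    def fvec(n1, n2):
        return comp.rhs(n1, n2, *vals)

    y_end = pts.copy()
    status = np.full(len(pts), DOMAIN, dtype=np.int8)
    ext_mask = np.zeros((len(pts), 2), bool)
    if valid0.any():
        ye, te, stt, em = _batch_integrate(fvec, pts[valid0], t_max, L, st)
        y_end[valid0] = ye
        status[valid0] = stt
        ext_mask[valid0] = em

    eps_ext = st.eps_ext_rel * L
    match_r = st.match_rel * L
    eq_locs = np.array([e.location for e in equilibria]) if equilibria else np.empty((0, 2))

    labels = np.empty(len(pts), dtype=object)
    for k in range(len(pts)):
        s = status[k]
        if s == DOMAIN:
            labels[k] = "domain"
        elif s == UNBOUNDED:
            labels[k] = "unbounded"
        elif s == EXTINCT:
            labels[k] = _label_extinct(ext_mask[k])
        elif s == CONVERGED:
            ye = y_end[k]
            low = ye < 10 * eps_ext
            if low.any():
                labels[k] = _label_extinct(low)
            elif len(eq_locs):
                d = np.hypot(*(eq_locs - ye).T)
                j = int(np.argmin(d))
                labels[k] = f"eq:{j}" if d[j] < match_r else "horizon"
            else:
                labels[k] = "horizon"
        else:
            labels[k] = "horizon"

    # cycle registration: probe a few unresolved cells for bounded recurrence
    attractors: list[dict] = []
    for j, e in enumerate(equilibria):
        if e.is_attractor:
            attractors.append({"id": f"eq:{j}", "type": "equilibrium",
                               "location": e.location,
                               "local_type": e.local_type})
    hz = np.nonzero(labels == "horizon")[0]
    if len(hz):
        rng = np.random.default_rng(0)
        probes = rng.choice(hz, size=min(3, len(hz)), replace=False)
        for p in probes:
            cyc = _detect_cycle(spec, params, y_end[p], L, st)
            if cyc is not None:
                cid = f"cycle:{len([a for a in attractors if a['type'] == 'cycle'])}"
                attractors.append({"id": cid, "type": "cycle", "bbox": cyc})
                (x0c, x1c), (y0c, y1c) = cyc
                mx, my = 0.15 * (x1c - x0c) + 1e-3 * L, 0.15 * (y1c - y0c) + 1e-3 * L
                inside = ((labels == "horizon")
                          & (y_end[:, 0] >= x0c - mx) & (y_end[:, 0] <= x1c + mx)
                          & (y_end[:, 1] >= y0c - my) & (y_end[:, 1] <= y1c + my))
                labels[inside] = cid
                break

    lab_grid = labels.reshape(grid_n, grid_n)
    uniq, cnt = np.unique(labels.astype(str), return_counts=True)
    counts = dict(zip(uniq.tolist(), cnt.tolist()))
    return BasinMap(x0_grid=(xs, xs), labels=lab_grid, attractors=tuple(attractors),
                    equilibria=tuple(equilibria), counts=counts,
                    grid_n=grid_n, t_max=t_max, box=(0.0, L))


def _detect_cycle(spec, params, y0, L, st: PhaseSettings):
    """Return the bounding box of a bounded recurrent orbit from y0, or None."""
    comp = M._compiled(spec.id)
    vals = M._vals(spec, params)

    def f(t, y):
        with np.errstate(all="ignore"):
            out = np.asarray(comp.rhs(y[0], y[1], *vals), float)
        return np.where(np.isfinite(out), out, 0.0)

    horizon = 4 * st.t_max
    sol = solve_ivp(f, (0.0, horizon), np.asarray(y0, float), method="LSODA",
                    rtol=1e-8, atol=1e-10 * L, dense_output=False,
                    max_step=horizon / 2000)
    ys = sol.y.T
    if not np.all(np.isfinite(ys)) or ys.max() > st.blowup_factor * L:
        return None
    tail = ys[len(ys) // 2:]
    ref = tail[0]
    d = np.hypot(*(tail - ref).T)
    far = d > 10 * st.cycle_return_rel * L
    if not far.any():
        return None  # spiralling into a point, not a cycle
    # recurrence: returns to the reference point after having left it
    first_far = int(np.argmax(far))
    returns = np.nonzero(d[first_far:] < st.cycle_return_rel * L)[0]
    if len(returns) == 0:
        return None
    return ((float(tail[:, 0].min()), float(tail[:, 0].max())),
            (float(tail[:, 1].min()), float(tail[:, 1].max())))


# ---------------------------------------------------------------------------
# Separatrices
# ---------------------------------------------------------------------------

def separatrix(model, params, saddle: Equilibrium,
               settings: PhaseSettings | None = None,
               box=None, t_horizon: float | None = None) -> Separatrix:
    """Trace the stable manifold of a saddle backward in time.

    The two branches start ``1e-6 * L`` from the saddle along its stable
    eigenvector and are integrated in reversed time until they exit the box,
    approach a backward-time rest point, or hit the horizon.
    """
    if not saddle.is_saddle:
        raise ValueError(f"separatrix requires a saddle, got {saddle.local_type}")
    spec = M.get_model(model)
    st = settings or PhaseSettings()
    if box is None:
        box = default_box(spec, params)
    L = float(box[1])
    t_horizon = float(t_horizon if t_horizon is not None else 4 * st.t_max)

    jac = M.jacobian(spec, params, saddle.location, check=False)
    w, v = np.linalg.eig(jac)
    k = int(np.argmin(w.real))
    vec = np.real(v[:, k])
    vec = vec / np.linalg.norm(vec)
    delta = 1e-6 * L
    x0s = [np.asarray(saddle.location) + delta * vec,
           np.asarray(saddle.location) - delta * vec]

    def f_back(t, y):
        out = M.rhs(spec, params, y, check=False)
        out = np.asarray(out, float)
        return -np.where(np.isfinite(out), out, 0.0)

    def ev_exit(t, y):
        return min(min(y), L - max(y)) + 1e-9 * L
    ev_exit.terminal = True
    ev_exit.direction = -1

    def ev_rest(t, y):
        return float(np.max(np.abs(f_back(t, y)))) - st.conv_tol_rel * max(1.0, L)
    ev_rest.terminal = True
    ev_rest.direction = -1

    branches, trunc = [], []
    for x0 in x0s:
        sol = solve_ivp(f_back, (0.0, t_horizon), x0, method="LSODA",
                        rtol=1e-9, atol=1e-12 * L, events=[ev_exit, ev_rest],
                        max_step=t_horizon / 400)
        pts = np.clip(sol.y.T, 0.0, L)
        branches.append(pts)
        if len(sol.t_events[0]):
            trunc.append("box_exit")
        elif len(sol.t_events[1]):
            trunc.append("origin")
        else:
            trunc.append("horizon")
    return Separatrix(saddle=saddle.location,
                      branches=(branches[0], branches[1]),
                      truncation=(trunc[0], trunc[1]))


def separatrix_consistency(sep: Separatrix, basin: BasinMap,
                           n_probes: int = 40, offset_rel: float = 0.04) -> float:
    """Fraction of probe pairs straddling the separatrix whose basin labels differ."""
    pts = np.vstack([b for b in sep.branches if len(b) > 2])
    L = basin.box[1]
    xs = basin.x0_grid[0]
    rng = np.random.default_rng(0)
    idx = rng.choice(len(pts) - 1, size=min(n_probes, len(pts) - 1), replace=False)
    agree, total = 0, 0
    for k in idx:
        p, q = pts[k], pts[k + 1]
        tangent = q - p
        nrm = np.linalg.norm(tangent)
        if nrm < 1e-12 * L:
            continue
        normal = np.array([-tangent[1], tangent[0]]) / nrm
        a = p + offset_rel * L * normal
        b = p - offset_rel * L * normal
        if not all(0 <= z <= L for z in (*a, *b)):
            continue
        ia = (int(np.clip(np.searchsorted(xs, a[0]), 0, len(xs) - 1)),
              int(np.clip(np.searchsorted(xs, a[1]), 0, len(xs) - 1)))
        ib = (int(np.clip(np.searchsorted(xs, b[0]), 0, len(xs) - 1)),
              int(np.clip(np.searchsorted(xs, b[1]), 0, len(xs) - 1)))
        la, lb = basin.labels[ia], basin.labels[ib]
        if "horizon" in (la, lb) or "domain" in (la, lb):
            continue
        total += 1
        if la != lb:
            agree += 1
    return agree / total if total else float("nan")


# ---------------------------------------------------------------------------
# Oscillation detection
# ---------------------------------------------------------------------------

def detect_oscillation(model, params, x0, settings: PhaseSettings | None = None,
                       t_max: float | None = None, box=None) -> dict:
    """Classify the oscillatory character of the orbit from ``x0``.

    After discarding the first half of the horizon as transient, the peak
    sequence of N1 decides: shrinking peaks with complex eigenvalues at the
    attractor -> ``damped``; peak amplitude stabilizing above the amplitude
    floor -> ``sustained`` (with an estimated period); otherwise ``none``.
    """
    spec = M.get_model(model)
    st = settings or PhaseSettings()
    if box is None:
        box = default_box(spec, params)
    L = float(box[1])
    t_max = float(t_max if t_max is not None else 2 * st.t_max)

    comp = M._compiled(spec.id)
    vals = M._vals(spec, params)

    def f(t, y):
        with np.errstate(all="ignore"):
            out = np.asarray(comp.rhs(y[0], y[1], *vals), float)
        return np.where(np.isfinite(out), out, 0.0)

    t_eval = np.linspace(0.0, t_max, 4000)
    sol = solve_ivp(f, (0.0, t_max), np.asarray(x0, float), method="LSODA",
                    rtol=1e-8, atol=1e-10 * L, t_eval=t_eval)
    y = sol.y
    if not np.all(np.isfinite(y)) or y.max() > st.blowup_factor * L:
        return {"kind": "none", "terminal": "unbounded"}
    if y[:, -1].min() < st.eps_ext_rel * L:
        return {"kind": "none", "terminal": "extinct"}

    half = y.shape[1] // 2
    n1 = y[0, half:]
    tt = sol.t[half:]
    span = float(n1.max() - n1.min())
    floor = 1e-4 * L
    peaks, _ = find_peaks(n1, prominence=0.25 * max(span, 1e-30))
    if span < floor or len(peaks) < 3:
        # settles (or already settled) without measurable oscillation; check
        # for a damped spiral by the local eigenvalues at the endpoint
        jac = M.jacobian(spec, params, y[:, -1], check=False)
        eig = np.linalg.eigvals(jac)
        res = np.max(np.abs(f(0.0, y[:, -1])))
        if (res < 1e-4 * max(1.0, L) and np.all(eig.real < 0)
                and np.any(np.abs(eig.imag) > 1e-8)):
            # converged onto a stable spiral: transient ringing was damped
            return {"kind": "damped", "terminal": "converged"}
        return {"kind": "none", "terminal": "converged" if res < 1e-4 * max(1.0, L) else "horizon"}

    amps = n1[peaks]
    drops = np.diff(amps)
    last = amps[-min(4, len(amps)):]
    stabilized = (np.ptp(last) < 0.05 * max(span, floor)) and span > floor
    shrinking = np.all(drops < 0) and (amps[0] - amps[-1]) > 0.05 * span
    if stabilized and not shrinking:
        period = float(np.mean(np.diff(tt[peaks[-min(4, len(peaks)):]])))
        return {"kind": "sustained", "terminal": "horizon", "period": period,
                "amplitude": float(np.ptp(last) + span)}
    return {"kind": "damped", "terminal": "horizon"}
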