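"""Registry machinery for two-species mutualism ODE models.

Every model is a pair of coupled ODEs for population densities ``(N1, N2)``,

    dN1/dt = f1(N1, N2; p),    dN2/dt = f2(N1, N2; p),

defined symbolically (sympy) so that right-hand sides, analytic Jacobians and
per-capita growth rates are derived from a single source expression and
compiled once to vectorized numpy callables.  All densities and rates are
dimensionless.

The concrete model library (classical pairwise-mutualism equations plus the
generic intraspecific/interspecific density-dependence cases) lives in
:mod:`mutualism.library` and registers itself here on import.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "N1",
    "N2",
    "ParameterDescriptor",
    "ParameterSet",
    "ModelSpec",
    "register",
    "get_model",
    "list_models",
    "make_params",
    "rhs",
    "jacobian",
    "jacobian_fd",
    "per_capita",
    "obligacy",
    "axis_invariant",
    "validate_params",
    "registry_manifest",
]

#: Symbolic state variables shared by every registered model.
N1, N2 = sp.symbols("N1 N2", real=True)

_INF = math.inf


@dataclass(frozen=True)
class ParameterDescriptor:
    """Admissible range and default for one model parameter.

    Bounds are exclusive unless the matching ``*_inclusive`` flag is set;
    the common convention (all parameters strictly positive) is the default.
    """

    symbol: str
    description: str
    default: float
    low: float = 0.0
    high: float = _INF
    low_inclusive: bool = False
    high_inclusive: bool = False

    def admits(self, value: float) -> bool:
        if not np.isfinite(value):
            return False
        lo_ok = value >= self.low if self.low_inclusive else value > self.low
        hi_ok = value <= self.high if self.high_inclusive else value < self.high
        return bool(lo_ok and hi_ok)

    def range_text(self) -> str:
        lo = "[" if self.low_inclusive else "("
        hi = "]" if self.high_inclusive else ")"
        return f"{lo}{self.low}, {self.high}{hi}"


def _free(symbol: str, *, lo=0.0, hi=_INF) -> ParameterDescriptor:
    """Descriptor for a sign-unconstrained parameter (e.g. intrinsic rates)."""
    return ParameterDescriptor(symbol, "", 0.0, low=-_INF, high=_INF)


@dataclass(frozen=True)
class ParameterSet:
    """Named parameter values validated against a model schema."""

    model_id: str
    values: Mapping[str, float]
    provenance: str = "user"  # "user" | "fixture"

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]

    def replace(self, **updates: float) -> "ParameterSet":
        merged = {**self.values, **updates}
        return make_params(self.model_id, provenance=self.provenance, **merged)


@dataclass(frozen=True)
class ModelSpec:
    """A registered two-species ODE model.

    ``exprs`` holds the symbolic right-hand sides ``(f1, f2)`` in the state
    symbols :data:`N1`, :data:`N2` and the schema's parameter symbols.
    ``validity`` (optional) maps ``(values, N1, N2) -> bool array`` and marks
    where the equations are defined; ``validity_text`` names the offending
    term for error messages.  ``obligacy_override`` replaces the default
    limit-based obligacy rule (used by the historical carrying-capacity
    convention of generic Case 3.1).
    """

    id: str
    source: str
    exprs: tuple[sp.Expr, sp.Expr]
    schema: tuple[ParameterDescriptor, ...]
    notes: str = ""
    validity: Callable[[Mapping[str, float], np.ndarray, np.ndarray], np.ndarray] | None = None
    validity_text: str = ""
    obligacy_override: Callable[[Mapping[str, float]], dict[int, str]] | None = None
    functional_responses: tuple[dict, ...] = ()

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(d.symbol for d in self.schema)

    def descriptor(self, symbol: str) -> ParameterDescriptor:
        for d in self.schema:
            if d.symbol == symbol:
                return d
        raise KeyError(f"model {self.id!r} has no parameter {symbol!r}")


_REGISTRY: dict[str, ModelSpec] = {}


def register(spec: ModelSpec) -> ModelSpec:
    if spec.id in _REGISTRY:
        raise ValueError(f"duplicate model id {spec.id!r}")
    _REGISTRY[spec.id] = spec
    return spec


def _ensure_library_loaded() -> None:
    # The library module registers all models on first import.
    from . import library  # noqa: F401


def get_model(model: str | ModelSpec) -> ModelSpec:
    """Resolve a model id to its immutable spec.

    Raises ``KeyError`` naming the registered ids for unknown keys.
    """
    if isinstance(model, ModelSpec):
        return model
    _ensure_library_loaded()
    try:
        return _REGISTRY[model]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown model id {model!r}; registered ids: {known}") from None


def list_models() -> list[str]:
    _ensure_library_loaded()
    return sorted(_REGISTRY)


class ParameterError(ValueError):
    """A parameter value violates the model schema."""


def validate_params(spec: ModelSpec, values: Mapping[str, float]) -> None:
    unknown = set(values) - set(spec.symbols)
    if unknown:
        raise ParameterError(
            f"unknown parameter(s) {sorted(unknown)} for model {spec.id!r}"
        )
    for d in spec.schema:
        if d.symbol not in values:
            raise ParameterError(f"missing parameter {d.symbol!r} for model {spec.id!r}")
        v = float(values[d.symbol])
        if not d.admits(v):
            raise ParameterError(
                f"parameter {d.symbol!r}={v} outside admissible range "
                f"{d.range_text()} for model {spec.id!r}"
            )


def make_params(model: str | ModelSpec, provenance: str = "user", **values: float) -> ParameterSet:
    """Build a validated :class:`ParameterSet`, filling schema defaults."""
    spec = get_model(model)
    full = {d.symbol: float(d.default) for d in spec.schema}
    full.update({k: float(v) for k, v in values.items()})
    validate_params(spec, full)
    return ParameterSet(spec.id, full, provenance)


# ---------------------------------------------------------------------------
# Symbolic compilation (cached per model id)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Compiled:
    param_syms: tuple[sp.Symbol, ...]
    rhs: Callable  # (N1, N2, *vals) -> (f1, f2)
    jac: Callable  # (N1, N2, *vals) -> ((j11, j12), (j21, j22))
    percap: Callable  # (N1, N2, *vals) -> (g1, g2); g_i = f_i / N_i (cancelled)
    axis_resid: tuple[sp.Expr, sp.Expr]  # f1 at N1=0, f2 at N2=0 (symbolic)


@lru_cache(maxsize=None)
def _compiled(model_id: str) -> _Compiled:
    spec = get_model(model_id)
    psyms = tuple(sp.Symbol(s, real=True) for s in spec.symbols)
    f1, f2 = spec.exprs
    args = (N1, N2, *psyms)
    jac_exprs = [[sp.diff(f, v) for v in (N1, N2)] for f in (f1, f2)]
    g1 = sp.cancel(sp.together(f1 / N1))
    g2 = sp.cancel(sp.together(f2 / N2))
    rhs_fn = sp.lambdify(args, [f1, f2], modules="numpy")
    jac_fn = sp.lambdify(args, jac_exprs, modules="numpy")
    percap_fn = sp.lambdify(args, [g1, g2], modules="numpy")
    axis1 = sp.simplify(f1.subs(N1, 0))
    axis2 = sp.simplify(f2.subs(N2, 0))
    return _Compiled(psyms, rhs_fn, jac_fn, percap_fn, (axis1, axis2))


def _vals(spec: ModelSpec, params: ParameterSet | Mapping[str, float]) -> tuple[float, ...]:
    values = params.values if isinstance(params, ParameterSet) else params
    return tuple(float(values[s]) for s in spec.symbols)


class DomainError(ValueError):
    """State lies outside the model's validity domain."""


def _check_validity(spec: ModelSpec, params, n1, n2) -> None:
    if spec.validity is None:
        return
    values = params.values if isinstance(params, ParameterSet) else params
    ok = np.asarray(spec.validity(values, np.asarray(n1, float), np.asarray(n2, float)))
    if not np.all(ok):
        raise DomainError(
            f"state outside validity domain of model {spec.id!r}: {spec.validity_text}"
        )


def valid_mask(model, params, n1, n2) -> np.ndarray:
    """Boolean mask of states where the model equations are defined."""
    spec = get_model(model)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    if spec.validity is None:
        return np.ones(np.broadcast(n1, n2).shape, bool)
    values = params.values if isinstance(params, ParameterSet) else params
    return np.asarray(spec.validity(values, n1, n2), bool)


def rhs(model, params, state, *, check: bool = True) -> np.ndarray:
    """Evaluate the per-species time derivatives at ``state = (N1, N2)``.

    Accepts scalars or broadcastable arrays for the two densities.
    """
    spec = get_model(model)
    comp = _compiled(spec.id)
    n1, n2 = np.asarray(state[0], float), np.asarray(state[1], float)
    if check:
        _check_validity(spec, params, n1, n2)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        f1, f2 = comp.rhs(n1, n2, *_vals(spec, params))
    f1 = np.broadcast_to(np.asarray(f1, float), np.broadcast(n1, n2).shape)
    f2 = np.broadcast_to(np.asarray(f2, float), np.broadcast(n1, n2).shape)
    if f1.shape == ():
        return np.array([float(f1), float(f2)])
    return np.stack([f1, f2])


def per_capita(model, params, state, *, check: bool = True) -> np.ndarray:
    """Per-capita growth rates ``g_i = f_i / N_i`` (symbolically cancelled)."""
    spec = get_model(model)
    comp = _compiled(spec.id)
    n1, n2 = np.asarray(state[0], float), np.asarray(state[1], float)
    if check:
        _check_validity(spec, params, n1, n2)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        g1, g2 = comp.percap(n1, n2, *_vals(spec, params))
    g1 = np.broadcast_to(np.asarray(g1, float), np.broadcast(n1, n2).shape)
    g2 = np.broadcast_to(np.asarray(g2, float), np.broadcast(n1, n2).shape)
    if g1.shape == ():
        return np.array([float(g1), float(g2)])
    return np.stack([g1, g2])


def jacobian(model, params, state, *, check: bool = True) -> np.ndarray:
    """Analytic 2x2 Jacobian of the right-hand side at ``state``."""
    spec = get_model(model)
    comp = _compiled(spec.id)
    n1, n2 = float(state[0]), float(state[1])
    if check:
        _check_validity(spec, params, n1, n2)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        j = comp.jac(n1, n2, *_vals(spec, params))
    return np.asarray(j, float)


def jacobian_fd(model, params, state) -> np.ndarray:
    """Central finite-difference Jacobian (independent numerical check)."""
    spec = get_model(model)
    x = np.asarray(state, float)
    out = np.empty((2, 2))
    root_eps = math.sqrt(np.finfo(float).eps)
    for k in range(2):
        h = root_eps * (1.0 + abs(x[k]))
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        fp = rhs(spec, params, xp, check=False)
        fm = rhs(spec, params, xm, check=False)
        out[:, k] = (fp - fm) / (2 * h)
    return out


def axis_invariant(model, params) -> tuple[bool, bool]:
    """Whether each coordinate axis ``N_i = 0`` is flow-invariant.

    Decided symbolically where possible; immigration-style terms that only
    vanish for particular parameter values (Thompson's ``I_i``) are resolved
    numerically against the supplied parameters.
    """
    spec = get_model(model)
    comp = _compiled(spec.id)
    values = params.values if isinstance(params, ParameterSet) else params
    out = []
    for expr in comp.axis_resid:
        if expr == 0:
            out.append(True)
            continue
        sub = expr.subs({sp.Symbol(k, real=True): float(v) for k, v in values.items()})
        sub = sp.simplify(sub)
        if sub == 0:
            out.append(True)
        elif sub.free_symbols - {N1, N2}:
            out.append(False)
        else:
            # residual depends on the partner density only; invariant iff it
            # vanishes identically there
            probe = [complex(sub.subs({N1: v, N2: v})) for v in (0.3, 1.7, 4.1)]
            out.append(all(abs(p) < 1e-12 for p in probe))
    return tuple(out)


_OBLIGACY_EPS = (1e-3, 1e-5, 1e-7)


def obligacy(model, params) -> dict[int, str]:
    """Per-species obligacy labels.

    Species ``i`` is *obligate* iff its per-capita growth rate has a
    non-positive limit as ``N_i -> 0+`` with the partner absent, i.e. it
    cannot invade an empty habitat alone.  Models carrying the historical
    carrying-capacity convention override this rule.
    """
    spec = get_model(model)
    out: dict[int, str] = {}
    if spec.obligacy_override is not None:
        values = params.values if isinstance(params, ParameterSet) else params
        out.update({i: lab for i, lab in spec.obligacy_override(values).items() if lab})
    for i in (1, 2):
        if i in out:
            continue
        limits = []
        for eps in _OBLIGACY_EPS:
            state = (eps, 0.0) if i == 1 else (0.0, eps)
            g = per_capita(spec, params, state, check=False)[i - 1]
            limits.append(g)
        g_lim = limits[-1]
        if np.isnan(g_lim):
            g_lim = limits[-2]
        if np.isneginf(g_lim):
            out[i] = "obligate"
        elif np.isposinf(g_lim):
            out[i] = "facultative"
        else:
            out[i] = "obligate" if g_lim <= 1e-9 else "facultative"
    return out


def registry_manifest() -> list[dict]:
    """Structured-text manifest of the registry (id, source, schema)."""
    _ensure_library_loaded()
    rows = []
    for mid in sorted(_REGISTRY):
        spec = _REGISTRY[mid]
        rows.append(
            {
                "id": spec.id,
                "source": spec.source,
                "notes": spec.notes,
                "parameters": [
                    {
                        "symbol": d.symbol,
                        "description": d.description,
                        "default": d.default,
                        "range": d.range_text(),
                    }
                    for d in spec.schema
                ],
            }
        )
    return rows
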