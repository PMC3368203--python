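"""Fractional-power autoregressive mapping models of cross-side perfusion coupling.

The model family relates the perfusion series of the two body sides through a
linear-in-parameters autoregression with a fractional-power basis,

    y(k) = a * y(k-1) + b * y(k-1)^0.3 + c * u(k) + d * u(k)^0.3,

where ``y`` is the series placed on the left-hand side (the declared model
input in the study design) and ``u`` the contemporaneous contralateral series.
Coefficients are identified by ordinary least squares, which is exact for this
model because it is linear in (a, b, c, d).

Two mapping modes are supported:

``regress-and-invert`` (default)
    Take the model literally: fit with the declared input side as regressand,
    then recover the mapped contralateral value at each k by solving the scalar
    static nonlinearity  c*x + d*x^0.3 = y(k) - a*y(k-1) - b*y(k-1)^0.3  for x
    with a bracketed root search.

``direct-regression``
    Swap the roles (contralateral side as regressand) and obtain mapped values
    by running the fitted recursion forward from a stated initial value.

Fractional powers of negative arguments (which arise when the model is probed
with a zero-mean standard signal) are evaluated with the real, odd extension
``sign(x) * |x|^p``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import NoRootError, RankDeficiencyError, StructuralError
from .protocol import GroupDataset

#: fixed fractional exponent of the regression basis
DEFAULT_POWER = 0.3

MODES = ("regress-and-invert", "direct-regression")

#: relative residual tolerance of the static-nonlinearity inversion
INVERT_RTOL = 1e-9

#: maximum number of bracket doublings in the root search
MAX_DOUBLINGS = 60


def signed_power(x, p: float):
    """Real odd extension of the fractional power: ``sign(x) * |x|**p``.

    Continuous, odd and strictly increasing in ``x`` for any ``p > 0``; accepts
    scalars or arrays.
    """
    if p <= 0:
        raise ValueError(f"exponent must be positive, got {p}")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** p
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MappingModel:
    """Identified coefficients of one cross-side mapping model plus fit metadata."""

    group: str
    direction: str
    mode: str
    a: float
    b: float
    c: float
    d: float
    power: float = DEFAULT_POWER
    n_rows: int = 0
    residual_sse: float = 0.0
    #: standard errors of (a, b, c, d) from the OLS covariance, if computed
    coef_se: tuple[float, float, float, float] | None = None
    #: free-run initial value for direct-regression mapping (mean of the
    #: training regressand); stated and configurable
    init_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise StructuralError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.residual_sse < 0:
            raise StructuralError("residual_sse must be non-negative")

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def to_json(self, **dump_kwargs) -> str:
        """Lossless JSON serialization (round-trips through :meth:`from_json`)."""
        payload = asdict(self)
        payload["coef_se"] = list(self.coef_se) if self.coef_se is not None else None
        dump_kwargs.setdefault("sort_keys", True)
        dump_kwargs.setdefault("indent", 2)
        return json.dumps(payload, **dump_kwargs)

    @classmethod
    def from_json(cls, text: str) -> "MappingModel":
        payload = json.loads(text)
        if payload.get("coef_se") is not None:
            payload["coef_se"] = tuple(payload["coef_se"])
        return cls(**payload)


def build_regression_rows(
    dataset: GroupDataset, mode: str = "regress-and-invert"
) -> tuple[np.ndarray, np.ndarray]:
    """Build the lagged design matrix and response vector for one group dataset.

    In ``regress-and-invert`` mode the regressand is the dataset's *input* side
    (the model as written places the declared input on the left-hand side) and
    the output side supplies the contemporaneous exogenous regressors; in
    ``direct-regression`` mode the roles are swapped.  Lags are taken strictly
    within per-subject blocks, so each block of length n contributes n - 1 rows.
    """
    if mode not in MODES:
        raise StructuralError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "regress-and-invert":
        y_all, u_all = dataset.input_values, dataset.output_values
    else:
        y_all, u_all = dataset.output_values, dataset.input_values

    rows, resp = [], []
    for sid, blk in dataset.blocks():
        y = y_all[blk]
        u = u_all[blk]
        if y.size < 2:
            raise StructuralError(
                f"subject {sid} has fewer than 2 pairs; cannot build lagged rows"
            )
        p = DEFAULT_POWER
        rows.append(
            np.column_stack(
                [y[:-1], signed_power(y[:-1], p), u[1:], signed_power(u[1:], p)]
            )
        )
        resp.append(y[1:])
    return np.vstack(rows), np.concatenate(resp)


def _collinear_columns(X: np.ndarray) -> tuple[int, ...]:
    """Columns dominating the smallest right-singular vector of the scaled design."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, _, vt = np.linalg.svd(X / norms, full_matrices=False)
    null = np.abs(vt[-1])
    return tuple(int(i) for i in np.flatnonzero(null > 0.25))


def fit_mapping_model(
    rows: np.ndarray,
    response: np.ndarray,
    *,
    group: str = "",
    direction: str = "L->R",
    mode: str = "regress-and-invert",
    power: float = DEFAULT_POWER,
    rcond: float = 1e-10,
) -> MappingModel:
    """Ordinary-least-squares fit of (a, b, c, d); deterministic for fixed input.

    The design must have full column rank at the relative condition threshold
    ``rcond``; a constant input makes the fractional-power columns collinear
    with their linear partners and is reported as such.
    """
    X = np.asarray(rows, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise StructuralError(f"design must have 4 columns, got shape {X.shape}")
    if X.shape[0] != y.size:
        raise StructuralError("design and response lengths differ")
    if X.shape[0] < 4:
        raise StructuralError(f"at least 4 rows required, got {X.shape[0]}")

    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        zero = tuple(int(i) for i in np.flatnonzero(norms == 0))
        raise RankDeficiencyError(f"design columns {zero} are identically zero", zero)
    sv = np.linalg.svd(X / norms, compute_uv=False)
    if sv[-1] < rcond * sv[0]:
        cols = _collinear_columns(X)
        raise RankDeficiencyError(
            f"design is rank deficient (condition {sv[0] / sv[-1]:.2e}); "
            f"columns {cols} are collinear (a constant regressor makes the "
            "fractional-power column indistinguishable from its linear partner)",
            cols,
        )

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    dof = X.shape[0] - 4
    se = None
    if dof > 0:
        sigma2 = sse / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = tuple(float(v) for v in np.sqrt(sigma2 * np.diag(xtx_inv)))
    return MappingModel(
        group=group,
        direction=direction,
        mode=mode,
        a=float(beta[0]),
        b=float(beta[1]),
        c=float(beta[2]),
        d=float(beta[3]),
        power=power,
        n_rows=int(X.shape[0]),
        residual_sse=sse,
        coef_se=se,
        init_value=float(np.mean(y)),
    )


@dataclass(frozen=True)
class InversionResult:
    """Root of the static nonlinearity, with multiplicity diagnostics."""

    root: float
    n_roots: int = 1
    bracket: tuple[float, float] = (0.0, 0.0)

    @property
    def multiple_roots(self) -> bool:
        return self.n_roots > 1

    def __float__(self) -> float:
        return self.root


def _static_g(c: float, d: float, power: float, x):
    return c * x + d * signed_power(x, power)


def invert_static_nonlinearity(
    c: float,
    d: float,
    target: float,
    power: float = DEFAULT_POWER,
    bracket_hint: float = 1.0,
) -> InversionResult:
    """Solve ``c*x + d*sign(x)|x|^power = target`` for x.

    For same-sign coefficients the map is strictly monotone and the unique root
    is found by bracket expansion from ``bracket_hint`` plus Brent's method.
    With mixed coefficient signs the map is non-monotone; all roots inside the
    expanded bracket are located on a sign-change grid and the one closest to
    ``bracket_hint`` is returned, with the total count flagged on the result.
    The residual satisfies ``|g(x) - target| <= 1e-9 * max(1, |target|)``.
    """
    if c == 0.0 and d == 0.0:
        raise ValueError("(c, d) must not both be zero")
    if bracket_hint <= 0:
        raise ValueError("bracket_hint must be positive")
    tol = INVERT_RTOL * max(1.0, abs(target))

    if c * d >= 0.0:
        # monotone branch: odd strictly monotone map, root sign = sign(target/slope)
        sign_flip = -1.0 if (c < 0 or (c == 0 and d < 0)) else 1.0
        cc, dd, tt = c * sign_flip, d * sign_flip, target * sign_flip
        if tt == 0.0:
            return InversionResult(0.0, 1, (0.0, 0.0))
        s = 1.0 if tt > 0 else -1.0
        ta = abs(tt)
        hi = bracket_hint
        for _ in range(MAX_DOUBLINGS + 1):
            if _static_g(cc, dd, power, hi) >= ta:
                break
            hi *= 2.0
        else:
            raise NoRootError(
                f"no bracket for target {target!r} within [0, {hi!r}]",
                interval=(0.0, hi),
            )
        root = brentq(
            lambda x: _static_g(cc, dd, power, x) - ta,
            0.0,
            hi,
            xtol=1e-300,
            rtol=8.882e-16,
            maxiter=300,
        )
        root *= s
        if abs(_static_g(c, d, power, root) - target) > tol:
            raise NoRootError(
                f"inversion residual exceeds tolerance at x={root!r}",
                interval=(0.0, hi),
            )
        return InversionResult(float(root), 1, (0.0, float(hi * s)))

    # mixed signs: non-monotone; locate every sign change on an expanding grid
    for m in range(8, MAX_DOUBLINGS + 1, 4):
        half = bracket_hint * 2.0**m
        grid = np.linspace(-half, half, 4097)
        vals = _static_g(c, d, power, grid) - target
        sign_changes = np.flatnonzero(np.diff(np.signbit(vals)))
        roots = []
        for i in sign_changes:
            lo_x, hi_x = grid[i], grid[i + 1]
            r = brentq(
                lambda x: _static_g(c, d, power, x) - target,
                lo_x,
                hi_x,
                xtol=1e-300,
                rtol=8.882e-16,
                maxiter=300,
            )
            roots.append(r)
        roots.extend(grid[np.flatnonzero(vals == 0.0)])
        roots = sorted(set(roots))
        if roots:
            best = min(roots, key=lambda r: abs(r - bracket_hint))
            if abs(_static_g(c, d, power, best) - target) <= tol:
                return InversionResult(float(best), len(roots), (-half, half))
    raise NoRootError(
        f"no sign change found for target {target!r} within [-{half!r}, {half!r}]",
        interval=(-half, half),
    )


def invert_static_nonlinearity_many(
    c: float,
    d: float,
    targets: np.ndarray,
    power: float = DEFAULT_POWER,
    bracket_hint: float = 1.0,
) -> np.ndarray:
    """Vectorized monotone inversion of the static nonlinearity for many targets.

    Requires same-sign (c, d); uses bracket doubling plus fixed-count bisection,
    which converges to machine precision and verifies the residual tolerance.
    Falls back to the scalar routine automatically when coefficients are mixed.
    """
    targets = np.asarray(targets, dtype=float)
    if c * d < 0.0:
        return _invert_many_mixed(c, d, targets, power, bracket_hint)
    if c == 0.0 and d == 0.0:
        raise ValueError("(c, d) must not both be zero")

    sign_flip = -1.0 if (c < 0 or (c == 0 and d < 0)) else 1.0
    cc, dd = c * sign_flip, d * sign_flip
    tt = targets * sign_flip
    s = np.sign(tt)
    ta = np.abs(tt)

    hi = np.full(ta.shape, float(bracket_hint))
    for _ in range(MAX_DOUBLINGS * 4):
        need = _static_g(cc, dd, power, hi) < ta
        if not need.any():
            break
        hi[need] *= 2.0
        if not np.isfinite(hi).all():
            k = int(np.argmax(~np.isfinite(hi)))
            raise NoRootError(
                "bracket expansion overflowed without enclosing the target",
                interval=(0.0, float(np.finfo(float).max)),
                k=k,
            )
    else:
        k = int(np.argmax(_static_g(cc, dd, power, hi) < ta))
        raise NoRootError(
            f"no bracket within [0, {hi.ravel()[0]!r}] for some targets",
            interval=(0.0, float(np.max(hi))),
            k=k,
        )
    lo = np.zeros_like(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        below = _static_g(cc, dd, power, mid) < ta
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    roots = s * 0.5 * (lo + hi)
    resid = np.abs(_static_g(c, d, power, roots) - targets)
    tol = INVERT_RTOL * np.maximum(1.0, np.abs(targets))
    bad = resid > tol
    if bad.any():
        k = int(np.argmax(bad))
        raise NoRootError(
            f"inversion residual exceeds tolerance at index {k}", k=k
        )
    return roots


def _invert_many_mixed(
    c: float, d: float, targets: np.ndarray, power: float, bracket_hint: float
) -> np.ndarray:
    """Vectorized inversion for mixed-sign (c, d).

    The map g(x) = c x + d sign(x)|x|^p is odd and non-monotone near the
    origin, but strictly monotone outside the stationary points at
    |x| = x0 = (p |d| / |c|)^(1/(1-p)).  Targets beyond the local extremum
    |g(x0)| have a unique root on the outer monotone branch and are bisected
    en masse; the few targets inside the fold (where up to three roots exist)
    fall back to the scalar routine, which picks the root nearest the hint.
    """
    # orient so the outer branches are increasing (|x| large: the larger-power
    # term dominates; for p < 1 that is the linear term)
    sign_flip = -1.0 if (abs(power) < 1.0 and c < 0) or (power > 1.0 and d < 0) else 1.0
    cc, dd = c * sign_flip, d * sign_flip
    tt = targets * sign_flip

    x0 = (power * abs(dd) / abs(cc)) ** (1.0 / (1.0 - power)) if power < 1.0 else (
        (abs(cc) / (power * abs(dd))) ** (1.0 / (power - 1.0))
    )
    g0 = abs(_static_g(cc, dd, power, x0))
    # outer-branch zero: beyond x1 the map has the sign of its argument
    x1 = x0
    while _static_g(cc, dd, power, x1) <= 0.0:
        x1 *= 2.0

    out = np.empty_like(tt)
    outer = np.abs(tt) > 2.0 * g0
    if outer.any():
        s = np.sign(tt[outer])
        ta = np.abs(tt[outer])
        lo = np.full(ta.shape, x1)
        hi = np.maximum(lo * 2.0, bracket_hint)
        for _ in range(MAX_DOUBLINGS * 4):
            need = _static_g(cc, dd, power, hi) < ta
            if not need.any():
                break
            hi[need] *= 2.0
            if not np.isfinite(hi).all():
                k = int(np.argmax(~np.isfinite(hi)))
                raise NoRootError(
                    "bracket expansion overflowed without enclosing the target", k=k
                )
        else:
            k = int(np.argmax(_static_g(cc, dd, power, hi) < ta))
            raise NoRootError("no outer bracket for some targets", k=k)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            below = _static_g(cc, dd, power, mid) < ta
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        # g_{cc,dd} = sign_flip * g_{c,d} and tt = sign_flip * targets, so the
        # oriented roots solve the original problem directly
        out[outer] = s * 0.5 * (lo + hi)
    if (~outer).any():
        for i in np.flatnonzero(~outer):
            out[i] = invert_static_nonlinearity(
                cc, dd, float(tt[i]), power, bracket_hint
            ).root
    resid = np.abs(_static_g(c, d, power, out) - targets)
    tol = INVERT_RTOL * np.maximum(1.0, np.abs(targets))
    bad = resid > tol
    if bad.any():
        k = int(np.argmax(bad))
        raise NoRootError(f"inversion residual exceeds tolerance at index {k}", k=k)
    return out


def map_series(
    model: MappingModel,
    input_series: Sequence[float] | np.ndarray,
    lag_seed_value: float | None = None,
    block_sizes: Sequence[int] | None = None,
) -> np.ndarray:
    """Map an input series through a fitted model to the estimated contralateral series.

    ``regress-and-invert`` mode solves, at each k,

        c*x + d*x^0.3 = input(k) - a*input(k-1) - b*input(k-1)^0.3

    for the mapped value x = f*(k).  ``direct-regression`` mode runs the fitted
    recursion forward from ``model.init_value``.  Subject boundaries (given as
    ``block_sizes``) restart the lag, so without a ``lag_seed_value`` each block
    contributes one fewer mapped point than input samples; with a seed (e.g. the
    standard signal evaluated at k-1 of the first index) every sample maps.
    Root-search failures propagate as :class:`NoRootError` carrying the
    offending sample index.
    """
    u = np.asarray(input_series, dtype=float)
    if block_sizes is None:
        block_sizes = (u.size,)
    if sum(block_sizes) != u.size:
        raise StructuralError("block sizes must partition the input series")
    min_len = 1 if lag_seed_value is not None else 2
    out: list[np.ndarray] = []
    start = 0
    for size in block_sizes:
        blk = u[start : start + size]
        start += size
        if blk.size < min_len:
            raise StructuralError(
                f"input block of length {blk.size} is too short to map"
            )
        if lag_seed_value is not None:
            prev = np.concatenate([[float(lag_seed_value)], blk[:-1]])
            cur = blk
            offset = 0
        else:
            prev = blk[:-1]
            cur = blk[1:]
            offset = 1
        if model.mode == "regress-and-invert":
            targets = cur - model.a * prev - model.b * signed_power(prev, model.power)
            hint = max(float(np.mean(np.abs(blk))), 1.0)
            try:
                out.append(
                    invert_static_nonlinearity_many(
                        model.c, model.d, targets, model.power, hint
                    )
                )
            except NoRootError as err:
                raise NoRootError(
                    f"mapping failed at k={offset + (err.k or 0)}: {err}",
                    interval=err.interval,
                    k=offset + (err.k or 0),
                ) from err
        else:
            if model.init_value is None:
                raise StructuralError(
                    "direct-regression mapping requires model.init_value"
                )
            f = np.empty(cur.size)
            prev_val = float(model.init_value)
            for i, uk in enumerate(cur):
                prev_val = (
                    model.a * prev_val
                    + model.b * signed_power(prev_val, model.power)
                    + model.c * uk
                    + model.d * signed_power(uk, model.power)
                )
                f[i] = prev_val
            out.append(f)
    return np.concatenate(out)
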