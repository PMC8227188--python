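"""Parametric foveal-pit models and smoothing methods.

Six model families from the foveal-pit literature are implemented together
with two non-parametric smoothers.  Each family is identified by the first
author of the publication that proposed it; the exact functional forms
below are reconstructions honoring each model's published parameter count,
fitted region and fixed-point behaviour — they are not numerical replicas
of the original implementations.

===========  =========================  ==================  ========
model id     family                     fitted region       n params
===========  =========================  ==================  ========
``dubis``    difference of 2 Gaussians  diametric profile      6
``ding``     polynomial + Gaussian      whole 2-D map          8
``scheibe``  2nd derivative of          per direction,         4
             a Gaussian (radial)        center-anchored
``liu``      sloped piecemeal Gaussian  pit region only        6
``yadav``    cubic Bezier curves        per direction,        2+3
                                        center+rim pinned
``breher``   sum of 3 Gaussians         diametric profile      9
===========  =========================  ==================  ========

B-scan-region models are fitted on *diametric* profiles: direction k of
the radial set is joined with direction k+12 (radii mirrored to negative
lateral coordinates), giving 12 two-sided profiles of 201 samples that
preserve each model's two-sided shape assumptions.

Fitting is nonlinear least squares (scipy trust-region reflective) with at
most 1000 residual evaluations and a tolerance of 1e-6 on both the
residuals and the coefficient steps.  Initial values are data driven; on
non-convergence up to 5 seeded jittered restarts are tried and the lowest
SSE solution kept.  Width-like coefficients are bounded positive;
amplitudes are unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .preprocessing import RadialProfileSet

MAX_ITERATIONS = 1000
FIT_TOL = 1e-6
N_RESTARTS = 5

LOESS_SPAN_RANGE = (0.01, 0.50)
MOVAVG_WINDOW_RANGE = (5, 60)

_WIDTH_LB = 1e-3  # lower bound for width-like coefficients (mm or mm^-gamma)


@dataclass(frozen=True)
class ModelSpec:
    """Static description of a model or smoothing method."""

    model_id: str
    family: str
    region: str  # bscan | trt_map | radial | center_rim | smoother
    n_params: int
    fixes_center: bool = False
    fixes_rim: bool = False


MODEL_SPECS: dict[str, ModelSpec] = {
    s.model_id: s
    for s in (
        ModelSpec("dubis", "difference of two Gaussians", "bscan", 6),
        ModelSpec("ding", "polynomial surface and Gaussian", "trt_map", 8),
        ModelSpec("scheibe", "second derivative of a Gaussian", "radial", 4,
                  fixes_center=True),
        ModelSpec("liu", "sloped piecemeal Gaussian", "bscan", 6),
        ModelSpec("yadav", "cubic Bezier curves", "center_rim", 5,
                  fixes_center=True, fixes_rim=True),
        ModelSpec("breher", "sum of three Gaussians", "bscan", 9),
        ModelSpec("loess", "local quadratic regression", "smoother", 1),
        ModelSpec("movavg", "centered moving average", "smoother", 1),
    )
}


def get_model_spec(model_id: str) -> ModelSpec:
    try:
        return MODEL_SPECS[model_id]
    except KeyError:
        raise ValueError(
            f"unknown model {model_id!r}; expected one of {sorted(MODEL_SPECS)}"
        ) from None


@dataclass
class FitResult:
    """Outcome of fitting one model to a radial profile set."""

    model_id: str
    coefficients: np.ndarray  # (n_units, n_params) or (n_params,) for trt_map
    fitted_values_um: np.ndarray  # same shape as the input profile set
    rmse_um: float
    converged: bool
    n_iterations: int
    unit_converged: np.ndarray | None = field(default=None, repr=False)
    #: boolean mask of the samples the model was actually fitted on; only
    #: the pit-region model (liu) uses a strict subset of the profile set
    fit_region_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.rmse_um < 0:
            raise ValueError("rmse_um must be non-negative")
        if self.n_iterations > MAX_ITERATIONS:
            raise ValueError("iteration count exceeds the configured maximum")


def rim_index(values: np.ndarray) -> int:
    """Index of the rim (argmax of TRT) excluding the center sample.

    Undefined (NaN) samples — out-of-hull tails of a decentered scan —
    are ignored.
    """
    values = np.asarray(values)
    return 1 + int(np.nanargmax(values[1:]))


# ---------------------------------------------------------------------------
# model evaluation


def _eval_dubis(c: np.ndarray, x: np.ndarray) -> np.ndarray:
    z0, x0, a1, s1, a2, s2 = c
    u = x - x0
    return z0 + a1 * np.exp(-u**2 / (2 * s1**2)) - a2 * np.exp(-u**2 / (2 * s2**2))


def _eval_ding(c: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    p00, p10, p01, p20, p02, a, sx, sy = c
    poly = p00 + p10 * x + p01 * y + p20 * x**2 + p02 * y**2
    return poly - a * np.exp(-(x**2 / (2 * sx**2) + y**2 / (2 * sy**2)))


def _eval_scheibe_rise(c: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Rise above the (anchored) center value; exactly 0 at r = 0."""
    mu, sigma, gamma, alpha = c
    rg = np.power(np.maximum(r, 0.0), gamma)
    e = np.exp(-mu * rg)
    return mu * sigma**2 * rg * e + alpha * (1.0 - e)


def _eval_liu(c: np.ndarray, x: np.ndarray) -> np.ndarray:
    z0, x0, w, s, a, sigma = c
    u = x - x0
    base = z0 + s * u
    d = np.maximum(np.abs(u) - w, 0.0)
    return base + a * (1.0 - np.exp(-(d**2) / (2 * sigma**2)))


def _eval_breher(c: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    for a, b, cw in np.asarray(c, dtype=float).reshape(3, 3):
        out += a * np.exp(-((x - b) ** 2) / (2 * cw**2))
    return out


def cubic_bezier(ordinates: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cubic Bezier ordinate at parameter t in [0, 1].

    The control abscissae sit at thirds of the segment, so the curve's
    lateral coordinate is linear in t and the ordinate is the Bernstein
    combination of the four control ordinates.
    """
    p0, p1, p2, p3 = ordinates
    mt = 1.0 - t
    return mt**3 * p0 + 3 * mt**2 * t * p1 + 3 * mt * t**2 * p2 + t**3 * p3


def evaluate_model(spec: ModelSpec | str, coefficients, coords) -> np.ndarray:
    """Evaluate a model family at the requested coordinates.

    ``coords`` is a lateral coordinate array for B-scan models, a radius
    array for ``scheibe`` (returning the rise above the anchored center),
    an ``(x, y)`` pair for ``ding``, and a parameter array t in [0, 1] for
    a single ``yadav`` Bezier segment whose 4 control ordinates are given.
    """
    if isinstance(spec, str):
        spec = get_model_spec(spec)
    c = np.asarray(coefficients, dtype=float)
    n_expected = {"dubis": 6, "ding": 8, "scheibe": 4, "liu": 6, "breher": 9, "yadav": 4}
    if spec.model_id not in n_expected:
        raise ValueError(f"evaluate_model does not support {spec.model_id!r}")
    if c.size != n_expected[spec.model_id]:
        raise ValueError(
            f"{spec.model_id} expects {n_expected[spec.model_id]} coefficients, got {c.size}"
        )
    if spec.model_id == "ding":
        x, y = coords
        return _eval_ding(c, np.asarray(x, float), np.asarray(y, float))
    coords = np.asarray(coords, dtype=float)
    return {
        "dubis": _eval_dubis,
        "scheibe": _eval_scheibe_rise,
        "liu": _eval_liu,
        "breher": _eval_breher,
        "yadav": cubic_bezier,
    }[spec.model_id](c, coords)


# ---------------------------------------------------------------------------
# diametric profile assembly


def diametric_profiles(profiles: RadialProfileSet) -> tuple[np.ndarray, np.ndarray]:
    """Join opposite directions into two-sided profiles.

    Returns ``(x, values)`` where x runs from -r_max to +r_max (2*n_r - 1
    samples) and row j combines direction j (positive side) with direction
    j + n/2 (negative side); the center sample is shared.
    """
    n_dir = profiles.n_directions
    if n_dir % 2:
        raise ValueError("diametric pairing needs an even number of directions")
    half = n_dir // 2
    r = profiles.radii_mm
    x = np.concatenate([-r[::-1], r[1:]])
    v = profiles.values_um
    rows = [np.concatenate([v[j + half][::-1], v[j][1:]]) for j in range(half)]
    return x, np.vstack(rows)


def _scatter_diametric(fitted_diam: np.ndarray, n_r: int, n_dir: int) -> np.ndarray:
    """Distribute fitted diametric rows back onto the (n_dir, n_r) layout."""
    half = n_dir // 2
    out = np.empty((n_dir, n_r))
    for j in range(half):
        row = fitted_diam[j]
        out[j] = row[n_r - 1:]
        out[j + half] = row[: n_r][::-1]
    return out


# ---------------------------------------------------------------------------
# nonlinear least-squares engine


def _solve_nls(residual_fn, x0, bounds, seed) -> tuple[np.ndarray, bool, int]:
    """least_squares with seeded jittered restarts; keeps the lowest SSE."""
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    best = None

    def attempt(start):
        start = np.clip(start, lo, hi)
        # TRF requires a strictly interior start
        span = np.where(np.isfinite(hi) & np.isfinite(lo), (hi - lo) * 1e-3, 1e-6)
        start = np.clip(start, lo + span, hi - span) if np.any(np.isfinite(lo)) else start
        return least_squares(
            residual_fn, start, bounds=bounds, method="trf",
            ftol=FIT_TOL, xtol=FIT_TOL, max_nfev=MAX_ITERATIONS,
        )

    res = attempt(np.asarray(x0, dtype=float))
    best = res
    tries = 0
    while (not best.success or best.status == 0) and tries < N_RESTARTS:
        tries += 1
        jitter = np.asarray(x0, dtype=float) * (1 + 0.2 * rng.standard_normal(len(x0)))
        jitter = jitter + 0.05 * rng.standard_normal(len(x0))
        res = attempt(jitter)
        if res.cost < best.cost or (res.success and not best.success):
            best = res
    converged = bool(best.success and best.status != 0)
    return best.x, converged, int(best.nfev)


# ---------------------------------------------------------------------------
# per-family initialization and canonicalization


def _edges_mean(y: np.ndarray) -> float:
    k = max(3, y.size // 20)
    return float(np.mean(np.concatenate([y[:k], y[-k:]])))


def _init_dubis(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    z0 = _edges_mean(y)
    center = float(y[np.argmin(np.abs(x))])
    rim = float(y.max())
    a1 = 2 * max(rim - z0, 5.0)
    a2 = z0 + a1 - center
    return np.array([z0, 0.0, a1, 1.0, a2, 0.35])


def _canon_dubis(c: np.ndarray) -> np.ndarray:
    # (z0,x0,A1,s1,A2,s2) and (z0,x0,-A2,s2,-A1,s1) are the same function;
    # fix the gauge so the wider Gaussian comes first.
    z0, x0, a1, s1, a2, s2 = c
    if s1 < s2:
        return np.array([z0, x0, -a2, s2, -a1, s1])
    return c


def _init_ding(xy: tuple[np.ndarray, np.ndarray], y: np.ndarray) -> np.ndarray:
    x, yy = xy
    r = np.hypot(x, yy)
    edge = float(np.mean(y[r > 0.8 * r.max()]))
    center = float(y[np.argmin(r)])
    return np.array([edge, 0.0, 0.0, 0.0, 0.0, max(edge - center, 5.0), 0.35, 0.35])


def _init_scheibe(r: np.ndarray, rise: np.ndarray) -> np.ndarray:
    i_rim = rim_index(rise)
    h = max(float(rise[i_rim]), 1.0)
    rr = max(float(r[i_rim]), 0.2)
    gamma = 2.0
    mu = rr**-gamma
    sigma = np.sqrt(h * np.e)
    alpha = max(float(rise[-1]), 0.5 * h)
    return np.array([mu, sigma, gamma, alpha])


def _init_liu(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    center = float(y[np.argmin(np.abs(x))])
    rim = float(y.max())
    rr = max(float(np.abs(x[np.argmax(y)])), 0.3)
    return np.array([center, 0.0, 0.25 * rr, 0.0, max(rim - center, 5.0), 0.4 * rr])


def _init_breher(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # two broad positive Gaussians at the rims carry the mound; a narrow
    # negative one at the center carves the pit
    center = float(y[np.argmin(np.abs(x))])
    rim = float(y.max())
    rr = max(float(np.abs(x[np.argmax(y)])), 0.3)
    a_side = 0.55 * rim
    at0 = 2 * a_side * np.exp(-(rr**2) / (2 * 0.9**2))
    return np.array([a_side, -rr, 0.9, center - at0, 0.0, 0.45, a_side, rr, 0.9])


def _canon_breher(c: np.ndarray) -> np.ndarray:
    """Sort Gaussian components by center (the sum is permutation invariant)."""
    comps = np.asarray(c, dtype=float).reshape(3, 3)
    order = np.lexsort((comps[:, 2], comps[:, 1]))
    return comps[order].ravel()


_BOUNDS = {
    "dubis": (np.array([-np.inf, -np.inf, -np.inf, _WIDTH_LB, -np.inf, _WIDTH_LB]),
              np.full(6, np.inf)),
    "ding": (np.array([-np.inf] * 6 + [_WIDTH_LB, _WIDTH_LB]), np.full(8, np.inf)),
    # scheibe: mu -> 0 collapses the model onto a degenerate power-law ridge
    # (exp(-mu r^gamma) ~ 1 - mu r^gamma) where alpha diverges; mu >= 0.05
    # still admits rim radii beyond the 2 mm analysis region. gamma < 0.5
    # would put a cusp at the anchored center.
    "scheibe": (np.array([0.05, _WIDTH_LB, 0.5, -np.inf]),
                np.array([np.inf, np.inf, 10.0, np.inf])),
    # liu: the pit center must lie near the scan center and the flat bottom
    # cannot swallow the whole profile, otherwise the Gaussian walls never
    # engage and the model degenerates to a line
    "liu": (np.array([-np.inf, -1.0, _WIDTH_LB, -np.inf, -np.inf, _WIDTH_LB]),
            np.array([np.inf, 1.0, 1.5, np.inf, np.inf, 5.0])),
    "breher": (np.array([-np.inf, -np.inf, _WIDTH_LB] * 3), np.full(9, np.inf)),
}


# ---------------------------------------------------------------------------
# fitting drivers


def _fit_bscan_family(profiles, model_id, init, seed):
    x, vals = diametric_profiles(profiles)
    n_units = vals.shape[0]
    eval_fn = {"dubis": _eval_dubis, "liu": _eval_liu, "breher": _eval_breher}[model_id]
    init_fn = {"dubis": _init_dubis, "liu": _init_liu, "breher": _init_breher}[model_id]
    coeffs, fitted, conv, iters = [], [], [], []
    region = np.ones_like(vals, dtype=bool)
    for j in range(n_units):
        y = vals[j]
        if model_id == "liu":
            # fit only the pit region between the two detected rims
            n_r = profiles.radii_mm.size
            i_pos = rim_index(y[n_r - 1:])
            i_neg = rim_index(y[: n_r][::-1])
            sl = slice(n_r - 1 - i_neg, n_r + i_pos)
            region[j] = False
            region[j, sl] = True
        region[j] &= np.isfinite(y)
        x_fit, y_fit = x[region[j]], y[region[j]]
        x0 = np.asarray(init, float) if init is not None else init_fn(x_fit, y_fit)
        c, ok, ni = _solve_nls(
            lambda c: eval_fn(c, x_fit) - y_fit, x0, _BOUNDS[model_id], seed + j
        )
        if model_id == "dubis":
            c = _canon_dubis(c)
        elif model_id == "breher":
            c = _canon_breher(c)
        coeffs.append(c)
        fitted.append(eval_fn(c, x))
        conv.append(ok)
        iters.append(ni)
    n_r, n_dir = profiles.radii_mm.size, profiles.n_directions
    fitted_map = _scatter_diametric(np.vstack(fitted), n_r, n_dir)
    region_map = _scatter_diametric(region.astype(float), n_r, n_dir) > 0.5
    return np.vstack(coeffs), fitted_map, np.array(conv), max(iters), region_map


def _fit_ding(profiles, init, seed):
    r = profiles.radii_mm[None, :]
    ang = profiles.angles_rad[:, None]
    x = (r * np.cos(ang)).ravel()
    y = (r * np.sin(ang)).ravel()
    z = profiles.values_um.ravel()
    ok_mask = np.isfinite(z)
    x, y, z = x[ok_mask], y[ok_mask], z[ok_mask]
    x0 = np.asarray(init, float) if init is not None else _init_ding((x, y), z)
    c, ok, ni = _solve_nls(
        lambda c: _eval_ding(c, x, y) - z, x0, _BOUNDS["ding"], seed
    )
    r = profiles.radii_mm[None, :]
    x = (r * np.cos(ang)).ravel()
    y = (r * np.sin(ang)).ravel()
    fitted = _eval_ding(c, x, y).reshape(profiles.values_um.shape)
    return c, fitted, np.array([ok]), ni


def _fit_scheibe(profiles, init, seed):
    r = profiles.radii_mm
    v = profiles.values_um
    center = v[0, 0]
    coeffs, fitted, conv, iters = [], [], [], []
    for k in range(profiles.n_directions):
        rise = v[k] - center
        fin = np.isfinite(rise)
        r_fit, rise_fit = r[fin], rise[fin]
        x0 = np.asarray(init, float) if init is not None else _init_scheibe(r_fit, rise_fit)
        c, ok, ni = _solve_nls(
            lambda c: _eval_scheibe_rise(c, r_fit) - rise_fit,
            x0, _BOUNDS["scheibe"], seed + k,
        )
        row = center + _eval_scheibe_rise(c, r)
        row[0] = center  # anchored: bit-identical center value
        coeffs.append(c)
        fitted.append(row)
        conv.append(ok)
        iters.append(ni)
    return np.vstack(coeffs), np.vstack(fitted), np.array(conv), max(iters)


def _fit_yadav(profiles, init, seed):
    """Two pinned cubic Bezier segments per direction (linear least squares).

    Inner segment (center to rim): both endpoint ordinates pinned to the
    raw data, 2 free control ordinates.  Outer segment (rim to the profile
    end): start pinned at the raw rim, 3 free values.  With the control
    abscissae at thirds the problem is linear and solved exactly.
    """
    r = profiles.radii_mm
    v = profiles.values_um
    coeffs, fitted = [], []
    for k in range(profiles.n_directions):
        y = v[k]
        i_rim = rim_index(y)
        row = np.empty_like(y)
        # inner: pinned p0 = y[0], p3 = y[i_rim]
        t = r[: i_rim + 1] / r[i_rim]
        mt = 1 - t
        basis = np.column_stack([3 * mt**2 * t, 3 * mt * t**2])
        target = y[: i_rim + 1] - mt**3 * y[0] - t**3 * y[i_rim]
        p12, *_ = np.linalg.lstsq(basis, target, rcond=None)
        row[: i_rim + 1] = cubic_bezier([y[0], p12[0], p12[1], y[i_rim]], t)
        # outer: pinned p0 = y[i_rim]; free p1, p2, p3
        if i_rim < y.size - 1:
            t2 = (r[i_rim:] - r[i_rim]) / (r[-1] - r[i_rim])
            mt2 = 1 - t2
            basis2 = np.column_stack([3 * mt2**2 * t2, 3 * mt2 * t2**2, t2**3])
            target2 = y[i_rim:] - mt2**3 * y[i_rim]
            fin = np.isfinite(target2)  # out-of-hull tail samples are skipped
            p_out, *_ = np.linalg.lstsq(basis2[fin], target2[fin], rcond=None)
            row[i_rim:] = cubic_bezier([y[i_rim], *p_out], t2)
        else:
            p_out = np.array([y[i_rim]] * 3)
        row[0] = y[0]        # pinned, bit-identical
        row[i_rim] = y[i_rim]
        coeffs.append(np.concatenate([p12, p_out]))
        fitted.append(row)
    n = profiles.n_directions
    return np.vstack(coeffs), np.vstack(fitted), np.ones(n, bool), 1


def fit_model(
    profiles: RadialProfileSet,
    spec: ModelSpec | str,
    init: np.ndarray | None = None,
    *,
    seed: int = 0,
    span: float = 0.2,
    window: int = 15,
) -> FitResult:
    """Fit a pit model (or apply a smoother) to a radial profile set.

    ``span`` and ``window`` are only consulted for the ``loess`` and
    ``movavg`` smoothers.  Non-convergence after the seeded restarts is
    reported through ``converged=False`` / ``unit_converged``, never
    silently.
    """
    if isinstance(spec, str):
        spec = get_model_spec(spec)
    if spec.region == "smoother":
        return smooth_profiles(profiles, spec.model_id, span=span, window=window)
    _check_defined_fraction(profiles)

    region = None
    if spec.region == "bscan":
        coeffs, fitted, conv, iters, region = _fit_bscan_family(
            profiles, spec.model_id, init, seed
        )
    elif spec.model_id == "ding":
        coeffs, fitted, conv, iters = _fit_ding(profiles, init, seed)
    elif spec.model_id == "scheibe":
        coeffs, fitted, conv, iters = _fit_scheibe(profiles, init, seed)
    elif spec.model_id == "yadav":
        coeffs, fitted, conv, iters = _fit_yadav(profiles, init, seed)
    else:  # pragma: no cover
        raise ValueError(f"structurally invalid spec: {spec}")

    defined = np.isfinite(profiles.values_um)
    rmse = float(np.sqrt(np.mean((fitted - profiles.values_um)[defined] ** 2)))
    return FitResult(
        model_id=spec.model_id,
        coefficients=coeffs,
        fitted_values_um=fitted,
        rmse_um=rmse,
        converged=bool(np.all(conv)),
        n_iterations=int(iters),
        unit_converged=conv,
        fit_region_mask=region if region is not None else defined,
    )


def _check_defined_fraction(profiles: RadialProfileSet, limit: float = 0.05) -> None:
    """Small out-of-hull tails are tolerated (skipped sample-wise); more
    undefined data than the resampling stage itself allows is an error."""
    frac = float(np.mean(~np.isfinite(profiles.values_um)))
    if frac > limit:
        raise ValueError(
            f"{frac:.1%} of profile samples are undefined (limit {limit:.0%})"
        )
    if not np.all(np.isfinite(profiles.values_um[:, 0])):
        raise ValueError("center sample is undefined")


# ---------------------------------------------------------------------------
# smoothing methods


def smooth_loess(profile: np.ndarray, span_fraction: float) -> np.ndarray:
    """LOESS: local second-degree polynomial regression with tricube weights.

    At each sample the nearest ``span_fraction * n`` points (at least 5)
    are fitted with a quadratic weighted by the tricube kernel of scaled
    distance; the smoothed value is the local fit at that sample.
    """
    lo, hi = LOESS_SPAN_RANGE
    if not (lo <= span_fraction <= hi):
        raise ValueError(f"span_fraction must be in [{lo}, {hi}], got {span_fraction}")
    y = np.asarray(profile, dtype=float)
    n = y.size
    k = max(5, int(round(span_fraction * n)))
    if n < k:
        raise ValueError(f"profile has {n} samples; needs at least {k} for this span")
    x = np.arange(n, dtype=float)
    out = np.empty(n)
    for i in range(n):
        left = min(max(i - (k - 1) // 2, 0), n - k)
        sl = slice(left, left + k)
        d = np.abs(x[sl] - i)
        w = (1 - (d / d.max()) ** 3) ** 3
        u = x[sl] - i
        design = np.column_stack([np.ones(k), u, u**2])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[sl] * sw, rcond=None)
        out[i] = beta[0]
    return out


def smooth_movavg(profile: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window shrinking at the edges.

    Odd windows are symmetric; even windows take one extra trailing
    sample.  Interior samples average exactly ``window`` values.
    """
    lo, hi = MOVAVG_WINDOW_RANGE
    if not (lo <= window <= hi):
        raise ValueError(f"window must be in [{lo}, {hi}], got {window}")
    y = np.asarray(profile, dtype=float)
    n = y.size
    if window > n:
        raise ValueError(f"window {window} exceeds profile length {n}")
    hl = (window - 1) // 2
    hr = window // 2
    csum = np.concatenate([[0.0], np.cumsum(y)])
    i = np.arange(n)
    a = np.maximum(i - hl, 0)
    b = np.minimum(i + hr, n - 1)
    return (csum[b + 1] - csum[a]) / (b - a + 1)


def smooth_profiles(
    profiles: RadialProfileSet,
    method: str,
    *,
    span: float = 0.2,
    window: int = 15,
) -> FitResult:
    """Apply a smoother to each diametric profile and repackage as a fit."""
    if method not in ("loess", "movavg"):
        raise ValueError(f"unknown smoother {method!r}")
    _check_defined_fraction(profiles)
    x, vals = diametric_profiles(profiles)
    fn = (lambda row: smooth_loess(row, span)) if method == "loess" else (
        lambda row: smooth_movavg(row, window)
    )
    hyper = span if method == "loess" else window
    sm = np.full_like(vals, np.nan)
    for j, row in enumerate(vals):
        fin = np.flatnonzero(np.isfinite(row))
        a, b = fin[0], fin[-1] + 1
        if not np.all(np.isfinite(row[a:b])):
            raise ValueError("undefined samples inside a profile; cannot smooth")
        sm[j, a:b] = fn(row[a:b])  # NaN tails stay undefined
    fitted = _scatter_diametric(sm, profiles.radii_mm.size, profiles.n_directions)
    defined = np.isfinite(profiles.values_um) & np.isfinite(fitted)
    rmse = float(np.sqrt(np.mean((fitted - profiles.values_um)[defined] ** 2)))
    n_units = vals.shape[0]
    return FitResult(
        model_id=method,
        coefficients=np.full((n_units, 1), float(hyper)),
        fitted_values_um=fitted,
        rmse_um=rmse,
        converged=True,
        n_iterations=0,
        unit_converged=np.ones(n_units, bool),
    )
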