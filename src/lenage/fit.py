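"""Maximum-likelihood fitting of the length-frequency mixture model.

Four candidate model structures are supported (seasonal vs traditional
growth x fixed vs variable size-at-age variance).  The likelihood
kernel is configurable because length-composition models are fit under
several conventions in practice:

``multinomial`` (default)
    Per month, observed bin counts are multinomial draws from the
    normalized predicted composition: -sum_i n_i * ln(p_hat_i).  For
    this kernel the per-month proportions-at-age are profiled out
    exactly by an inner EM pass (the model is a finite mixture per
    month), so the outer optimizer only searches the growth and sigma
    parameters.
``poisson``
    Bin counts independent Poisson with mean equal to predicted counts.
``concentrated_normal``
    Least squares on counts with the error variance concentrated out:
    (n_cells/2) * ln(SSE/n_cells).

Parameter counting for information criteria follows the spreadsheet
convention of the source analysis: proportions are counted as
4 ages x n_months even though only 3 per month are free on the simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .growth import GrowthParams
from .lfreq import (
    N_AGE_CLASSES,
    AgeStructure,
    BinGrid,
    LengthHistogram,
    age_means_and_masses,
    masses_stack,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "GridSearchResult",
    "negative_log_likelihood",
    "count_parameters",
    "fit_model",
    "sensitivity_run",
    "random_start_grid_search",
]

EPS = 1e-12

# t_s and t_b are periodic (reduced mod 1 by GrowthParams); their search
# interval extends past [0, 1) so optima near the wrap point are not
# pinned to an artificial boundary
_GROWTH_BOUNDS = {
    "L_inf": (50.0, 2000.0),
    "K": (1e-3, 3.0),
    "C": (0.0, 1.0),
    "t_s": (-1.0, 2.0),
    "t_b": (-1.0, 2.0),
}
_START_RANGES = {
    "L_inf": (300.0, 700.0),
    "K": (0.05, 1.5),
    "C": (0.0, 1.0),
    "t_s": (0.0, 1.0),
    "t_b": (0.0, 1.0),
}
_SIGMA_BOUNDS = (1.0, 100.0)
_DEFAULT_START = {"L_inf": 500.0, "K": 0.5, "C": 0.5, "t_s": 0.5, "t_b": 0.5}
_DEFAULT_SIGMA_START = 25.0


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate model.

    ``fixed_params`` pins named growth parameters (conventionally
    L_inf at the maximum observed length, t0 at 0); pinned parameters
    are excluded from the free vector and from the parameter count.
    """

    seasonal: bool
    variance_at_age: str  # "fixed" | "variable"
    fixed_params: dict = field(default_factory=lambda: {"L_inf": 448.0, "t0": 0.0})
    grid: BinGrid = field(default_factory=BinGrid)
    n_months: int = 6
    objective: str = "multinomial"

    def __post_init__(self) -> None:
        if self.variance_at_age not in ("fixed", "variable"):
            raise ValueError("variance_at_age must be 'fixed' or 'variable'")
        if self.objective not in ("multinomial", "poisson", "concentrated_normal"):
            raise ValueError(f"unknown objective {self.objective!r}")

    @property
    def free_growth_names(self) -> tuple[str, ...]:
        names = ["L_inf", "K", "C", "t_s", "t_b"] if self.seasonal else ["L_inf", "K", "t_b"]
        return tuple(n for n in names if n not in self.fixed_params)

    @property
    def n_sigmas(self) -> int:
        return N_AGE_CLASSES if self.variance_at_age == "variable" else 1


@dataclass
class FitResult:
    params: GrowthParams
    sigmas: tuple[float, ...]
    proportions: list[AgeStructure]
    neg_log_lik: float
    K_params: int
    converged: bool
    n_evals: int
    start_point: np.ndarray
    spec: ModelSpec

    def theta(self) -> np.ndarray:
        """The free outer parameter vector at the optimum."""
        vals = [getattr(self.params, n) for n in self.spec.free_growth_names]
        vals += list(self.sigmas[: self.spec.n_sigmas])
        return np.array(vals)

    def proportions_table(self, months) -> pd.DataFrame:
        """Monthly proportions-at-age plus their sample-size-weighted mean."""
        rows = []
        for m, p in zip(months, self.proportions):
            rows.append([m.label, *p.normalized(), m.N_t])
        df = pd.DataFrame(rows, columns=["month", "age0", "age1", "age2", "age3", "n"])
        n = df["n"].to_numpy(dtype=float)
        wmean = [
            float((df[f"age{a}"].to_numpy() * n).sum() / n.sum()) for a in range(4)
        ]
        df.loc[len(df)] = ["weighted_mean", *wmean, int(n.sum())]
        return df


@dataclass
class GridSearchResult:
    fits: list
    best: FitResult
    objective_spread: float
    multimodal: bool


def weighted_mean_proportions(P: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Sample-size-weighted average of monthly proportion rows."""
    P = np.asarray(P, dtype=float)
    n = np.asarray(n, dtype=float)
    return (P * n[:, None]).sum(axis=0) / n.sum()


# ---------------------------------------------------------------------------
# likelihood kernels


def _check_aligned(obs: list[LengthHistogram], pred: list[LengthHistogram]) -> None:
    if len(obs) != len(pred):
        raise ValueError("observed and predicted sets differ in length")
    for o, p in zip(obs, pred):
        if o.grid != p.grid:
            raise ValueError(f"grid mismatch for month {o.month.label!r}")
        if o.month.label != p.month.label:
            raise ValueError(f"month mismatch: {o.month.label!r} vs {p.month.label!r}")


def negative_log_likelihood(
    obs: list[LengthHistogram],
    pred: list[LengthHistogram],
    objective: str = "multinomial",
) -> float:
    """Compare observed and predicted histogram sets under a kernel.

    Additive over months.  Predicted bin probabilities are floored at
    1e-12 so an observed count in a zero-prediction bin penalizes the
    fit rather than raising.
    """
    _check_aligned(obs, pred)
    total = 0.0
    for o, p in zip(obs, pred):
        n = o.counts
        mu = p.counts
        if objective == "multinomial":
            if n.sum() == 0:
                continue
            phat = np.maximum(mu / max(mu.sum(), EPS), EPS)
            total += -float((n * np.log(phat)).sum())
        elif objective == "poisson":
            total += float((mu - n * np.log(np.maximum(mu, EPS))).sum())
        elif objective == "concentrated_normal":
            # accumulated below over all months jointly
            pass
        else:
            raise ValueError(f"unknown objective {objective!r}")
    if objective == "concentrated_normal":
        sse = sum(float(((o.counts - p.counts) ** 2).sum()) for o, p in zip(obs, pred))
        ncells = sum(o.counts.size for o in obs)
        total = 0.5 * ncells * math.log(max(sse, EPS) / ncells)
    return total


def count_parameters(spec: ModelSpec) -> int:
    """Free-parameter count under the source analysis's convention.

    Growth parameters not pinned in ``fixed_params``, plus the sigma
    parameters (1 shared or 4 at-age), plus proportions counted as
    4 age classes x n_months.
    """
    return len(spec.free_growth_names) + spec.n_sigmas + N_AGE_CLASSES * spec.n_months


# ---------------------------------------------------------------------------
# EM profiling of per-month mixture weights (multinomial kernel)


def _em_profile(
    counts: np.ndarray,
    masses: np.ndarray,
    w0: np.ndarray | None = None,
    max_iter: int = 3000,
    tol: float = 1e-11,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximize the per-month multinomial likelihoods over the age mixes.

    ``counts`` is (months x bins), ``masses`` (months x ages x bins) of
    normal bin masses.  The normalized composition of month t is
    p_hat_i = sum_a P_a m_ai / sum_a P_a Q_a with Q_a the within-grid
    mass of component a; substituting w_a proportional to P_a Q_a
    reduces each month to standard mixture-weight EM on grid-normalized
    components, run vectorized over months with optional warm start.
    Returns (total nll, weights w, proportions P on the simplex).
    """
    counts = np.asarray(counts, dtype=float)
    N = counts.sum(axis=1)
    live = N > 0
    Q = np.maximum(masses.sum(axis=2), EPS)  # (months, ages)
    comp = masses / Q[:, :, None]
    w = (
        np.full((counts.shape[0], N_AGE_CLASSES), 1.0 / N_AGE_CLASSES)
        if w0 is None
        else w0.copy()
    )
    Nsafe = np.where(live, N, 1.0)[:, None]
    prev = np.inf
    nll = np.inf
    for _ in range(max_iter):
        mix = np.maximum(np.einsum("ma,mab->mb", w, comp), EPS)
        nll = -float((counts[live] * np.log(mix[live])).sum())
        w = np.einsum("mab,mb->ma", comp, counts / mix) * w / Nsafe
        w[~live] = 1.0 / N_AGE_CLASSES
        if prev - nll < tol:
            break
        prev = nll
    P = w / Q
    Psum = P.sum(axis=1, keepdims=True)
    P = np.where(Psum > 0, P / np.maximum(Psum, EPS), 1.0 / N_AGE_CLASSES)
    return nll, w, P


def _profile_month(n: np.ndarray, masses: np.ndarray) -> tuple[float, np.ndarray]:
    """Single-month convenience wrapper around :func:`_em_profile`."""
    nll, _, P = _em_profile(n[None, :], masses[None, :, :])
    return nll, P[0]


def _softmax(z: np.ndarray) -> np.ndarray:
    full = np.concatenate([[0.0], z])  # first logit anchored at 0
    e = np.exp(full - full.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# model fitting


class _Packer:
    """Maps the free outer vector <-> (GrowthParams, sigmas[, logits])."""

    def __init__(self, spec: ModelSpec, with_proportions: bool):
        self.spec = spec
        self.growth_names = spec.free_growth_names
        self.with_proportions = with_proportions
        self.n_growth = len(self.growth_names)
        self.n_sig = spec.n_sigmas
        self.n_logits = (N_AGE_CLASSES - 1) * spec.n_months if with_proportions else 0
        self.size = self.n_growth + self.n_sig + self.n_logits
        self.bounds = [_GROWTH_BOUNDS[n] for n in self.growth_names]
        self.bounds += [_SIGMA_BOUNDS] * self.n_sig
        self.bounds += [(-20.0, 20.0)] * self.n_logits

    def unpack(self, theta: np.ndarray):
        gvals = dict(zip(self.growth_names, theta[: self.n_growth]))
        fixed = dict(self.spec.fixed_params)
        fixed.setdefault("t0", 0.0)
        if not self.spec.seasonal:
            gvals.setdefault("C", 0.0)
            gvals.setdefault("t_s", 0.0)
        params = GrowthParams(**{**fixed, **gvals})
        sig = theta[self.n_growth : self.n_growth + self.n_sig]
        sigmas = np.repeat(sig, N_AGE_CLASSES) if self.n_sig == 1 else np.asarray(sig)
        props = None
        if self.with_proportions:
            logits = theta[self.n_growth + self.n_sig :].reshape(
                self.spec.n_months, N_AGE_CLASSES - 1
            )
            props = np.stack([_softmax(z) for z in logits])
        return params, sigmas, props

    def default_start(self, rng: np.random.Generator | None = None) -> np.ndarray:
        theta = np.empty(self.size)
        for i, nme in enumerate(self.growth_names):
            theta[i] = _DEFAULT_START[nme]
        theta[self.n_growth : self.n_growth + self.n_sig] = _DEFAULT_SIGMA_START
        theta[self.n_growth + self.n_sig :] = 0.0
        if rng is not None:
            ranges = [_START_RANGES[n] for n in self.growth_names]
            ranges += [_SIGMA_BOUNDS] * self.n_sig
            lo = np.array([r[0] for r in ranges])
            hi = np.array([r[1] for r in ranges])
            theta[: lo.size] = lo + (hi - lo) * rng.uniform(size=lo.size)
            theta[self.n_growth + self.n_sig :] = rng.normal(
                scale=0.5, size=self.n_logits
            )
        return theta


def _objective_factory(data: list[LengthHistogram], spec: ModelSpec, packer: _Packer):
    """Build the outer objective.

    For the multinomial kernel the per-month age mixes are profiled out
    by EM at every evaluated point; the returned callable also supplies
    the gradient via the envelope theorem (the gradient of the profiled
    objective equals the partial gradient of the fixed-mix objective at
    the inner optimum), so the expensive EM runs once per optimizer
    point rather than once per finite-difference probe.  The inner
    problem is convex per month, so warm-starting the EM (floored away
    from the absorbing zero-weight states) changes nothing but speed.
    """
    months = [h.month for h in data]
    counts = np.stack([h.counts for h in data])
    lo = np.array([b[0] for b in packer.bounds])
    hi = np.array([b[1] for b in packer.bounds])
    state = {"evals": 0, "w": None}

    def masses_for(theta) -> np.ndarray:
        # clip: finite-difference probes may sit a hair outside bounds
        params, sigmas, props = packer.unpack(np.clip(theta, lo, hi))
        return (
            masses_stack(params, months, spec.grid, sigmas, seasonal=spec.seasonal),
            props,
        )

    def nll_fixed_w(theta, w) -> float:
        masses, _ = masses_for(theta)
        comp = masses / np.maximum(masses.sum(axis=2, keepdims=True), EPS)
        mix = np.einsum("ma,mab->mb", w, comp)
        val = -float((counts * np.log(np.maximum(mix, EPS))).sum())
        return val if np.isfinite(val) else 1e12

    def fun_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        state["evals"] += 1
        w0 = state["w"]
        if w0 is not None:
            w0 = np.maximum(w0, 1e-3)
            w0 /= w0.sum(axis=1, keepdims=True)
        masses, _ = masses_for(theta)
        nll, w, _ = _em_profile(counts, masses, w0=w0, max_iter=20000, tol=1e-12)
        state["w"] = w
        grad = np.empty_like(theta)
        for i in range(theta.size):
            h = 1e-6 * (1.0 + abs(theta[i]))
            tp = theta.copy()
            tp[i] += h
            tm = theta.copy()
            tm[i] -= h
            grad[i] = (nll_fixed_w(tp, w) - nll_fixed_w(tm, w)) / (2.0 * h)
        if not np.isfinite(nll):
            return 1e12, np.zeros_like(theta)
        return nll, grad

    def fn(theta: np.ndarray) -> float:
        state["evals"] += 1
        masses, props = masses_for(theta)
        Nt = np.array([m.N_t for m in months], dtype=float)
        mu = Nt[:, None] * np.einsum("ma,mab->mb", props, masses)
        if spec.objective == "poisson":
            total = float((mu - counts * np.log(np.maximum(mu, EPS))).sum())
        else:
            ncells = counts.size
            sse = float(((counts - mu) ** 2).sum())
            total = 0.5 * ncells * math.log(max(sse, EPS) / ncells)
        return total if np.isfinite(total) else 1e12

    if spec.objective == "multinomial":
        return fun_and_grad, True, state
    return fn, False, state


def _extract_result(
    data: list[LengthHistogram],
    spec: ModelSpec,
    packer: _Packer,
    theta: np.ndarray,
    nll: float,
    converged: bool,
    n_evals: int,
    start: np.ndarray,
) -> FitResult:
    params, sigmas, props = packer.unpack(theta)
    proportions = []
    if spec.objective == "multinomial":
        nll = 0.0  # recompute from fully converged cold EM at the optimum
    for j, h in enumerate(data):
        if spec.objective == "multinomial":
            _, masses = age_means_and_masses(
                params, h.month, spec.grid, sigmas, seasonal=spec.seasonal
            )
            month_nll, P = _profile_month(h.counts, masses)
            nll += month_nll
        else:
            P = props[j]
        proportions.append(AgeStructure(tuple(P)))
    return FitResult(
        params=params,
        sigmas=tuple(float(s) for s in sigmas),
        proportions=proportions,
        neg_log_lik=float(nll),
        K_params=count_parameters(spec),
        converged=converged,
        n_evals=n_evals,
        start_point=np.asarray(start, dtype=float),
        spec=spec,
    )


def fit_model(
    data: list[LengthHistogram],
    spec: ModelSpec,
    start: np.ndarray | None = None,
    n_starts: int = 25,
    seed: int = 0,
    options: dict | None = None,
) -> FitResult:
    """Fit one candidate model by bounded quasi-Newton with multi-start.

    The first start is ``start`` if given, else a fixed central point;
    the remaining ``n_starts - 1`` starts are drawn uniformly within the
    parameter bounds from a generator seeded with ``seed``, so a fit is
    fully reproducible from (data, spec, start, n_starts, seed).
    ``options`` overrides the L-BFGS-B settings (e.g. looser ftol/gtol
    for large simulation studies).
    """
    if not any(h.total > 0 for h in data):
        raise ValueError("need at least one month with observations")
    if len(data) != spec.n_months:
        raise ValueError(
            f"spec declares {spec.n_months} months but data has {len(data)}"
        )
    packer = _Packer(spec, with_proportions=spec.objective != "multinomial")
    fn, has_jac, state = _objective_factory(data, spec, packer)
    rng = np.random.default_rng(seed)
    starts = [np.asarray(start, dtype=float) if start is not None else packer.default_start()]
    starts += [packer.default_start(rng) for _ in range(max(0, n_starts - 1))]

    best = None
    any_success = False
    for s in starts:
        state["w"] = None  # fresh inner warm-start per outer start
        res = minimize(
            fn, s, jac=has_jac, method="L-BFGS-B", bounds=packer.bounds,
            options=options or {"maxiter": 800, "ftol": 1e-13, "gtol": 1e-9},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.copy(), s)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("optimizer failed on all starts")
    nll, theta, s0 = best
    return _extract_result(
        data, spec, packer, theta, nll, any_success, state["evals"], s0
    )


def sensitivity_run(
    data: list[LengthHistogram],
    base: FitResult,
    param_name: str,
    delta: float,
    n_starts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Refit with one parameter clamped at base * (1 + delta).

    ``param_name`` is a growth parameter name or ``sigma``/``sigma_<a>``.
    All remaining parameters are re-optimized from the base optimum.
    """
    spec = base.spec
    if param_name in ("L_inf", "K", "C", "t_s", "t_b"):
        if param_name in spec.fixed_params:
            value = spec.fixed_params[param_name] * (1.0 + delta)
        else:
            value = getattr(base.params, param_name) * (1.0 + delta)
        new_spec = ModelSpec(
            seasonal=spec.seasonal,
            variance_at_age=spec.variance_at_age,
            fixed_params={**spec.fixed_params, param_name: value},
            grid=spec.grid,
            n_months=spec.n_months,
            objective=spec.objective,
        )
        packer = _Packer(new_spec, with_proportions=spec.objective != "multinomial")
        base_theta = base.theta()
        drop = list(spec.free_growth_names).index(param_name) if param_name in spec.free_growth_names else None
        start = np.delete(base_theta, drop) if drop is not None else base_theta
        if packer.with_proportions:
            start = np.concatenate([start, np.zeros(packer.n_logits)])
        return fit_model(data, new_spec, start=start, n_starts=n_starts, seed=seed)
    raise ValueError(f"unknown parameter {param_name!r}")


def random_start_grid_search(
    data: list[LengthHistogram],
    base: FitResult,
    n_starts: int = 25,
    jitter: float = 0.25,
    seed: int = 0,
    tol: float = 1e-3,
) -> GridSearchResult:
    """Robustness check: refit from starts jittered +/- ``jitter`` of the base.

    Flags multimodality when converged objectives spread more than
    ``tol`` — a well-identified fit should land on one optimum from
    every start.
    """
    spec = base.spec
    packer = _Packer(spec, with_proportions=spec.objective != "multinomial")
    rng = np.random.default_rng(seed)
    base_theta = base.theta()
    if packer.with_proportions:
        base_theta = np.concatenate([base_theta, np.zeros(packer.n_logits)])
    lo = np.array([b[0] for b in packer.bounds])
    hi = np.array([b[1] for b in packer.bounds])
    fits = []
    for _ in range(n_starts):
        s = base_theta * (1.0 + rng.uniform(-jitter, jitter, size=base_theta.size))
        s = np.clip(s, lo, hi)
        fits.append(fit_model(data, spec, start=s, n_starts=1, seed=0))
    objs = np.array([f.neg_log_lik for f in fits])
    best = fits[int(np.argmin(objs))]
    spread = float(objs.max() - objs.min())
    return GridSearchResult(
        fits=fits, best=best, objective_spread=spread, multimodal=spread > tol
    )
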