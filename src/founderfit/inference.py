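"""Maximum-likelihood fitting, bootstrap intervals, and model selection.

Fitting maximizes the per-pair Poisson composite log-likelihood, summed over
datasets, by bounded global stochastic search (differential evolution) with
a deterministic seed, followed by a Nelder-Mead polish.  Population sizes
are searched on a log10 scale.  Inter-parameter constraints (``d <= T_b - 1``,
``N_b <= N_a - 1`` for the two-population model) and model-invariant
violations are handled by a sentinel objective value that orders below every
finite likelihood.

Confidence intervals use the parametric bootstrap: every observed bin count
is redrawn as Poisson with mean equal to the observed count, and the model
is refit.  Model selection compares the single- and two-population fits via
a bootstrap null distribution of the log-likelihood gain.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .demography import Model, SinglePopModel, TwoPopModel
from .likelihood import joint_loglik, poisson_composite_loglik
from .segments import GenomeMap, SegmentCountTable, expected_bin_counts

__all__ = [
    "TIED",
    "ParameterSpace",
    "FitResult",
    "ModelSelectionResult",
    "default_space",
    "fit",
    "refit_fixed_subset",
    "bootstrap_ci",
    "model_selection_bootstrap",
]

logger = logging.getLogger(__name__)

PARAM_ORDER = {
    "single": ("N_a", "N_b", "T_b", "d", "N_c"),
    "two_pop": ("N_a", "N_b", "T_b", "d", "N_c", "f", "N_g"),
}
LOG_SCALE_PARAMS = frozenset({"N_a", "N_b", "N_c", "N_g"})

# The model is discrete in generations: the likelihood is piecewise in the
# epoch timings (a continuous shift of T_b or d only matters when an epoch
# boundary crosses an integer generation), so the timings are searched on
# the integer grid.
INTEGER_PARAMS = frozenset({"T_b", "d"})

#: sentinel for "N_g tracks N_b"
TIED = "tied"

SENTINEL = -1e18

DEFAULT_BOUNDS = {
    "N_a": (500.0, 1e5),
    "N_b": (50.0, 1e5),
    "T_b": (20.0, 100.0),
    "d": (1.0, 60.0),
    "N_c": (1e4, 1e8),
    "f": (0.01, 0.99),
    "N_g": (50.0, 1e5),
}

DEFAULT_DE_OPTIONS = dict(
    popsize=15,
    maxiter=250,
    tol=1e-7,
    mutation=(0.5, 1.0),
    recombination=0.7,
    init="latinhypercube",
    updating="immediate",
)


@dataclass(frozen=True)
class ParameterSpace:
    """Bounds, fixed values, and scale for the searched parameters."""

    model_type: str
    bounds: Dict[str, Tuple[float, float]]
    fixed: Dict[str, object] = field(default_factory=dict)
    log_scale: frozenset = LOG_SCALE_PARAMS
    integer: frozenset = INTEGER_PARAMS

    def __post_init__(self) -> None:
        if self.model_type not in PARAM_ORDER:
            raise ValueError(f"unknown model type {self.model_type!r}")
        names = PARAM_ORDER[self.model_type]
        for name in names:
            if name in self.fixed:
                continue
            if name not in self.bounds:
                raise ValueError(f"parameter {name} has neither bounds nor a fixed value")
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")
        for name in self.fixed:
            if name not in names:
                raise ValueError(f"fixed parameter {name} not in model {self.model_type}")

    @property
    def free_names(self) -> Tuple[str, ...]:
        return tuple(n for n in PARAM_ORDER[self.model_type] if n not in self.fixed)

    def transformed_bounds(self) -> List[Tuple[float, float]]:
        out = []
        for name in self.free_names:
            lo, hi = self.bounds[name]
            if name in self.log_scale:
                out.append((np.log10(lo), np.log10(hi)))
            else:
                out.append((lo, hi))
        return out

    def decode(self, x: Sequence[float]) -> Dict[str, float]:
        """Full parameter dict from a transformed free-parameter vector."""
        params: Dict[str, object] = dict(self.fixed)
        for name, val in zip(self.free_names, x):
            v = 10.0 ** val if name in self.log_scale else float(val)
            if name in self.integer:
                v = float(round(v))
            params[name] = v
        if params.get("N_g") == TIED:
            params["N_g"] = params["N_b"]
        return {k: float(v) for k, v in params.items()}

    def encode(self, params: Dict[str, float]) -> np.ndarray:
        x = []
        for name in self.free_names:
            v = params[name]
            x.append(np.log10(v) if name in self.log_scale else v)
        return np.asarray(x, dtype=float)

    def clip(self, x: np.ndarray) -> np.ndarray:
        b = np.asarray(self.transformed_bounds())
        return np.clip(x, b[:, 0], b[:, 1])


def default_space(
    model_type: str,
    fixed: Optional[Dict[str, object]] = None,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
) -> ParameterSpace:
    """The package's default search space for a model type.

    For the two-population model ``N_g`` is tied to ``N_b`` unless fixed or
    bounded explicitly.
    """
    fx = dict(fixed or {})
    bd = dict(DEFAULT_BOUNDS)
    bd.update(bounds or {})
    if model_type == "two_pop" and "N_g" not in fx and "N_g" not in (bounds or {}):
        fx["N_g"] = TIED
    bd = {k: v for k, v in bd.items() if k in PARAM_ORDER[model_type] and k not in fx}
    return ParameterSpace(model_type=model_type, bounds=bd, fixed=fx)


def _build_model(model_type: str, params: Dict[str, float]) -> Optional[Model]:
    # explicit inter-parameter constraints, then the model's own invariants
    if params["d"] > params["T_b"] - 1.0:
        return None
    try:
        if model_type == "single":
            return SinglePopModel(
                N_a=params["N_a"], N_b=params["N_b"], T_b=params["T_b"],
                d=params["d"], N_c=params["N_c"],
            )
        if params["N_b"] > params["N_a"] - 1.0:
            return None
        return TwoPopModel(
            N_a=params["N_a"], N_b=params["N_b"], T_b=params["T_b"],
            d=params["d"], N_c=params["N_c"], f=params["f"], N_g=params["N_g"],
        )
    except ValueError:
        return None


class _Objective:
    """Negative joint per-pair log-likelihood over a transformed vector."""

    def __init__(
        self,
        datasets: Sequence[SegmentCountTable],
        space: ParameterSpace,
        genome: GenomeMap,
    ):
        self.datasets = list(datasets)
        self.space = space
        self.genome = genome
        self.n_evals = 0

    def loglik(self, params: Dict[str, float]) -> float:
        model = _build_model(self.space.model_type, params)
        if model is None:
            return SENTINEL
        values = []
        for ds in self.datasets:
            try:
                lam = expected_bin_counts(
                    model, ds.sampling, self.genome, ds.bins, ds.pair_count
                )
            except ValueError:
                return SENTINEL
            lv = poisson_composite_loglik(ds, lam)
            if not lv.is_finite:
                return SENTINEL
            values.append(lv)
        return joint_loglik(*values)

    def __call__(self, x: np.ndarray) -> float:
        self.n_evals += 1
        return -self.loglik(self.space.decode(x))


@dataclass
class FitResult:
    """Point estimates plus optimizer diagnostics and optional intervals."""

    model_type: str
    estimates: Dict[str, float]
    fixed: Dict[str, float]
    loglik: float
    n_evals: int
    seed: int
    converged: bool
    space: ParameterSpace
    ci: Optional[Dict[str, Tuple[float, float]]] = None

    @property
    def params(self) -> Dict[str, float]:
        return {**self.fixed, **self.estimates}

    @property
    def model(self) -> Model:
        return _build_model(self.model_type, self.params)

    def to_dict(self) -> dict:
        return {
            "model_type": self.model_type,
            "estimates": self.estimates,
            "fixed": self.fixed,
            "loglik": self.loglik,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "converged": self.converged,
            "ci": {k: list(v) for k, v in self.ci.items()} if self.ci else None,
        }


def _resolved_fixed(space: ParameterSpace, params: Dict[str, float]) -> Dict[str, float]:
    return {k: params[k] for k in space.fixed}


def _polish(objective: _Objective, x0: np.ndarray, maxiter: int = 400):
    bounds = objective.space.transformed_bounds()
    res = minimize(
        objective,
        objective.space.clip(np.asarray(x0, dtype=float)),
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
    )
    return res


def _polish_continuous(
    objective: _Objective, x: np.ndarray, cont_idx: Sequence[int], maxiter: int = 300
) -> Tuple[np.ndarray, float]:
    """Nelder-Mead over the continuous coordinates, integers held fixed."""
    if not cont_idx:
        return x, float(objective(x))
    bounds_all = objective.space.transformed_bounds()

    def sub(xc):
        full = x.copy()
        full[list(cont_idx)] = xc
        return objective(full)

    res = minimize(
        sub,
        x[list(cont_idx)],
        method="Nelder-Mead",
        bounds=[bounds_all[i] for i in cont_idx],
        options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-11},
    )
    full = x.copy()
    full[list(cont_idx)] = res.x
    return full, float(res.fun)


def _refine_integer_cells(
    objective: _Objective, x0: np.ndarray, f0: float, window: int = 10
) -> Tuple[np.ndarray, float]:
    """Windowed grid search over the integer epoch-timing parameters.

    The likelihood is piecewise in the timings, and the bottleneck onset
    and duration compensate each other along narrow, interleaved valleys
    with several local optima, which defeats greedy descent.  Every integer
    cell within ``window`` of the stochastic-search optimum is scored with
    a coarse polish of the continuous size parameters; the best-ranked
    cells are then polished fully.
    """
    space = objective.space
    free = space.free_names
    int_idx = [i for i, n in enumerate(free) if n in space.integer]
    cont_idx = [i for i, n in enumerate(free) if n not in space.integer]
    if not int_idx:
        return x0, f0
    bounds = space.transformed_bounds()
    best_x, best_f = x0.copy(), f0
    for _ in range(4):
        centers = [int(round(best_x[i])) for i in int_idx]
        best_x, best_f = _grid_pass(
            objective, best_x, best_f, int_idx, cont_idx, bounds, centers, window
        )
        new_cells = [int(round(best_x[i])) for i in int_idx]
        if new_cells == centers:  # fixed point of the window center
            break
    return best_x, best_f


def _grid_pass(objective, x0, f0, int_idx, cont_idx, bounds, centers, window):
    space = objective.space
    ranges = [
        range(
            max(int(math.ceil(bounds[i][0])), c - window),
            min(int(math.floor(bounds[i][1])), c + window) + 1,
        )
        for i, c in zip(int_idx, centers)
    ]
    # Coarse pass over all cells, warm-starting the size polish from the
    # best already-polished neighboring cell (adjacent optima are close).
    polished: Dict[Tuple[int, ...], Tuple[float, np.ndarray]] = {}
    for combo in itertools.product(*ranges):
        seed_x = x0
        best_nb = None
        # axis and diagonal neighbors: the valleys run diagonally
        for offset in itertools.product((-1, 0, 1), repeat=len(combo)):
            if all(o == 0 for o in offset):
                continue
            nb = tuple(v + o for v, o in zip(combo, offset))
            if nb in polished and (best_nb is None or polished[nb][0] < best_nb[0]):
                best_nb = polished[nb]
        if best_nb is not None:
            seed_x = best_nb[1]
        cand = seed_x.copy()
        for i, v in zip(int_idx, combo):
            cand[i] = float(v)
        params = space.decode(cand)
        if params["d"] > params["T_b"] - 1.0:
            continue
        cand, fc = _polish_continuous(objective, cand, cont_idx, maxiter=100)
        polished[combo] = (fc, cand)
    scored = sorted(polished.values(), key=lambda t: t[0])
    best_x, best_f = x0.copy(), f0
    for fc, cand in scored[:12]:
        cand, fc = _polish_continuous(objective, cand, cont_idx, maxiter=800)
        if fc < best_f:
            best_x, best_f = cand, fc
    # cells can hide secondary size basins; retry the leaders seeded from
    # the best continuous values found anywhere
    for fc, cand in scored[:12]:
        cand = cand.copy()
        cand[list(cont_idx)] = best_x[list(cont_idx)]
        cand, fc = _polish_continuous(objective, cand, cont_idx, maxiter=400)
        if fc < best_f:
            best_x, best_f = cand, fc
    return best_x, best_f


def fit(
    datasets: Sequence[SegmentCountTable],
    space: ParameterSpace,
    seed: int = 0,
    genome: Optional[GenomeMap] = None,
    de_options: Optional[dict] = None,
    refine: bool = True,
) -> FitResult:
    """Maximum-composite-likelihood fit by seeded differential evolution.

    The objective is the per-pair composite log-likelihood summed over
    ``datasets``.  With an empty free set the fixed point is evaluated
    directly.  Two runs with the same seed return identical results.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    genome = genome or GenomeMap.default()
    objective = _Objective(datasets, space, genome)
    free = space.free_names
    if not free:
        params = space.decode(())
        ll = objective.loglik(params)
        if not np.isfinite(ll) or ll <= SENTINEL:
            raise ValueError("fixed parameter point is infeasible")
        return FitResult(
            model_type=space.model_type,
            estimates={},
            fixed=_resolved_fixed(space, params),
            loglik=ll,
            n_evals=objective.n_evals,
            seed=seed,
            converged=True,
            space=space,
        )
    opts = dict(DEFAULT_DE_OPTIONS)
    opts.update(de_options or {})
    result = differential_evolution(
        objective,
        bounds=space.transformed_bounds(),
        seed=seed,
        polish=False,
        **opts,
    )
    best_x, best_fun = result.x, result.fun
    pol = _polish(objective, best_x)
    if pol.fun < best_fun:
        best_x, best_fun = pol.x, pol.fun
    if refine:
        best_x, best_fun = _refine_integer_cells(objective, best_x, best_fun)
    params = space.decode(best_x)
    estimates = {k: params[k] for k in free}
    return FitResult(
        model_type=space.model_type,
        estimates=estimates,
        fixed=_resolved_fixed(space, params),
        loglik=-float(best_fun),
        n_evals=objective.n_evals,
        seed=seed,
        converged=bool(result.success or pol.success),
        space=space,
    )


def refit_fixed_subset(
    prior_fit: FitResult,
    free: Sequence[str],
    datasets: Sequence[SegmentCountTable],
    seed: int = 0,
    genome: Optional[GenomeMap] = None,
    de_options: Optional[dict] = None,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
) -> FitResult:
    """Refit a parameter subset, fixing the rest to a prior fit's values.

    This is the building block of the constrained fits: e.g. freeing
    ``(N_a, N_b)`` against ancient ROH to fit a narrower bottleneck, or
    freeing ``T_b`` for a longer one, then freeing ``(d, N_c)`` against
    modern IBD — each step is one call; sequencing is the caller's pipeline.
    """
    free = tuple(free)
    if not free:
        raise ValueError("free set must be non-empty")
    names = PARAM_ORDER[prior_fit.model_type]
    for name in free:
        if name not in names:
            raise ValueError(f"unknown parameter {name}")
    prior_params = prior_fit.params
    fixed = {n: prior_params[n] for n in names if n not in free}
    bd = dict(prior_fit.space.bounds)
    bd.update(bounds or {})
    bd.update({n: DEFAULT_BOUNDS[n] for n in free if n not in bd})
    space = ParameterSpace(
        model_type=prior_fit.model_type,
        bounds={k: v for k, v in bd.items() if k in free},
        fixed=fixed,
    )
    return fit(datasets, space, seed=seed, genome=genome, de_options=de_options)


def _perturb_counts(
    datasets: Sequence[SegmentCountTable], rng: np.random.Generator
) -> List[SegmentCountTable]:
    """Parametric-bootstrap resample: K_b -> Poisson(K_b) per bin."""
    return [replace(ds, counts=rng.poisson(ds.counts)) for ds in datasets]


def _refit_near(
    objective: _Objective,
    x_hat: np.ndarray,
    space: ParameterSpace,
    de_seed: int,
    de_options: Optional[dict],
):
    """Local refit from the point estimate; full-space DE restart on failure."""
    res = _polish(objective, x_hat)
    if np.isfinite(res.fun) and res.fun < -SENTINEL / 2:
        return res.x, res.fun
    opts = dict(DEFAULT_DE_OPTIONS)
    opts.update({"popsize": 8, "maxiter": 60})
    opts.update(de_options or {})
    res = differential_evolution(
        objective,
        bounds=space.transformed_bounds(),
        seed=de_seed,
        polish=False,
        **opts,
    )
    return res.x, res.fun


def bootstrap_ci(
    fit_result: FitResult,
    datasets: Sequence[SegmentCountTable],
    n_replicates: int = 100,
    seed: int = 0,
    genome: Optional[GenomeMap] = None,
    de_options: Optional[dict] = None,
    max_failure_fraction: float = 0.2,
) -> FitResult:
    """Parametric-bootstrap 95% intervals ([2.5, 97.5] percentiles).

    Each replicate redraws every observed bin count as Poisson with mean
    equal to the observed count and refits the free parameters, starting
    from the point estimate's neighborhood (full-space restart on failure).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    genome = genome or GenomeMap.default()
    space = fit_result.space
    free = space.free_names
    if not free:
        raise ValueError("no free parameters to bootstrap")
    x_hat = space.encode(fit_result.params)
    rng = np.random.default_rng(seed)
    draws: List[np.ndarray] = []
    failures = 0
    for _ in range(n_replicates):
        rep = _perturb_counts(datasets, rng)
        objective = _Objective(rep, space, genome)
        de_seed = int(rng.integers(2**31 - 1))
        try:
            x, fun = _refit_near(objective, x_hat, space, de_seed, de_options)
        except Exception:  # noqa: BLE001 - replicate failures are tallied
            failures += 1
            continue
        if not np.isfinite(fun) or fun >= -SENTINEL / 2:
            failures += 1
            continue
        params = space.decode(x)
        draws.append(np.array([params[k] for k in free]))
    if failures > max_failure_fraction * n_replicates:
        raise RuntimeError(
            f"{failures}/{n_replicates} bootstrap replicates failed"
        )
    if failures:
        logger.warning("%d/%d bootstrap replicates failed and were excluded",
                       failures, n_replicates)
    mat = np.vstack(draws)
    lo, hi = np.percentile(mat, [2.5, 97.5], axis=0)
    ci = {name: (float(l), float(h)) for name, l, h in zip(free, lo, hi)}
    return dataclasses.replace(fit_result, ci=ci)


@dataclass
class ModelSelectionResult:
    p_value: float
    delta_observed: float
    delta_null: np.ndarray
    single_fit: FitResult
    two_pop_fit: FitResult

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "delta_observed": self.delta_observed,
            "delta_null": [float(d) for d in self.delta_null],
            "single_fit": self.single_fit.to_dict(),
            "two_pop_fit": self.two_pop_fit.to_dict(),
        }


def _embed_single_in_two_pop(
    single_fit: FitResult, two_pop_space: ParameterSpace
) -> Optional[np.ndarray]:
    """Transformed two-pop vector approximating the single-population fit."""
    params = dict(single_fit.params)
    try:
        x = []
        for name in two_pop_space.free_names:
            if name == "f":
                v = two_pop_space.bounds["f"][1]
            elif name == "N_g":
                v = params["N_b"]
            else:
                v = params[name]
            lo, hi = two_pop_space.bounds[name]
            v = min(max(v, lo), hi)
            x.append(np.log10(v) if name in two_pop_space.log_scale else v)
        return np.asarray(x)
    except KeyError:
        return None


def _fit_two_pop_with_embedding(
    datasets, two_pop_space, single_fit, seed, genome, de_options
) -> FitResult:
    result = fit(datasets, two_pop_space, seed=seed, genome=genome, de_options=de_options)
    x_embed = _embed_single_in_two_pop(single_fit, two_pop_space)
    if x_embed is not None and two_pop_space.free_names:
        objective = _Objective(datasets, two_pop_space, genome)
        pol = _polish(objective, x_embed)
        if np.isfinite(pol.fun) and -pol.fun > result.loglik:
            params = two_pop_space.decode(pol.x)
            result = dataclasses.replace(
                result,
                estimates={k: params[k] for k in two_pop_space.free_names},
                fixed=_resolved_fixed(two_pop_space, params),
                loglik=-float(pol.fun),
            )
    return result


def model_selection_bootstrap(
    datasets: Sequence[SegmentCountTable],
    single_space: ParameterSpace,
    two_pop_space: ParameterSpace,
    n_replicates: int = 100,
    seed: int = 0,
    genome: Optional[GenomeMap] = None,
    de_options: Optional[dict] = None,
) -> ModelSelectionResult:
    """Parametric-bootstrap test of the two-population model.

    The observed statistic is the gain in joint per-pair log-likelihood of
    the two-population fit over the single-population fit.  The null
    distribution is built by simulating bin counts as Poisson with means
    from the fitted single-population model and refitting both models.
    ``p = (1 + #{delta* >= delta}) / (n_replicates + 1)``.
    """
    genome = genome or GenomeMap.default()
    rng = np.random.default_rng(seed)
    s1 = int(rng.integers(2**31 - 1))
    s2 = int(rng.integers(2**31 - 1))
    single_fit = fit(datasets, single_space, seed=s1, genome=genome, de_options=de_options)
    two_fit = _fit_two_pop_with_embedding(
        datasets, two_pop_space, single_fit, s2, genome, de_options
    )
    delta_obs = two_fit.loglik - single_fit.loglik

    null_model = single_fit.model
    null_lams = [
        expected_bin_counts(null_model, ds.sampling, genome, ds.bins, ds.pair_count)
        for ds in datasets
    ]
    deltas = []
    for _ in range(n_replicates):
        rep = [
            replace(ds, counts=rng.poisson(lam))
            for ds, lam in zip(datasets, null_lams)
        ]
        rs1 = int(rng.integers(2**31 - 1))
        rs2 = int(rng.integers(2**31 - 1))
        rep_single = fit(rep, single_space, seed=rs1, genome=genome, de_options=de_options)
        rep_two = _fit_two_pop_with_embedding(
            rep, two_pop_space, rep_single, rs2, genome, de_options
        )
        deltas.append(rep_two.loglik - rep_single.loglik)
    deltas = np.asarray(deltas)
    p = (1.0 + float(np.sum(deltas >= delta_obs))) / (n_replicates + 1.0)
    return ModelSelectionResult(
        p_value=p,
        delta_observed=float(delta_obs),
        delta_null=deltas,
        single_fit=single_fit,
        two_pop_fit=two_fit,
    )
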