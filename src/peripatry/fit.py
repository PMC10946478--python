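"""Composite-likelihood fitting and information-criterion bookkeeping.

The observed folded jSFS is treated as independent Poisson counts per cell
(a composite likelihood): cell c has mean theta * M_c(p), where M(p) is the
theta-free expected spectrum under parameter vector p and theta is profiled
out analytically (its MLE is a ratio of sums). Models are fitted by
multi-round randomized restarts: round 1 draws starts log-uniformly within
bounds, later rounds perturb the incumbent best by a shrinking fold factor,
and every start runs a bounded Nelder-Mead search in log-parameter space.
Monte-Carlo noise in the objective is controlled with common random numbers
(one engine seed per restart) plus a high-replicate refit of the final best
point. Models are compared by AIC and Akaike weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from . import engine as _engine
from .engine import ExpectedSpectrum, expected_jsfs, fold_expected
from .models import ModelSpec, get_model
from .sfs import JointSFS

__all__ = [
    "EngineConfig",
    "FitResult",
    "TraceEntry",
    "OptimizationError",
    "optimal_theta",
    "poisson_loglik",
    "optimize_model",
    "aic_weights",
    "DEFAULT_ROUNDS",
    "DEFAULT_PERTURB_FOLDS",
]

log = logging.getLogger(__name__)

# the four-round restart schedule used throughout: replicate counts per round
# and the perturbation fold applied to the incumbent when drawing new starts
DEFAULT_ROUNDS: Tuple[int, ...] = (60, 70, 70, 80)
DEFAULT_PERTURB_FOLDS: Tuple[int, ...] = (3, 2, 2, 1)

_MODEL_EPS = 1e-12


@dataclass
class EngineConfig:
    """Monte-Carlo and local-search effort knobs.

    ``search_replicates`` genealogies per likelihood evaluation during the
    randomized search; ``refit_replicates`` for the final evaluation of the
    best point; ``max_evals`` / ``ftol`` bound each Nelder-Mead run.
    """

    search_replicates: int = 20_000
    refit_replicates: int = 200_000
    max_evals: int = 300
    ftol: float = 1e-4
    polish_evals: int = 40


class OptimizationError(RuntimeError):
    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class TraceEntry:
    stage: str  # "search" or "refit"
    round: int
    replicate: int
    start_params: Dict[str, float]
    params: Dict[str, float]
    loglik: float  # high-replicate validated log-likelihood
    loglik_search: float = float("nan")  # objective value at search replicates


@dataclass
class FitResult:
    model_name: str
    params_hat: Dict[str, float]
    loglik: float
    theta_hat: float
    aic: float
    k: int
    trace: List[TraceEntry]
    seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_dict(), indent=2)

    def trace_dataframe(self):
        """Replicate trace as a DataFrame (one row per restart/refit)."""
        import pandas as pd

        rows = []
        for t in self.trace:
            row = {"stage": t.stage, "round": t.round, "replicate": t.replicate,
                   "loglik": t.loglik, "loglik_search": t.loglik_search}
            row.update({f"start_{k}": v for k, v in t.start_params.items()})
            row.update({f"fit_{k}": v for k, v in t.params.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def write_trace(self, path) -> None:
        self.trace_dataframe().to_csv(path, sep="\t", index=False)


def _spectra_compatible(data: JointSFS, model_rel: Union[ExpectedSpectrum, JointSFS]) -> None:
    mvals = model_rel.values if isinstance(model_rel, ExpectedSpectrum) else model_rel.counts
    if mvals.shape != data.counts.shape:
        raise ValueError(
            f"shape mismatch: data {data.counts.shape} vs model {mvals.shape}"
        )
    if model_rel.folded != data.folded:
        raise ValueError("data and model must share fold state")


def _values_mask(model_rel):
    if isinstance(model_rel, ExpectedSpectrum):
        return model_rel.values, model_rel.mask
    return model_rel.counts, model_rel.mask


def optimal_theta(data: JointSFS, model_rel: Union[ExpectedSpectrum, JointSFS]) -> float:
    """Poisson maximum-likelihood scale: sum(data) / sum(model) over unmasked cells."""
    _spectra_compatible(data, model_rel)
    mvals, mmask = _values_mask(model_rel)
    keep = ~(data.mask | mmask)
    denom = float(mvals[keep].sum())
    if denom <= 0:
        raise ValueError("model spectrum has no positive mass on unmasked cells")
    num = float(data.counts[keep].sum())
    if num == 0:
        warnings.warn("data spectrum is all zeros; theta-hat = 0", stacklevel=2)
    return num / denom


def poisson_loglik(
    data: JointSFS,
    model_rel: Union[ExpectedSpectrum, JointSFS],
    theta: Optional[float] = None,
) -> float:
    """Composite Poisson log-likelihood (log-factorial constant dropped).

    With mu_c = theta * max(model_c, eps): sum over unmasked cells of
    data_c * ln(mu_c) - mu_c. ``theta`` defaults to its analytic MLE.
    """
    _spectra_compatible(data, model_rel)
    if theta is None:
        theta = optimal_theta(data, model_rel)
    mvals, mmask = _values_mask(model_rel)
    keep = ~(data.mask | mmask)
    mu = theta * np.maximum(mvals[keep], _MODEL_EPS)
    d = data.counts[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(d > 0, d * np.log(np.maximum(mu, 1e-300)), 0.0) - mu
    return float(terms.sum())


def aic_weights(fits: Sequence[Union[FitResult, float]]) -> Dict[str, float]:
    """Akaike weights: w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    if isinstance(fits[0], FitResult):
        names = [f.model_name for f in fits]
        aics = np.array([f.aic for f in fits], dtype=float)
    else:  # raw AIC values
        names = [str(i) for i in range(len(fits))]
        aics = np.asarray(fits, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return dict(zip(names, w))


# round-1 starts are drawn log-uniformly from demographically plausible
# subranges (intersected with each model's bounds) rather than the full
# optimization box: starts at the box edges (e.g. sizes of 1e-3 or 100)
# essentially never reach the basin of attraction within a restart budget
_START_RANGES = {
    "size": (0.05, 20.0),
    "time": (0.02, 3.0),
    "mig": (0.05, 10.0),
    "s": (0.01, 0.5),
}


def _param_kind(name: str) -> str:
    if name.startswith("nu"):
        return "size"
    if name.startswith("T"):
        return "time"
    if name.startswith("m"):
        return "mig"
    return "s"


def _draw_start(rng: np.random.Generator, spec: ModelSpec) -> np.ndarray:
    out = np.empty(len(spec.param_names))
    for i, p in enumerate(spec.param_names):
        blo, bhi = spec.bounds[p]
        slo, shi = _START_RANGES[_param_kind(p)]
        lo, hi = max(blo, slo), min(bhi, shi)
        if not lo < hi:
            lo, hi = blo, bhi
        out[i] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    return out


def _perturb(rng: np.random.Generator, spec: ModelSpec, p: np.ndarray, fold: float) -> np.ndarray:
    lo = np.array([spec.bounds[q][0] for q in spec.param_names])
    hi = np.array([spec.bounds[q][1] for q in spec.param_names])
    return np.clip(p * 2.0 ** rng.uniform(-fold, fold, size=p.size), lo, hi)


def _make_objective(spec: ModelSpec, data: JointSFS, n_reps: int, engine_seed: int):
    lo = np.array([spec.bounds[p][0] for p in spec.param_names])
    hi = np.array([spec.bounds[p][1] for p in spec.param_names])
    n1, n2 = data.n1, data.n2

    def negll(x: np.ndarray) -> float:
        p = np.clip(np.exp(x), lo, hi)
        params = dict(zip(spec.param_names, p))
        try:
            dem = spec.builder(**params)
            es = expected_jsfs(dem, n1, n2, n_reps, engine_seed)
            ll = poisson_loglik(data, fold_expected(es))
        except (ValueError, FloatingPointError):
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    def params_of(x: np.ndarray) -> Dict[str, float]:
        return dict(zip(spec.param_names, np.clip(np.exp(x), lo, hi)))

    return negll, params_of


def optimize_model(
    spec: Union[ModelSpec, str],
    data: JointSFS,
    rounds: Sequence[int] = DEFAULT_ROUNDS,
    perturb_folds: Sequence[float] = DEFAULT_PERTURB_FOLDS,
    seed: int = 0,
    engine_config: Optional[EngineConfig] = None,
    refit_seed: Optional[int] = None,
) -> FitResult:
    """Fit one model to a folded jSFS by multi-round randomized restarts.

    Each restart runs a bounded Nelder-Mead search in log-parameter space
    with its own engine seed (common random numbers within the run); the
    restart's endpoint is then re-evaluated at ``refit_replicates`` under a
    single shared engine seed, and those low-noise validated likelihoods
    drive incumbent selection across restarts and the reported result.
    Deterministic under a fixed ``seed``.
    """
    if isinstance(spec, str):
        spec = get_model(spec)
    if not data.folded:
        raise ValueError("optimize_model requires a folded data spectrum")
    if len(rounds) != len(perturb_folds):
        raise ValueError("rounds and perturb_folds must have equal length")
    cfg = engine_config or EngineConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if refit_seed is None:
        refit_seed = int(rng.integers(2**31))
    else:
        rng.integers(2**31)  # keep the draw sequence aligned
    n1, n2 = data.n1, data.n2

    def validate(params: Dict[str, float]) -> float:
        dem = spec.builder(**params)
        es = fold_expected(expected_jsfs(dem, n1, n2, cfg.refit_replicates, refit_seed))
        return poisson_loglik(data, es)

    trace: List[TraceEntry] = []
    best_ll = -np.inf
    best_params: Optional[Dict[str, float]] = None
    for r, (n_starts, fold) in enumerate(zip(rounds, perturb_folds), start=1):
        for rep in range(1, n_starts + 1):
            engine_seed = int(rng.integers(2**31))
            if best_params is None:
                start = _draw_start(rng, spec)
            else:
                start = _perturb(
                    rng, spec, np.array([best_params[p] for p in spec.param_names]), fold
                )
            negll, params_of = _make_objective(spec, data, cfg.search_replicates, engine_seed)
            x0 = np.log(start)
            # fixed-size initial simplex: log-space coordinates sit near 0 for
            # parameters ~1, where scipy's relative default degenerates
            simplex = np.vstack([x0, x0 + 0.3 * np.eye(x0.size)])
            res = minimize(
                negll,
                x0,
                method="Nelder-Mead",
                options={
                    "maxfev": cfg.max_evals,
                    "fatol": cfg.ftol,
                    "xatol": 1e-3,
                    "initial_simplex": simplex,
                },
            )
            ll_search = -float(res.fun)
            end_params = params_of(res.x)
            try:
                ll_val = validate(end_params) if np.isfinite(ll_search) else -np.inf
            except ValueError:
                ll_val = -np.inf
            trace.append(
                TraceEntry(
                    "search", r, rep,
                    dict(zip(spec.param_names, start)),
                    end_params, ll_val, ll_search,
                )
            )
            if np.isfinite(ll_val) and ll_val > best_ll:
                best_ll = ll_val
                best_params = end_params
    if best_params is None:
        raise OptimizationError(
            f"no restart reached a finite likelihood for {spec.name}", trace
        )
    if cfg.polish_evals > 0:
        # short climb of the low-noise surface itself: Nelder-Mead at refit
        # replicates under the shared refit seed, from the best point
        negll, params_of = _make_objective(spec, data, cfg.refit_replicates, refit_seed)
        x0 = np.log(np.array([best_params[p] for p in spec.param_names]))
        simplex = np.vstack([x0, x0 + 0.1 * np.eye(x0.size)])
        res = minimize(
            negll,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": cfg.polish_evals,
                "fatol": cfg.ftol,
                "xatol": 1e-3,
                "initial_simplex": simplex,
            },
        )
        if np.isfinite(res.fun) and -float(res.fun) > best_ll:
            best_ll = -float(res.fun)
            best_params = params_of(res.x)
    # the reported likelihood is the shared-seed high-replicate evaluation
    dem = spec.builder(**best_params)
    es = fold_expected(expected_jsfs(dem, n1, n2, cfg.refit_replicates, refit_seed))
    theta_hat = optimal_theta(data, es)
    loglik = poisson_loglik(data, es, theta=theta_hat)
    trace.append(TraceEntry("refit", len(rounds) + 1, 0, best_params, best_params, loglik, loglik))
    aic = 2.0 * spec.k - 2.0 * loglik
    return FitResult(
        model_name=spec.name,
        params_hat=best_params,
        loglik=loglik,
        theta_hat=theta_hat,
        aic=aic,
        k=spec.k,
        trace=trace,
        seed=int(seed),
    )
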