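"""Model fitting: likelihoods, MAP estimation, empirical priors, evidence.

Subject-level parameters are estimated by maximum a posteriori (MAP)
optimization in an unconstrained space (logit for unit-interval parameters,
log for inverse temperatures, identity for the perseveration weight) under
a group-level Gaussian prior. The group prior itself is estimated by an
empirical-Bayes expectation-maximization scheme (Laplace approximation to
each subject's posterior), and per-subject model evidence is approximated
by Monte-Carlo integration of the likelihood over draws from that empirical
prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from ._likelihood import nll_core
from .agents import ParameterSet, Session
from .config import PARAM_NAMES, TaskConfig

__all__ = [
    "MODELS",
    "free_params",
    "to_unconstrained",
    "to_native",
    "EmpiricalPrior",
    "FitResult",
    "default_prior",
    "session_nll",
    "fit_map",
    "fit_empirical_prior",
    "model_evidence",
]

MODELS = ("mf", "mb", "hybrid")

# Parameters pinned per model: the model-free model is the hybrid with
# omega = 0; the model-based model the hybrid with omega = 1, where alpha1
# and lam no longer influence choice and are pinned to 0.
_FIXED = {
    "hybrid": {},
    "mf": {"omega": 0.0},
    "mb": {"omega": 1.0, "alpha1": 0.0, "lam": 0.0},
}

_UNIT = ("omega", "alpha1", "alpha2", "lam")
_POSITIVE = ("beta1", "beta2")


def free_params(model: str) -> tuple[str, ...]:
    """Names of the parameters a model actually fits, canonical order."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    return tuple(n for n in PARAM_NAMES if n not in _FIXED[model])


def _pin(params: ParameterSet, model: str) -> ParameterSet:
    fixed = _FIXED[model]
    return replace(params, **fixed) if fixed else params


def to_unconstrained(params: ParameterSet, model: str = "hybrid") -> np.ndarray:
    """Map a native ParameterSet to the model's unconstrained vector."""
    out = []
    for name in free_params(model):
        v = getattr(params, name)
        if name in _UNIT:
            out.append(logit(np.clip(v, 1e-12, 1 - 1e-12)))
        elif name in _POSITIVE:
            out.append(np.log(max(v, 1e-12)))
        else:
            out.append(v)
    return np.asarray(out, dtype=float)


def to_native(x: np.ndarray, model: str = "hybrid") -> ParameterSet:
    """Inverse of :func:`to_unconstrained`; fixed parameters are filled in."""
    names = free_params(model)
    x = np.asarray(x, dtype=float)
    if x.shape != (len(names),):
        raise ValueError(f"expected vector of length {len(names)} for {model!r}")
    values = dict(_FIXED[model])
    for name, xi in zip(names, x):
        if name in _UNIT:
            values[name] = float(expit(xi))
        elif name in _POSITIVE:
            values[name] = float(np.exp(np.minimum(xi, 30.0)))
        else:
            values[name] = float(xi)
    return ParameterSet(**values)


@dataclass
class EmpiricalPrior:
    """Diagonal Gaussian over a model's unconstrained parameter vector."""

    model: str
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        d = len(free_params(self.model))
        if self.mean.shape != (d,) or self.var.shape != (d,):
            raise ValueError(f"prior dimension must be {d} for model {self.model!r}")
        if np.any(self.var < 0):
            raise ValueError("prior variances must be non-negative")

    def logpdf(self, x: np.ndarray) -> float:
        v = np.maximum(self.var, 1e-300)
        z = (np.asarray(x) - self.mean) ** 2 / v
        return float(-0.5 * np.sum(z + np.log(2.0 * np.pi * v)))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        sd = np.sqrt(self.var)
        return self.mean[None, :] + rng.standard_normal((n, len(self.mean))) * sd[None, :]


def default_prior(model: str = "hybrid") -> EmpiricalPrior:
    """Broad initial prior: unit-interval parameters centered at 0.5,
    temperatures at 3, perseveration at 0."""
    mean, var = [], []
    for name in free_params(model):
        if name in _UNIT:
            mean.append(0.0)
            var.append(3.0)
        elif name in _POSITIVE:
            mean.append(np.log(3.0))
            var.append(1.0)
        else:
            mean.append(0.0)
            var.append(1.0)
    return EmpiricalPrior(model, np.array(mean), np.array(var))


@dataclass
class FitResult:
    """MAP fit of one session under one model."""

    model: str
    map_params: ParameterSet
    x_map: np.ndarray
    nll: float
    log_posterior: float
    converged: bool
    n_restarts: int
    posterior_cov: np.ndarray | None = None


def _session_arrays(session: Session):
    return (
        np.ascontiguousarray(session.a1, dtype=np.int64),
        np.ascontiguousarray(session.s2, dtype=np.int64),
        np.ascontiguousarray(session.a2, dtype=np.int64),
        np.ascontiguousarray(session.reward, dtype=np.float64),
        np.ascontiguousarray(session.valid, dtype=np.int64),
    )


def session_nll(
    params: ParameterSet,
    session: Session,
    model: str = "hybrid",
    config: TaskConfig | None = None,
) -> float:
    """Negative log-likelihood of a session's choices under a model.

    Valid trials contribute -log P(a1) - log P(a2) with values updated
    exactly as the generative agents do; invalid trials contribute nothing
    and trigger no updates. The model pins: mf -> omega=0; mb -> omega=1
    with alpha1 and lam inert.
    """
    if session.n_valid < 1:
        raise ValueError("session needs at least one valid trial")
    config = config or TaskConfig()
    p = _pin(params, model)
    a1, s2, a2, r, valid = _session_arrays(session)
    nll = nll_core(
        a1, s2, a2, r, valid,
        p.omega, p.alpha1, p.alpha2, p.lam, p.beta1, p.beta2, p.rho,
        config.p_common, config.q_init,
    )
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite negative log-likelihood")
    return float(nll)


def _objective(session: Session, prior: EmpiricalPrior, config: TaskConfig):
    model = prior.model
    a1, s2, a2, r, valid = _session_arrays(session)
    p_common, q_init = config.p_common, config.q_init
    names = free_params(model)

    template = np.zeros(len(PARAM_NAMES))
    for name, v in _FIXED[model].items():
        template[PARAM_NAMES.index(name)] = v
    free_pos = np.array([PARAM_NAMES.index(n) for n in names])
    unit_idx = np.array([i for i, n in enumerate(names) if n in _UNIT], dtype=int)
    pos_idx = np.array([i for i, n in enumerate(names) if n in _POSITIVE], dtype=int)

    def fun(x: np.ndarray) -> float:
        v = np.array(x, dtype=float)
        v[unit_idx] = expit(v[unit_idx])
        v[pos_idx] = np.exp(np.minimum(v[pos_idx], 30.0))
        full = template.copy()
        full[free_pos] = v
        nll = nll_core(a1, s2, a2, r, valid, *full, p_common, q_init)
        return nll - prior.logpdf(x)

    return fun


def fit_map(
    session: Session,
    prior: EmpiricalPrior | None = None,
    model: str = "hybrid",
    n_restarts: int = 10,
    seed: int = 0,
    config: TaskConfig | None = None,
    x0: np.ndarray | None = None,
) -> FitResult:
    """MAP estimate by multi-start quasi-Newton optimization.

    Starts from the prior mean plus ``n_restarts - 1`` draws from the prior
    (and an optional warm start ``x0``); the best converged optimum wins.
    """
    if prior is None:
        prior = default_prior(model)
    if prior.model != model:
        raise ValueError("prior was built for a different model")
    config = config or TaskConfig()
    fun = _objective(session, prior, config)
    rng = np.random.default_rng(seed)

    starts = [prior.mean.copy()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    jitter_sd = np.sqrt(np.maximum(prior.var, 1e-6))
    while len(starts) < max(n_restarts, 1) + (x0 is not None):
        starts.append(prior.mean + rng.standard_normal(len(prior.mean)) * jitter_sd)

    best = None
    any_success = False
    failures = []
    for s in starts:
        try:
            res = optimize.minimize(fun, s, method="L-BFGS-B")
        except FloatingPointError as err:  # pragma: no cover - defensive
            failures.append(str(err))
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all optimizer restarts failed: {failures}")

    params = to_native(best.x, model)
    nll = session_nll(params, session, model, config)
    return FitResult(
        model=model,
        map_params=params,
        x_map=np.asarray(best.x, dtype=float),
        nll=nll,
        log_posterior=-float(best.fun),
        converged=any_success,
        n_restarts=len(starts),
    )


def _fd_hessian(fun, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central finite-difference Hessian."""
    d = len(x)
    H = np.empty((d, d))
    hs = h * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = hs[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / hs[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


def _posterior_cov(fun, x: np.ndarray) -> np.ndarray:
    """Laplace covariance: inverse Hessian at the MAP, with fallbacks when
    the curvature is not positive-definite."""
    H = _fd_hessian(fun, x)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.all(eigvals > 0):
            return np.linalg.inv(H)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        pass
    diag = np.diag(H)
    if np.all(diag > 0):
        return np.diag(1.0 / diag)
    return np.eye(len(x)) * 0.1


def fit_empirical_prior(
    sessions: list[Session],
    model: str = "hybrid",
    max_iter: int = 40,
    tol: float = 2e-3,
    n_restarts: int = 10,
    seed: int = 0,
    config: TaskConfig | None = None,
    var_floor: float = 1e-4,
) -> tuple[EmpiricalPrior, list[FitResult], bool]:
    """Estimate the group-level empirical prior by Laplace EM.

    Alternates (E) per-subject MAP fits with a curvature-based Gaussian
    posterior approximation and (M) moment updates of the prior mean and
    diagonal variance (MAP scatter plus mean posterior variance, floored at
    ``var_floor``). Stops when the prior mean moves less than ``tol`` in
    max-norm. Returns ``(prior, per-subject fits, converged)``; on
    non-convergence a warning is raised and the flag is False, never a
    silent result.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions to estimate a group prior")
    config = config or TaskConfig()
    prior = default_prior(model)
    fits: list[FitResult] = [None] * len(sessions)  # type: ignore[list-item]
    converged = False
    for iteration in range(max_iter):
        # After the first multi-start sweep, E-steps are deterministic:
        # warm start from the previous MAP plus the current prior mean.
        restarts = n_restarts if iteration == 0 else 1
        for i, session in enumerate(sessions):
            warm = fits[i].x_map if fits[i] is not None else None
            fit = fit_map(
                session, prior, model,
                n_restarts=restarts,
                seed=seed + 1009 * iteration + i,
                config=config,
                x0=warm,
            )
            fun = _objective(session, prior, config)
            fit.posterior_cov = _posterior_cov(fun, fit.x_map)
            fits[i] = fit
        maps = np.array([f.x_map for f in fits])
        covs = np.array([np.diag(f.posterior_cov) for f in fits])
        new_mean = maps.mean(axis=0)
        new_var = np.maximum(
            ((maps - new_mean) ** 2).mean(axis=0) + covs.mean(axis=0), var_floor
        )
        shift = float(np.max(np.abs(new_mean - prior.mean)))
        prior = EmpiricalPrior(model, new_mean, new_var)
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"empirical-prior EM did not converge in {max_iter} iterations "
            f"(last mean shift {shift:.2e})",
            RuntimeWarning,
        )
    # Final E-step so the returned fits are MAPs under the returned prior.
    for i, session in enumerate(sessions):
        fit = fit_map(
            session, prior, model, n_restarts=3, seed=seed + 7919 + i,
            config=config, x0=fits[i].x_map,
        )
        fun = _objective(session, prior, config)
        fit.posterior_cov = _posterior_cov(fun, fit.x_map)
        fits[i] = fit
    return prior, fits, converged


def model_evidence(
    session: Session,
    prior: EmpiricalPrior,
    model: str | None = None,
    n_samples: int = 2000,
    seed: int = 0,
    config: TaskConfig | None = None,
) -> tuple[float, float]:
    """Log marginal likelihood by sampling parameters from the prior.

    Averages the session likelihood over ``n_samples`` prior draws
    (log-sum-exp stabilized) and returns ``(log_evidence, mc_se)`` where the
    Monte-Carlo standard error of the log is estimated by the delta method.
    """
    model = model or prior.model
    if prior.model != model:
        raise ValueError("prior was built for a different model")
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    draws = prior.sample(n_samples, rng)
    ll = np.empty(n_samples)
    a1, s2, a2, r, valid = _session_arrays(session)
    for k in range(n_samples):
        p = to_native(draws[k], model)
        ll[k] = -nll_core(
            a1, s2, a2, r, valid,
            p.omega, p.alpha1, p.alpha2, p.lam, p.beta1, p.beta2, p.rho,
            config.p_common, config.q_init,
        )
    m = ll.max()
    w = np.exp(ll - m)
    mean_w = w.mean()
    log_ev = float(m + np.log(mean_w))
    se = float(w.std(ddof=1) / (mean_w * np.sqrt(n_samples))) if n_samples > 1 else 0.0
    return log_ev, se
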