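"""Hierarchical empirical-Bayes model fitting by importance-sampling EM.

The procedure treats the cohort as exchangeable draws from group-level
parameter distributions (Beta for learning rates, Normal for the gambling
bias, Gamma for the inverse-temperature and outcome-sensitivity weights).
Each iteration draws S parameter settings from the current priors, scores
every subject's choices under every setting (the E-step importance
weights), and refits the prior hyperparameters to the pooled, weighted
sample by weighted method of moments (M-step). Iteration stops once the
model evidence — the sum over subjects of the log mean likelihood over the
sample batch — stops improving. Per-subject parameter estimates are the
likelihood-weighted means of the final batch, which shrinks poorly
constrained subjects toward the group mean. The fit pools all subjects
regardless of any group labels, so between-group comparisons of the
per-subject estimates are not biased by group-specific priors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import models
from .models import PARAM_FAMILIES, get_model
from .task import SessionLog

#: EM defaults: sample batch size, evidence tolerance, iteration cap
DEFAULT_SAMPLES = 100_000
DEFAULT_TOL = 0.1
DEFAULT_MAX_ITER = 50

_SIGMA_FLOOR = 1e-2
_VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class Prior:
    """One parameter's group-level distribution."""

    family: str  # beta | normal | gamma
    p1: float    # a     | mu     | kappa (shape)
    p2: float    # b     | sigma  | theta (scale)

    def __post_init__(self):
        if self.family not in ("beta", "normal", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "normal":
            if self.p2 <= 0:
                raise ValueError("normal prior needs sigma > 0")
        elif self.p1 <= 0 or self.p2 <= 0:
            raise ValueError(f"{self.family} prior needs positive parameters")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.p1, self.p2, size)
        if self.family == "normal":
            return rng.normal(self.p1, self.p2, size)
        return rng.gamma(self.p1, self.p2, size)

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.p1 / (self.p1 + self.p2)
        if self.family == "normal":
            return self.p1
        return self.p1 * self.p2


PriorSet = dict[str, Prior]


def default_priors(model) -> PriorSet:
    """Initial priors: Beta(1,1), Normal(0,1), Gamma(1,1) per family."""
    model = get_model(model)
    out: PriorSet = {}
    for name in model.params:
        fam = PARAM_FAMILIES[name]
        if fam == "beta":
            out[name] = Prior("beta", 1.0, 1.0)
        elif fam == "normal":
            out[name] = Prior("normal", 0.0, 1.0)
        else:
            out[name] = Prior("gamma", 1.0, 1.0)
    return out


def sample_priors(priors: PriorSet, S: int,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw S i.i.d. settings from the product of per-parameter priors."""
    if S < 1:
        raise ValueError("need at least one sample")
    return {name: prior.sample(S, rng) for name, prior in priors.items()}


def loglik_matrix(logs: list[SessionLog], samples: dict[str, np.ndarray],
                  model) -> np.ndarray:
    """(n_subjects, S) log-likelihood of each subject under each setting."""
    model = get_model(model)
    return np.vstack([models.session_loglik_batch(model, samples, log)
                      for log in logs])


def e_step(loglik: np.ndarray) -> np.ndarray:
    """Normalized importance weights per subject (rows sum to one)."""
    if not np.all(np.isfinite(np.max(loglik, axis=1))):
        bad = np.where(~np.isfinite(np.max(loglik, axis=1)))[0]
        raise FloatingPointError(
            f"all-zero importance weights for subjects {bad.tolist()}")
    logw = loglik - logsumexp(loglik, axis=1, keepdims=True)
    return np.exp(logw)


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    w = w / w.sum()
    m = float(w @ x)
    v = float(w @ (x - m) ** 2)
    return m, v


def _refit_prior(name: str, x: np.ndarray, w: np.ndarray,
                 prev: Prior) -> Prior:
    m, v = _weighted_moments(x, w)
    fam = prev.family
    if fam == "normal":
        return Prior("normal", m, max(np.sqrt(v), _SIGMA_FLOOR))
    if v < _VAR_FLOOR:
        warnings.warn(f"degenerate weighted variance for {name!r}; "
                      "widening previous prior", RuntimeWarning)
        return Prior(fam, prev.p1 / 2, prev.p2 * (2 if fam == "gamma" else 0.5))
    if fam == "beta":
        if not 0.0 < m < 1.0 or v >= m * (1.0 - m):
            warnings.warn(f"beta moment fit infeasible for {name!r}; "
                          "widening previous prior", RuntimeWarning)
            return Prior("beta", prev.p1 / 2, prev.p2 / 2)
        nu = m * (1.0 - m) / v - 1.0
        return Prior("beta", m * nu, (1.0 - m) * nu)
    # gamma: shape from squared CV, scale from mean
    return Prior("gamma", m * m / v, v / m)


def m_step(samples: dict[str, np.ndarray], pooled_weights: np.ndarray,
           priors: PriorSet) -> PriorSet:
    """Refit each prior to the pooled weighted sample by method of moments.

    ``pooled_weights`` is the per-sample sum of the normalized per-subject
    weights, so each subject contributes total mass one.
    """
    return {name: _refit_prior(name, samples[name], pooled_weights, prior)
            for name, prior in priors.items()}


@dataclass
class FitResult:
    """Output of :func:`fit`: fitted priors, per-subject estimates, trace."""

    model_id: int
    model_name: str
    priors: PriorSet
    estimates: pd.DataFrame  # index subject_id, one column per parameter
    mean_loglik: pd.Series   # per-subject log mean likelihood, final batch
    evidence_trace: list[float]
    n_samples: int
    converged: bool
    seed: int | None = None

    @property
    def evidence(self) -> float:
        return self.evidence_trace[-1]

    def to_json(self, path=None) -> str:
        payload = {
            "model_id": self.model_id,
            "model_name": self.model_name,
            "priors": {k: [p.family, p.p1, p.p2]
                       for k, p in self.priors.items()},
            "estimates": self.estimates.to_dict(orient="index"),
            "mean_loglik": self.mean_loglik.to_dict(),
            "evidence_trace": self.evidence_trace,
            "n_samples": self.n_samples,
            "converged": self.converged,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit(logs: list[SessionLog], model, S: int = DEFAULT_SAMPLES,
        rng: np.random.Generator | None = None, tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        init_priors: PriorSet | None = None) -> FitResult:
    """Fit one model to a cohort of single-session logs.

    Fresh samples are drawn from the current priors at every iteration
    (resampling EM). The evidence trace is monitored and iteration stops
    when the improvement falls below ``tol``; the per-subject estimates and
    reported priors come from the final batch. Sessions from different days
    should be fitted in separate calls.
    """
    if len(logs) < 2:
        raise ValueError("hierarchical fitting needs at least two subjects")
    if len({(log.subject_id, log.session) for log in logs}) != len(logs):
        raise ValueError("duplicate subject/session in cohort")
    if len({log.session for log in logs}) != 1:
        raise ValueError("fit one session at a time")
    model = get_model(model)
    rng = np.random.default_rng() if rng is None else rng
    priors = dict(init_priors) if init_priors else default_priors(model)

    trace: list[float] = []
    converged = False
    best = -np.inf
    for _ in range(max_iter):
        samples = sample_priors(priors, S, rng)
        ll = loglik_matrix(logs, samples, model)
        evidence = float(np.sum(logsumexp(ll, axis=1) - np.log(S)))
        trace.append(evidence)
        weights = e_step(ll)
        priors = m_step(samples, weights.sum(axis=0), priors)
        if evidence - best < tol and len(trace) > 1:
            converged = True
            break
        best = max(best, evidence)
    if not converged:
        warnings.warn("EM reached max_iter without the evidence levelling "
                      "off", RuntimeWarning)

    est = {name: weights @ samples[name] for name in model.params}
    estimates = pd.DataFrame(est, index=[log.subject_id for log in logs])
    mean_ll = pd.Series(logsumexp(ll, axis=1) - np.log(S),
                        index=estimates.index, name="log_mean_lik")
    return FitResult(model_id=model.model_id, model_name=model.name,
                     priors=priors, estimates=estimates, mean_loglik=mean_ll,
                     evidence_trace=trace, n_samples=S, converged=converged)
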