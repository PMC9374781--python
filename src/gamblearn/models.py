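"""The reinforcement-learning model space for the gambling card task.

Every model turns the visible trial state into a scalar "evidence" term and
passes it through a logistic function to get the gamble probability:

* model 1, ``gambling_bias``:              evidence = b'
* model 2, ``gambling_bias_number``:       evidence = b' + b'' * N
* model 3, ``q_learning``:                 evidence = b' + b'' * N + b''' * Q[d]
* model 4, ``adjusted_q_learning``:        model 3 with delta = r - Q - N
* model 5, ``asymmetric_q_learning``:      model 3 with eta+/eta- by outcome
* model 6, ``adjusted_asymmetric``:        model 4 with eta+/eta-
* model 7, ``adjusted_sensitivity``:       model 4 with r scaled by rho+/rho-
* model 8, ``adjusted_asymmetric_sensitivity``: model 6 with rho+/rho-

Here N is the computer number rescaled to [-1, 1] (1 -> +1, 9 -> -1), Q[d]
the learned deck value (Q0 = 0, updated only after taken gambles, since
declined outcomes are hidden), and r = +1/-1 the gamble outcome. The
"adjusted" prediction error delta = r - Q - N subtracts the scaled computer
number, so surprising outcomes (wins against high numbers, losses against
low ones) teach more. Models 7 and 8 premultiply r by a valence-specific
outcome sensitivity rho before the prediction error is formed; the learning
rate applied to a win/loss is always chosen by the sign of the raw outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import task
from .task import MISS, SessionLog, DeckSpec

#: parameter name -> prior family used by the hierarchical fit
PARAM_FAMILIES = {
    "bias": "normal",         # b'   gambling bias
    "beta_number": "gamma",   # b''  weight on the scaled computer number
    "beta_value": "gamma",    # b''' weight on the learned deck value
    "eta": "beta",
    "eta_pos": "beta",
    "eta_neg": "beta",
    "rho_pos": "gamma",
    "rho_neg": "gamma",
}


def scale_number(n) -> float | np.ndarray:
    """Map a computer number 1..9 onto [-1, 1] (1 -> +1, 9 -> -1)."""
    return (5.0 - np.asarray(n, dtype=float)) / 4.0


@dataclass(frozen=True)
class ModelSpec:
    model_id: int
    name: str
    params: tuple[str, ...]
    uses_number: bool = False
    uses_learning: bool = False
    adjusted_pe: bool = False
    asymmetric_lr: bool = False
    asymmetric_sensitivity: bool = False

    @property
    def n_params(self) -> int:
        return len(self.params)


def _spec(mid, name, *, number=False, learning=False, adjusted=False,
          asym_lr=False, asym_sens=False) -> ModelSpec:
    params = ["bias"]
    if number:
        params.append("beta_number")
    if learning:
        params.append("beta_value")
        params += ["eta_pos", "eta_neg"] if asym_lr else ["eta"]
    if asym_sens:
        params += ["rho_pos", "rho_neg"]
    return ModelSpec(mid, name, tuple(params), uses_number=number,
                     uses_learning=learning, adjusted_pe=adjusted,
                     asymmetric_lr=asym_lr, asymmetric_sensitivity=asym_sens)


MODELS: dict[int, ModelSpec] = {m.model_id: m for m in [
    _spec(1, "gambling_bias"),
    _spec(2, "gambling_bias_number", number=True),
    _spec(3, "q_learning", number=True, learning=True),
    _spec(4, "adjusted_q_learning", number=True, learning=True,
          adjusted=True),
    _spec(5, "asymmetric_q_learning", number=True, learning=True,
          asym_lr=True),
    _spec(6, "adjusted_asymmetric", number=True, learning=True,
          adjusted=True, asym_lr=True),
    _spec(7, "adjusted_sensitivity", number=True, learning=True,
          adjusted=True, asym_sens=True),
    _spec(8, "adjusted_asymmetric_sensitivity", number=True, learning=True,
          adjusted=True, asym_lr=True, asym_sens=True),
]}

_BY_NAME = {m.name: m for m in MODELS.values()}


def get_model(model: int | str | ModelSpec) -> ModelSpec:
    """Look up a model by id, registry name, or pass a spec through."""
    if isinstance(model, ModelSpec):
        return model
    if isinstance(model, int):
        return MODELS[model]
    return _BY_NAME[model]


def validate_params(model: ModelSpec, params: dict[str, float]) -> None:
    for name in model.params:
        if name not in params:
            raise ValueError(f"model {model.name} needs parameter {name!r}")
        v = params[name]
        fam = PARAM_FAMILIES[name]
        if fam == "beta" and not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
        if fam == "gamma" and v < 0.0:
            raise ValueError(f"{name} must be nonnegative")


_DECK_INDEX = {d: i for i, d in enumerate(task.DECK_LABELS)}


def evidence(model: ModelSpec, params: dict[str, float],
             q: np.ndarray, deck: str, computer_number: int) -> float:
    """Evidence term entering the logistic choice rule for one trial."""
    if deck not in _DECK_INDEX:
        raise ValueError(f"unknown deck {deck!r}")
    e = params["bias"]
    if model.uses_number:
        e += params["beta_number"] * scale_number(computer_number)
    if model.uses_learning:
        e += params["beta_value"] * q[_DECK_INDEX[deck]]
    return float(e)


def p_gamble(ev) -> float | np.ndarray:
    """Logistic choice probability, 1 / (1 + exp(-evidence))."""
    ev = np.asarray(ev, dtype=float)
    out = np.where(ev >= 0, 1.0 / (1.0 + np.exp(-np.abs(ev))),
                   np.exp(-np.abs(ev)) / (1.0 + np.exp(-np.abs(ev))))
    return float(out) if out.ndim == 0 else out


def update_q(model: ModelSpec, params: dict[str, float], q: np.ndarray,
             deck: str, computer_number: int, outcome: int) -> np.ndarray:
    """Return the updated deck-value vector after a taken gamble."""
    if not model.uses_learning:
        return q
    if outcome not in (1, -1):
        raise ValueError("outcome must be +1 or -1")
    d = _DECK_INDEX[deck]
    r = float(outcome)
    if model.asymmetric_sensitivity:
        r *= params["rho_pos"] if outcome > 0 else params["rho_neg"]
    delta = r - q[d]
    if model.adjusted_pe:
        delta -= scale_number(computer_number)
    if model.asymmetric_lr:
        eta = params["eta_pos"] if outcome > 0 else params["eta_neg"]
    else:
        eta = params["eta"]
    q = q.copy()
    q[d] += eta * delta
    return q


def _log_logistic(ev, choice):
    # ln p(c | ev): -log(1 + e^-ev) for gamble, -log(1 + e^ev) for decline
    sign = np.where(choice == 1, 1.0, -1.0)
    return -np.logaddexp(0.0, -sign * np.asarray(ev, dtype=float))


def session_loglik(model, params: dict[str, float], log: SessionLog) -> float:
    """Log-likelihood of one session's choices under one parameter setting.

    Straight replay of the trial sequence: deck values start at zero, every
    non-miss choice contributes a log-logistic term, and Q is updated only
    after taken gambles. Missed responses contribute nothing.
    """
    model = get_model(model)
    validate_params(model, params)
    q = np.zeros(3)
    total = 0.0
    last = 0
    for t in log.trials:
        if t.trial_index <= last:
            raise ValueError("session log is not chronologically ordered")
        last = t.trial_index
        if t.choice == MISS:
            continue
        if t.outcome_shown != (t.choice == 1):
            raise ValueError("outcome shown on a declined trial")
        ev = evidence(model, params, q, t.deck, t.computer_number)
        total += float(_log_logistic(ev, t.choice))
        if t.choice == 1:
            q = update_q(model, params, q, t.deck, t.computer_number,
                         t.outcome)
    return total


def _trial_arrays(log: SessionLog):
    ts = [t for t in log.trials if t.choice != MISS]
    deck = np.array([_DECK_INDEX[t.deck] for t in ts])
    nsc = scale_number(np.array([t.computer_number for t in ts]))
    choice = np.array([t.choice for t in ts])
    outcome = np.array([t.outcome for t in ts], dtype=float)
    return deck, nsc, choice, outcome


def session_loglik_batch(model, samples: dict[str, np.ndarray],
                         log: SessionLog) -> np.ndarray:
    """Log-likelihood of one session under S parameter settings at once.

    ``samples`` maps each parameter name to a length-S vector. Returns the
    length-S vector of log-likelihoods; used by the hierarchical fit, where
    S is large. Agrees with :func:`session_loglik` applied per setting.
    """
    model = get_model(model)
    S = len(samples[model.params[0]])
    deck, nsc, choice, outcome = _trial_arrays(log)
    ev_base = np.broadcast_to(samples["bias"], (S,)).astype(float)
    total = np.zeros(S)
    if not model.uses_learning:
        for i in range(len(deck)):
            ev = ev_base
            if model.uses_number:
                ev = ev + samples["beta_number"] * nsc[i]
            total += _log_logistic(ev, choice[i])
        return total
    q = np.zeros((S, 3))
    bn = samples["beta_number"]
    bv = samples["beta_value"]
    if model.asymmetric_lr:
        eta_pos, eta_neg = samples["eta_pos"], samples["eta_neg"]
    else:
        eta_pos = eta_neg = samples["eta"]
    for i in range(len(deck)):
        d = deck[i]
        ev = ev_base + bn * nsc[i] + bv * q[:, d]
        total += _log_logistic(ev, choice[i])
        if choice[i] == 1:
            r = outcome[i]
            if model.asymmetric_sensitivity:
                r = r * (samples["rho_pos"] if r > 0 else samples["rho_neg"])
            delta = r - q[:, d]
            if model.adjusted_pe:
                delta = delta - nsc[i]
            eta = eta_pos if outcome[i] > 0 else eta_neg
            q[:, d] = q[:, d] + eta * delta
    return total


class AgentPolicy:
    """A model-driven agent usable with :func:`gamblearn.task.generate_session`.

    Keeps the per-deck Q state internally; optionally records the Q
    trajectory for diagnostics.
    """

    def __init__(self, model, params: dict[str, float],
                 record_q: bool = False):
        self.model = get_model(model)
        validate_params(self.model, params)
        self.params = dict(params)
        self.q = np.zeros(3)
        self.q_trace: list[np.ndarray] | None = [] if record_q else None

    def p_gamble(self, deck: str, computer_number: int) -> float:
        ev = evidence(self.model, self.params, self.q, deck, computer_number)
        return p_gamble(ev)

    def observe(self, deck: str, computer_number: int, outcome: int) -> None:
        self.q = update_q(self.model, self.params, self.q, deck,
                          computer_number, outcome)
        if self.q_trace is not None:
            self.q_trace.append(self.q.copy())


def simulate_agent(model, params: dict[str, float],
                   decks: dict[str, DeckSpec] | None = None,
                   rng: np.random.Generator | None = None,
                   subject_id: str = "sim", session: int = 1) -> SessionLog:
    """Simulate one full session of a model-driven agent."""
    if decks is None:
        decks = task.build_decks()
    if rng is None:
        rng = np.random.default_rng()
    policy = AgentPolicy(model, params)
    return task.generate_session(decks, policy, rng, subject_id=subject_id,
                                 session=session)
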