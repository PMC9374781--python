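"""Trial-by-trial logistic regression of gamble decisions.

For every trial t the model

    p(c_t = 1) = logistic(b0 + b1*x1 + b2*x2 + b3*x3)

relates the decision to gamble (c_t = 1) or decline (c_t = 0) to three
regressors: x1, the computer number scaled to [-1, 1] (1 -> +1, 9 -> -1);
x2, cumulative success with the current deck — the sum over its previous
winning gambles of (+1 * computer number); and x3, cumulative failure — the
sum over its previous losing gambles of (-1 * (10 - computer number)). The
number weighting encodes that a win against a high number, or a loss
against a low one, is stronger evidence about the deck. x2 and x3 are
range-normalized to [-1, 1] within each subject-session so coefficient
sizes are comparable.

The asymmetry statistic b2 - b3 summarizes how unequally cumulative success
and failure drive gambling. Both regressors are coded so a positive
coefficient means the intuitive effect (more success -> more gambling; b3's
regressor is negative-valued, so positive b3 means failure promotes
declining); equal sensitivity to the two valences therefore gives
b2 - b3 = 0, and a positive value means wins outweigh losses. This
composite tracks the learning-rate asymmetry eta+ - eta- of the
reinforcement-learning models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .task import MISS, SessionLog

#: |coefficient| above which a fit is flagged as (quasi-)separated
_SEPARATION_BOUND = 30.0


def _range_normalize(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def build_regressors(log: SessionLog, normalize: str = "range") -> pd.DataFrame:
    """Regressor rows (x1, x2, x3, c) for every non-miss trial.

    Cumulative sums include strictly previous trials (the current outcome
    is not known at decision time). ``normalize='range'`` maps each
    cumulative regressor's observed range onto [-1, 1]; ``'absmax'``
    divides by its maximum absolute value instead, preserving zero;
    ``'none'`` returns the raw number-weighted sums.
    """
    if normalize not in ("range", "absmax", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    cum_win: dict[str, float] = {}
    cum_loss: dict[str, float] = {}
    rows = []
    last = 0
    for t in log.trials:
        if t.trial_index <= last:
            raise ValueError("session log is not chronologically ordered")
        last = t.trial_index
        if t.choice == MISS:
            continue
        d = t.deck
        rows.append(((5.0 - t.computer_number) / 4.0,
                     cum_win.get(d, 0.0), cum_loss.get(d, 0.0), t.choice))
        if t.choice == 1:
            if t.outcome == 1:
                cum_win[d] = cum_win.get(d, 0.0) + t.computer_number
            else:
                cum_loss[d] = cum_loss.get(d, 0.0) - (10.0 - t.computer_number)
    df = pd.DataFrame(rows, columns=["x1", "x2", "x3", "c"])
    if normalize == "none":
        return df
    for col in ("x2", "x3"):
        x = df[col].to_numpy(dtype=float)
        if normalize == "range":
            df[col] = _range_normalize(x)
        else:
            amax = np.abs(x).max()
            df[col] = x / amax if amax > 1e-12 else 0.0
    return df


@dataclass(frozen=True)
class RegressionFit:
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    converged: bool

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


def fit_subject(rows: pd.DataFrame, min_each: int = 5) -> RegressionFit:
    """Maximum-likelihood logistic fit for one subject-session.

    Subjects with fewer than ``min_each`` accepted or declined trials, or
    with separated/non-converged fits, are flagged ``converged=False`` and
    should be excluded from group summaries.
    """
    y = rows["c"].to_numpy(dtype=float)
    if min(y.sum(), len(y) - y.sum()) < min_each:
        return RegressionFit(np.nan, np.nan, np.nan, np.nan, False)
    X = sm.add_constant(rows[["x1", "x2", "x3"]].to_numpy(dtype=float),
                        has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return RegressionFit(np.nan, np.nan, np.nan, np.nan, False)
    b = res.params
    ok = bool(res.mle_retvals.get("converged", False)) and bool(
        np.all(np.isfinite(b)) and np.max(np.abs(b)) < _SEPARATION_BOUND)
    return RegressionFit(float(b[0]), float(b[1]), float(b[2]), float(b[3]),
                         ok)


def asymmetry_stat(fit: RegressionFit) -> float:
    """b2 - b3: the asymmetric effect of cumulative success vs. failure."""
    if not fit.converged:
        raise ValueError("asymmetry undefined for a non-converged fit")
    return fit.beta2 - fit.beta3


def fit_cohort(logs: list[SessionLog], normalize: str = "range"
               ) -> pd.DataFrame:
    """One regression per subject-session; returns a coefficient table."""
    rows = []
    for log in logs:
        fit = fit_subject(build_regressors(log, normalize=normalize))
        rows.append((log.subject_id, log.session, fit.beta0, fit.beta1,
                     fit.beta2, fit.beta3,
                     fit.beta2 - fit.beta3 if fit.converged else np.nan,
                     fit.converged))
    return pd.DataFrame(rows, columns=["subject_id", "session", "beta0",
                                       "beta1", "beta2", "beta3",
                                       "asymmetry", "converged"])
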