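"""Synthetic two-group cohorts and group-level contrasts.

Emulates the study design the analysis pipeline assumes: two groups of
subjects (labelled ``drug`` and ``placebo``) whose model parameters are
drawn from group-level distributions, with the drug group's learning-rate
asymmetry shifted — mean eta+ lowered and mean eta- raised by delta/2 each,
at fixed Beta concentration (a + b held constant) — mirroring a prolonged
SSRI effect of reduced reward learning and enhanced punishment learning.
Ground-truth parameters are retained for recovery scoring. Group contrasts
on fitted (or true) per-subject learning rates report Welch t statistics
per valence and a valence-by-group interaction contrast,
(drug: eta+ - eta-) - (placebo: eta+ - eta-), with a permutation p-value
obtained by shuffling group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models, task
from .hierfit import Prior, PriorSet
from .models import get_model
from .task import SessionLog

GROUPS = ("drug", "placebo")


def _default_generating_priors(model) -> PriorSet:
    """Population distributions the synthetic cohort draws from.

    Learning rates are mid-range Beta(4, 4); temperature weights Gamma(4, 1),
    which puts simulated agents at the ~86-87% percent-correct choice
    determinism that fitted models reach on real cohorts of this task.
    """
    model = get_model(model)
    priors: PriorSet = {}
    for name in model.params:
        fam = models.PARAM_FAMILIES[name]
        if fam == "beta":
            priors[name] = Prior("beta", 4.0, 4.0)
        elif fam == "normal":
            priors[name] = Prior("normal", 0.0, 0.5)
        elif name.startswith("rho"):
            priors[name] = Prior("gamma", 4.0, 0.25)  # outcome scale near 1
        else:
            priors[name] = Prior("gamma", 4.0, 1.0)
    return priors


def shift_beta_mean(prior: Prior, new_mean: float) -> Prior:
    """Move a Beta prior's mean at fixed concentration a + b."""
    if prior.family != "beta":
        raise ValueError("can only shift a Beta prior")
    if not 0.0 < new_mean < 1.0:
        raise ValueError(f"shifted Beta mean {new_mean} outside (0, 1)")
    c = prior.p1 + prior.p2
    return Prior("beta", new_mean * c, (1.0 - new_mean) * c)


@dataclass
class CohortSpec:
    """Design of a synthetic two-group cohort.

    ``delta`` is the between-group learning-asymmetry shift: the drug
    group's mean eta+ is lowered and mean eta- raised by ``delta / 2``
    each, so the expected interaction contrast equals ``-delta``.
    """

    n_per_group: int = 33
    model: int | str = 6
    delta: float = 0.0
    sessions: int = 1
    base_priors: PriorSet | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least two subjects per group")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")

    def group_priors(self, group: str) -> PriorSet:
        spec = get_model(self.model)
        priors = dict(self.base_priors or _default_generating_priors(spec))
        if group == "drug" and self.delta > 0:
            if not {"eta_pos", "eta_neg"} <= set(priors):
                raise ValueError("asymmetry shift needs eta_pos and eta_neg")
            priors["eta_pos"] = shift_beta_mean(
                priors["eta_pos"], priors["eta_pos"].mean - self.delta / 2)
            priors["eta_neg"] = shift_beta_mean(
                priors["eta_neg"], priors["eta_neg"].mean + self.delta / 2)
        return priors


def generate_cohort(spec: CohortSpec,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[SessionLog], pd.DataFrame]:
    """Simulate the cohort; returns (logs, ground-truth parameter table).

    Parameters are drawn once per subject; each session is an independent
    run of the task (fresh decks, fresh schedule, Q reset), as subjects see
    unrelated decks on the two study days.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mspec = get_model(spec.model)
    decks = task.build_decks()
    logs: list[SessionLog] = []
    truth_rows = []
    for group in GROUPS:
        priors = spec.group_priors(group)
        for i in range(spec.n_per_group):
            sid = f"{group}_{i:03d}"
            params = {k: float(p.sample(1, rng)[0])
                      for k, p in priors.items()}
            truth_rows.append({"subject_id": sid, "group": group, **params})
            for ses in range(1, spec.sessions + 1):
                logs.append(models.simulate_agent(
                    mspec, params, decks=decks, rng=rng, subject_id=sid,
                    session=ses))
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    return logs, truth


@dataclass(frozen=True)
class GroupContrast:
    """Welch t-tests per valence plus the valence-by-group interaction."""

    group_means: pd.DataFrame       # rows drug/placebo, cols eta_pos/eta_neg
    group_sds: pd.DataFrame
    t_eta_pos: float
    p_eta_pos: float
    t_eta_neg: float
    p_eta_neg: float
    interaction: float              # (drug: e+ - e-) - (placebo: e+ - e-)
    interaction_p: float            # two-sided permutation p-value


def group_contrast(estimates: pd.DataFrame, labels: pd.Series,
                   n_permutations: int = 2000,
                   rng: np.random.Generator | None = None) -> GroupContrast:
    """Contrast per-subject learning rates between the two groups.

    ``estimates`` must carry ``eta_pos`` and ``eta_neg`` columns indexed by
    subject; ``labels`` maps each subject to ``drug`` or ``placebo``. The
    interaction p-value comes from permuting group labels, which leaves the
    hierarchical fit untouched (it pooled the groups to begin with).
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = labels.reindex(estimates.index)
    if labels.isna().any():
        raise ValueError("every subject needs a group label")
    for g in GROUPS:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} needs at least two subjects")
    eta = estimates[["eta_pos", "eta_neg"]]
    drug = eta[labels == "drug"]
    plac = eta[labels == "placebo"]

    t_pos, p_pos = stats.ttest_ind(drug["eta_pos"], plac["eta_pos"],
                                   equal_var=False)
    t_neg, p_neg = stats.ttest_ind(drug["eta_neg"], plac["eta_neg"],
                                   equal_var=False)

    asym = (eta["eta_pos"] - eta["eta_neg"]).to_numpy()
    is_drug = (labels == "drug").to_numpy()

    def contrast(mask):
        return float(asym[mask].mean() - asym[~mask].mean())

    obs = contrast(is_drug)
    perm = np.empty(n_permutations)
    for k in range(n_permutations):
        perm[k] = contrast(rng.permutation(is_drug))
    p_int = (1.0 + np.sum(np.abs(perm) >= abs(obs))) / (n_permutations + 1.0)

    means = pd.DataFrame({g: eta[labels == g].mean() for g in GROUPS}).T
    sds = pd.DataFrame({g: eta[labels == g].std(ddof=1) for g in GROUPS}).T
    return GroupContrast(group_means=means, group_sds=sds,
                         t_eta_pos=float(t_pos), p_eta_pos=float(p_pos),
                         t_eta_neg=float(t_neg), p_eta_neg=float(p_neg),
                         interaction=obs, interaction_p=float(p_int))


# ---------------------------------------------------------------------------
# Simulation studies linking the analyses
# ---------------------------------------------------------------------------

#: learning models whose data enter the regression-asymmetry correlation
#: study; single-rate models are simulated under their asymmetric
#: counterpart (which nests them) so eta+ and eta- can vary independently
ASYMMETRY_STUDY_MODELS = (3, 4, 5, 6, 8)
_ASYM_COUNTERPART = {3: 5, 4: 6}


def asymmetry_correlation(model, n_agents: int = 60,
                          rng: np.random.Generator | None = None) -> float:
    """Correlation between regression and model-based learning asymmetry.

    Simulates ``n_agents`` agents of the given learning model with eta+
    and eta- drawn independently from Uniform(0, 1) (other parameters from
    the calibrated validation priors), fits the trial-by-trial logistic
    regression to each agent's session, and returns the Pearson r between
    the regression asymmetry b2 - b3 and the generating eta+ - eta-.
    Non-converged regressions are excluded, as in the cohort analysis.
    """
    from . import regression
    from .compare import recovery_priors
    rng = np.random.default_rng() if rng is None else rng
    mspec = get_model(model)
    mspec = get_model(_ASYM_COUNTERPART.get(mspec.model_id, mspec.model_id))
    priors = recovery_priors(mspec, learning_rates="uniform")
    decks = task.build_decks()
    truth, stat = [], []
    for i in range(n_agents):
        params = {k: float(p.sample(1, rng)[0]) for k, p in priors.items()}
        log = models.simulate_agent(mspec, params, decks=decks, rng=rng,
                                    subject_id=f"a{i:03d}")
        fit = regression.fit_subject(regression.build_regressors(log))
        if fit.converged:
            truth.append(params["eta_pos"] - params["eta_neg"])
            stat.append(regression.asymmetry_stat(fit))
    if len(truth) < 3:
        raise RuntimeError("too few converged regressions to correlate")
    return float(np.corrcoef(truth, stat)[0, 1])


def mean_gamble_rate(n_agents: int = 50, model: int | str = 6,
                     priors: PriorSet | None = None,
                     rng: np.random.Generator | None = None) -> float:
    """Cohort mean fraction of accepted gambles under the adaptive task.

    The default priors are the mid-range population defaults; the adaptive
    computer-number schedule should hold the cohort mean near 0.5.
    """
    rng = np.random.default_rng() if rng is None else rng
    mspec = get_model(model)
    priors = priors or _default_generating_priors(mspec)
    decks = task.build_decks()
    rates = []
    for i in range(n_agents):
        params = {k: float(p.sample(1, rng)[0]) for k, p in priors.items()}
        log = models.simulate_agent(mspec, params, decks=decks, rng=rng)
        rates.append(np.mean([t.choice for t in log.trials]))
    return float(np.mean(rates))


def net_reward_by_learning_rate(
        etas: np.ndarray | None = None, n_sessions: int = 200,
        model: int | str = 4, bias: float = 0.0, beta_number: float = 4.0,
        beta_value: float = 4.0,
        rng: np.random.Generator | None = None) -> pd.Series:
    """Mean net reward (wins minus losses) per symmetric learning rate.

    Simulates ``n_sessions`` task sessions of a single-rate learning agent
    at each grid value of eta, holding the bias and temperature weights
    fixed at the calibrated population means, and returns the mean session
    net reward indexed by eta. The grid maximizer estimates the task's
    optimal learning rate: too-slow learners never separate the decks,
    too-fast learners chase single recent outcomes.
    """
    rng = np.random.default_rng() if rng is None else rng
    if etas is None:
        etas = np.round(np.arange(0.05, 0.951, 0.05), 2)
    mspec = get_model(model)
    if mspec.asymmetric_lr or not mspec.uses_learning:
        raise ValueError("needs a single-learning-rate learning model")
    decks = task.build_decks()
    out = {}
    for eta in etas:
        params = {"bias": bias, "beta_number": beta_number,
                  "beta_value": beta_value, "eta": float(eta)}
        total = 0.0
        for _ in range(n_sessions):
            log = models.simulate_agent(mspec, params, decks=decks, rng=rng)
            total += sum(t.outcome for t in log.trials)
        out[float(eta)] = total / n_sessions
    return pd.Series(out, name="mean_net_reward")
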