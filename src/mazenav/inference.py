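"""Belief updating, policy evaluation and learning.

Per policy, posterior beliefs over the hidden location at every epoch of a
trial are relaxed (by a damped gradient flow on log expectations) toward the
exact chain posterior given the outcomes observed so far; the per-iteration
variational free energy is recorded and is non-increasing by construction.
Policies are scored by expected free energy -- risk (divergence of predicted
outcomes from log preferences) plus ambiguity minus novelty (expected
information gain about the Dirichlet likelihood parameters) -- and a precision
(inverse temperature) is updated from the shift in the policy distribution
induced by each new outcome.  Observed outcomes are finally consolidated into
the likelihood concentrations (associative plasticity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .environment import observe, step
from .errors import (
    InvalidArgumentError,
    NumericalDegeneracyError,
    PrecisionFloorWarning,
)
from .model_core import (
    PROB_FLOOR,
    AgentConfig,
    GenerativeModel,
    MazeGrid,
    expected_log_likelihood,
)
from .neural import SessionTrace

__all__ = [
    "BeliefState",
    "EFEBreakdown",
    "TrialResult",
    "softmax",
    "infer_states",
    "expected_free_energy",
    "novelty_kernel",
    "policy_posterior",
    "update_precision",
    "select_action",
    "learn_likelihood",
    "run_trial",
]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class BeliefState:
    """Per-policy, per-epoch posteriors plus the policy distribution and precision."""

    s: np.ndarray  # [n_policies, n_epochs, n_states]; softmax of v
    v: np.ndarray  # log expectations ("depolarisation")
    pi: np.ndarray  # categorical over policies
    gamma: float
    beta: float
    f_trace: np.ndarray = field(default_factory=lambda: np.empty(0))  # per iteration
    f_policy: np.ndarray = field(default_factory=lambda: np.empty(0))  # converged, per policy
    s_history: np.ndarray | None = None  # [n_iters, n_policies, n_epochs, n_states]
    v_history: np.ndarray | None = None


@dataclass
class EFEBreakdown:
    """Expected free energy per policy, decomposed."""

    risk: np.ndarray
    ambiguity: np.ndarray
    novelty: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.risk + self.ambiguity - self.novelty


def _chain_marginals(lnlik: np.ndarray, b_seq: list[np.ndarray], d: np.ndarray):
    """Exact forward-backward marginals and log evidence of one policy's chain."""
    n_epochs, n = lnlik.shape
    lik = np.exp(lnlik)
    alphas = np.empty((n_epochs, n))
    log_z = 0.0
    a = lik[0] * d
    for tau in range(n_epochs):
        if tau > 0:
            a = lik[tau] * (b_seq[tau - 1] @ alphas[tau - 1])
        tot = a.sum()
        if not tot > 0:
            raise NumericalDegeneracyError("all-zero forward message")
        alphas[tau] = a / tot
        log_z += np.log(tot)
    betas = np.empty((n_epochs, n))
    betas[-1] = 1.0
    for tau in range(n_epochs - 2, -1, -1):
        b = b_seq[tau].T @ (lik[tau + 1] * betas[tau + 1])
        tot = b.sum()
        if not tot > 0:
            raise NumericalDegeneracyError("all-zero backward message")
        betas[tau] = b / tot
    p = alphas * betas
    tot = p.sum(axis=1, keepdims=True)
    if not (tot > 0).all():
        raise NumericalDegeneracyError("non-normalizable posterior marginal")
    return p / tot, log_z


def infer_states(
    model: GenerativeModel,
    policies: np.ndarray,
    outcomes: Sequence[tuple[int, int]],
    v_init: np.ndarray | None = None,
    *,
    n_iter: int = 16,
    step_size: float = 0.25,
    f_tol: float = 1e-4,
    d: np.ndarray | None = None,
    record: bool = False,
) -> BeliefState:
    """Update state expectations for every policy given outcomes up to now.

    ``policies`` is an ``[n_policies, horizon]`` array of action indices and
    ``outcomes`` the list of ``(what, where)`` pairs observed so far (epochs
    ``0..t``).  Log expectations ``v`` are relaxed with damped steps of size
    ``step_size`` toward the combination of likelihood evidence and forward /
    backward transition messages, whose fixed point is the exact per-policy
    posterior; iteration stops after ``n_iter`` steps or once the free-energy
    change falls below ``f_tol``.  Epochs not yet constrained by an outcome
    converge to the pure prediction ``B s``.
    """
    policies = np.atleast_2d(np.asarray(policies, dtype=int))
    n_pol, horizon = policies.shape
    n_epochs = horizon + 1
    n = model.n_states
    if len(outcomes) > n_epochs:
        raise InvalidArgumentError("more outcomes than epochs in a trial")
    d = model.d if d is None else np.asarray(d, dtype=float)

    _, ln_abar = expected_log_likelihood(model.likelihood.a_what)
    ln_awhere = np.log(np.maximum(model.likelihood.A_where, PROB_FLOOR))

    lnlik = np.zeros((n_epochs, n))
    for tau, (o_what, o_where) in enumerate(outcomes):
        lnlik[tau] = ln_abar[o_what] + ln_awhere[o_where]

    targets = np.empty((n_pol, n_epochs, n))
    f_policy = np.empty(n_pol)
    marginals = np.empty((n_pol, n_epochs, n))
    for p in range(n_pol):
        b_seq = [model.transitions[u] for u in policies[p]]
        marg, log_z = _chain_marginals(lnlik, b_seq, d)
        marginals[p] = marg
        targets[p] = np.log(np.maximum(marg, PROB_FLOOR))
        f_policy[p] = -log_z

    if v_init is None:
        v = np.full((n_pol, n_epochs, n), -np.log(n))
    else:
        v = np.array(v_init, dtype=float)
        if v.shape != (n_pol, n_epochs, n):
            raise InvalidArgumentError("v_init has the wrong shape")

    s_hist, v_hist, f_trace = [], [], []
    ln_marg = targets  # already floored logs of the fixed points
    f_prev = None
    for _ in range(n_iter):
        v = v + step_size * (targets - v)
        s = softmax(v, axis=-1)
        # F = sum_tau KL(q_tau || p_tau) - log Z, averaged over policies
        kl = np.sum(s * (np.log(np.maximum(s, PROB_FLOOR)) - ln_marg), axis=(1, 2))
        f_now = float(np.mean(kl + f_policy))
        f_trace.append(f_now)
        if record:
            s_hist.append(s.copy())
            v_hist.append(v.copy())
        if f_prev is not None and abs(f_prev - f_now) < f_tol:
            break
        f_prev = f_now

    s = softmax(v, axis=-1)
    return BeliefState(
        s=s,
        v=v,
        pi=np.full(n_pol, 1.0 / n_pol),
        gamma=1.0,
        beta=1.0,
        f_trace=np.asarray(f_trace),
        f_policy=f_policy,
        s_history=np.asarray(s_hist) if record else None,
        v_history=np.asarray(v_hist) if record else None,
    )


def novelty_kernel(a: np.ndarray) -> np.ndarray:
    """Expected-information-gain kernel of a Dirichlet likelihood array."""
    a = np.asarray(a, dtype=float)
    if (a <= 0).any():
        raise InvalidArgumentError("concentrations must be positive")
    return 0.5 * (1.0 / a - 1.0 / a.sum(axis=0, keepdims=True))


def expected_free_energy(
    model: GenerativeModel,
    s: np.ndarray,
    future_epochs: Sequence[int],
    novelty_on: bool = True,
    a_what: np.ndarray | None = None,
) -> EFEBreakdown:
    """Score each policy over the given future epochs.

    Risk is the divergence of predicted outcomes from the log preferences (both
    modalities), ambiguity the expected conditional outcome entropy, and
    novelty the expected information gain about the ``what`` concentrations
    (the only modality with Dirichlet uncertainty).  ``a_what`` overrides the
    model's concentrations, e.g. with the running within-trial posterior.
    """
    s = np.atleast_3d(np.asarray(s, dtype=float))
    n_pol = s.shape[0]
    a = model.likelihood.a_what if a_what is None else a_what
    abar, _ = expected_log_likelihood(a)
    w = novelty_kernel(a)
    safe = np.maximum(abar, PROB_FLOOR)
    h_what = -(abar * np.log(safe)).sum(axis=0)  # conditional entropy per state
    c_what = model.preferences.c_what
    c_where = model.preferences.c_where

    risk = np.zeros(n_pol)
    ambiguity = np.zeros(n_pol)
    novelty = np.zeros(n_pol)
    for p in range(n_pol):
        for tau in future_epochs:
            sbar = s[p, tau]
            o_what = abar @ sbar
            o_where = model.likelihood.A_where @ sbar
            risk[p] += o_what @ (np.log(np.maximum(o_what, PROB_FLOOR)) - c_what)
            risk[p] += o_where @ (np.log(np.maximum(o_where, PROB_FLOOR)) - c_where)
            ambiguity[p] += sbar @ h_what
            if novelty_on:
                novelty[p] += o_what @ (w @ sbar)
    return EFEBreakdown(risk=risk, ambiguity=ambiguity, novelty=novelty)


def policy_posterior(g: np.ndarray, gamma: float) -> np.ndarray:
    """Softmax of (negative) precision-weighted expected free energy."""
    if not gamma > 0:
        raise InvalidArgumentError("gamma must be positive")
    g = np.asarray(g, dtype=float)
    if not np.isfinite(g).all():
        raise InvalidArgumentError("expected free energies must be finite")
    return softmax(-gamma * g)


_BETA_FLOOR = 1e-2


def update_precision(
    g: np.ndarray,
    pi_prior: np.ndarray,
    pi_posterior: np.ndarray,
    beta0: float,
    damping: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 256,
) -> tuple[float, float]:
    """Damped fixed-point iteration for the precision hyper-parameters.

    Converges to ``beta = beta0 + (pi_posterior - pi_prior) . g``; when the
    posterior favours lower-G policies than the prior, beta falls and the
    precision ``gamma = 1/beta`` (confidence) rises.
    """
    g = np.asarray(g, dtype=float)
    drive = float((np.asarray(pi_posterior) - np.asarray(pi_prior)) @ g)
    beta = float(beta0)
    for _ in range(max_iter):
        new = beta + damping * ((beta0 + drive) - beta)
        if abs(new - beta) < tol:
            beta = new
            break
        beta = new
    if beta <= 0:
        warnings.warn("precision update drove beta <= 0; flooring", PrecisionFloorWarning)
        beta = _BETA_FLOOR
    return beta, 1.0 / beta


def _update_precision_coupled(
    f_policy: np.ndarray,
    g: np.ndarray,
    beta0: float,
    damping: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 256,
) -> tuple[float, float, np.ndarray]:
    """Precision update with the policy distributions recomputed each sweep.

    The prior distribution scores policies by expected free energy alone; the
    posterior additionally weighs the evidence ``f_policy`` that observed
    outcomes provide for each policy.  Returns ``(beta, gamma, pi_post)``.
    """
    f = np.asarray(f_policy, dtype=float)
    g = np.asarray(g, dtype=float)
    beta = float(beta0)
    for _ in range(max_iter):
        gamma = 1.0 / beta
        pi_prior = softmax(-gamma * g)
        pi_post = softmax(-f - gamma * g)
        target = beta0 + float((pi_post - pi_prior) @ g)
        new = beta + damping * (target - beta)
        if new <= 0:
            warnings.warn(
                "precision update drove beta <= 0; flooring", PrecisionFloorWarning
            )
            new = _BETA_FLOOR
        if abs(new - beta) < tol:
            beta = new
            break
        beta = new
    gamma = 1.0 / beta
    return beta, gamma, softmax(-f - gamma * g)


def select_action(
    pi: np.ndarray, policies: np.ndarray, current_step: int, n_actions: int = 5
) -> int:
    """Most likely action at ``current_step`` under the policy distribution.

    Ties are broken by the fixed action order (lower index wins).
    """
    policies = np.atleast_2d(policies)
    marginal = np.zeros(n_actions)
    np.add.at(marginal, policies[:, current_step], np.asarray(pi, dtype=float))
    return int(np.argmax(marginal))


def learn_likelihood(
    a_what: np.ndarray,
    outcomes: Sequence[tuple[int, int]],
    bma_states: np.ndarray,
    eta: float = 1.0,
    decay: float = 0.0,
) -> np.ndarray:
    """Consolidate observed outcomes into the likelihood concentrations.

    Each observed epoch adds ``eta`` times the outer product of the one-hot
    ``what`` outcome with the policy-averaged state expectation (total added
    mass ``eta`` per epoch).  ``decay`` optionally shrinks the pre-existing
    counts first; it is off by default.
    """
    a = np.asarray(a_what, dtype=float).copy()
    if decay:
        a *= 1.0 - decay
    bma_states = np.atleast_2d(np.asarray(bma_states, dtype=float))
    if len(outcomes) > bma_states.shape[0]:
        raise InvalidArgumentError("need one averaged state vector per outcome")
    for tau, (o_what, _) in enumerate(outcomes):
        a[o_what] += eta * bma_states[tau]
    return a


@dataclass
class TrialResult:
    """Everything a single trial produced."""

    path: list[int]
    actions: list[int]
    outcomes: list[tuple[int, int]]
    beliefs: BeliefState
    g_per_epoch: list[np.ndarray]
    efe_per_epoch: list[EFEBreakdown]


def run_trial(
    model: GenerativeModel,
    maze: MazeGrid,
    location: int,
    config: AgentConfig | None = None,
    trace: SessionTrace | None = None,
    trial_index: int = 0,
    learn: bool = True,
) -> TrialResult:
    """Run one trial (``horizon`` actions, ``horizon + 1`` outcomes).

    Beliefs, the policy distribution and precision are reset at the trial
    boundary; the initial-state prior is a delta at ``location``.  The model's
    likelihood concentrations are updated in place when ``learn`` is True.
    """
    config = config or AgentConfig()
    n_epochs = config.epochs_per_trial
    if model.policy_set.horizon != config.horizon:
        raise InvalidArgumentError("policy horizon does not match config horizon")
    n = model.n_states
    d = np.zeros(n)
    d[location] = 1.0

    pols = model.policy_set.policies
    outcomes: list[tuple[int, int]] = []
    path = [location]
    actions: list[int] = []
    v_prev: np.ndarray | None = None
    beta, gamma = config.beta0, 1.0 / config.beta0
    g_per_epoch: list[np.ndarray] = []
    efe_per_epoch: list[EFEBreakdown] = []
    beliefs: BeliefState | None = None
    pi = None

    # running within-trial posterior over the likelihood: observed outcomes
    # count immediately for policy evaluation (novelty is consumed on arrival)
    a_trial = model.likelihood.a_what.copy()

    for tau in range(n_epochs):
        o_what, o_where = observe(maze, location)
        outcomes.append((o_what, o_where))
        a_trial[o_what, o_where] += config.eta
        beliefs = infer_states(
            model,
            pols,
            outcomes,
            v_init=v_prev,
            n_iter=config.iterations_per_epoch,
            step_size=config.step_size,
            f_tol=config.f_tol,
            d=d,
            record=trace is not None,
        )
        efe = expected_free_energy(
            model,
            beliefs.s,
            range(tau + 1, n_epochs),
            novelty_on=config.novelty_on,
            a_what=a_trial,
        )
        g = efe.total
        g_per_epoch.append(g)
        efe_per_epoch.append(efe)
        # evidence for each policy: its free energy given the outcomes so far
        # (policies whose past actions mismatch the executed ones are crushed)
        f_rel = beliefs.f_policy - beliefs.f_policy.min()
        beta, gamma, pi = _update_precision_coupled(f_rel, g, config.beta0)
        beliefs.pi, beliefs.gamma, beliefs.beta = pi, gamma, beta

        if trace is not None:
            _record_epoch(trace, beliefs, pi, gamma, location, trial_index, tau, config)
            trace.outcomes.append((trial_index, tau, *outcomes[-1]))

        if tau < n_epochs - 1:
            action = select_action(pi, pols, tau, n_actions=len(model.policy_set.actions))
            actions.append(action)
            v_prev = beliefs.v
            location = step(maze, location, action)
            path.append(location)
            if trace is not None:
                trace.actions.append((trial_index, tau, action))

    if learn:
        s_bma = np.einsum("p,ptn->tn", pi, beliefs.s)
        model.likelihood.a_what = learn_likelihood(
            model.likelihood.a_what, outcomes, s_bma, eta=config.eta, decay=config.decay
        )
    model.d = d

    return TrialResult(
        path=path,
        actions=actions,
        outcomes=outcomes,
        beliefs=beliefs,
        g_per_epoch=g_per_epoch,
        efe_per_epoch=efe_per_epoch,
    )


def _record_epoch(
    trace: SessionTrace,
    beliefs: BeliefState,
    pi: np.ndarray,
    gamma: float,
    location: int,
    trial_index: int,
    tau: int,
    config: AgentConfig,
) -> None:
    """Append one epoch's iteration history to the trace, padded to full length."""
    s_hist = beliefs.s_history
    v_hist = beliefs.v_history
    f_trace = beliefs.f_trace
    n_iter = config.iterations_per_epoch
    k_actual = s_hist.shape[0]
    for k in range(n_iter):
        kk = min(k, k_actual - 1)
        s_bma = np.einsum("p,ptn->tn", pi, s_hist[kk])
        v_bma = np.einsum("p,ptn->tn", pi, v_hist[kk])
        trace.add_bin(
            s_bma.reshape(-1),
            v_bma.reshape(-1),
            f_trace[kk],
            gamma,
            location,
            trial_index,
            tau,
        )
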