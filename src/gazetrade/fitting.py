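"""Hierarchical empirical-Bayes fitting by iterative importance sampling.

Each participant's parameter vector is treated as a draw from group-level
normal distributions in an unconstrained space (identity for the alpha/beta
weights, probit for unit-interval rates, log for the learning-rate offset).
Fitting alternates (a) per-participant importance sampling -- draw parameter
vectors from the current group distribution and weight them by the session
likelihood -- with (b) group-level re-estimation by importance-weighted
moment matching, an EM-like scheme that converges on maximum-likelihood
hyperparameters.  The per-participant log marginal likelihood is estimated
as the log mean importance weight, and models are compared with an
integrated BIC:

    iBIC = -2 sum_j log p(data_j | group) + n_hyper * log(N)

where N counts every modeled decision event (gather, look and choice) in
the cohort and n_hyper is twice the number of free parameters (a mean and a
standard deviation each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import json
import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .agent import PARAM_NAMES, AgentParams, constrain
from .likelihood import MODEL_SPECS, ModelSpec, ParticipantData, \
    dataset_loglik_many

__all__ = [
    "GroupHyperparams",
    "FitResult",
    "default_hyperpriors",
    "sample_params",
    "iis_fit",
    "ibic",
    "compare_models",
]

_IDX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: floor on group standard deviations (unconstrained space)
SD_FLOOR = 1e-3


@dataclass
class GroupHyperparams:
    """Group-level normal mean/sd per parameter, in unconstrained space."""

    mu: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.sd.items():
            if s < 0:
                raise ValueError(f"group sd for {name} must be nonnegative")

    def arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([self.mu[n] for n in names]),
                np.array([self.sd[n] for n in names]))

    def copy(self) -> "GroupHyperparams":
        return GroupHyperparams(mu=dict(self.mu), sd=dict(self.sd))

    def to_dict(self) -> dict:
        return {"mu": dict(self.mu), "sd": dict(self.sd)}


def default_hyperpriors() -> GroupHyperparams:
    """The starting hyperpriors: standard normals for all weights and for
    the probit-transformed unit-interval rates; for epsilon a lognormal with
    mean 2 and standard deviation 2 (underlying normal mu = ln 2 - ln(2)/2,
    sigma = sqrt(ln 2))."""
    mu = {n: 0.0 for n in PARAM_NAMES}
    sd = {n: 1.0 for n in PARAM_NAMES}
    mu["epsilon"] = float(np.log(2.0) - 0.5 * np.log(2.0))
    sd["epsilon"] = float(np.sqrt(np.log(2.0)))
    return GroupHyperparams(mu=mu, sd=sd)


def _constrain_matrix(x: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.empty_like(x)
    for j, n in enumerate(names):
        out[:, j] = constrain(n, x[:, j])
    return out


def _full_theta(constrained: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Embed active-parameter draws into full 13-column vectors (inactive
    weights fixed at 0, rates at benign defaults they never influence)."""
    S = constrained.shape[0]
    theta = np.zeros((S, len(PARAM_NAMES)))
    theta[:, _IDX["tau"]] = 0.5
    theta[:, _IDX["tau_color"]] = 0.5
    theta[:, _IDX["omega_color"]] = 0.5
    theta[:, _IDX["epsilon"]] = 1.0
    for j, n in enumerate(names):
        theta[:, _IDX[n]] = constrained[:, j]
    return theta


def sample_params(hyper: GroupHyperparams, n: int,
                  rng: np.random.Generator,
                  names: Sequence[str] = PARAM_NAMES) -> list[AgentParams]:
    """Draw ``n`` participant parameter sets from the group distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    x = _sample_unconstrained(hyper, n, rng, names)
    theta = _full_theta(_constrain_matrix(x, names), names)
    return [AgentParams.from_array(row) for row in theta]


def _sample_unconstrained(hyper: GroupHyperparams, n: int,
                          rng: np.random.Generator,
                          names: Sequence[str]) -> np.ndarray:
    """Draw unconstrained parameter matrices from the group normals.

    The standard-normal innovations are generated for the full parameter
    set and the active columns selected, so nested model variants fitted
    under the same seed share their innovations for shared parameters
    (common random numbers; marginal-likelihood noise then largely cancels
    in model comparisons).
    """
    mu, sd = hyper.arrays(names)
    z = rng.standard_normal((n, len(PARAM_NAMES)))
    cols = [_IDX[name] for name in names]
    return mu + sd * z[:, cols]


@dataclass
class FitResult:
    """Outcome of a hierarchical fit."""

    spec: ModelSpec
    hyper: GroupHyperparams
    param_names: tuple[str, ...]
    posterior_means: pd.DataFrame      # per participant, constrained space
    log_marginals: np.ndarray          # per participant
    ess: np.ndarray                    # per participant, final iteration
    trace: pd.DataFrame                # per-iteration hyperparameter path
    n_decisions: int
    n_iterations: int
    converged: bool
    samples: Optional[list[np.ndarray]] = field(default=None, repr=False)
    weights: Optional[list[np.ndarray]] = field(default=None, repr=False)

    @property
    def n_hyperparams(self) -> int:
        return 2 * len(self.param_names)

    def to_json(self) -> str:
        return json.dumps({
            "spec": self.spec.name,
            "hyper": self.hyper.to_dict(),
            "param_names": list(self.param_names),
            "posterior_means": self.posterior_means.to_dict(orient="list"),
            "log_marginals": [float(v) for v in self.log_marginals],
            "n_decisions": self.n_decisions,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        })


def iis_fit(cohort: Sequence[ParticipantData],
            spec: ModelSpec = MODEL_SPECS["full"],
            n_samples: int = 2000,
            max_iters: int = 50,
            tol: float = 1e-2,
            seed: int = 0,
            init: Optional[GroupHyperparams] = None,
            final_eval_samples: Optional[int] = None,
            keep_samples: bool = False,
            verbose: bool = False) -> FitResult:
    """Fit the group distribution and participant posteriors.

    Per iteration, each participant receives ``n_samples`` fresh draws from
    the current group distribution, weighted by exp(session loglik); group
    means and sds are re-estimated from the importance-weighted moments
    pooled across participants.  Stops when the largest change in any
    hyperparameter falls below ``tol``.  Deterministic under ``seed``.

    ``final_eval_samples`` requests one extra evaluation pass at the final
    group distribution with that many draws; the per-participant log
    marginals, posterior means and ESS then come from this larger sample,
    which stabilizes model comparisons.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    names = spec.active_params
    hyper = (init or default_hyperpriors()).copy()
    P = len(cohort)
    trace_rows = []
    log_marginals = np.zeros(P)
    ess = np.zeros(P)
    post_mean_con = np.zeros((P, len(names)))
    samples_kept: list[np.ndarray] = []
    weights_kept: list[np.ndarray] = []
    converged = False
    it = 0

    def _pass(it_tag: int, n_s: int) -> tuple[np.ndarray, np.ndarray]:
        """One importance-sampling sweep at the current hyperparameters."""
        mean_x = np.zeros((P, len(names)))
        m2_x = np.zeros((P, len(names)))
        if keep_samples:
            samples_kept.clear()
            weights_kept.clear()
        for j, data in enumerate(cohort):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, it_tag, j]))
            x = _sample_unconstrained(hyper, n_s, rng, names)
            theta = _full_theta(_constrain_matrix(x, names), names)
            ll = dataset_loglik_many(data, theta, spec)
            m = ll.max()
            w = np.exp(ll - m)
            wsum = w.sum()
            if wsum <= 0 or not np.isfinite(wsum):
                warnings.warn(f"participant {j}: degenerate importance "
                              f"weights (ESS ~ 0)")
                w = np.ones_like(w)
                wsum = w.sum()
            w /= wsum
            log_marginals[j] = logsumexp(ll) - np.log(n_s)
            ess[j] = 1.0 / np.sum(w ** 2)
            mean_x[j] = w @ x
            m2_x[j] = w @ (x ** 2)
            post_mean_con[j] = w @ _constrain_matrix(x, names)
            if keep_samples:
                samples_kept.append(theta)
                weights_kept.append(w.copy())
        return mean_x, m2_x

    for it in range(1, max_iters + 1):
        mean_x, m2_x = _pass(it, n_samples)
        new_mu = mean_x.mean(axis=0)
        var = m2_x.mean(axis=0) - 2.0 * new_mu * mean_x.mean(axis=0) \
            + new_mu ** 2
        new_sd = np.sqrt(np.maximum(var, SD_FLOOR ** 2))
        old_mu, old_sd = hyper.arrays(names)
        delta = max(np.abs(new_mu - old_mu).max(),
                    np.abs(new_sd - old_sd).max())
        hyper = GroupHyperparams(
            mu={n: float(v) for n, v in zip(names, new_mu)},
            sd={n: float(v) for n, v in zip(names, new_sd)},
        )
        trace_rows.append({"iteration": it, "delta": delta,
                           "mean_log_marginal": float(log_marginals.mean()),
                           "min_ess": float(ess.min()),
                           **{f"mu_{n}": hyper.mu[n] for n in names},
                           **{f"sd_{n}": hyper.sd[n] for n in names}})
        if verbose:
            print(f"  iter {it:3d}  delta={delta:.4f}  "
                  f"logZ={log_marginals.sum():.1f}  minESS={ess.min():.0f}")
        if delta < tol:
            converged = True
            break
    if final_eval_samples:
        _pass(0, final_eval_samples)  # iteration tags start at 1
    posterior_means = pd.DataFrame(post_mean_con, columns=list(names))
    n_decisions = int(sum(d.n_decisions for d in cohort))
    return FitResult(
        spec=spec, hyper=hyper, param_names=tuple(names),
        posterior_means=posterior_means, log_marginals=log_marginals.copy(),
        ess=ess.copy(), trace=pd.DataFrame(trace_rows),
        n_decisions=n_decisions, n_iterations=it, converged=converged,
        samples=samples_kept if keep_samples else None,
        weights=weights_kept if keep_samples else None,
    )


def ibic(fit: FitResult, cohort: Optional[Sequence[ParticipantData]] = None
         ) -> float:
    """Integrated BIC: -2 * sum log marginal + n_hyper * log(N decisions)."""
    n = fit.n_decisions if cohort is None \
        else int(sum(d.n_decisions for d in cohort))
    return float(-2.0 * fit.log_marginals.sum()
                 + fit.n_hyperparams * np.log(n))


def compare_models(cohort: Sequence[ParticipantData],
                   specs: Sequence[ModelSpec] = tuple(MODEL_SPECS.values()),
                   n_samples: int = 2000, max_iters: int = 50,
                   tol: float = 1e-2, seed: int = 0,
                   final_eval_samples: Optional[int] = None,
                   verbose: bool = False) -> pd.DataFrame:
    """Fit each model variant with a shared seed and rank them by iBIC."""
    rows = []
    fits = {}
    for spec in specs:
        fit = iis_fit(cohort, spec, n_samples=n_samples, max_iters=max_iters,
                      tol=tol, seed=seed,
                      final_eval_samples=final_eval_samples, verbose=verbose)
        fits[spec.name] = fit
        rows.append({
            "model": spec.name,
            "n_params": len(spec.active_params),
            "n_hyperparams": fit.n_hyperparams,
            "sum_log_marginal": float(fit.log_marginals.sum()),
            "deviance": float(-2.0 * fit.log_marginals.sum()),
            "ibic": ibic(fit),
            "converged": fit.converged,
            "n_iterations": fit.n_iterations,
        })
    table = pd.DataFrame(rows).sort_values("ibic").reset_index(drop=True)
    table.attrs["fits"] = fits
    return table
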