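"""From-scratch survival machinery.

Implements the three statistical tools the prognostic-score validation
rests on, without delegating to an external survival package:

* the Kaplan–Meier product-limit estimator (:func:`km_estimate`), with
  step-function evaluation and median extraction;
* the k-sample log-rank test (:func:`logrank_test`), using the
  hypergeometric observed-minus-expected formulation;
* Cox proportional-hazards regression (:class:`CoxPH`), maximising the
  partial likelihood by Newton–Raphson with Breslow tie handling (Efron
  behind a switch), Wald standard errors, and step-halving safeguards.

Conventions: time is measured in months from the start of radiotherapy;
events are deaths; a censored subject tied with a death at the same time is
still at risk for that death (the standard convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "KaplanMeierCurve",
    "LogRankResult",
    "km_estimate",
    "survival_probability_at",
    "km_median",
    "logrank_test",
    "CoxPH",
    "CoxPHResults",
    "median_follow_up_survivors",
    "as_arrays",
]


def as_arrays(durations, events) -> tuple[np.ndarray, np.ndarray]:
    """Coerce durations/events to float and boolean (True = died) arrays."""
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events)
    if e.dtype.kind in "USO":
        e = np.asarray([str(x).lower() in ("died", "dead", "1", "true") for x in e])
    e = e.astype(bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("durations and events must be 1-d and equal length")
    if t.size == 0:
        raise ValueError("empty survival sample")
    if np.any(t < 0):
        raise ValueError("durations must be >= 0")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KaplanMeierCurve:
    """Product-limit estimate on the grid of distinct death times.

    ``survival[i]`` is S(t) at ``event_times[i]``, the running product of
    ``1 - events/at_risk``; S is 1 before the first death.  ``max_follow_up``
    is the largest observed time (death or censoring): the step function is
    undefined beyond it and evaluation there returns NaN.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    n: int
    max_follow_up: float
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        """S(t) by step-function evaluation; NaN beyond last follow-up."""
        if t < 0:
            raise ValueError("time must be >= 0")
        if t > self.max_follow_up:
            return math.nan
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self):
        """Smallest death time with S(t) <= 0.5, or None when not reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        if below.size == 0:
            return None
        return float(self.event_times[below[0]])


def km_estimate(durations, events) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit estimator.

    Parameters may be any sequences of times and death indicators (boolean,
    0/1, or "died"/"censored" strings).  An all-censored sample yields the
    constant curve S = 1, flagged via ``all_censored``.
    """
    t, e = as_arrays(durations, events)
    n = t.size
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]

    death_times, deaths = np.unique(t[e], return_counts=True)
    if death_times.size == 0:
        return KaplanMeierCurve(
            event_times=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            events=np.empty(0, dtype=int),
            survival=np.empty(0),
            n=n,
            max_follow_up=float(t[-1]),
            all_censored=True,
        )
    # at risk at time u: everyone with observed time >= u (ties censored at a
    # death time stay in that death's risk set)
    at_risk = n - np.searchsorted(t, death_times, side="left")
    survival = np.cumprod(1.0 - deaths / at_risk)
    return KaplanMeierCurve(
        event_times=death_times,
        at_risk=at_risk.astype(int),
        events=deaths,
        survival=survival,
        n=n,
        max_follow_up=float(t[-1]),
    )


def survival_probability_at(curve: KaplanMeierCurve, t: float) -> float:
    """Step-function evaluation of a KM curve at time ``t`` (months)."""
    return curve.survival_at(t)


def km_median(curve: KaplanMeierCurve):
    """Median survival: first death time with S <= 0.5; None if not reached."""
    return curve.median()


def median_follow_up_survivors(durations, events) -> float:
    """Median follow-up among censored (alive) patients only."""
    t, e = as_arrays(durations, events)
    alive = t[~e]
    if alive.size == 0:
        raise ValueError("no censored patients: median follow-up undefined")
    return float(np.median(alive))


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    observed: np.ndarray = field(default=None, repr=False)
    expected: np.ndarray = field(default=None, repr=False)


def logrank_test(groups: Sequence[tuple]) -> LogRankResult:
    """k-sample log-rank test.

    ``groups`` is a sequence of ``(durations, events)`` pairs, one per
    group.  At each distinct death time the observed deaths per group are
    compared with their hypergeometric expectation given the risk sets; the
    summed differences give a chi-square statistic with k-1 degrees of
    freedom.  With zero deaths overall the statistic is 0 and p = 1.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ts, es, labels = [], [], []
    for j, (durations, events) in enumerate(groups):
        t, e = as_arrays(durations, events)
        ts.append(t)
        es.append(e)
        labels.append(np.full(t.size, j))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(labels)

    death_times = np.unique(t[e])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for u in death_times:
        at_risk_mask = t >= u
        n_total = at_risk_mask.sum()
        dead_mask = (t == u) & e
        d_total = dead_mask.sum()
        n_j = np.bincount(g[at_risk_mask], minlength=k).astype(float)
        d_j = np.bincount(g[dead_mask], minlength=k).astype(float)
        observed += d_j
        p_j = n_j / n_total
        expected += d_total * p_j
        if n_total > 1:
            scale = d_total * (n_total - d_total) / (n_total - 1)
            cov += scale * (np.diag(p_j) - np.outer(p_j, p_j))

    df = k - 1
    if observed.sum() == 0:
        return LogRankResult(0.0, df, 1.0, observed, expected)
    z = (observed - expected)[:df]
    v = cov[:df, :df]
    chi2 = float(z @ np.linalg.pinv(v) @ z)
    chi2 = max(chi2, 0.0)
    p = float(_stats.chi2.sf(chi2, df))
    return LogRankResult(chi2, df, p, observed, expected)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    pass


class CoxPH:
    """Cox proportional-hazards model, fit by maximum partial likelihood.

    Parameters
    ----------
    durations, events : array-like
        Follow-up times (months) and death indicators.
    exog : array-like, shape (n, p)
        Covariate matrix; categorical covariates must already be expanded
        against their reference level (the reference carries no column and
        reports hazard ratio 1 by construction).
    names : sequence of str, optional
        Covariate names for the results tables.
    ties : {"breslow", "efron"}
        Tie-handling approximation; Breslow is the default.
    """

    def __init__(self, durations, events, exog, names=None, ties="breslow"):
        self.durations, self.events = as_arrays(durations, events)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.durations.size:
            raise ValueError("exog rows must match number of observations")
        self.exog = X
        self.names = (
            list(names)
            if names is not None
            else [f"x{i}" for i in range(X.shape[1])]
        )
        if len(self.names) != X.shape[1]:
            raise ValueError("names length must match exog columns")
        if ties not in ("breslow", "efron"):
            raise ValueError("ties must be 'breslow' or 'efron'")
        self.ties = ties
        if int(np.unique(self.durations[self.events]).size) < 2:
            raise ValueError("need at least two distinct event times")
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            raise ValueError("design matrix is rank deficient after centering")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, duration_col: str, event_col: str,
        covariate_cols: Sequence[str], ties: str = "breslow",
    ) -> "CoxPH":
        return cls(
            df[duration_col].to_numpy(),
            df[event_col].to_numpy(),
            df[list(covariate_cols)].to_numpy(dtype=float),
            names=list(covariate_cols),
            ties=ties,
        )

    # -- partial likelihood machinery -------------------------------------

    def _prepare(self):
        """Sort descending by time; precompute tied-death-time structure."""
        order = np.argsort(-self.durations, kind="stable")
        t = self.durations[order]
        e = self.events[order]
        X = self.exog[order]
        death_times = np.unique(t[e])[::-1]  # descending
        # last index (descending order) of the risk set {j : t_j >= u}
        hi = np.searchsorted(-t, -death_times, side="right") - 1
        death_pos = np.nonzero(e)[0]
        td = t[death_pos]  # descending with possible ties
        lo_b = np.searchsorted(-td, -death_times, side="left")
        hi_b = np.searchsorted(-td, -death_times, side="right")
        dead_idx = [death_pos[a:b] for a, b in zip(lo_b, hi_b)]
        d = hi_b - lo_b
        self._cache = dict(t=t, e=e, X=X, hi=hi, dead_idx=dead_idx, d=d)
        return self._cache

    def _loglik_grad_hess(self, beta, c):
        X, e, hi, d = c["X"], c["e"], c["hi"], c["d"]
        p = X.shape[1]
        eta = X @ beta
        eta -= eta.max()  # overflow guard; the shift cancels in ll and ratios
        w = np.exp(eta)
        # cumulative risk-set sums in descending-time order
        S0 = np.cumsum(w)
        S1 = np.cumsum(w[:, None] * X, axis=0)
        S2 = np.cumsum(np.einsum("ij,ik->ijk", X, X) * w[:, None, None], axis=0)

        s0 = S0[hi]
        mu = S1[hi] / s0[:, None]
        ll = float(eta[e].sum() - (d * np.log(s0)).sum())
        grad = X[e].sum(axis=0) - (d[:, None] * mu).sum(axis=0)
        hess = -(
            S2[hi] / s0[:, None, None]
            - np.einsum("ij,ik->ijk", mu, mu)
        )
        hess = (d[:, None, None] * hess).sum(axis=0)

        if self.ties == "efron":
            # replace the Breslow contribution of tied groups (d > 1) with
            # Efron's successively-thinned denominators
            for m in np.nonzero(d > 1)[0]:
                dead = c["dead_idx"][m]
                dm = d[m]
                xs = X[dead].sum(axis=0)
                s0m, s1m, s2m = S0[hi[m]], S1[hi[m]], S2[hi[m]]
                mum = s1m / s0m
                ll += dm * math.log(s0m)
                grad -= xs - dm * mum
                hess += dm * (s2m / s0m - np.outer(mum, mum))
                wd = w[dead].sum()
                s1d = (w[dead, None] * X[dead]).sum(axis=0)
                s2d = np.einsum("ij,ik->jk", X[dead] * w[dead, None], X[dead])
                for l in range(dm):
                    f = l / dm
                    s0l = s0m - f * wd
                    s1l = s1m - f * s1d
                    s2l = s2m - f * s2d
                    ll -= math.log(s0l)
                    mul = s1l / s0l
                    grad += xs / dm - mul
                    hess -= s2l / s0l - np.outer(mul, mul)
        return ll, grad, hess

    def fit(
        self, max_iter: int = 50, tol: float = 1e-9, gtol: float = 1e-8
    ) -> "CoxPHResults":
        """Newton–Raphson with step-halving on partial-likelihood decrease.

        Convergence requires a relative change in the log partial
        likelihood below ``tol`` together with either a score (gradient)
        norm below ``gtol`` or a Newton decrement (the attainable further
        likelihood gain, g'H^-1 g / 2) at floating-point noise level — the
        latter handles large samples where the likelihood plateaus before
        the absolute gradient norm can shrink further.  Monotone likelihood
        (perfect separation) is reported via ``separation_suspected`` and
        ``converged=False`` rather than raised.
        """
        cache = self._prepare()
        p = self.exog.shape[1]
        beta = np.zeros(p)
        ll, grad, hess = self._loglik_grad_hess(beta, cache)
        converged = False
        separation = False
        it = 0
        for it in range(1, max_iter + 1):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            new_beta = beta + step
            new = self._loglik_grad_hess(new_beta, cache)
            # step-halve only on decreases beyond floating-point noise in
            # the likelihood, so late Newton steps can still shrink the score
            noise = 64 * np.finfo(float).eps * max(1.0, abs(ll))
            halvings = 0
            while new[0] < ll - noise and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new = self._loglik_grad_hess(new_beta, cache)
                halvings += 1
            beta = new_beta
            rel = abs(new[0] - ll) / max(1.0, abs(ll))
            ll, grad, hess = new
            if np.any(np.abs(beta) > 20):
                separation = True
                break
            if np.linalg.norm(grad) < gtol:
                converged = True
                break
            if rel < tol:
                try:
                    polish = np.linalg.solve(-hess, grad)
                    decrement = 0.5 * float(grad @ polish)
                except np.linalg.LinAlgError:
                    polish, decrement = None, math.inf
                if decrement < 1e-12:
                    if polish is not None:
                        # one last full Newton step costs nothing measurable
                        # in likelihood but crushes the remaining score norm
                        candidate = self._loglik_grad_hess(beta + polish, cache)
                        if np.linalg.norm(candidate[1]) < np.linalg.norm(grad):
                            beta = beta + polish
                            ll, grad, hess = candidate
                    converged = True
                    break

        cov = np.linalg.pinv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return CoxPHResults(
            model=self,
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(se, index=self.names),
            cov_params=pd.DataFrame(cov, index=self.names, columns=self.names),
            loglik=ll,
            score_norm=float(np.linalg.norm(grad)),
            converged=converged,
            iterations=it,
            separation_suspected=separation,
        )


@dataclass
class CoxPHResults:
    """Fitted Cox model: coefficients, Wald inference and diagnostics."""

    model: CoxPH
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    score_norm: float
    converged: bool
    iterations: int
    separation_suspected: bool = False

    _Z95 = 1.959963984540054

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self) -> pd.DataFrame:
        """95% Wald confidence intervals on the hazard-ratio scale."""
        lo = np.exp(self.params - self._Z95 * self.bse)
        hi = np.exp(self.params + self._Z95 * self.bse)
        return pd.DataFrame({"hr_lower95": lo, "hr_upper95": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(
            2.0 * _stats.norm.sf(np.abs(z)), index=self.params.index
        )

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "HR": self.hazard_ratios,
                "hr_lower95": ci["hr_lower95"],
                "hr_upper95": ci["hr_upper95"],
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        frame = self.summary_frame()
        lines = [
            "Cox proportional hazards (partial likelihood, "
            f"{self.model.ties} ties)",
            f"n = {self.model.durations.size}, "
            f"events = {int(self.model.events.sum())}, "
            f"log PL = {self.loglik:.3f}",
            f"converged = {self.converged} in {self.iterations} iterations "
            f"(|score| = {self.score_norm:.2e})",
        ]
        if self.separation_suspected:
            lines.append(
                "WARNING: monotone likelihood suspected (possible perfect "
                "separation); estimates are unreliable"
            )
        lines.append(frame.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)
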