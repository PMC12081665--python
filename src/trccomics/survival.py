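"""Survival analysis: Kaplan-Meier, log-rank, univariate Cox, optimal cutpoint.

The stratification workflow mirrors common tumour-cohort practice: a
continuous per-sample score (e.g. an OxPhos or myCAF signature score) is
dichotomized at the cutpoint maximising the standardized log-rank statistic
over all admissible thresholds (maximally selected rank statistic, the
``surv_cutpoint`` approach), and the induced high/low groups are compared by
Kaplan-Meier curves, log-rank test and a univariate Cox model reporting the
hazard ratio.  Because the cutpoint is chosen to maximise separation, the
log-rank p-value at the selected threshold is optimistic; results carry an
explicit flag saying so.

The Cox fit maximises the Breslow partial likelihood by Newton-Raphson;
standard errors come from the observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass
class SurvivalTable:
    """Right-censored time-to-event records keyed by sample id."""

    table: pd.DataFrame  # sample_id, time, event (+ covariates)

    def __post_init__(self) -> None:
        for col in ("sample_id", "time", "event"):
            if col not in self.table.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (self.table["time"] <= 0).any():
            raise ValueError("times must be positive")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SurvivalTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def join_scores(self, scores: pd.Series, name: str | None = None) -> "SurvivalTable":
        """Attach a per-sample score column, inner-joined on sample id."""
        name = name or scores.name or "score"
        merged = self.table.merge(
            scores.rename(name), left_on="sample_id", right_index=True, how="inner"
        )
        return SurvivalTable(merged)


def km_estimate(
    table: SurvivalTable, groups: Sequence | None = None
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, optionally per group.

    Returns ``{group: DataFrame(time, survival, at_risk)}``; the pooled
    cohort is keyed ``"all"`` when no groups are given.
    """
    t, e = table.time, table.event
    if groups is None:
        groups = np.repeat("all", len(table))
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=e[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        out[str(g)] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(),
                "at_risk": at_risk.to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def plot_km(table: SurvivalTable, groups: Sequence, ax=None, labels=("low", "high")):
    """Plot Kaplan-Meier curves per group (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(table.time[mask], event_observed=table.event[mask])
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    return ax


def _logrank_o_e_v(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float, float]:
    """Observed events, expectation and hypergeometric variance for group 1."""
    order = np.argsort(time, kind="stable")
    t, e, g1 = time[order], event[order], in_group1[order]
    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        dying = (t == et) & (e == 1)
        d = dying.sum()
        d1 = (dying & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(O), float(E), float(V)


def logrank_test(
    table: SurvivalTable, groups: Sequence
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    Standard observed-minus-expected statistic over pooled event times with
    hypergeometric variance.  With no events at all the statistic is
    undefined and ``(nan, nan)`` is returned.
    """
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"expected two groups, got {len(uniq)}")
    if (groups == uniq[0]).sum() == 0 or (groups == uniq[1]).sum() == 0:
        raise ValueError("both groups must be non-empty")
    if table.event.sum() == 0:
        return float("nan"), float("nan")
    O, E, V = _logrank_o_e_v(table.time, table.event, groups == uniq[0])
    if V == 0:
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxFit:
    """Univariate Cox proportional-hazards fit (Breslow partial likelihood)."""

    covariate: str
    beta: float
    se: float
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    separation: bool = False

    @property
    def hazard_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def wald_p(self) -> float:
        if self.se == 0 or not np.isfinite(self.se):
            return float("nan")
        z = self.beta / self.se
        return float(2 * stats.norm.sf(abs(z)))

    def confint(self, alpha: float = 0.05) -> tuple[float, float]:
        """Hazard-ratio confidence interval."""
        z = stats.norm.ppf(1 - alpha / 2)
        return float(np.exp(self.beta - z * self.se)), float(np.exp(self.beta + z * self.se))

    def summary(self) -> str:
        lo, hi = self.confint()
        lines = [
            f"Cox PH (univariate, Breslow ties)  n={self.n}, events={self.n_events}",
            f"  covariate : {self.covariate}",
            f"  beta      : {self.beta:.4f} (SE {self.se:.4f})",
            f"  HR        : {self.hazard_ratio:.3f} [95% CI {lo:.3f}, {hi:.3f}]",
            f"  Wald p    : {self.wald_p:.3g}",
        ]
        if self.separation:
            lines.append("  warning   : monotone likelihood, beta capped")
        if not self.converged:
            lines.append("  warning   : Newton-Raphson did not converge")
        return "\n".join(lines)


def _breslow_loglik_grad_hess(
    beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Breslow partial log-likelihood and derivatives for one covariate."""
    order = np.argsort(-t, kind="stable")  # decreasing time: cumulative risk sets
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    # risk set of an event at time ti = all with t >= ti; with decreasing sort,
    # all indices up to the last position sharing ti
    ll = grad = hess = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # events at this time
        ev = e[i : j + 1] == 1
        d = ev.sum()
        if d > 0:
            S0, S1, S2 = s0[j], s1[j], s2[j]
            xs = x[i : j + 1][ev]
            ll += beta * xs.sum() - d * np.log(S0)
            mean = S1 / S0
            grad += xs.sum() - d * mean
            hess += d * (S2 / S0 - mean**2)
        i = j + 1
    return ll, grad, hess


def cox_univariate(
    table: SurvivalTable,
    covariate: str | Sequence[float],
    max_iter: int = 50,
    tol: float = 1e-9,
    beta_cap: float = 15.0,
) -> CoxFit:
    """Fit a univariate Cox model by Newton-Raphson (Breslow ties).

    ``covariate`` may name a column of the table or be a vector aligned with
    its rows.  Monotone likelihood (perfect separation) is detected when the
    estimate runs away; beta is capped and flagged.
    """
    if isinstance(covariate, str):
        if covariate not in table.table.columns:
            raise ValueError(f"covariate {covariate!r} not in table")
        x = table.table[covariate].to_numpy(dtype=float)
        name = covariate
    else:
        x = np.asarray(covariate, dtype=float)
        name = "score"
        if len(x) != len(table):
            raise ValueError("covariate length mismatch")
    t, e = table.time, table.event
    if e.sum() == 0:
        raise ValueError("no events; Cox model undefined")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    scale = np.std(x)
    xs = (x - x.mean()) / scale  # standardized for stable Newton steps
    beta = 0.0
    converged = False
    separation = False
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik_grad_hess(beta, t, e, xs)
        if hess <= 0:
            separation = True
            break
        step = grad / hess
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(beta) * 1.0 > beta_cap:  # on the standardized scale
            beta = float(np.sign(beta) * beta_cap)
            separation = True
            break
        if abs(step) < tol:
            converged = True
            break
    ll, grad, hess = _breslow_loglik_grad_hess(beta, t, e, xs)
    se_std = 1.0 / np.sqrt(hess) if hess > 0 else float("inf")
    return CoxFit(
        covariate=name,
        beta=beta / scale,
        se=se_std / scale,
        log_likelihood=float(ll),
        n=len(table),
        n_events=int(e.sum()),
        converged=converged,
        separation=separation,
    )


@dataclass
class CutpointResult:
    """Maximally selected log-rank stratification of a continuous score."""

    covariate: str
    threshold: float
    statistic: float  # standardized log-rank |z| at the chosen threshold
    groups: pd.Series = field(repr=False)  # "high"/"low" per sample
    minprop: float = 0.1
    logrank_chi2: float = float("nan")
    logrank_p: float = float("nan")
    cox: CoxFit | None = None
    p_is_optimistic: bool = True  # threshold chosen to maximise separation

    def summary(self) -> str:
        lines = [
            f"Optimal cutpoint for {self.covariate!r} (minprop={self.minprop})",
            f"  threshold     : {self.threshold:.6g}",
            f"  max |z|       : {self.statistic:.4f}",
            f"  group sizes   : high={int((self.groups == 'high').sum())}, "
            f"low={int((self.groups == 'low').sum())}",
            f"  log-rank chi2 : {self.logrank_chi2:.4f} (p={self.logrank_p:.3g}, "
            "optimistic: threshold maximises separation)",
        ]
        if self.cox is not None:
            lo, hi = self.cox.confint()
            lines.append(
                f"  Cox HR (high vs low): {self.cox.hazard_ratio:.3f} "
                f"[95% CI {lo:.3f}, {hi:.3f}], Wald p={self.cox.wald_p:.3g}"
            )
        return "\n".join(lines)


def optimal_cutpoint(
    table: SurvivalTable,
    score: str | Sequence[float],
    minprop: float = 0.1,
    fit_cox: bool = True,
) -> CutpointResult:
    """Dichotomize a score at the maximally selected log-rank threshold.

    Every midpoint between consecutive distinct score values whose induced
    split leaves at least ``minprop`` of the samples on each side is
    evaluated by the standardized log-rank statistic |O - E| / sqrt(V);
    the argmax wins (ties: lower threshold).  The returned result carries
    the induced high/low groups and the log-rank / Cox statistics of the
    split, flagged as optimistic.
    """
    if not (0 < minprop < 0.5):
        raise ValueError("minprop must be in (0, 0.5)")
    if isinstance(score, str):
        x = table.table[score].to_numpy(dtype=float)
        name = score
    else:
        x = np.asarray(score, dtype=float)
        name = "score"
        if len(x) != len(table):
            raise ValueError("score length mismatch")
    if np.all(x == x[0]):
        raise ValueError("score is constant; no admissible split")
    n = len(x)
    t, e = table.time, table.event
    distinct = np.unique(x)
    thresholds = (distinct[:-1] + distinct[1:]) / 2
    best_z, best_thr = -np.inf, None
    for thr in thresholds:
        high = x > thr
        n_high = int(high.sum())
        if min(n_high, n - n_high) < minprop * n:
            continue
        O, E, V = _logrank_o_e_v(t, e, high)
        if V <= 0:
            continue
        z = abs(O - E) / np.sqrt(V)
        if z > best_z + 1e-12:  # strict improvement; ties keep the lower threshold
            best_z, best_thr = z, float(thr)
    if best_thr is None:
        raise ValueError("no admissible split satisfies minprop")
    high = x > best_thr
    groups = pd.Series(
        np.where(high, "high", "low"), index=table.table["sample_id"], name="group"
    )
    chi2, p = logrank_test(table, np.where(high, "high", "low"))
    cox = None
    if fit_cox:
        cox = cox_univariate(table, high.astype(float))
        cox.covariate = f"{name} > {best_thr:.6g}"
    return CutpointResult(
        covariate=name,
        threshold=best_thr,
        statistic=float(best_z),
        groups=groups,
        minprop=minprop,
        logrank_chi2=chi2,
        logrank_p=p,
        cox=cox,
    )
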