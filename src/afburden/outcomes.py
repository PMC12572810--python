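"""12-month landmark outcome analysis by AF-burden quartile.

Cohort construction (patients event-free and alive at the landmark with at
least two analysable first-year ECGs), burden-quartile assignment with exact
zeros tied into Q1, incidence rates per 100 patient-years, the Aalen-Johansen
cumulative-incidence estimator under competing risks, a Newton-Raphson Cox
proportional-hazards fit of the partial likelihood with Breslow tie handling,
and a LOESS smoother of event probability against burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

EVENT_CODES = {"censored": 0, "primary": 1, "competing_death": 2}
QUARTILES = ("Q1", "Q2", "Q3", "Q4")


class ConvergenceError(RuntimeError):
    pass


# --------------------------------------------------------------------------- #
# quartiles and rates
# --------------------------------------------------------------------------- #


def assign_quartiles(burdens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical quartile labels (1..4) and the [q25, q50, q75] edges.

    A burden exactly equal to an edge is resolved downward, so all exact-zero
    burdens fall into Q1 even when zeros exceed a quarter of the cohort;
    group sizes are then unequal by construction.
    """
    burdens = np.asarray(burdens, dtype=float)
    if len(burdens) < 4:
        raise ValueError("need at least 4 patients")
    edges = np.quantile(burdens, [0.25, 0.5, 0.75])
    if np.all(burdens == burdens[0]):
        warnings.warn("all burdens identical: single quartile group", stacklevel=2)
    labels = np.searchsorted(edges, burdens, side="left") + 1
    return labels.astype(int), edges


def incidence_rate(n_events: int, person_years: float) -> float:
    """Events per 100 patient-years, rounded to one decimal (two when the
    rate is below 0.5, following the precision used for rare components)."""
    if n_events < 0:
        raise ValueError("negative event count")
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    rate = 100.0 * n_events / person_years
    return round(rate, 2) if rate < 0.5 else round(rate, 1)


# --------------------------------------------------------------------------- #
# landmark cohort
# --------------------------------------------------------------------------- #


@dataclass
class LandmarkCohort:
    records: pd.DataFrame
    landmark_day: int
    quartile_edges: np.ndarray
    n_excluded_event: int
    n_excluded_ecgs: int


def build_landmark_cohort(
    patients: pd.DataFrame,
    landmark_day: int = 365,
    burden_col: str = "burden",
    event_day_col: str = "event_day",
    event_type_col: str = "event_type",
    n_ecgs_col: str = "n_ecgs_analysable",
) -> LandmarkCohort:
    """Restart the clock at the landmark.

    Excludes patients with a primary event or death before the landmark and
    patients with fewer than two analysable first-year ECGs; remaining
    follow-up is measured from the landmark. Burden must already be computed
    from first-year observations only.
    """
    df = patients.copy()
    if (df[event_day_col] < 0).any():
        raise ValueError("event before randomization")
    fatal = df[event_type_col].isin(["primary", "competing_death"])
    pre_landmark = fatal & (df[event_day_col] <= landmark_day)
    too_few = df[n_ecgs_col] < 2
    kept = df[~pre_landmark & ~too_few].copy()
    kept["time_days"] = kept[event_day_col] - landmark_day
    kept = kept[kept["time_days"] > 0]
    labels, edges = assign_quartiles(kept[burden_col].to_numpy())
    kept["quartile"] = [f"Q{q}" for q in labels]
    return LandmarkCohort(
        records=kept.reset_index(drop=True),
        landmark_day=landmark_day,
        quartile_edges=edges,
        n_excluded_event=int(pre_landmark.sum()),
        n_excluded_ecgs=int((too_few & ~pre_landmark).sum()),
    )


def rates_by_group(
    records: pd.DataFrame,
    group_col: str = "quartile",
    time_col: str = "time_days",
    event_type_col: str = "event_type",
) -> pd.DataFrame:
    """Events, person-years and incidence per 100 patient-years per group."""
    rows = []
    for grp, sub in records.groupby(group_col, sort=True):
        py = sub[time_col].sum() / 365.0
        n_ev = int((sub[event_type_col] == "primary").sum())
        rows.append(
            {
                group_col: grp,
                "n": len(sub),
                "events": n_ev,
                "person_years": py,
                "rate_per_100py": incidence_rate(n_ev, py),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# Aalen-Johansen
# --------------------------------------------------------------------------- #


def aalen_johansen(
    records: pd.DataFrame,
    target_event: str = "primary",
    time_col: str = "time_days",
    event_type_col: str = "event_type",
) -> pd.DataFrame:
    """Cumulative incidence of ``target_event`` under competing risks.

    CIF(t) = sum over event times t_i <= t of S(t_i-) * d_i / n_i, with S the
    all-cause Kaplan-Meier survivor. Returns a step function with columns
    time, cif and survival (all-cause); at every step the survivor plus the
    CIFs of all event types sums to one.
    """
    if len(records) == 0:
        raise ValueError("no records")
    ev = records[event_type_col]
    unknown = set(ev.unique()) - set(EVENT_CODES)
    if unknown:
        raise ValueError(f"unknown event code(s): {sorted(unknown)}")
    if target_event not in EVENT_CODES or target_event == "censored":
        raise ValueError(f"invalid target event {target_event!r}")

    t = records[time_col].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t = t[order]
    ev = ev.to_numpy()[order]

    times = np.unique(t[ev != "censored"])
    n = len(t)
    out = [(0.0, 0.0, 1.0)]
    surv = 1.0
    cif = 0.0
    for ti in times:
        at_risk = int(np.count_nonzero(t >= ti))
        d_all = int(np.count_nonzero((t == ti) & (ev != "censored")))
        d_target = int(np.count_nonzero((t == ti) & (ev == target_event)))
        cif += surv * d_target / at_risk
        surv *= 1.0 - d_all / at_risk
        out.append((float(ti), cif, surv))
    return pd.DataFrame(out, columns=["time", "cif", "survival"])


# --------------------------------------------------------------------------- #
# Cox proportional hazards (Breslow ties)
# --------------------------------------------------------------------------- #


def _cox_loglik_blocks(beta, blocks):
    """Sum the Breslow partial likelihood over independent strata."""
    p = len(beta)
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for X, t, d in blocks:
        l, g, h = _cox_loglik(beta, X, t, d)
        ll += l
        grad += g
        hess += h
    return ll, grad, hess


def _cox_loglik(beta, X, t, d):
    """Breslow partial log-likelihood with gradient and Hessian."""
    eta = X @ beta
    eta = eta - eta.max()  # stabilise; constant shift cancels in the ratio
    w = np.exp(eta)
    order = np.argsort(-t, kind="stable")  # decreasing time
    Xo, to, do_, wo = X[order], t[order], d[order], w[order]
    p = X.shape[1]

    cs0 = np.cumsum(wo)
    cs1 = np.cumsum(wo[:, None] * Xo, axis=0)
    cs2 = np.cumsum(wo[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)

    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    n = len(to)
    eta_o = eta[order]
    while i < n:
        j = i
        while j < n and to[j] == to[i]:
            j += 1
        # risk set for this time = all with t >= to[i] = entries [0, j)
        ev = slice(i, j)
        d_here = int(do_[ev].sum())
        if d_here > 0:
            s0 = cs0[j - 1]
            s1 = cs1[j - 1]
            s2 = cs2[j - 1]
            mask = do_[ev].astype(bool)
            ll += float(eta_o[ev][mask].sum()) - d_here * np.log(s0)
            xbar = s1 / s0
            grad += Xo[ev][mask].sum(axis=0) - d_here * xbar
            hess -= d_here * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return ll, grad, hess


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time_days",
    event_col: str = "event",
    strata: str | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Newton-Raphson fit of the Cox partial likelihood (Breslow ties).

    ``event_col`` is 1/True for the event of interest and 0/False otherwise
    (competing events treated as censoring for the cause-specific hazard).
    ``strata`` names an optional grouping column (e.g. study centre) giving
    each stratum its own baseline hazard — the partial likelihood is summed
    over strata. Returns one row per covariate: coef, hr, se, 95% Wald CI
    and two-sided p-value. Raises :class:`ConvergenceError` on
    non-convergence or separation-like divergence.
    """
    X = records[covariates].to_numpy(dtype=float)
    t = records[time_col].to_numpy(dtype=float)
    d = records[event_col].to_numpy(dtype=float)
    if int(d.sum()) < 2 or len(np.unique(t[d > 0])) < 2:
        raise ValueError("need at least 2 distinct event times")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    # scale covariates for stable Newton steps; back-transform at the end
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale

    if strata is None:
        blocks = [(Xs, t, d)]
    else:
        codes = records[strata].to_numpy()
        blocks = [
            (Xs[codes == s], t[codes == s], d[codes == s])
            for s in np.unique(codes)
        ]

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_blocks(beta, blocks)
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving line search
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new = _cox_loglik_blocks(cand, blocks)[0]
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2
        beta = beta + alpha * step
        if np.max(np.abs(beta)) > 10:  # log-HR per SD beyond any plausible fit
            raise ConvergenceError(
                "diverging coefficients (possible separation): "
                f"max |beta| = {np.max(np.abs(beta)):.1f} on the scaled covariates"
            )
        if abs(ll_new - ll_old) < tol and np.max(np.abs(grad)) < 1e-6:
            break
        ll_old = ll_new
    else:
        raise ConvergenceError(f"no convergence after {max_iter} iterations")

    _, grad, hess = _cox_loglik_blocks(beta, blocks)
    if np.max(np.abs(grad)) > 1e-5:
        raise ConvergenceError(f"gradient not null at optimum: {grad}")
    cov = np.linalg.inv(-hess)
    se_s = np.sqrt(np.diag(cov))
    coef = beta / scale
    se = se_s / scale
    z = coef / se
    from scipy import stats

    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "covariate": covariates,
            "coef": coef,
            "hr": np.exp(coef),
            "se": se,
            "ci_lower": np.exp(coef - 1.959963984540054 * se),
            "ci_upper": np.exp(coef + 1.959963984540054 * se),
            "p": p,
        }
    )


# --------------------------------------------------------------------------- #
# LOESS
# --------------------------------------------------------------------------- #


def loess_event_probability(
    burdens: np.ndarray,
    event_indicators: np.ndarray,
    span: float = 0.6,
) -> pd.DataFrame:
    """Tricube-weighted local linear smoother of event probability against
    burden (visualisation aid, no inference)."""
    burdens = np.asarray(burdens, dtype=float)
    event_indicators = np.asarray(event_indicators, dtype=float)
    if not (0.0 < span <= 1.0):
        raise ValueError("span must be in (0, 1]")
    if len(burdens) < 20:
        raise ValueError("need at least 20 observations")
    if len(burdens) != len(event_indicators):
        raise ValueError("length mismatch")
    # no robustness iterations: residuals of a 0/1 indicator are always
    # "large" for the minority class and robust reweighting would bias the
    # estimated probability toward the majority
    sm = lowess(event_indicators, burdens, frac=span, it=0, return_sorted=True)
    return pd.DataFrame({"burden": sm[:, 0], "event_probability": sm[:, 1]})
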