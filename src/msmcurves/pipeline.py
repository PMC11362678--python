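"""Array-level IPW pooled-logistic pipeline.

This module is the computational core behind the public `weights`,
`hazard`, `curves` and `model` interfaces.  Everything here works on plain
numpy arrays so that the bootstrap (which re-runs the whole pipeline in
every replicate) stays cheap; the DataFrame-facing wrappers translate to
and from these structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._glm import ConvergenceError, LogisticFit, fit_logistic
from .io import is_target_event
from .simulate import REGIMES

__all__ = [
    "PipelineOptions", "ArrayData", "PipelineFit", "PositivityError",
    "arrays_from_cohort", "run_pipeline", "expand_core",
]


class PositivityError(RuntimeError):
    """A denominator probability fell below the positivity floor."""


@dataclass
class PipelineOptions:
    K: int = 14
    time_terms: str = "quadratic"          # "linear" | "quadratic" | "categorical"
    regime_time_interactions: bool = True
    truncation_percentile: float = 99.0
    positivity_floor: float = 1e-6
    censoring_weights: bool = True

    def __post_init__(self):
        if not 50.0 < self.truncation_percentile <= 100.0:
            raise ValueError("truncation percentile must lie in (50, 100]")
        if self.time_terms not in ("linear", "quadratic", "categorical"):
            raise ValueError("time_terms must be linear, quadratic or categorical")


@dataclass
class ArrayData:
    """Analysis-ready arrays for one cohort: baseline design ``X0``
    (covariates plus region indicator columns, no intercept), wave-2 design
    ``X1``, exposures, follow-up years ``T``, the target-cause event
    indicator and the lost-to-follow-up indicator."""

    X0: np.ndarray
    X1: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    T: np.ndarray
    event: np.ndarray
    ltfu: np.ndarray
    x0_names: list = field(default_factory=list)
    x1_names: list = field(default_factory=list)

    @property
    def n(self):
        return len(self.T)

    def take(self, idx):
        return ArrayData(self.X0[idx], self.X1[idx], self.A1[idx], self.A2[idx],
                         self.T[idx], self.event[idx], self.ltfu[idx],
                         self.x0_names, self.x1_names)


def arrays_from_cohort(cohort: pd.DataFrame, baseline_covariates,
                       timevarying_covariates, region_col: str,
                       target_cause: str, K: int) -> ArrayData:
    """Build ``ArrayData`` from a complete (no missing covariates) cohort."""
    T = cohort["T"].to_numpy(dtype=np.int64)
    bad = (T < 1) | (T > K)
    if bad.any():
        ids = cohort.loc[bad, "id"].head().tolist()
        raise ValueError(f"follow-up T outside 1..{K} for subjects {ids}")

    cov = cohort[list(baseline_covariates)]
    if cov.isna().any().any() or cohort[list(timevarying_covariates)].isna().any().any():
        raise ValueError("cohort has missing covariates; impute first")
    X0 = cov.to_numpy(dtype=float)
    x0_names = list(baseline_covariates)
    if region_col is not None:
        dummies = pd.get_dummies(cohort[region_col].astype("category"),
                                 prefix=region_col, drop_first=True, dtype=float)
        observed = cohort[region_col].nunique()
        if hasattr(cohort[region_col], "cat") and \
                len(cohort[region_col].cat.categories) > observed:
            warnings.warn("region levels with no subjects were dropped")
        X0 = np.column_stack([X0, dummies.to_numpy()])
        x0_names = x0_names + list(dummies.columns)
    X1 = cohort[list(timevarying_covariates)].to_numpy(dtype=float)

    ev_any = cohort["event"].to_numpy(dtype=bool)
    codes = cohort["cause_code"].fillna("").astype(str).to_numpy()
    event = np.array([ev_any[i] and is_target_event(codes[i], target_cause)
                      for i in range(len(T))], dtype=bool)
    ltfu = (~ev_any) & (T < K)
    return ArrayData(X0, X1,
                     cohort["A1"].to_numpy(dtype=float),
                     cohort["A2"].to_numpy(dtype=float),
                     T, event, ltfu,
                     x0_names, list(timevarying_covariates))


# ---------------------------------------------------------------------------
# person-year expansion

def expand_core(ad: ArrayData):
    """Expand to person-years.  Returns (idx, k, event_row, uncens_row):
    subject row index, year 1..T_i, terminal target-event indicator and the
    remaining-uncensored indicator (0 only in the final year of subjects
    lost to follow-up)."""
    T = ad.T
    total = int(T.sum())
    idx = np.repeat(np.arange(ad.n), T)
    offsets = np.concatenate([[0], np.cumsum(T)[:-1]])
    k = np.arange(total) - offsets[idx] + 1
    terminal = k == T[idx]
    ev = terminal & ad.event[idx]
    u = ~(terminal & ad.ltfu[idx])
    return idx, k.astype(float), ev.astype(float), u.astype(float)


# ---------------------------------------------------------------------------
# weights

def _obs_prob(p1, a):
    return np.where(a == 1, p1, 1.0 - p1)


def _check_positivity(p_obs, floor, what):
    bad = p_obs < floor
    if bad.any():
        idx = np.flatnonzero(bad)[:10].tolist()
        raise PositivityError(
            f"{what}: {int(bad.sum())} denominator probabilities below "
            f"{floor:g} (e.g. rows {idx})")


def fit_exposure_core(ad: ArrayData, floor: float, warm=None):
    """Four logistic fits (two denominators, two numerators) and the
    per-subject stabilized exposure weights."""
    warm = warm or {}
    n = ad.n
    ones = np.ones((n, 1))
    Xd1 = np.column_stack([ones, ad.X0])
    d1 = fit_logistic(Xd1, ad.A1, names=["const"] + ad.x0_names,
                      start=warm.get("den_w1"),
                      name="wave-1 exposure denominator")
    n1 = fit_logistic(ones, ad.A1, names=["const"],
                      name="wave-1 exposure numerator")
    Xd2 = np.column_stack([ones, ad.A1[:, None], ad.X0, ad.X1])
    d2 = fit_logistic(Xd2, ad.A2,
                      names=["const", "A1"] + ad.x0_names + ad.x1_names,
                      start=warm.get("den_w2"),
                      name="wave-2 exposure denominator")
    Xn2 = np.column_stack([ones, ad.A1[:, None]])
    n2 = fit_logistic(Xn2, ad.A2, names=["const", "A1"],
                      start=warm.get("num_w2"),
                      name="wave-2 exposure numerator")

    pd1 = _obs_prob(d1.predict(Xd1), ad.A1)
    pn1 = _obs_prob(n1.predict(ones), ad.A1)
    pd2 = _obs_prob(d2.predict(Xd2), ad.A2)
    pn2 = _obs_prob(n2.predict(Xn2), ad.A2)
    _check_positivity(pd1, floor, "wave-1 exposure model")
    _check_positivity(pd2, floor, "wave-2 exposure model")
    sw1 = pn1 / pd1
    sw2 = pn2 / pd2
    return sw1, sw2, {"den_w1": d1, "num_w1": n1, "den_w2": d2, "num_w2": n2}


def _time_cols(k, time_terms):
    if time_terms == "linear":
        return [k], ["k"]
    return [k, k * k], ["k", "k2"]


def fit_censoring_core(ad: ArrayData, idx, k, u, floor: float, time_terms: str,
                       warm=None):
    """Pooled logistic censoring models; returns per-row cumulative
    stabilized censoring weights.  With no loss to follow-up at all the
    models are degenerate and all weights are 1."""
    if not ad.ltfu.any():
        return np.ones(len(k)), None, True
    warm = warm or {}
    tcols, tnames = _time_cols(k, "quadratic" if time_terms == "categorical" else time_terms)
    ones = np.ones(len(k))
    Xn = np.column_stack([ones] + tcols + [ad.A1[idx], ad.A2[idx]])
    names_n = ["const"] + tnames + ["A1", "A2"]
    Xd = np.column_stack([Xn, ad.X0[idx], ad.X1[idx]])
    names_d = names_n + ad.x0_names + ad.x1_names
    den = fit_logistic(Xd, u, names=names_d, start=warm.get("cens_den"),
                       name="censoring denominator")
    num = fit_logistic(Xn, u, names=names_n, start=warm.get("cens_num"),
                       name="censoring numerator")
    p_den = den.predict(Xd)
    p_num = num.predict(Xn)
    _check_positivity(p_den, floor, "censoring model")
    logr = np.log(p_num) - np.log(p_den)
    # cumulative product within subject (rows are subject-ordered by k)
    cs = np.cumsum(logr)
    starts = np.concatenate([[0], np.cumsum(ad.T)[:-1]])
    base = np.repeat(cs[starts] - logr[starts], ad.T)
    swc = np.exp(cs - base)
    return swc, {"den": den, "num": num}, False


def truncate(values, percentile):
    """Cap a weight vector at its empirical percentile (linear
    interpolation); returns (truncated, threshold, n_capped)."""
    thr = float(np.percentile(values, percentile))
    capped = np.minimum(values, thr)
    return capped, thr, int(np.sum(values > thr))


# ---------------------------------------------------------------------------
# hazard model and curves

def hazard_design(k, a1, a2, opts: PipelineOptions):
    """Design matrix for the pooled logistic hazard model: intercept, time
    terms, regime indicators against the (0,0) reference, and optional
    regime x time products."""
    r01 = (a1 == 0) & (a2 == 1)
    r10 = (a1 == 1) & (a2 == 0)
    r11 = (a1 == 1) & (a2 == 1)
    cols = [np.ones(len(k))]
    names = ["const"]
    if opts.time_terms == "categorical":
        for kk in range(2, opts.K + 1):
            cols.append((k == kk).astype(float))
            names.append(f"k_{kk}")
    else:
        tcols, tnames = _time_cols(k, opts.time_terms)
        cols += tcols
        names += tnames
    cols += [r01.astype(float), r10.astype(float), r11.astype(float)]
    names += ["r01", "r10", "r11"]
    if opts.regime_time_interactions and opts.time_terms != "categorical":
        for rname, r in (("r01", r01), ("r10", r10), ("r11", r11)):
            cols.append(r * k)
            names.append(f"{rname}:k")
    return np.column_stack(cols), names


@dataclass
class PipelineFit:
    """Everything one pipeline pass produces."""

    hazards: np.ndarray          # (4, K) counterfactual discrete hazards
    cuminc: np.ndarray           # (4, K) counterfactual cumulative incidence
    hazard_fit: LogisticFit
    exposure_fits: dict
    censoring_fits: Optional[dict]
    options: PipelineOptions
    diagnostics: Optional[pd.DataFrame] = None
    weights: Optional[dict] = None

    def survival(self):
        return 1.0 - self.cuminc

    def warm_start(self) -> dict:
        """Coefficient vectors usable as Newton starting values for
        re-fits on resampled data."""
        out = {key: fit.params for key, fit in self.exposure_fits.items()}
        if self.censoring_fits is not None:
            out["cens_den"] = self.censoring_fits["den"].params
            out["cens_num"] = self.censoring_fits["num"].params
        out["hazard"] = self.hazard_fit.params
        return out


def _weight_summary(name, values, percentile, threshold, n_capped):
    return {"family": name, "mean": float(np.mean(values)),
            "sd": float(np.std(values)), "min": float(np.min(values)),
            "max": float(np.max(values)),
            "p_truncation": float(np.percentile(values, percentile)),
            "threshold": threshold, "n_truncated": n_capped}


def run_pipeline(ad: ArrayData, opts: PipelineOptions,
                 collect_diagnostics: bool = True,
                 warm_start: Optional[dict] = None) -> PipelineFit:
    """One full IPW + pooled logistic pass: exposure weights, person-year
    expansion, censoring weights, truncation, weighted hazard fit and the
    four counterfactual cumulative-incidence curves.

    ``warm_start`` maps model keys to coefficient vectors used as Newton
    starting values (the bootstrap passes the full-data estimates).
    """
    sw1, sw2, exp_fits = fit_exposure_core(ad, opts.positivity_floor, warm_start)
    idx, k, ev, u = expand_core(ad)
    if opts.censoring_weights:
        swc, cens_fits, degenerate = fit_censoring_core(
            ad, idx, k, u, opts.positivity_floor, opts.time_terms, warm_start)
    else:
        swc, cens_fits, degenerate = np.ones(len(k)), None, True

    sw_a = sw1 * sw2
    sw_a_t, thr_a, ncap_a = truncate(sw_a, opts.truncation_percentile)
    if degenerate:
        swc_t, thr_c, ncap_c = swc, 1.0, 0
    else:
        swc_t, thr_c, ncap_c = truncate(swc, opts.truncation_percentile)
    w = sw_a_t[idx] * swc_t

    if ev.sum() == 0:
        raise ConvergenceError("no target-cause events in the person-year table")
    X, names = hazard_design(k, ad.A1[idx], ad.A2[idx], opts)
    hz = fit_logistic(X, ev, sample_weight=w, names=names,
                      start=(warm_start or {}).get("hazard"),
                      name="pooled logistic hazard model")

    kk = np.arange(1, opts.K + 1, dtype=float)
    hazards = np.empty((4, opts.K))
    cuminc = np.empty((4, opts.K))
    for i, (a1, a2) in enumerate(REGIMES):
        Xr, _ = hazard_design(kk, np.full(opts.K, float(a1)),
                              np.full(opts.K, float(a2)), opts)
        h = hz.predict(Xr)
        hazards[i] = h
        cuminc[i] = 1.0 - np.cumprod(1.0 - h)

    diagnostics = None
    weights = None
    if collect_diagnostics:
        pct = opts.truncation_percentile
        rows = [
            _weight_summary("sw_A1", sw1, pct, None, 0),
            _weight_summary("sw_A2", sw2, pct, None, 0),
            _weight_summary("sw_A1*sw_A2", sw_a, pct, thr_a, ncap_a),
            _weight_summary("sw_C", swc, pct, thr_c, ncap_c),
            _weight_summary("w_final", w, pct, None, 0),
        ]
        diagnostics = pd.DataFrame(rows)
        weights = {"sw_A1": sw1, "sw_A2": sw2, "sw_A": sw_a,
                   "sw_A_trunc": sw_a_t, "sw_C": swc, "sw_C_trunc": swc_t,
                   "w_final": w, "py_index": idx, "py_year": k}
    return PipelineFit(hazards, cuminc, hz, exp_fits, cens_fits, opts,
                       diagnostics, weights)
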