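"""Discrete-time hazard machinery: person-year expansion, the weighted
pooled logistic hazard model, and the Kaplan-Meier diagnostic comparator.

Follow-up is divided into one-year intervals k = 1..K.  A subject with T
years of follow-up contributes T rows; the event indicator is 1 only in the
terminal row of subjects who died of the target cause.  Deaths from
non-target causes end follow-up event-free (cause-specific censoring) but
are not treated as loss to follow-up; only genuinely lost subjects get
``uncensored = 0`` in their final row, which is what the censoring-weight
models are fit on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.special import expit

from ._glm import fit_logistic
from .io import TARGET_CAUSES, is_target_event
from .simulate import REGIMES, REGIME_LABELS

__all__ = ["HazardModel", "expand_person_years", "fit_pooled_logistic",
           "km_estimate", "predict_hazard", "DEFAULT_TERMS"]

#: default hazard-model terms: quadratic time, saturated regime indicators
#: against the doubly-unexposed reference, and regime x time products
DEFAULT_TERMS = ("k", "k2", "r01", "r10", "r11", "r01:k", "r10:k", "r11:k")
PARSIMONIOUS_TERMS = ("k", "k2", "r01", "r10", "r11")


def expand_person_years(cohort: pd.DataFrame, K: int, target_cause: str,
                        covariates=()) -> pd.DataFrame:
    """Expand a cohort into the person-year (person-period) format.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject with ``id``, ``A1``, ``A2``, ``T``, ``event``
        and ``cause_code`` columns.
    K : int
        Administrative end of follow-up in years.
    target_cause : {"suicide", "non_suicide", "all_cause"}
    covariates : sequence of str
        Extra columns copied onto every person-year row (needed by the
        censoring models).

    Returns
    -------
    DataFrame with one row per subject-year: ``id``, ``k`` (1..T), ``A1``,
    ``A2``, regime indicators ``r01``/``r10``/``r11``, ``uncensored``,
    ``event`` and any requested covariate columns.
    """
    if target_cause not in TARGET_CAUSES:
        raise ValueError(f"target_cause must be one of {TARGET_CAUSES}")
    T = cohort["T"].to_numpy(dtype=np.int64)
    bad = (T < 1) | (T > K)
    if bad.any():
        ids = cohort.loc[bad, "id"].head().tolist()
        raise ValueError(f"follow-up T outside 1..{K} for subjects {ids}")

    ev_any = cohort["event"].to_numpy(dtype=bool)
    codes = cohort["cause_code"].fillna("").astype(str).to_numpy()
    is_target = np.array([ev_any[i] and is_target_event(codes[i], target_cause)
                          for i in range(len(cohort))])
    ltfu = (~ev_any) & (T < K)

    idx = np.repeat(np.arange(len(cohort)), T)
    offsets = np.concatenate([[0], np.cumsum(T)[:-1]])
    k = np.arange(int(T.sum())) - offsets[idx] + 1
    terminal = k == T[idx]

    a1 = cohort["A1"].to_numpy(dtype=int)[idx]
    a2 = cohort["A2"].to_numpy(dtype=int)[idx]
    py = pd.DataFrame({
        "id": cohort["id"].to_numpy()[idx],
        "k": k.astype(int),
        "A1": a1,
        "A2": a2,
        "r01": ((a1 == 0) & (a2 == 1)).astype(int),
        "r10": ((a1 == 1) & (a2 == 0)).astype(int),
        "r11": ((a1 == 1) & (a2 == 1)).astype(int),
        "uncensored": (~(terminal & ltfu[idx])).astype(int),
        "event": (terminal & is_target[idx]).astype(int),
    })
    for col in covariates:
        py[col] = cohort[col].to_numpy()[idx]
    return py


@dataclass
class HazardModel:
    """Fitted weighted pooled logistic discrete-time hazard model."""

    terms: list                 # term names including "const"
    params: np.ndarray
    cov_robust: Optional[np.ndarray]
    converged: bool
    K: int

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.terms)

    def robust_se(self) -> Optional[pd.Series]:
        if self.cov_robust is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.terms)

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"term": self.terms, "estimate": self.params})
        se = self.robust_se()
        out["robust_se"] = se.to_numpy() if se is not None else np.nan
        return out


def _term_column(py: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate one hazard-model term on a person-year table."""
    if ":" in term:
        left, right = term.split(":", 1)
        return _term_column(py, left) * _term_column(py, right)
    if term == "k2":
        return py["k"].to_numpy(dtype=float) ** 2
    if term.startswith("k_"):           # categorical-time dummy, e.g. k_3
        return (py["k"].to_numpy(dtype=float) == float(term[2:])).astype(float)
    return py[term].to_numpy(dtype=float)


def _hazard_matrix(py: pd.DataFrame, terms) -> np.ndarray:
    cols = [np.ones(len(py))] + [_term_column(py, t) for t in terms]
    return np.column_stack(cols)


def fit_pooled_logistic(person_years: pd.DataFrame, terms=DEFAULT_TERMS,
                        weight_col: Optional[str] = "w_final",
                        K: Optional[int] = None) -> HazardModel:
    """Weighted ML fit of the discrete-time hazard.

    ``terms`` name the linear-predictor columns besides the intercept:
    ``k``, ``k2``, categorical-time dummies ``k_2``..``k_K``, regime
    indicators ``r01``/``r10``/``r11`` and products like ``r11:k``.  A
    robust (HC0 sandwich) covariance is attached as a diagnostic; inference
    downstream uses the bootstrap.
    """
    y = person_years["event"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("no events in the person-year table")
    w = None
    if weight_col is not None and weight_col in person_years.columns:
        w = person_years[weight_col].to_numpy(dtype=float)
    for cell, rname in ((("r01"), "with-alone"), (("r10"), "alone-with"),
                        (("r11"), "alone-alone")):
        if cell in person_years.columns:
            mask = person_years[cell].to_numpy() == 1
            if mask.any() and y[mask].sum() == 0:
                warnings.warn(f"no events in regime cell {rname}")
    X = _hazard_matrix(person_years, terms)
    fit = fit_logistic(X, y, sample_weight=w, names=["const"] + list(terms),
                       name="pooled logistic hazard model")
    cov = fit.cov_sandwich(X, y, sample_weight=w)
    kmax = int(K if K is not None else person_years["k"].max())
    return HazardModel(fit.names, fit.params, cov, fit.converged, kmax)


def predict_hazard(model: HazardModel, regime, k) -> np.ndarray:
    """Counterfactual discrete hazard at year(s) ``k`` under ``regime``.

    ``k`` must lie within the fitted range 1..K (no extrapolation).
    """
    a1, a2 = regime
    kk = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(kk < 1) or np.any(kk > model.K):
        raise ValueError(f"year k outside fitted range 1..{model.K}")
    fake = pd.DataFrame({
        "k": kk,
        "A1": float(a1), "A2": float(a2),
        "r01": float(a1 == 0 and a2 == 1),
        "r10": float(a1 == 1 and a2 == 0),
        "r11": float(a1 == 1 and a2 == 1),
    })
    X = _hazard_matrix(fake, model.terms[1:])
    h = expit(X @ model.params)
    return h if np.ndim(k) else float(h[0])


def km_estimate(cohort: pd.DataFrame, target_cause: str,
                group_by: Optional[str] = None) -> pd.DataFrame:
    """Kaplan-Meier survival on the discrete yearly grid.

    Deaths from non-target causes censor at their death year — the same
    cause-specific convention as :func:`expand_person_years`.  With
    ``group_by="regime"`` one curve per (A1, A2) pattern is returned; empty
    groups are omitted with a warning.

    Returns a tidy frame (group, k, survival) with k = 0..max(T).
    """
    ev_any = cohort["event"].to_numpy(dtype=bool)
    codes = cohort["cause_code"].fillna("").astype(str).to_numpy()
    observed = np.array([ev_any[i] and is_target_event(codes[i], target_cause)
                         for i in range(len(cohort))])
    T = cohort["T"].to_numpy(dtype=int)

    if group_by is None:
        groups = {"all": np.ones(len(cohort), dtype=bool)}
    elif group_by == "regime":
        groups = {REGIME_LABELS[r]: (cohort["A1"].to_numpy() == r[0])
                  & (cohort["A2"].to_numpy() == r[1]) for r in REGIMES}
    else:
        groups = {str(v): (cohort[group_by] == v).to_numpy()
                  for v in sorted(cohort[group_by].unique())}

    kmax = int(T.max())
    grid = np.arange(0, kmax + 1)
    frames = []
    for label, mask in groups.items():
        if not mask.any():
            warnings.warn(f"empty group {label!r} omitted from KM estimate")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(T[mask], event_observed=observed[mask], timeline=grid)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        frames.append(pd.DataFrame({"group": label, "k": grid, "survival": surv}))
    return pd.concat(frames, ignore_index=True)
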