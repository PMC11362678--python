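"""Iterative random-forest imputation of missing covariates (the
missForest algorithm of Stekhoven & Buhlmann).

Variables are initialized with their column mean (continuous) or mode
(categorical) and then revisited in order of increasing missingness: each
incomplete variable is regressed on all the others with a random forest fit
on its observed rows, and its missing cells are replaced by the forest's
predictions.  Iteration stops when the normalized change statistic
increases for both the continuous and the categorical variable sets (the
previous iteration's values are then returned) or when ``max_iter`` is
reached.  Exposures and follow-up variables are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = ["ImputationResult", "rf_impute"]

#: columns that must never be imputed (missing exposure/follow-up data are
#: handled by excluding subjects, not by imputation)
ALWAYS_EXCLUDED = ("id", "A1", "A2", "T", "event", "cause_code")


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    n_iterations: int
    divergence_trace: pd.DataFrame
    seed: int
    imputed_columns: list = field(default_factory=list)


def _is_continuous(s: pd.Series) -> bool:
    vals = s.dropna().unique()
    return pd.api.types.is_float_dtype(s) and len(vals) > 10


def _delta_continuous(new: dict, old: dict) -> float:
    num = sum(float(np.sum((new[c] - old[c]) ** 2)) for c in new)
    den = sum(float(np.sum(new[c] ** 2)) for c in new)
    return num / den if den > 0 else 0.0


def _delta_categorical(new: dict, old: dict, n_missing: int) -> float:
    changed = sum(int(np.sum(new[c] != old[c])) for c in new)
    return changed / n_missing if n_missing else 0.0


def rf_impute(cohort: pd.DataFrame, excluded_columns=(), max_iter: int = 10,
              seed: int = 0, n_estimators: int = 100) -> ImputationResult:
    """Impute missing covariate cells with the missForest loop.

    Parameters
    ----------
    cohort : DataFrame
        Analysis table; missing cells are NaN.
    excluded_columns : sequence of str
        Columns left untouched and not used as responses; the exposure,
        follow-up and cause columns are always excluded.  Excluded columns
        (other than ``cause_code``) must themselves be complete.
    max_iter : int
        Hard cap on missForest sweeps.
    seed : int
        Seed for the per-forest random states.
    n_estimators : int
        Trees per forest (missForest default 100); ``max_features`` is the
        square-root rule.

    Returns
    -------
    ImputationResult
        ``completed`` has no missing cells in the imputed columns and all
        originally observed cells unchanged.
    """
    excluded = set(excluded_columns) | set(c for c in ALWAYS_EXCLUDED
                                           if c in cohort.columns)
    for col in excluded:
        if col == "cause_code":
            continue
        if cohort[col].isna().any():
            raise ValueError(
                f"excluded column {col!r} has missing values; subjects with "
                "missing exposure/follow-up must be dropped, not imputed")

    candidates = [c for c in cohort.columns if c not in excluded]
    fully_missing = [c for c in candidates if cohort[c].isna().all()]
    if fully_missing:
        raise ValueError(f"columns entirely missing: {fully_missing}")
    targets = [c for c in candidates if cohort[c].isna().any()]

    out = cohort.copy()
    if not targets:
        trace = pd.DataFrame(columns=["iteration", "delta_continuous",
                                      "delta_categorical"])
        return ImputationResult(out, 1, trace, seed, [])

    rng = np.random.default_rng(seed)
    masks = {c: cohort[c].isna().to_numpy() for c in targets}
    continuous = {c for c in targets if _is_continuous(cohort[c])}
    # predictors: every non-excluded column plus the (complete) exposures
    predictors = candidates + [c for c in ("A1", "A2") if c in cohort.columns]

    # mean/mode initialization
    for c in targets:
        if c in continuous:
            out[c] = out[c].fillna(cohort[c].mean())
        else:
            out[c] = out[c].fillna(cohort[c].mode(dropna=True).iloc[0])
    # visit order: increasing missingness (missForest convention)
    targets = sorted(targets, key=lambda c: masks[c].sum())
    n_missing_cat = sum(int(masks[c].sum()) for c in targets
                        if c not in continuous)

    def snapshot():
        return {c: out.loc[masks[c], c].to_numpy(copy=True) for c in targets}

    prev_vals = snapshot()
    prev_out = out.copy()
    best = out.copy()
    d_cont_prev = np.inf
    d_cat_prev = np.inf
    trace_rows = []
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        for c in targets:
            mask = masks[c]
            Xcols = [p for p in predictors if p != c]
            X = out[Xcols].to_numpy(dtype=float)
            y = out[c]
            rs = int(rng.integers(0, 2**31 - 1))
            if c in continuous:
                forest = RandomForestRegressor(
                    n_estimators=n_estimators, max_features="sqrt",
                    random_state=rs, n_jobs=1)
                forest.fit(X[~mask], y.to_numpy(dtype=float)[~mask])
                out.loc[mask, c] = forest.predict(X[mask])
            else:
                forest = RandomForestClassifier(
                    n_estimators=n_estimators, max_features="sqrt",
                    random_state=rs, n_jobs=1)
                forest.fit(X[~mask], y.to_numpy()[~mask])
                out.loc[mask, c] = forest.predict(X[mask])
        new_vals = snapshot()
        cont_new = {c: new_vals[c] for c in new_vals if c in continuous}
        cont_old = {c: prev_vals[c] for c in cont_new}
        cat_new = {c: new_vals[c] for c in new_vals if c not in continuous}
        cat_old = {c: prev_vals[c] for c in cat_new}
        d_cont = _delta_continuous(cont_new, cont_old) if cont_new else None
        d_cat = _delta_categorical(cat_new, cat_old, n_missing_cat) if cat_new else None
        trace_rows.append({"iteration": it, "delta_continuous": d_cont,
                           "delta_categorical": d_cat})
        cont_up = d_cont is None or d_cont >= d_cont_prev
        cat_up = d_cat is None or d_cat >= d_cat_prev
        if it > 1 and cont_up and cat_up:
            # both change statistics rose: return the previous sweep
            best = prev_out
            break
        best = out.copy()
        prev_out = out.copy()
        prev_vals = new_vals
        d_cont_prev = d_cont if d_cont is not None else np.inf
        d_cat_prev = d_cat if d_cat is not None else np.inf

    trace = pd.DataFrame(trace_rows)
    return ImputationResult(best, n_iter, trace, seed, list(targets))
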