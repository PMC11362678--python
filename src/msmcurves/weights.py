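"""Stabilized inverse-probability weights for exposure and censoring.

Exposure weights follow the two-wave construction: a wave-1 model of the
exposure on baseline covariates and region, and a wave-2 model on the
wave-1 exposure plus baseline and time-varying covariates and region, each
stabilized by a numerator model conditioning on exposure history only.
Censoring weights are cumulative stabilized products of pooled logistic
models of remaining uncensored.  Every weight family is truncated at an
empirical percentile (default the 99th, linear-interpolation convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._glm import LogisticFit, fit_logistic
from .pipeline import _check_positivity, _obs_prob, truncate

__all__ = [
    "ExposureModels", "CensoringModels", "WeightSet",
    "fit_exposure_models", "compute_exposure_weights",
    "fit_censoring_models", "compute_censoring_weights",
    "truncate_weights", "combine_weights",
]


def build_design(df: pd.DataFrame, covariates, region_col=None, prepend=()):
    """Intercept + optional leading columns + covariates + region dummies."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["const"]
    for name in prepend:
        cols.append(df[name].to_numpy(dtype=float))
        names.append(name)
    for name in covariates:
        cols.append(df[name].to_numpy(dtype=float))
        names.append(name)
    if region_col is not None:
        dummies = pd.get_dummies(df[region_col].astype("category"),
                                 prefix=region_col, drop_first=True, dtype=float)
        cols.append(dummies.to_numpy())
        names += list(dummies.columns)
    return np.column_stack(cols), names


@dataclass
class ExposureModels:
    """The four fitted logistic exposure models (stabilized-weight
    numerators and denominators) plus the design specification needed to
    re-evaluate them on new data."""

    den_w1: LogisticFit
    num_w1: LogisticFit
    den_w2: LogisticFit
    num_w2: LogisticFit
    baseline_covariates: list
    timevarying_covariates: list
    region_col: Optional[str]

    @property
    def converged(self):
        return all(m.converged for m in
                   (self.den_w1, self.num_w1, self.den_w2, self.num_w2))


def fit_exposure_models(cohort: pd.DataFrame, baseline_covariates,
                        timevarying_covariates, region_col="region") -> ExposureModels:
    """Fit the four exposure models by maximum likelihood.

    Denominators: A1 ~ L0 + region; A2 ~ A1 + L0 + L1 + region.
    Numerators: A1 ~ 1; A2 ~ A1.  Regions enter as fixed-effect indicator
    columns.  Raises on missing covariates, separation or non-convergence.
    """
    cov = list(baseline_covariates) + list(timevarying_covariates)
    if cohort[cov].isna().any().any():
        raise ValueError("cohort has missing covariates; impute first")
    A1 = cohort["A1"].to_numpy(dtype=float)
    A2 = cohort["A2"].to_numpy(dtype=float)

    Xd1, names_d1 = build_design(cohort, baseline_covariates, region_col)
    den_w1 = fit_logistic(Xd1, A1, names=names_d1, name="wave-1 exposure denominator")
    num_w1 = fit_logistic(np.ones((len(cohort), 1)), A1, names=["const"],
                          name="wave-1 exposure numerator")
    Xd2, names_d2 = build_design(
        cohort, list(baseline_covariates) + list(timevarying_covariates),
        region_col, prepend=("A1",))
    den_w2 = fit_logistic(Xd2, A2, names=names_d2, name="wave-2 exposure denominator")
    Xn2, names_n2 = build_design(cohort, [], None, prepend=("A1",))
    num_w2 = fit_logistic(Xn2, A2, names=names_n2, name="wave-2 exposure numerator")
    return ExposureModels(den_w1, num_w1, den_w2, num_w2,
                          list(baseline_covariates), list(timevarying_covariates),
                          region_col)


@dataclass
class WeightSet:
    """Weight components for one cohort.

    ``sw_A1``/``sw_A2`` are per-subject stabilized exposure weights;
    ``sw_C`` is the per-person-year cumulative stabilized censoring weight
    aligned with a person-year table; ``w_final`` the combined, truncated
    product.  ``thresholds`` records truncation caps actually applied.
    """

    sw_A1: Optional[np.ndarray] = None
    sw_A2: Optional[np.ndarray] = None
    sw_C: Optional[np.ndarray] = None
    sw_A1_trunc: Optional[np.ndarray] = None
    sw_A2_trunc: Optional[np.ndarray] = None
    sw_A_trunc: Optional[np.ndarray] = None
    sw_C_trunc: Optional[np.ndarray] = None
    w_final: Optional[np.ndarray] = None
    thresholds: dict = field(default_factory=dict)

    @property
    def sw_A(self):
        if self.sw_A1 is None or self.sw_A2 is None:
            return None
        return self.sw_A1 * self.sw_A2

    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for name in ("sw_A1", "sw_A2", "sw_A", "sw_C", "w_final"):
            v = getattr(self, name)
            if v is None:
                continue
            rows.append({"family": name, "mean": float(np.mean(v)),
                         "sd": float(np.std(v)), "min": float(np.min(v)),
                         "max": float(np.max(v)),
                         "p99": float(np.percentile(v, 99))})
        return pd.DataFrame(rows)


def compute_exposure_weights(models: ExposureModels, cohort: pd.DataFrame,
                             positivity_floor: float = 1e-6) -> WeightSet:
    """Per-subject stabilized exposure weights, evaluated at the exposure
    values actually received."""
    A1 = cohort["A1"].to_numpy(dtype=float)
    A2 = cohort["A2"].to_numpy(dtype=float)
    Xd1, _ = build_design(cohort, models.baseline_covariates, models.region_col)
    Xd2, _ = build_design(
        cohort, models.baseline_covariates + models.timevarying_covariates,
        models.region_col, prepend=("A1",))
    Xn2, _ = build_design(cohort, [], None, prepend=("A1",))
    ones = np.ones((len(cohort), 1))

    pd1 = _obs_prob(models.den_w1.predict(Xd1), A1)
    pn1 = _obs_prob(models.num_w1.predict(ones), A1)
    pd2 = _obs_prob(models.den_w2.predict(Xd2), A2)
    pn2 = _obs_prob(models.num_w2.predict(Xn2), A2)
    _check_positivity(pd1, positivity_floor, "wave-1 exposure model")
    _check_positivity(pd2, positivity_floor, "wave-2 exposure model")
    return WeightSet(sw_A1=pn1 / pd1, sw_A2=pn2 / pd2)


@dataclass
class CensoringModels:
    """Pooled logistic models of remaining uncensored at year k."""

    den: Optional[LogisticFit]
    num: Optional[LogisticFit]
    covariates: list
    region_col: Optional[str]
    time_terms: str
    degenerate: bool = False       # no censoring events: all weights 1


def _censoring_design(py: pd.DataFrame, covariates, region_col, time_terms):
    k = py["k"].to_numpy(dtype=float)
    tcols = {"k": k}
    if time_terms == "quadratic":
        tcols["k2"] = k * k
    num_cols = [np.ones(len(py))] + list(tcols.values()) + \
        [py["A1"].to_numpy(float), py["A2"].to_numpy(float)]
    num_names = ["const"] + list(tcols) + ["A1", "A2"]
    Xn = np.column_stack(num_cols)
    den_extra, den_names = build_design(py, covariates, region_col)
    Xd = np.column_stack([Xn, den_extra[:, 1:]])   # drop duplicate intercept
    return Xn, num_names, Xd, num_names + den_names[1:]


def fit_censoring_models(person_years: pd.DataFrame, covariates,
                         region_col="region", time_terms="quadratic") -> CensoringModels:
    """Fit the stabilized-censoring-weight numerator and denominator.

    The response is the remaining-uncensored indicator.  If no one is lost
    to follow-up the models are flagged degenerate and all censoring
    weights default to 1.
    """
    u = person_years["uncensored"].to_numpy(dtype=float)
    if np.all(u == 1.0):
        return CensoringModels(None, None, list(covariates), region_col,
                               time_terms, degenerate=True)
    Xn, names_n, Xd, names_d = _censoring_design(
        person_years, covariates, region_col, time_terms)
    den = fit_logistic(Xd, u, names=names_d, name="censoring denominator")
    num = fit_logistic(Xn, u, names=names_n, name="censoring numerator")
    return CensoringModels(den, num, list(covariates), region_col, time_terms)


def compute_censoring_weights(models: CensoringModels,
                              person_years: pd.DataFrame,
                              positivity_floor: float = 1e-6) -> np.ndarray:
    """Cumulative stabilized censoring weights, one per person-year row:
    sw_C(k) = prod_{j<=k} P_num(uncensored at j)/P_den(uncensored at j)."""
    if models.degenerate:
        return np.ones(len(person_years))
    Xn, _, Xd, _ = _censoring_design(
        person_years, models.covariates, models.region_col, models.time_terms)
    p_den = models.den.predict(Xd)
    p_num = models.num.predict(Xn)
    _check_positivity(p_den, positivity_floor, "censoring model")
    ratio = pd.Series(p_num / p_den, index=person_years.index)
    return ratio.groupby(person_years["id"].to_numpy()).cumprod().to_numpy()


def truncate_weights(weights: WeightSet, percentile: float = 99.0) -> WeightSet:
    """Cap each weight family at its own empirical percentile.

    The exposure families are truncated on the product sw_A1*sw_A2 and the
    censoring family per person-year on the cumulative sw_C, upper tail
    only.  Thresholds are recorded on the returned WeightSet.
    """
    if not 50.0 < percentile <= 100.0:
        raise ValueError("truncation percentile must lie in (50, 100]")
    out = WeightSet(sw_A1=weights.sw_A1, sw_A2=weights.sw_A2, sw_C=weights.sw_C,
                    thresholds=dict(weights.thresholds))
    if weights.sw_A1 is not None and weights.sw_A2 is not None:
        capped, thr, n_cap = truncate(weights.sw_A, percentile)
        out.sw_A_trunc = capped
        out.thresholds["sw_A"] = {"threshold": thr, "n_truncated": n_cap}
    if weights.sw_C is not None:
        capped, thr, n_cap = truncate(weights.sw_C, percentile)
        out.sw_C_trunc = capped
        out.thresholds["sw_C"] = {"threshold": thr, "n_truncated": n_cap}
    return out


def combine_weights(weights: WeightSet, person_years: pd.DataFrame) -> pd.DataFrame:
    """Attach w_final(k) = truncated exposure weight x truncated sw_C(k) to
    every person-year row (subjects aligned by the ``id`` column)."""
    py = person_years.copy()
    if weights.sw_A_trunc is None:
        raise ValueError("exposure weights missing; run truncate_weights first")
    sw_c = weights.sw_C_trunc
    if sw_c is None:
        sw_c = np.ones(len(py))
    if len(sw_c) != len(py):
        raise ValueError("censoring weight vector does not match person-years")
    ids = py["id"].to_numpy()
    uniq, first_pos = np.unique(ids, return_index=True)
    if len(weights.sw_A_trunc) != len(uniq):
        raise ValueError("exposure weight vector does not match subject count")
    subject_w = pd.Series(weights.sw_A_trunc,
                          index=ids[np.sort(first_pos)])
    py["w_final"] = subject_w.reindex(ids).to_numpy() * sw_c
    return py
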