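"""Counterfactual cumulative-incidence curves, RD/RR contrasts and the
subject-level percentile bootstrap.

Survival under a regime is the exact product S(k) = prod_{j<=k} (1 - h(j))
of the predicted discrete hazards (no exponential approximation); the
cumulative incidence is F(k) = 1 - S(k).  Contrasts are risk differences
(reported in percentage points) and risk ratios of each regime against the
doubly-unexposed reference, by default at the follow-up midpoint and end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._glm import ConvergenceError
from .hazard import HazardModel, predict_hazard
from .pipeline import (ArrayData, PipelineOptions, PositivityError,
                       run_pipeline)
from .simulate import REGIMES, REGIME_LABELS

__all__ = ["RegimeCurve", "ContrastEstimate", "build_regime_curves",
           "compute_contrasts", "BootstrapResult", "bootstrap_pipeline",
           "percentile_ci"]

REFERENCE = (0, 0)


@dataclass
class RegimeCurve:
    """Hazard/survival/cumulative-incidence sequence for one regime,
    k = 1..K (S(0) = 1 implicitly)."""

    regime: tuple
    label: str
    hazard: np.ndarray
    survival: np.ndarray
    cuminc: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        K = len(self.hazard)
        return pd.DataFrame({"a1": self.regime[0], "a2": self.regime[1],
                             "label": self.label, "k": np.arange(1, K + 1),
                             "hazard": self.hazard, "survival": self.survival,
                             "cuminc": self.cuminc})


@dataclass
class ContrastEstimate:
    """RD (percentage points) and RR of a regime against the reference at
    one horizon, with optional percentile bootstrap CIs."""

    regime: tuple
    label: str
    horizon: int
    rd: float                    # percentage points
    rr: Optional[float]          # None when the reference risk is 0
    rd_ci: Optional[tuple] = None
    rr_ci: Optional[tuple] = None
    n_boot: Optional[int] = None


def build_regime_curves(model: HazardModel, K: int) -> list:
    """Counterfactual curves for the four regimes from a fitted hazard
    model, using the exact hazard-product formula."""
    kk = np.arange(1, K + 1)
    out = []
    for regime in REGIMES:
        h = np.asarray(predict_hazard(model, regime, kk), dtype=float)
        S = np.cumprod(1.0 - h)
        out.append(RegimeCurve(regime, REGIME_LABELS[regime], h, S, 1.0 - S))
    return out


def curves_from_cuminc(cuminc: np.ndarray) -> list:
    """Wrap a (4, K) cumulative-incidence array as RegimeCurve objects."""
    out = []
    for i, regime in enumerate(REGIMES):
        F = cuminc[i]
        S = 1.0 - F
        h = np.empty_like(F)
        h[0] = F[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            h[1:] = 1.0 - S[1:] / S[:-1]
        out.append(RegimeCurve(regime, REGIME_LABELS[regime], h, S, F))
    return out


def compute_contrasts(curves, horizons=(7, 14)) -> list:
    """RD/RR of every regime against the with-with reference at each
    horizon.  RR is reported missing (None) when the reference risk is 0."""
    by_regime = {c.regime: c for c in curves}
    ref = by_regime[REFERENCE]
    K = len(ref.cuminc)
    out = []
    for h in horizons:
        if not 1 <= h <= K:
            raise ValueError(f"horizon {h} outside 1..{K}")
        f_ref = ref.cuminc[h - 1]
        for regime in REGIMES:
            if regime == REFERENCE:
                continue
            f = by_regime[regime].cuminc[h - 1]
            rr = None if f_ref == 0 else float(f / f_ref)
            out.append(ContrastEstimate(regime, REGIME_LABELS[regime], int(h),
                                        rd=float((f - f_ref) * 100.0), rr=rr))
    return out


def percentile_ci(samples, lower=2.5, upper=97.5) -> tuple:
    """Pointwise percentile interval (linear-interpolation convention,
    matching the weight-truncation percentile)."""
    arr = np.asarray(samples, dtype=float)
    return (float(np.percentile(arr, lower)), float(np.percentile(arr, upper)))


@dataclass
class BootstrapResult:
    """Replicate draws and pointwise percentile CIs for curves and
    contrasts."""

    cuminc_reps: np.ndarray          # (B_ok, 4, K)
    n_requested: int
    n_failed: int
    cuminc_ci: np.ndarray            # (4, K, 2)
    contrasts: list = field(default_factory=list)
    rr_excluded: int = 0             # replicates with zero reference risk

    @property
    def n_used(self):
        return self.cuminc_reps.shape[0]


def bootstrap_pipeline(data: ArrayData, options: PipelineOptions, B: int,
                       seed: int, horizons=(7, 14),
                       point_contrasts: Optional[list] = None,
                       max_failure_fraction: float = 0.05) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the whole pipeline.

    Subjects are resampled with replacement; exposure and censoring models
    are re-fit within each replicate (the weights are estimated
    quantities).  Replicates that fail to converge are recorded and
    skipped; if more than ``max_failure_fraction`` fail, the bootstrap
    aborts.  CIs are pointwise 2.5/97.5 percentiles across replicates.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = data.n
    K = options.K
    # full-data estimates warm-start every replicate's Newton iterations
    try:
        warm = run_pipeline(data, options, collect_diagnostics=False).warm_start()
    except (ConvergenceError, PositivityError):
        warm = None
    reps = np.empty((B, 4, K))
    failed = 0
    kept = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            fit = run_pipeline(data.take(idx), options,
                               collect_diagnostics=False, warm_start=warm)
        except (ConvergenceError, PositivityError, np.linalg.LinAlgError):
            failed += 1
            continue
        reps[kept] = fit.cuminc
        kept += 1
    if failed > max_failure_fraction * B:
        raise RuntimeError(
            f"bootstrap aborted: {failed}/{B} replicates failed to converge")
    reps = reps[:kept]

    ci = np.stack([np.percentile(reps, 2.5, axis=0),
                   np.percentile(reps, 97.5, axis=0)], axis=-1)

    contrasts = []
    rr_excluded_total = 0
    ref_idx = REGIMES.index(REFERENCE)
    point = {(c.regime, c.horizon): c
             for c in point_contrasts} if point_contrasts else None
    for h in horizons:
        f_ref = reps[:, ref_idx, h - 1]
        for regime in REGIMES:
            if regime == REFERENCE:
                continue
            i = REGIMES.index(regime)
            f = reps[:, i, h - 1]
            rd_reps = (f - f_ref) * 100.0
            ok = f_ref > 0
            rr_excluded_total += int((~ok).sum())
            rr_reps = f[ok] / f_ref[ok]
            est = point.get((regime, h)) if point else None
            contrasts.append(ContrastEstimate(
                regime, REGIME_LABELS[regime], int(h),
                rd=est.rd if est else float(np.mean(rd_reps)),
                rr=est.rr if est else float(np.mean(rr_reps)),
                rd_ci=percentile_ci(rd_reps),
                rr_ci=percentile_ci(rr_reps) if ok.any() else None,
                n_boot=kept))
    return BootstrapResult(reps, B, failed, ci, contrasts, rr_excluded_total)
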