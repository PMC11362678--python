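"""Cohort CSV readers/writers, cause-of-death coding and run configuration."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd
import yaml

from .simulate import BASELINE_COVARIATES, WAVE2_COVARIATES

__all__ = [
    "classify_cause",
    "read_cohort",
    "write_cohort",
    "AnalysisConfig",
    "load_config",
    "TARGET_CAUSES",
]

logger = logging.getLogger("msmcurves")

TARGET_CAUSES = ("suicide", "non_suicide", "all_cause")

# ICD-10 code: capital letter, two digits, optional decimal subcode
_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d+)?$")


def classify_cause(icd10_code: str) -> str:
    """Classify an ICD-10 cause-of-death code.

    Codes X60-X84 (intentional self-harm, subcodes included) map to
    ``"suicide"``; any other valid code to ``"non_suicide"``; an empty
    string (no death) to ``"none"``.

    Raises
    ------
    ValueError
        For strings that are not empty and do not match the ICD-10
        letter-plus-two-digits pattern.
    """
    if icd10_code is None:
        return "none"
    code = str(icd10_code).strip()
    if code == "" or code.lower() == "nan":
        return "none"
    m = _ICD10_RE.match(code)
    if m is None:
        raise ValueError(f"malformed ICD-10 code: {icd10_code!r}")
    letter, number = m.group(1), int(m.group(2))
    if letter == "X" and 60 <= number <= 84:
        return "suicide"
    return "non_suicide"


def is_target_event(cause_code, target_cause: str) -> bool:
    """Whether a death with this cause code counts as the target event."""
    label = classify_cause(cause_code)
    if label == "none":
        return False
    if target_cause == "all_cause":
        return True
    return label == target_cause


_REQUIRED = ("id", "A1", "A2", "T", "event", "cause_code")


def read_cohort(path, covariates=None) -> pd.DataFrame:
    """Read a cohort CSV into an analysis-ready table.

    Empty cells and ``"NA"`` both parse to missing.  Subjects missing
    either exposure or the follow-up duration are excluded (their count is
    logged): exposure and follow-up are never imputed.

    Raises on missing required columns, duplicate ids or non-numeric T.
    """
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True,
                     dtype={"cause_code": str})
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].head().tolist()
        raise ValueError(f"duplicate subject ids, e.g. {dups}")
    try:
        df["T"] = pd.to_numeric(df["T"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError("non-numeric follow-up duration T") from exc

    before = len(df)
    df = df.dropna(subset=["A1", "A2", "T"]).copy()
    excluded = before - len(df)
    if excluded:
        logger.info("read_cohort: excluded %d subjects missing A1/A2/T", excluded)
    df["A1"] = df["A1"].astype(int)
    df["A2"] = df["A2"].astype(int)
    df["T"] = df["T"].astype(int)
    df["event"] = df["event"].astype(int)
    df["cause_code"] = df["cause_code"].fillna("")
    # event=1 requires a cause code
    bad = (df["event"] == 1) & (df["cause_code"] == "")
    if bad.any():
        raise ValueError(f"{int(bad.sum())} deaths lack a cause_code")
    return df.reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    target_cause: str = "suicide"
    K: int = 14
    horizons: tuple = (7, 14)
    baseline_covariates: list = field(default_factory=lambda: list(BASELINE_COVARIATES))
    timevarying_covariates: list = field(default_factory=lambda: list(WAVE2_COVARIATES))
    region_col: str = "region"
    stratify: Optional[str] = None          # None | "age_threshold" | "gender"
    age_threshold: float = 60.0
    time_terms: str = "quadratic"           # "linear" | "quadratic" | "categorical"
    regime_time_interactions: bool = True
    parsimonious: bool = False              # drops regime x time products
    truncation_percentile: float = 99.0
    positivity_floor: float = 1e-6
    bootstrap_replicates: int = 500
    impute_max_iter: int = 10
    seed: int = 0
    input_path: Optional[str] = None
    output_dir: str = "results"

    def __post_init__(self):
        if self.target_cause not in TARGET_CAUSES:
            raise ValueError(f"target_cause must be one of {TARGET_CAUSES}")
        self.horizons = tuple(int(h) for h in self.horizons)
        if any(h < 1 or h > self.K for h in self.horizons):
            raise ValueError("horizons must lie in 1..K")

    def to_yaml(self, path):
        d = asdict(self)
        d["horizons"] = list(d["horizons"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)
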