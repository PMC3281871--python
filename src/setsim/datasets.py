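"""Pooled-cohort container: linked subject and session tables with masks."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema

__all__ = ["PooledDataset", "build_model_frame"]


@dataclass
class PooledDataset:
    """Linked subject/session tables plus per-cell missingness masks.

    Invariants: every session references an existing subject; subject-level
    variables are constant across a subject's sessions (they live only in
    ``subjects``); a missing cell is NaN in the table and True in the mask.
    """

    subjects: pd.DataFrame
    sessions: pd.DataFrame
    subject_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    session_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.subject_mask is None:
            self.subject_mask = self.subjects[list(schema.IMPUTABLE_SUBJECT)].isna()
        if self.session_mask is None:
            self.session_mask = self.sessions[list(schema.IMPUTABLE_SESSION)].isna()

    # -- basic properties -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def n_studies(self) -> int:
        return int(self.subjects["study_id"].nunique())

    def copy(self) -> "PooledDataset":
        return PooledDataset(
            self.subjects.copy(),
            self.sessions.copy(),
            self.subject_mask.copy(),
            self.session_mask.copy(),
        )

    def validate(self) -> None:
        """Check referential and constancy invariants; raise ValueError."""
        missing_ref = ~self.sessions["subject_id"].isin(self.subjects["subject_id"])
        if missing_ref.any():
            bad = self.sessions.loc[missing_ref, "session_id"].tolist()[:5]
            raise ValueError(f"sessions reference unknown subjects: {bad}")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in subject table")
        # hallucinogen_naive may flip true -> false over a subject's sessions
        # (earlier experimental sessions count as exposure) but never back.
        naive = self.sessions.sort_values(["subject_id", "occasion"])
        for _, grp in naive.groupby("subject_id", sort=False):
            vals = grp["hallucinogen_naive"].dropna().to_numpy()
            if len(vals) > 1 and np.any(np.diff(vals) > 0):
                raise ValueError("hallucinogen_naive switched from False to True in time order")
        out = self.sessions[list(schema.OUTCOMES)].to_numpy(dtype=float)
        if np.nanmin(out) < 0:
            raise ValueError("raw outcome scores must be non-negative")

    def missing_rates(self) -> pd.Series:
        """Fraction of missing cells per imputable column (subject level for
        subject variables, session level for session variables)."""
        rates = {}
        for c in schema.IMPUTABLE_SUBJECT:
            rates[c] = float(self.subject_mask[c].mean())
        for c in schema.IMPUTABLE_SESSION:
            rates[c] = float(self.session_mask[c].mean())
        return pd.Series(rates, name="missing_rate")

    @property
    def has_missing(self) -> bool:
        return bool(self.subject_mask.to_numpy().any() or self.session_mask.to_numpy().any())

    # -- joined views ------------------------------------------------------
    def merged(self) -> pd.DataFrame:
        """Session-level frame with subject variables broadcast to sessions."""
        subj = self.subjects.drop(columns=["study_id"])
        return self.sessions.merge(subj, on="subject_id", how="left", validate="m:1")

    # -- persistence -------------------------------------------------------
    def to_csv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(directory / "subjects.csv", index=False)
        self.sessions.to_csv(directory / "sessions.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "PooledDataset":
        directory = Path(directory)
        subjects = pd.read_csv(directory / "subjects.csv")
        sessions = pd.read_csv(directory / "sessions.csv")
        return cls(subjects, sessions)


def build_model_frame(data: PooledDataset | pd.DataFrame) -> pd.DataFrame:
    """Session-level modelling frame with the full fixed-effect term set.

    Expands the ordered THC variable into two cumulative dummies whose
    coefficients are the sequential differences never->rarely and
    rarely->sometimes, and keeps ids, design variables, predictors and raw
    outcome columns.  Missing values propagate (imputation happens first in
    the pipeline; this function does not require completeness).
    """
    df = data.merged() if isinstance(data, PooledDataset) else data.copy()
    thc = df["thc"].to_numpy(dtype=float)
    df["thc_rarely"] = np.where(np.isnan(thc), np.nan, (thc >= 1).astype(float))
    df["thc_sometimes"] = np.where(np.isnan(thc), np.nan, (thc >= 2).astype(float))
    keep = ["session_id", "subject_id", "study_id", "occasion"] + list(schema.MODEL_TERMS) + list(schema.OUTCOMES)
    return df[keep]
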