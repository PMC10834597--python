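"""Patient-level survival data container.

A :class:`SurvivalDataset` holds a dense covariate matrix, a binary treatment
vector, follow-up times in months, and event indicators. Continuous covariates
are expected to be numeric; categorical covariates are one-hot encoded by
:meth:`SurvivalDataset.from_dataframe`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset"]


@dataclass
class SurvivalDataset:
    """Covariates, treatment, follow-up time (months) and event indicator.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Covariate matrix, no missing values.
    treatment : ndarray of shape (n,)
        Binary treatment assignment (1 = treated).
    time : ndarray of shape (n,)
        Follow-up time in months, nonnegative.
    event : ndarray of shape (n,)
        1 if the event (death) was observed, 0 if censored.
    feature_names : list of str, optional
        Column names for ``X``.
    ids : ndarray, optional
        Subject identifiers; defaults to 0..n-1.
    """

    X: np.ndarray
    treatment: np.ndarray
    time: np.ndarray
    event: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d array")
        n = self.X.shape[0]
        self.treatment = np.asarray(self.treatment).astype(int).ravel()
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).astype(int).ravel()
        for name, arr in (("treatment", self.treatment), ("time", self.time),
                          ("event", self.event)):
            if arr.shape[0] != n:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if np.any(self.time < 0):
            raise ValueError("time must be nonnegative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be binary")
        if not np.isin(self.treatment, (0, 1)).all():
            raise ValueError("treatment must be binary")
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match X")
        if self.ids is None:
            self.ids = np.arange(n)
        else:
            self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        covariates: list[str],
        treatment: str,
        time: str,
        event: str,
        categorical: list[str] | None = None,
        id_col: str | None = None,
    ) -> "SurvivalDataset":
        """Build a dataset from a tidy data frame, one-hot encoding categoricals.

        ``categorical`` defaults to the object/category-dtype columns among
        ``covariates``.
        """
        missing = [c for c in [*covariates, treatment, time, event] if c not in df.columns]
        if missing:
            raise KeyError(f"columns not found in data frame: {missing}")
        if categorical is None:
            categorical = [c for c in covariates
                           if df[c].dtype == object or str(df[c].dtype) == "category"]
        cov = df[covariates]
        if categorical:
            cov = pd.get_dummies(cov, columns=categorical, dtype=float)
        return cls(
            X=cov.to_numpy(dtype=float),
            treatment=df[treatment].to_numpy(),
            time=df[time].to_numpy(dtype=float),
            event=df[event].to_numpy(),
            feature_names=list(cov.columns),
            ids=df[id_col].to_numpy() if id_col else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(self.X, columns=self.feature_names)
        out.insert(0, "id", self.ids)
        out["treatment"] = self.treatment
        out["time"] = self.time
        out["event"] = self.event
        return out

    def subset(self, index: np.ndarray) -> "SurvivalDataset":
        """Row subset by integer or boolean index."""
        index = np.asarray(index)
        return SurvivalDataset(
            X=self.X[index],
            treatment=self.treatment[index],
            time=self.time[index],
            event=self.event[index],
            feature_names=list(self.feature_names),
            ids=self.ids[index],
        )

    def arm(self, a: int) -> "SurvivalDataset":
        """Subjects who actually received treatment ``a``."""
        return self.subset(self.treatment == a)

    def require_both_arms_with_events(self) -> None:
        """Raise if either arm is empty or event-free (unusable for fitting)."""
        for a in (0, 1):
            mask = self.treatment == a
            name = "treated" if a == 1 else "control"
            if not mask.any():
                raise ValueError(f"degenerate cohort: {name} arm is empty")
            if self.event[mask].sum() == 0:
                raise ValueError(f"{name} arm has no observed events")
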