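"""Subjects × features container with provenance and scaling state.

A :class:`FeatureMatrix` wraps a pandas DataFrame (rows = subjects, columns =
named features) plus two bookkeeping fields: which pipeline block the features
came from (``language`` / ``clinical`` / ``connectivity`` / ``morphometry``)
and whether the values are raw or z-scored. Keeping the state on the object
lets downstream stages refuse silent double-scaling.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DuplicateSubject, InsufficientSubjects

VALID_PROVENANCES = ("language", "clinical", "connectivity", "morphometry", "mixed")


@dataclass
class FeatureMatrix:
    data: pd.DataFrame                     # index = subject_id, columns = features
    provenance: str = "mixed"
    state: str = "raw"                     # "raw" | "zscored" | "harmonized"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateSubject(f"duplicate subject ids: {dupes}")
        if len(self.data) < 1:
            raise InsufficientSubjects("feature matrix needs at least one subject")

    # -- convenience views ----------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, **changes) -> "FeatureMatrix":
        """Copy carrying provenance/meta, with new values."""
        return replace(self, data=data, **changes)

    def subset(self, subjects) -> "FeatureMatrix":
        missing = [s for s in subjects if s not in self.data.index]
        if missing:
            raise KeyError(f"subjects not in matrix: {missing}")
        return self.with_data(self.data.loc[list(subjects)])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="subject_id")

    @classmethod
    def from_tsv(cls, path, provenance: str = "mixed", state: str = "raw") -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col="subject_id")
        df.index = df.index.astype(str)
        return cls(df, provenance=provenance, state=state)
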