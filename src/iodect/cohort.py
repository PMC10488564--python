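"""Cohort feature table: one row per case, nine features plus labels.

The on-disk form is a plain UTF-8 comma-separated file with a header row and
"." decimals, so round trips are bit-exact (floats are written in shortest
round-trip representation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import FEATURE_NAMES, FeatureVector, TumorGroup, ValidationError

REQUIRED_COLUMNS = ("case_id", "group", *FEATURE_NAMES)
OPTIONAL_COLUMNS = ("fibrosis_grade",)


@dataclass
class CohortTable:
    """Validated wrapper around a per-case feature ``DataFrame``."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"cohort table missing required columns: {missing}")
        frame = self.frame.reset_index(drop=True).copy()
        if frame["case_id"].duplicated().any():
            dupes = frame.loc[frame["case_id"].duplicated(), "case_id"].tolist()
            raise ValidationError(f"duplicate case_id values: {dupes}")
        try:
            frame["group"] = frame["group"].map(lambda g: TumorGroup(g).value)
        except ValueError as exc:
            raise ValidationError(f"unknown group label: {exc}") from exc
        for col in FEATURE_NAMES:
            frame[col] = frame[col].astype(float)
        if "fibrosis_grade" in frame.columns:
            grades = frame["fibrosis_grade"].dropna()
            if not grades.isin([1, 2, 3]).all():
                raise ValidationError("fibrosis_grade values must be in {1, 2, 3}")
            frame["fibrosis_grade"] = frame["fibrosis_grade"].astype("Int64")
        self.frame = frame

    # -- construction -----------------------------------------------------
    @classmethod
    def from_rows(
        cls,
        rows: Iterable[tuple[str, TumorGroup, FeatureVector, Optional[int]]],
    ) -> "CohortTable":
        records = []
        for case_id, group, fv, fibrosis in rows:
            rec = {"case_id": case_id, "group": TumorGroup(group).value}
            rec.update(fv.as_dict())
            rec["fibrosis_grade"] = fibrosis
            records.append(rec)
        return cls(pd.DataFrame.from_records(records))

    # -- accessors --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def group_counts(self) -> dict[str, int]:
        return self.frame["group"].value_counts().to_dict()

    def feature(self, name: str) -> np.ndarray:
        if name not in FEATURE_NAMES:
            raise ValidationError(f"unknown feature {name!r}")
        return self.frame[name].to_numpy(dtype=float)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    """Write the cohort CSV (comma-separated, UTF-8, header, '.' decimal)."""
    table.frame.to_csv(path, index=False, encoding="utf-8")


def read_cohort_table(path: str | Path) -> CohortTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, encoding="utf-8")
    return CohortTable(frame)
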