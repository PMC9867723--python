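"""Core in-memory containers shared by all pipeline stages.

An :class:`ExpressionMatrix` is a features x samples table of intensities
(raw stage) or log2 expression values (later stages) with an explicit
processing-stage tag, so that out-of-order preprocessing is refused rather
than silently producing nonsense.  A :class:`CohortDesign` holds per-sample
metadata (donor, group, time point, batch) and supports designs with missing
donor/time-point combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Processing stages in mandatory order.
STAGES = ("raw", "bgcorr", "qnorm", "log2", "batchcorr")

GROUPS = ("PD", "HC")


class SchemaError(ValueError):
    """Malformed input table or metadata (missing columns, bad ids, ...)."""


class StageError(ValueError):
    """A preprocessing operation was applied out of order."""


@dataclass
class ExpressionMatrix:
    """Features x samples expression grid with a processing-stage flag.

    Parameters
    ----------
    data:
        DataFrame indexed by feature id, one column per sample id.
    stage:
        One of :data:`STAGES`; records how far preprocessing has run.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise SchemaError("duplicate sample ids in matrix columns")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, got {self.stage!r}; "
                "run the preprocessing steps in order "
                "(normexp -> quantile -> log2 -> batch)"
            )

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, values: np.ndarray | pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix with the same labels at a new stage."""
        if isinstance(values, pd.DataFrame):
            df = values
        else:
            df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, stage=stage)


DESIGN_COLUMNS = ("donor", "group", "time_h", "batch")


@dataclass
class CohortDesign:
    """Per-sample metadata: donor, group (PD/HC), time point in hours, batch.

    The table is indexed by sample id.  Missing donor/time combinations are
    simply absent rows; no imputation happens anywhere downstream.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"design table missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise SchemaError("duplicate sample ids in design")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise SchemaError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        self.table = self.table.assign(time_h=self.table["time_h"].astype(float))

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def time_points(self) -> list[float]:
        return sorted(self.table["time_h"].unique())

    @property
    def donors(self) -> list[str]:
        return sorted(self.table["donor"].unique())

    def samples_at(self, group: str | None = None, time_h: float | None = None) -> pd.Index:
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"] == group
        if time_h is not None:
            mask &= self.table["time_h"] == float(time_h)
        return self.table.index[mask]

    def donor_samples(self, donor: str) -> pd.DataFrame:
        """Rows for one donor, sorted by time."""
        sub = self.table[self.table["donor"] == donor]
        return sub.sort_values("time_h")

    def group_of_donor(self, donor: str) -> str:
        sub = self.table[self.table["donor"] == donor]
        if sub.empty:
            raise SchemaError(f"unknown donor {donor!r}")
        return str(sub["group"].iloc[0])


def check_matching(matrix: ExpressionMatrix, design: CohortDesign) -> None:
    """Raise :class:`SchemaError` if matrix and design sample ids differ."""
    m = set(matrix.sample_ids)
    d = set(design.sample_ids)
    only_m = sorted(m - d)
    only_d = sorted(d - m)
    if only_m or only_d:
        raise SchemaError(
            f"matrix/design sample mismatch: in matrix only {only_m[:5]}, "
            f"in design only {only_d[:5]}"
        )
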