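"""Case/control expression study container and its TSV dialects.

An :class:`ExpressionStudy` is a features x samples matrix plus a per-sample
group label.  Two platform dialects are supported:

``array``
    continuous log2 intensities (finite reals);
``rnaseq``
    raw sequencing counts (non-negative integers, possibly stored as floats).

On disk a study is a pair of TSV files: the matrix (first column = feature id,
remaining columns = sample ids) and a sample sheet with columns
``sample_id`` and ``group`` (``case`` / ``control``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

CASE = "case"
CONTROL = "control"
PLATFORMS = ("array", "rnaseq")


@dataclass
class ExpressionStudy:
    """One case/control study.

    Parameters
    ----------
    study_id
        Free-text identifier, used in logs and output tables.
    platform
        ``"array"`` or ``"rnaseq"``; decides which DE engine applies.
    values
        DataFrame of shape (features, samples); the index holds feature ids
        (platform-native probe ids before harmonization, gene symbols after).
    group
        Series indexed by sample id with values ``"case"`` / ``"control"``,
        covering exactly the matrix columns.
    """

    study_id: str
    platform: str
    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ConfigError(f"platform: {self.platform!r} not in {PLATFORMS}")
        if not self.values.index.is_unique:
            raise DataError(f"{self.study_id}: duplicate feature ids in matrix")
        if list(self.group.index) != list(self.values.columns):
            raise DataError(
                f"{self.study_id}: sample sheet does not match matrix columns"
            )
        bad = set(self.group.unique()) - {CASE, CONTROL}
        if bad:
            raise DataError(f"{self.study_id}: unknown group labels {sorted(bad)}")
        vals = self.values.to_numpy()
        if self.platform == "rnaseq":
            if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                raise DataError(f"{self.study_id}: rnaseq counts must be non-negative integers")
        else:
            if not np.all(np.isfinite(vals)):
                raise DataError(f"{self.study_id}: array intensities must be finite")

    # -- convenience ------------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.group.index[self.group == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.group.index[self.group == CONTROL])

    @property
    def n_case(self) -> int:
        return int((self.group == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.group == CONTROL).sum())

    @property
    def n_total(self) -> int:
        return len(self.group)

    @property
    def is_case(self) -> np.ndarray:
        return (self.group == CASE).to_numpy()

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        """Write the matrix and sample sheet in the package TSV dialect."""
        mat = self.values.copy()
        mat.index.name = "feature_id"
        if self.platform == "rnaseq":
            mat = mat.astype(np.int64)
        mat.to_csv(matrix_path, sep="\t", lineterminator="\n")
        sheet = pd.DataFrame(
            {"sample_id": self.group.index, "group": self.group.to_numpy()}
        )
        sheet.to_csv(samples_path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(
        cls,
        study_id: str,
        platform: str,
        matrix_path: str | Path,
        samples_path: str | Path,
    ) -> "ExpressionStudy":
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        mat.index = mat.index.astype(str)
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(sheet.columns):
            raise DataError(f"{samples_path}: sample sheet needs sample_id and group columns")
        group = pd.Series(sheet["group"].to_numpy(), index=sheet["sample_id"].to_numpy())
        missing = [s for s in mat.columns if s not in group.index]
        if missing:
            raise DataError(f"{study_id}: samples {missing} missing from sample sheet")
        group = group.reindex(mat.columns)
        return cls(study_id=study_id, platform=platform, values=mat, group=group)
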