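"""Q-matrix, kinship and trait-table CSV formats.

Trait tables are plain pandas DataFrames indexed by individual id; binomial
columns hold {0, 1, NaN} and categorical columns {0, 1, 2, NaN}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    pass


@dataclass
class QMatrix:
    """Admixture proportions: one row per individual, K cluster columns."""

    individuals: list[str]
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.individuals):
            raise TableFormatError("Q shape inconsistent with individual ids")
        if np.any((self.q < -1e-9) | (self.q > 1 + 1e-9)):
            raise TableFormatError("Q entries outside [0, 1]")
        if np.any(np.abs(self.q.sum(axis=1) - 1.0) > 1e-9):
            raise TableFormatError("Q rows do not sum to 1")

    @property
    def k(self) -> int:
        return self.q.shape[1]

    def subset(self, ids: list[str]) -> "QMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        return QMatrix(list(ids), self.q[[pos[i] for i in ids]])


@dataclass
class KinshipMatrix:
    """Square symmetric relatedness matrix keyed by individual id."""

    individuals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise TableFormatError("kinship matrix not square / id mismatch")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise TableFormatError("kinship matrix not symmetric")

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = [pos[i] for i in ids]
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def mean_kinship(self, include_diagonal: bool = True) -> float:
        if include_diagonal:
            return float(self.values.mean())
        n = len(self.individuals)
        off = self.values[~np.eye(n, dtype=bool)]
        return float(off.mean())


def read_q_csv(path) -> QMatrix:
    df = pd.read_csv(path, dtype={"individual_id": str}).set_index("individual_id")
    return QMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_q_csv(Q: QMatrix, path) -> None:
    cols = [f"Q{k + 1}" for k in range(Q.k)]
    pd.DataFrame(Q.q, index=Q.individuals, columns=cols).to_csv(
        path, index_label="individual_id"
    )


def read_kinship_csv(path) -> KinshipMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise TableFormatError(f"{path}: kinship row/column ids disagree")
    return KinshipMatrix([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_kinship_csv(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.individuals, columns=K.individuals).to_csv(path)


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str}).set_index("individual_id")
    if df.columns.duplicated().any():
        raise TableFormatError(f"{path}: duplicate trait columns")
    return df


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="individual_id")
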