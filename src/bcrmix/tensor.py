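"""The clonal abundance tensor x_ist: clone x individual x time counts."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd


@dataclass
class AbundanceTensor:
    """K x S x T array of counts with the identifiers for each axis.

    ``time_ids`` are integer time points (days), sorted ascending; a time
    point of 0 denotes the pre-vaccination sample.  Only observed clones
    (total abundance >= 1) are represented.
    """

    x: np.ndarray
    clone_ids: list = field(default_factory=list)
    individual_ids: list = field(default_factory=list)
    time_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x)
        if self.x.ndim != 3:
            raise ValueError("abundance tensor must be 3-dimensional (K, S, T)")
        if np.any(self.x < 0):
            raise ValueError("abundances must be non-negative")
        k, s, t = self.x.shape
        if not self.clone_ids:
            self.clone_ids = list(range(k))
        if not self.individual_ids:
            self.individual_ids = list(range(s))
        if not self.time_ids:
            self.time_ids = list(range(t))
        if [len(self.clone_ids), len(self.individual_ids), len(self.time_ids)] != [k, s, t]:
            raise ValueError("axis identifier lengths do not match tensor shape")
        if list(self.time_ids) != sorted(self.time_ids):
            order = np.argsort(self.time_ids)
            self.x = self.x[:, :, order]
            self.time_ids = [self.time_ids[i] for i in order]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.x.shape

    @property
    def n_clones(self) -> int:
        return self.x.shape[0]

    def require_baseline(self) -> None:
        if 0 not in self.time_ids:
            raise ValueError("tensor has no pre-vaccination (time = 0) samples")

    def validate_observed(self) -> None:
        totals = self.x.sum(axis=(1, 2))
        if np.any(totals < 1):
            raise ValueError("every clone must be observed at least once")

    # -- tabular round trip ----------------------------------------------
    def to_frame(self, keep_zeros: bool = False) -> pd.DataFrame:
        k, s, t = self.shape
        ci, si, ti = np.unravel_index(np.arange(k * s * t), (k, s, t))
        df = pd.DataFrame(
            {
                "clone_id": np.asarray(self.clone_ids, dtype=object)[ci],
                "individual": np.asarray(self.individual_ids, dtype=object)[si],
                "time": np.asarray(self.time_ids)[ti],
                "abundance": self.x.ravel(),
            }
        )
        if not keep_zeros:
            df = df[df["abundance"] > 0].reset_index(drop=True)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTensor":
        required = {"clone_id", "individual", "time", "abundance"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tensor table is missing columns: {sorted(missing)}")
        clones = list(pd.unique(df["clone_id"]))
        individuals = sorted(pd.unique(df["individual"]), key=str)
        times = sorted(int(t) for t in pd.unique(df["time"]))
        ci = pd.Categorical(df["clone_id"], categories=clones).codes
        si = pd.Categorical(df["individual"], categories=individuals).codes
        ti = pd.Categorical(df["time"].astype(int), categories=times).codes
        x = np.zeros((len(clones), len(individuals), len(times)), dtype=np.int64)
        np.add.at(x, (ci, si, ti), df["abundance"].to_numpy())
        return cls(x, clones, individuals, times)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "AbundanceTensor":
        return cls.from_frame(pd.read_csv(path, sep="\t", comment="#"))


def as_tensor(x) -> AbundanceTensor:
    """Coerce an array or AbundanceTensor to an AbundanceTensor."""
    if isinstance(x, AbundanceTensor):
        return x
    return AbundanceTensor(np.asarray(x))
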