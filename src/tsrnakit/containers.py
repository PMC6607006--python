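"""Shared tabular containers."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """A feature x sample count table with a raw/normalized flag.

    Raw matrices hold nonnegative integers; normalized matrices hold
    nonnegative floats on the median-of-ratios common scale.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        if (self.data.values < 0).any():
            raise ValueError("count matrix contains negative values")
        if not self.normalized:
            vals = self.data.values
            if not (vals == vals.astype(int)).all():
                raise ValueError("raw count matrix must be integer-valued")

    @property
    def features(self):
        return list(self.data.index)

    @property
    def samples(self):
        return list(self.data.columns)

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# normalized={str(self.normalized).lower()}\n")
            self.data.to_csv(fh, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        normalized = False
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                if "normalized=true" in line:
                    normalized = True
        df = pd.read_csv(path, sep="\t", index_col="feature", skiprows=skip)
        return cls(data=df, normalized=normalized)
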