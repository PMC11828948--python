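"""Shared in-memory containers for screen count data."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

BASELINE = "baseline"
UNTREATED = "untreated"
TREATED = "treated"
CONDITIONS = (BASELINE, UNTREATED, TREATED)


@dataclass
class ScreenCounts:
    """Construct x sample count matrix with sample and construct metadata.

    ``counts`` is indexed by construct_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns condition / replicate /
    day; ``annotations`` is indexed by construct_id with columns pos1, pos2,
    target1, target2, pair_class.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns do not match the sample sheet")
        if not self.annotations.index.equals(self.counts.index):
            raise ValueError("annotations do not cover the count matrix rows")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if (self.samples["condition"] == BASELINE).sum() < 1:
            raise ValueError("a baseline sample is required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def baseline_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == BASELINE])

    def endpoint_samples(self, condition: str) -> pd.DataFrame:
        return self.samples[self.samples["condition"] == condition]

    def subset(self, construct_ids) -> "ScreenCounts":
        return ScreenCounts(
            counts=self.counts.loc[construct_ids],
            samples=self.samples,
            annotations=self.annotations.loc[construct_ids],
        )

    # --- plain-text round trip -------------------------------------------
    def write(self, counts_path: str | Path, samples_path: str | Path,
              annotations_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="construct_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
        self.annotations.to_csv(annotations_path, sep="\t", index_label="construct_id")

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path,
             annotations_path: str | Path) -> "ScreenCounts":
        counts = pd.read_csv(counts_path, sep="\t", index_col="construct_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        ann = pd.read_csv(annotations_path, sep="\t", index_col="construct_id")
        return cls(counts=counts, samples=samples, annotations=ann)


def annotations_from_library(library) -> pd.DataFrame:
    df = library.constructs_frame().set_index("construct_id")
    return df[["pos1", "pos2", "target1", "target2", "pair_class"]]
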