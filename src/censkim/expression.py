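"""CPM normalization and replicate aggregation of transcript hit counts.

CPM (counts per million reads mapped) = hit_number / library_size * 1e6.
Aggregation is two-stage: CPM is computed per sequencing run, averaged
within each biological replicate, and the replicate means are then
summarized per sample label (mean and sample SD across replicates), which
keeps the biological replicate as the error unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class HitCountSample:
    label: str  # tissue / developmental stage
    replicate: str
    run: str
    hit_count: int
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if not 0 <= self.hit_count <= self.library_size:
            raise ValueError("hit_count must be in [0, library_size]")


def cpm(hit_count: int, library_size: int) -> float:
    """Counts per million reads mapped: hit_count / library_size * 1e6."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if hit_count < 0:
        raise ValueError("hit_count must be >= 0")
    return hit_count / library_size * 1_000_000


def aggregate(samples: list[HitCountSample]) -> pd.DataFrame:
    """Per-label mean and sample SD of replicate-averaged CPM values.

    Returns columns (label, mean_cpm, sd, n_replicates).  A label with a
    single replicate reports SD 0 with a warning.
    """
    if not samples:
        raise ValueError("no samples to aggregate")
    df = pd.DataFrame(
        [
            {
                "label": s.label,
                "replicate": s.replicate,
                "cpm": cpm(s.hit_count, s.library_size),
            }
            for s in samples
        ]
    )
    per_replicate = (
        df.groupby(["label", "replicate"], sort=False)["cpm"].mean().reset_index()
    )
    rows = []
    for label, grp in per_replicate.groupby("label", sort=False):
        values = grp["cpm"].to_numpy()
        if len(values) == 1:
            warnings.warn(f"label {label!r} has a single replicate; SD reported as 0")
            sd = 0.0
        else:
            sd = float(values.std(ddof=1))
        rows.append(
            {
                "label": label,
                "mean_cpm": float(values.mean()),
                "sd": sd,
                "n_replicates": len(values),
            }
        )
    return pd.DataFrame(rows)


def aggregate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate from a TSV-shaped frame with columns
    (label, replicate, run, hit_count, library_size)."""
    samples = [
        HitCountSample(
            str(r.label), str(r.replicate), str(r.run), int(r.hit_count), int(r.library_size)
        )
        for r in df.itertuples()
    ]
    return aggregate(samples)
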