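"""Genus-level relative-abundance time series for spoilage experiments.

Works on a genus-aggregated, total-sum normalized table: one trajectory per
genus per treatment, replicates at a timepoint averaged but also retained
individually.  "Prominent" genera are ranked by the maximum normalized read
count they attain in any sample across treatments — an operational proxy
for high abundance during the spoilage course — with lexicographic
tie-breaking so the selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import TableError
from .tables import OtuTable, SampleMetadata


@dataclass
class AbundanceTimeSeries:
    """One genus's trajectory under one treatment."""

    genus: str
    treatment: str
    timepoints: np.ndarray
    means: np.ndarray
    replicate_values: list[np.ndarray]  # per timepoint
    replicate_ids: list[list[str]]  # sample ids per timepoint

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.timepoints) > 0):
            raise TableError(f"genus {self.genus!r}: timepoints must increase strictly")

    @property
    def max_reads(self) -> float:
        return float(max(v.max() for v in self.replicate_values))


def build_timeseries(
    table: OtuTable,
    metadata: Mapping[str, SampleMetadata],
    treatment: str,
) -> list[AbundanceTimeSeries]:
    """One series per genus row for samples in ``treatment``.

    Requires ``timepoint_days`` and ``group`` in the metadata of every
    sample used; replicates at a timepoint are averaged arithmetically.
    """
    samples: list[str] = []
    for sid in table.sample_ids:
        md = metadata.get(sid)
        if md is None:
            raise TableError(f"sample {sid!r} missing from metadata")
        if md.group == treatment:
            if md.timepoint_days is None:
                raise TableError(f"sample {sid!r} has no timepoint_days")
            samples.append(sid)
    if not samples:
        raise TableError(f"no samples for treatment {treatment!r}")

    by_time: dict[float, list[str]] = {}
    for sid in samples:
        by_time.setdefault(float(metadata[sid].timepoint_days), []).append(sid)
    timepoints = np.array(sorted(by_time), float)

    series: list[AbundanceTimeSeries] = []
    for genus in table.otu_ids:
        row = table.counts.loc[genus]
        rep_values = [row[by_time[t]].to_numpy(float) for t in timepoints]
        means = np.array([v.mean() for v in rep_values])
        series.append(
            AbundanceTimeSeries(
                genus=genus,
                treatment=treatment,
                timepoints=timepoints,
                means=means,
                replicate_values=rep_values,
                replicate_ids=[list(by_time[t]) for t in timepoints],
            )
        )
    return series


def select_prominent_genera(
    series: Sequence[AbundanceTimeSeries], k: int = 6
) -> list[str]:
    """Top-``k`` genera by maximum normalized reads attained in any sample.

    The ranking pools all treatments present in ``series``; ties break
    lexicographically.  ``k`` beyond the genus count returns all genera.
    """
    if k < 1:
        raise TableError("k must be >= 1")
    best: dict[str, float] = {}
    for s in series:
        best[s.genus] = max(best.get(s.genus, -np.inf), s.max_reads)
    ranked = sorted(best, key=lambda g: (-best[g], g))
    return ranked[:k]


def timeseries_long_frame(
    series: Sequence[AbundanceTimeSeries], genera: Sequence[str] | None = None
) -> pd.DataFrame:
    """Long-format table: genus, treatment, timepoint, replicate, reads."""
    rows = []
    keep = None if genera is None else set(genera)
    for s in series:
        if keep is not None and s.genus not in keep:
            continue
        for t, values, sids in zip(s.timepoints, s.replicate_values, s.replicate_ids):
            for rep, (value, sid) in enumerate(zip(values, sids), start=1):
                rows.append(
                    {
                        "genus": s.genus,
                        "treatment": s.treatment,
                        "timepoint_days": t,
                        "replicate": rep,
                        "sample_id": sid,
                        "normalized_reads": value,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "genus",
            "treatment",
            "timepoint_days",
            "replicate",
            "sample_id",
            "normalized_reads",
        ],
    )
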