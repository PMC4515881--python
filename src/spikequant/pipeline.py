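"""End-to-end pipelines with run manifests.

Every stage decision that affects sample-to-sample comparability — dropped
low-depth samples, the anchor value actually used, per-OTU excluded points
— is recorded in a manifest.  The manifest's ``parameters`` block can be
passed back verbatim to reproduce a run; internal ordering is canonical
(lexicographic by id), so results never depend on input row/column order.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .calibrate import (
    PanelResult,
    build_dilution_series,
    calibrate_panel,
)
from .errors import InsufficientDataError, TableError
from .normalize import (
    ReferenceSpec,
    reference_otu_normalize,
    total_sum_normalize,
)
from .profile import build_timeseries, select_prominent_genera, timeseries_long_frame
from .tables import (
    OtuTable,
    SampleMetadata,
    aggregate_by_genus,
    filter_low_depth_samples,
)

logger = logging.getLogger("spikequant")


def _infer_controls(metadata: Mapping[str, SampleMetadata], samples: Sequence[str]) -> list[str]:
    return [
        s
        for s in samples
        if s in metadata and not metadata[s].spike_spores_per_sample
    ]


def run_canned_food_pipeline(
    table: OtuTable,
    metadata: Mapping[str, SampleMetadata],
    *,
    ref_otu_id: str,
    otu_ids: Sequence[str],
    reference_value: float | None = None,
    control_sample_ids: Sequence[str] | None = None,
    min_reads: int = 1000,
    target_total: float = 10_000.0,
    min_reads_for_fit: float = 5.0,
    exclude_zero_reads: bool = True,
    read_threshold: float = 1.0,
    volume_ml: float = 0.85,
    endogenous_otu_ids: Sequence[str] = (),
) -> tuple[PanelResult, dict]:
    """Filter → total-sum → reference anchor → calibrate panel.

    Returns the panel result and a manifest recording every excluded sample
    and point together with the rule that excluded it.
    """
    table = table.sorted_by_id()
    filtered, dropped = filter_low_depth_samples(table, min_reads=min_reads)
    depths = table.sample_depths()
    logger.info("depth filter: dropped %d of %d samples", len(dropped), table.n_samples)
    if filtered.n_samples == 0:
        raise InsufficientDataError("all samples dropped by the depth filter")

    total = total_sum_normalize(filtered, target_total=target_total)
    if control_sample_ids is None:
        control_sample_ids = _infer_controls(metadata, total.sample_ids)
    spec = ReferenceSpec(
        ref_otu_id=ref_otu_id,
        reference_value=reference_value,
        control_sample_ids=tuple(control_sample_ids),
    )
    anchored, unnormalizable = reference_otu_normalize(total, spec)
    value_used = float(anchored.counts.loc[ref_otu_id].iloc[0]) if anchored.n_samples else None
    logger.info("reference anchor %s set to %s", ref_otu_id, value_used)

    panel = calibrate_panel(
        anchored,
        metadata,
        otu_ids,
        min_reads_for_fit=min_reads_for_fit,
        exclude_zero_reads=exclude_zero_reads,
        read_threshold=read_threshold,
        volume_ml=volume_ml,
        endogenous_otu_ids=endogenous_otu_ids,
    )

    excluded_points: dict[str, list] = {}
    for otu_id in otu_ids:
        try:
            series = build_dilution_series(
                anchored,
                metadata,
                otu_id,
                min_reads_for_fit=min_reads_for_fit,
                exclude_zero_reads=exclude_zero_reads,
            )
            excluded_points[otu_id] = [
                {"sample_id": sid, "reads": reads, "rule": rule}
                for sid, reads, rule in series.exclusions()
            ]
        except (InsufficientDataError, TableError):
            continue

    manifest = {
        "pipeline": "canned_food",
        "version": __version__,
        "parameters": {
            "ref_otu_id": ref_otu_id,
            "otu_ids": list(otu_ids),
            "reference_value": reference_value,
            "control_sample_ids": list(control_sample_ids),
            "min_reads": min_reads,
            "target_total": target_total,
            "min_reads_for_fit": min_reads_for_fit,
            "exclude_zero_reads": exclude_zero_reads,
            "read_threshold": read_threshold,
            "volume_ml": volume_ml,
            "endogenous_otu_ids": list(endogenous_otu_ids),
        },
        "sample_depths": {s: float(depths[s]) for s in table.sample_ids},
        "dropped_low_depth_samples": [
            {"sample_id": s, "depth": float(depths[s]), "rule": f"depth < {min_reads}"}
            for s in dropped
        ],
        "reference_value_used": value_used,
        "unnormalizable_samples": [
            {"sample_id": s, "rule": "reference OTU at zero reads"}
            for s in unnormalizable
        ],
        "excluded_points": excluded_points,
        "failures": panel.failures,
        "summary_formula": panel.summary_formula,
    }
    return panel, manifest


def run_rte_pipeline(
    table: OtuTable,
    metadata: Mapping[str, SampleMetadata],
    *,
    treatment: str,
    min_reads: int = 1000,
    target_total: float = 10_000.0,
    k: int = 6,
) -> tuple[pd.DataFrame, dict]:
    """Filter → total-sum → genus aggregate → time series → top-k genera."""
    if table.taxonomy is None:
        raise TableError("RTE pipeline requires taxonomy for genus aggregation")
    table = table.sorted_by_id()
    filtered, dropped = filter_low_depth_samples(table, min_reads=min_reads)
    if filtered.n_samples == 0:
        raise InsufficientDataError("all samples dropped by the depth filter")
    total = total_sum_normalize(filtered, target_total=target_total)
    genus_table = aggregate_by_genus(total)
    series = build_timeseries(genus_table, metadata, treatment)
    genera = select_prominent_genera(series, k=k)
    report = timeseries_long_frame(series, genera)

    manifest = {
        "pipeline": "rte",
        "version": __version__,
        "parameters": {
            "treatment": treatment,
            "min_reads": min_reads,
            "target_total": target_total,
            "k": k,
        },
        "dropped_low_depth_samples": [
            {"sample_id": s, "rule": f"depth < {min_reads}"} for s in dropped
        ],
        "selected_genera": genera,
    }
    return report, manifest
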