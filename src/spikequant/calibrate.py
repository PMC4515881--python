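"""Dilution-series calibration and detection limits.

A spiked dilution series is summarized per OTU as paired observations
(spores/sample, reference-normalized reads).  A line y = a·x + b is fitted
by ordinary least squares in log10–log10 space over the included points;
the detection limit is the exact functional inverse of the fitted line at a
chosen read threshold y*:

    x* = (log10 y* − b) / a,   detection limit = 10^x* spores/sample.

Point-inclusion rules follow the calibration protocol: samples yielding no
reads are excluded outright, and points at or below ``min_reads_for_fit``
(default 5 normalized reads/sample, strict) are marked not included.  The
limit scales linearly with the read threshold (tenfold higher at ten reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, TableError
from .tables import OtuTable, SampleMetadata

DEFAULT_MIN_READS_FOR_FIT = 5.0
DEFAULT_READ_THRESHOLD = 1.0
DEFAULT_VOLUME_ML = 0.85


@dataclass
class DilutionSeries:
    """Per-OTU paired (spores/sample, normalized reads) observations."""

    otu_id: str
    spores: np.ndarray
    reads: np.ndarray
    included: np.ndarray
    sample_ids: list[str]
    min_reads_for_fit: float = DEFAULT_MIN_READS_FOR_FIT

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def exclusions(self) -> list[tuple[str, float, str]]:
        """(sample_id, reads, rule) for every point left out of the fit."""
        out = []
        for sid, reads, inc in zip(self.sample_ids, self.reads, self.included):
            if inc:
                continue
            rule = "zero reads" if reads == 0 else f"reads <= {self.min_reads_for_fit:g}"
            out.append((sid, float(reads), rule))
        return out


@dataclass(frozen=True)
class CalibrationFit:
    """Log-log line y = a·x + b with its detection limit.

    ``detection_limit_log10`` is x* = (log10(read_threshold) − b)/a;
    ``detection_limit_spores`` = 10^x*.  Negative log10 limits are reported
    as-is and flagged ``non_physical`` (they arise for matrix-endogenous
    OTUs with a flat dose response, where the "limit" is an artefact of the
    background, or when the line crosses the threshold below one spore).
    """

    otu_id: str
    slope_a: float
    intercept_b: float
    r_squared: float
    n_points: int
    read_threshold: float | None = None
    detection_limit_log10: float | None = None
    detection_limit_spores: float | None = None
    detection_limit_per_ml: float | None = None
    endogenous: bool = False
    non_physical: bool = False


def build_dilution_series(
    table: OtuTable,
    metadata: Mapping[str, SampleMetadata],
    otu_id: str,
    min_reads_for_fit: float = DEFAULT_MIN_READS_FOR_FIT,
    exclude_zero_reads: bool = True,
) -> DilutionSeries:
    """Collect the (spike level, normalized reads) points for one OTU.

    Only samples with a positive spike level in the metadata enter the
    series; replicates remain separate points.  Inclusion requires strictly
    more than ``min_reads_for_fit`` reads, and (by default) any reads at all.
    Raises when fewer than two points survive.
    """
    if table.state != "reference_normalized":
        raise TableError("dilution series require a reference-normalized table")
    if otu_id not in table.counts.index:
        raise TableError(f"OTU {otu_id!r} absent from table")
    sample_ids: list[str] = []
    spores: list[float] = []
    for sid in table.sample_ids:
        md = metadata.get(sid)
        if md is None:
            raise TableError(f"sample {sid!r} missing from metadata")
        if md.spike_spores_per_sample is not None and md.spike_spores_per_sample > 0:
            sample_ids.append(sid)
            spores.append(float(md.spike_spores_per_sample))
    if not sample_ids:
        raise InsufficientDataError(f"OTU {otu_id!r}: no spiked samples")
    reads = table.counts.loc[otu_id, sample_ids].to_numpy(float)
    spores_arr = np.asarray(spores, float)
    included = reads > min_reads_for_fit  # strict: a point at the cutoff is out
    if exclude_zero_reads:
        included &= reads > 0
    else:
        included &= reads > 0  # log10 needs positive reads regardless
    series = DilutionSeries(
        otu_id=otu_id,
        spores=spores_arr,
        reads=reads,
        included=included,
        sample_ids=sample_ids,
        min_reads_for_fit=min_reads_for_fit,
    )
    if series.n_included < 2:
        raise InsufficientDataError(
            f"OTU {otu_id!r}: insufficient points for regression "
            f"({series.n_included} included)"
        )
    return series


def fit_loglog(series: DilutionSeries) -> CalibrationFit:
    """Ordinary least squares of log10(reads) on log10(spores).

    R² is the squared Pearson correlation of (x, y); any two-point series is
    an exact interpolation, so its R² is exactly 1.
    """
    x = np.log10(series.spores[series.included])
    y = np.log10(series.reads[series.included])
    if x.size < 2:
        raise InsufficientDataError(
            f"OTU {series.otu_id!r}: insufficient points for regression"
        )
    if np.unique(x).size < 2:
        raise InsufficientDataError(
            f"OTU {series.otu_id!r}: all points at one spore level, no spread"
        )
    res = stats.linregress(x, y)
    r_squared = 1.0 if x.size == 2 else float(res.rvalue) ** 2
    return CalibrationFit(
        otu_id=series.otu_id,
        slope_a=float(res.slope),
        intercept_b=float(res.intercept),
        r_squared=r_squared,
        n_points=int(x.size),
    )


def detection_limit(
    fit: CalibrationFit,
    read_threshold: float = DEFAULT_READ_THRESHOLD,
    endogenous: bool | None = None,
) -> CalibrationFit:
    """Complete a fit with its detection limit at ``read_threshold`` reads."""
    if read_threshold <= 0:
        raise TableError("read_threshold must be > 0")
    if fit.slope_a == 0:
        raise InsufficientDataError(f"OTU {fit.otu_id!r}: zero slope, no dose response")
    if endogenous is None:
        endogenous = fit.endogenous
    log10_limit = (math.log10(read_threshold) - fit.intercept_b) / fit.slope_a
    spores = 10.0 ** log10_limit
    return replace(
        fit,
        read_threshold=read_threshold,
        detection_limit_log10=log10_limit,
        detection_limit_spores=spores,
        detection_limit_per_ml=None,
        endogenous=endogenous,
        non_physical=bool(endogenous or log10_limit < 0),
    )


def detection_limit_from_line(
    slope_a: float, intercept_b: float, read_threshold: float = DEFAULT_READ_THRESHOLD
) -> tuple[float, float]:
    """Closed-form limit (log10 spores, spores) for a given line y = a·x + b."""
    if slope_a == 0:
        raise InsufficientDataError("zero slope, no dose response")
    log10_limit = (math.log10(read_threshold) - intercept_b) / slope_a
    return log10_limit, 10.0 ** log10_limit


def per_ml(fit: CalibrationFit, volume_ml: float = DEFAULT_VOLUME_ML) -> float:
    """Detection limit per ml of sample matrix."""
    if volume_ml <= 0:
        raise TableError("volume_ml must be > 0")
    if fit.detection_limit_spores is None:
        raise InsufficientDataError("detection limit not computed yet")
    return fit.detection_limit_spores / volume_ml


@dataclass
class PanelResult:
    """Per-OTU calibration fits plus a panel-level summary.

    The summary is the arithmetic mean of per-OTU detection limits over
    spike OTUs (matrix-endogenous OTUs excluded), per sample and per ml;
    ``summary_formula`` records how it was computed.
    """

    fits: list[CalibrationFit]
    failures: dict[str, str] = field(default_factory=dict)
    mean_detection_limit_spores: float | None = None
    mean_detection_limit_per_ml: float | None = None
    summary_formula: str = (
        "arithmetic mean of per-OTU detection limits (spores/sample and "
        "spores/ml) over non-endogenous spike OTUs"
    )

    def to_records(self) -> list[dict]:
        return [
            {
                "otu_id": f.otu_id,
                "a": f.slope_a,
                "b": f.intercept_b,
                "r_squared": f.r_squared,
                "n_points": f.n_points,
                "dl_log10": f.detection_limit_log10,
                "dl_spores": f.detection_limit_spores,
                "dl_per_ml": f.detection_limit_per_ml,
                "endogenous": f.endogenous,
                "non_physical": f.non_physical,
            }
            for f in self.fits
        ]


def calibrate_panel(
    table: OtuTable,
    metadata: Mapping[str, SampleMetadata],
    otu_ids: Sequence[str],
    *,
    min_reads_for_fit: float = DEFAULT_MIN_READS_FOR_FIT,
    exclude_zero_reads: bool = True,
    read_threshold: float = DEFAULT_READ_THRESHOLD,
    volume_ml: float = DEFAULT_VOLUME_ML,
    endogenous_otu_ids: Iterable[str] = (),
) -> PanelResult:
    """Fit every OTU in the panel; continue past single-OTU failures."""
    endogenous = set(endogenous_otu_ids)
    fits: list[CalibrationFit] = []
    failures: dict[str, str] = {}
    for otu_id in otu_ids:
        try:
            series = build_dilution_series(
                table,
                metadata,
                otu_id,
                min_reads_for_fit=min_reads_for_fit,
                exclude_zero_reads=exclude_zero_reads,
            )
            fit = detection_limit(
                fit_loglog(series),
                read_threshold=read_threshold,
                endogenous=otu_id in endogenous,
            )
            fit = replace(fit, detection_limit_per_ml=per_ml(fit, volume_ml))
        except (InsufficientDataError, TableError) as exc:
            failures[otu_id] = str(exc)
            continue
        fits.append(fit)
    result = PanelResult(fits=fits, failures=failures)
    spike_fits = [f for f in fits if not f.endogenous]
    if spike_fits:
        result.mean_detection_limit_spores = float(
            np.mean([f.detection_limit_spores for f in spike_fits])
        )
        result.mean_detection_limit_per_ml = float(
            np.mean([f.detection_limit_per_ml for f in spike_fits])
        )
    return result
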