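"""Two-stage normalization for spike-anchored quantification.

Stage one is total-sum scaling: every sample is rescaled to a fixed read
total (10,000 by default), turning counts into relative abundances on a
common scale.  Stage two anchors an internal-standard OTU — a species
present at the same concentration in every sample, such as an inactivated
water contaminant in the food matrix — to a fixed read value (e.g. 340),
making read counts comparable across samples in absolute terms.

The second stage requires total-sum normalized input; running it on raw
counts would entangle sequencing depth with the anchor.  Samples where the
reference OTU yielded zero reads cannot be anchored (the reference was
diluted below detectability, as happens in heavily overgrown samples); they
are reported, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, TableError
from .tables import OtuTable

DEFAULT_TARGET_TOTAL = 10_000.0


@dataclass(frozen=True)
class ReferenceSpec:
    """How to anchor the reference (internal-standard) OTU.

    ``reference_value`` is the read value the reference OTU is set to in
    every sample; when None it is derived as the mean reference-OTU reads
    over ``control_sample_ids`` (unspiked samples).
    """

    ref_otu_id: str
    reference_value: float | None = None
    control_sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.reference_value is not None and self.reference_value <= 0:
            raise TableError("reference_value must be > 0")


def total_sum_normalize(
    table: OtuTable, target_total: float = DEFAULT_TARGET_TOTAL
) -> OtuTable:
    """Scale each sample so its column sum equals ``target_total``.

    Within-sample OTU ratios are untouched.  A zero-depth sample cannot be
    scaled and raises an error naming it.
    """
    if target_total <= 0:
        raise TableError("target_total must be > 0")
    depths = table.counts.sum(axis=0)
    zero = depths[depths <= 0]
    if len(zero):
        raise TableError(f"sample {zero.index[0]!r} has zero total reads")
    scaled = table.counts.astype(float) * (target_total / depths)
    return OtuTable(counts=scaled, taxonomy=table.taxonomy, state="total_sum_normalized")


def reference_value_from_controls(
    table: OtuTable, ref_otu_id: str, control_sample_ids: Sequence[str]
) -> float:
    """Arithmetic mean of reference-OTU reads over the control samples."""
    if ref_otu_id not in table.counts.index:
        raise TableError(f"reference OTU {ref_otu_id!r} absent from table")
    missing = [s for s in control_sample_ids if s not in table.counts.columns]
    if missing:
        raise TableError(f"control sample {missing[0]!r} absent from table")
    if not len(control_sample_ids):
        raise TableError("no control samples given")
    mean = float(table.counts.loc[ref_otu_id, list(control_sample_ids)].mean())
    if mean <= 0:
        raise InsufficientDataError(
            f"reference OTU {ref_otu_id!r} undetected in all controls"
        )
    return mean


def reference_otu_normalize(
    table: OtuTable, spec: ReferenceSpec
) -> tuple[OtuTable, list[str]]:
    """Anchor the reference OTU to ``spec.reference_value`` in every sample.

    Each sample is scaled by ``reference_value / ref_reads``; in the output
    the reference-OTU row equals the reference value exactly.  Samples with
    zero reference reads are excluded from the normalized table and returned
    as the second element (input order).  Idempotent: re-anchoring an
    already anchored table is the identity.
    """
    if table.state not in ("total_sum_normalized", "reference_normalized"):
        raise TableError(
            "reference_otu_normalize requires a total-sum normalized table "
            f"(got state={table.state!r})"
        )
    if spec.ref_otu_id not in table.counts.index:
        raise TableError(f"reference OTU {spec.ref_otu_id!r} absent from table")
    reference_value = spec.reference_value
    if reference_value is None:
        reference_value = reference_value_from_controls(
            table, spec.ref_otu_id, spec.control_sample_ids
        )

    ref_reads = table.counts.loc[spec.ref_otu_id]
    unnormalizable = [s for s in table.sample_ids if ref_reads[s] == 0]
    keep = [s for s in table.sample_ids if ref_reads[s] > 0]
    scaled = table.counts[keep] * (reference_value / ref_reads[keep])
    # pin the anchor row exactly (kills the last-ulp division error)
    scaled.loc[spec.ref_otu_id] = reference_value
    out = OtuTable(counts=scaled, taxonomy=table.taxonomy, state="reference_normalized")
    return out, unnormalizable
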