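"""OTU count tables and sample metadata: I/O, depth filtering, genus aggregation.

The table dialect is plain TSV, UTF-8, with header ``#OTU_ID<TAB>sample1<TAB>...``
and an optional trailing ``taxonomy`` column holding semicolon-delimited
lineages (genus in the sixth rank field).  Empty cells parse as zero reads —
the sparse-export convention: an absent observation is no reads.

An :class:`OtuTable` carries a normalization-state tag so downstream stages
can enforce their preconditions: raw integer counts, total-sum scaled
(each sample summing to a fixed read total), or reference-OTU anchored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import TableError

STATES = ("raw", "total_sum_normalized", "reference_normalized")

OTU_ID_HEADER = "#OTU_ID"
TAXONOMY_COLUMN = "taxonomy"
UNCLASSIFIED = "unclassified"

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


@dataclass
class OtuTable:
    """Rectangular non-negative abundance matrix over OTU ids × sample ids.

    ``counts`` is indexed by OTU id (rows) and sample id (columns) — the
    classic OTU-table layout.  Raw tables must hold whole numbers.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise TableError(f"unknown table state {self.state!r}")
        idx = self.counts.index
        cols = self.counts.columns
        for axis_name, labels in (("OTU", idx), ("sample", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise TableError(f"duplicate {axis_name} id {dup[0]!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise TableError("counts must be numeric")
        if values.size and (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative count at OTU {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.state == "raw" and values.size:
            if not np.allclose(values, np.round(values), rtol=0, atol=1e-9):
                r, c = np.argwhere(
                    ~np.isclose(values, np.round(values), rtol=0, atol=1e-9)
                )[0]
                raise TableError(
                    f"raw table holds non-integer count at OTU {idx[r]!r}, "
                    f"sample {cols[c]!r}"
                )

    # -- conveniences -------------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Per-sample column sums (read depth for raw tables)."""
        return self.counts.sum(axis=0)

    def sorted_by_id(self) -> "OtuTable":
        """Canonical ordering: rows and columns sorted lexicographically."""
        counts = self.counts.sort_index(axis=0).sort_index(axis=1)
        return replace(self, counts=counts)

    def equals(self, other: "OtuTable", rtol: float = 1e-9) -> bool:
        if self.otu_ids != other.otu_ids or self.sample_ids != other.sample_ids:
            return False
        if self.state != other.state or (self.taxonomy or {}) != (other.taxonomy or {}):
            return False
        return np.allclose(
            self.counts.to_numpy(float), other.counts.to_numpy(float), rtol=rtol, atol=0
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations used by calibration and profiling.

    ``spike_spores_per_sample`` is the known spore count of each spiked
    species added to the sample (None when the sample was never spiked);
    ``volume_ml`` is the extracted sample volume (0.85 ml in the canned-food
    dilution series).
    """

    sample_id: str
    group: str = ""
    spike_spores_per_sample: float | None = None
    timepoint_days: float | None = None
    replicate: int = 1
    volume_ml: float = 0.85

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise TableError(f"sample {self.sample_id!r}: volume_ml must be > 0")
        if (
            self.spike_spores_per_sample is not None
            and self.spike_spores_per_sample < 0
        ):
            raise TableError(
                f"sample {self.sample_id!r}: spike_spores_per_sample must be >= 0"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_otu_table(
    path: str | Path,
    taxonomy_column: str | None = None,
    state: str = "raw",
) -> OtuTable:
    """Read a tab-separated OTU table (OTUs as rows, samples as columns).

    Empty cells parse as 0.  ``taxonomy_column`` names the lineage column;
    when omitted, a column literally named ``taxonomy`` is used if present.
    ``state`` tags the result (``raw`` by default, in which case counts must
    be whole numbers).
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 1 or not header[0]:
        raise TableError(f"{path}: missing header row")
    columns = header[1:]
    seen: set[str] = set()
    for name in columns:
        if name in seen:
            raise TableError(f"{path}: duplicate sample column {name!r} in header")
        seen.add(name)

    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False, encoding="utf-8"
    )
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise TableError(f"{path}: duplicate OTU id {dup[0]!r}")

    tax_col = taxonomy_column
    if tax_col is None and TAXONOMY_COLUMN in df.columns:
        tax_col = TAXONOMY_COLUMN
    taxonomy = None
    if tax_col is not None:
        if tax_col not in df.columns:
            raise TableError(f"{path}: taxonomy column {tax_col!r} not found")
        taxonomy = {otu: str(v) for otu, v in df[tax_col].items()}
        df = df.drop(columns=[tax_col])

    values = np.zeros(df.shape, dtype=float)
    raw = df.to_numpy()
    for (r, c), cell in np.ndenumerate(raw):
        text = cell.strip()
        if text == "":
            continue  # sparse convention: empty cell = 0 reads
        try:
            values[r, c] = float(text)
        except ValueError:
            raise TableError(
                f"{path}: non-numeric count {text!r} at OTU {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            ) from None
        if values[r, c] < 0:
            raise TableError(
                f"{path}: negative count at OTU {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
    counts = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns)
    if state == "raw":
        counts = counts.round().astype(np.int64) if _is_integral(values) else counts
    return OtuTable(counts=counts, taxonomy=taxonomy, state=state)


def _is_integral(values: np.ndarray) -> bool:
    return bool(np.allclose(values, np.round(values), rtol=0, atol=1e-9))


def write_otu_table(table: OtuTable, path: str | Path) -> Path:
    """Write the TSV dialect; raw integers are serialized without decimals,
    normalized reals with 12 significant digits (round-trip safe to 1e-9)."""
    path = Path(path)
    df = table.counts.copy()
    if table.state == "raw":
        df = df.astype(np.int64)
    if table.taxonomy is not None:
        df[TAXONOMY_COLUMN] = [table.taxonomy.get(o, "") for o in df.index]
    df.to_csv(path, sep="\t", index_label=OTU_ID_HEADER, float_format="%.12g")
    return path


def read_sample_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read a metadata TSV with mandatory ``sample_id`` column.

    Recognized columns: group, spike_spores_per_sample, timepoint_days,
    replicate, volume_ml; unknown columns are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise TableError(f"{path}: metadata must have a sample_id column")
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise TableError(f"{path}: duplicate sample_id {sid!r}")
        kwargs: dict = {"sample_id": sid}
        if row.get("group", "") != "":
            kwargs["group"] = row["group"]
        for col, cast in (
            ("spike_spores_per_sample", float),
            ("timepoint_days", float),
            ("replicate", int),
            ("volume_ml", float),
        ):
            text = row.get(col, "")
            if text != "":
                try:
                    kwargs[col] = cast(float(text)) if cast is int else cast(text)
                except ValueError:
                    raise TableError(
                        f"{path}: bad value {text!r} for {col} of sample {sid!r}"
                    ) from None
        out[sid] = SampleMetadata(**kwargs)
    return out


def write_sample_metadata(
    metadata: Mapping[str, SampleMetadata], path: str | Path
) -> Path:
    path = Path(path)
    rows = []
    for sid, md in metadata.items():
        rows.append(
            {
                "sample_id": sid,
                "group": md.group,
                "spike_spores_per_sample": (
                    "" if md.spike_spores_per_sample is None else repr(md.spike_spores_per_sample)
                ),
                "timepoint_days": "" if md.timepoint_days is None else repr(md.timepoint_days),
                "replicate": md.replicate,
                "volume_ml": repr(md.volume_ml),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Depth filter and genus aggregation
# ---------------------------------------------------------------------------


def filter_low_depth_samples(
    table: OtuTable, min_reads: int = 1000
) -> tuple[OtuTable, list[str]]:
    """Drop samples with column sum strictly below ``min_reads``.

    The boundary is kept: a sample at exactly ``min_reads`` survives
    (samples with *insufficient* reads, <1000, are discarded).  Survivor
    order is preserved; the dropped list follows input order.  Idempotent.
    """
    if table.state != "raw":
        raise TableError("depth filtering applies to raw tables")
    depths = table.sample_depths()
    keep = [s for s in table.sample_ids if depths[s] >= min_reads]
    dropped = [s for s in table.sample_ids if depths[s] < min_reads]
    return replace(table, counts=table.counts[keep]), dropped


def genus_of(lineage: str) -> str:
    """Extract the genus (sixth rank field) from a semicolon-delimited lineage.

    Rank prefixes like ``g__`` are stripped; unparseable lineages map to
    ``unclassified``.
    """
    fields = [f.strip() for f in str(lineage).split(";")]
    if len(fields) < 6:
        return UNCLASSIFIED
    genus = _RANK_PREFIX.sub("", fields[5]).strip()
    return genus if genus else UNCLASSIFIED


def aggregate_by_genus(table: OtuTable) -> OtuTable:
    """Sum OTU rows sharing a genus label; column sums are conserved exactly.

    OTUs without a genus assignment pool under ``unclassified``.  The output
    is ordered by genus label (canonical) and keeps the input state.
    """
    if table.taxonomy is None:
        raise TableError("genus aggregation requires taxonomy")
    genera = [genus_of(table.taxonomy.get(o, "")) for o in table.otu_ids]
    grouped = table.counts.groupby(pd.Index(genera, name="genus"), sort=True).sum()
    grouped.index = grouped.index.astype(str)
    return OtuTable(
        counts=grouped,
        taxonomy={g: g for g in grouped.index},
        state=table.state,
    )
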