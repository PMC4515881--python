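"""Synthetic spike-experiment and spoilage-time-series generators.

The generative model mirrors the structure the calibration analysis
assumes.  Each spiked species contributes template DNA proportional to

    w_s(n) = n · extraction_efficiency_s · copy_number_s

for n spores/sample, optionally split over two OTUs (some strains carry two
distinct 16S sequences).  Extraction efficiencies span up to three orders
of magnitude between spore species — the dominant quantification bias —
and 16S rRNA gene copy numbers lie in the 8–14 range typical of *Bacillus*
and *Geobacillus*.  A constant background matrix adds a dominant endogenous
OTU and a low-abundance internal-standard (reference) OTU.  Read counts are
multinomial draws given a per-sample depth from a normal distribution
(truncated at one read, rounded), so increasing spike load dilutes the
background OTUs' read share — the behaviour that limits reference
normalization in overgrown samples.

Because the model is exactly log-log linear with slope 1 in expectation,
every simulated table ships with closed-form truths
(:class:`SimulationTruth`, :func:`true_detection_limit`) for recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpikeQuantError, TableError
from .tables import OtuTable, SampleMetadata

DEFAULT_DILUTION_LEVELS = (8.5e0, 8.5e1, 8.5e2, 8.5e3, 8.5e4, 8.5e5)
DEFAULT_REFERENCE_VALUE = 340.0


@dataclass(frozen=True)
class SpeciesSpikeModel:
    """Generative parameters for one spiked spore species.

    ``extraction_efficiency`` is the relative template yield per spore
    (arbitrary units, comparable across species); ``copy_number`` the 16S
    rRNA gene copies per genome; ``otu_weights`` the split over this
    species' OTUs (two-OTU strains default to 0.5/0.5).
    """

    species_label: str
    otu_ids: tuple[str, ...]
    extraction_efficiency: float
    copy_number: int
    otu_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.otu_ids:
            raise TableError(f"{self.species_label}: needs at least one OTU")
        if self.extraction_efficiency <= 0:
            raise TableError(f"{self.species_label}: efficiency must be > 0")
        if self.copy_number < 1:
            raise TableError(f"{self.species_label}: copy_number must be >= 1")
        weights = self.otu_weights
        if weights is None:
            weights = tuple(1.0 / len(self.otu_ids) for _ in self.otu_ids)
            object.__setattr__(self, "otu_weights", weights)
        if len(weights) != len(self.otu_ids):
            raise TableError(f"{self.species_label}: one weight per OTU required")
        if any(w <= 0 for w in weights) or not math.isclose(sum(weights), 1.0):
            raise TableError(f"{self.species_label}: OTU weights must be > 0 and sum to 1")

    def otu_split(self, otu_id: str) -> float:
        return self.otu_weights[self.otu_ids.index(otu_id)]


@dataclass(frozen=True)
class BackgroundModel:
    """Constant per-sample template weights of the food-matrix flora.

    One OTU is designated the internal standard (reference); optionally a
    dominant endogenous OTU dwarfs it, as a heat-inactivated resident strain
    does in processed food.
    """

    background_otus: tuple[tuple[str, float], ...]
    reference_otu_id: str
    dominant_otu_id: str | None = None

    def __post_init__(self) -> None:
        ids = [o for o, _ in self.background_otus]
        if len(set(ids)) != len(ids):
            raise TableError("duplicate background OTU id")
        if any(w <= 0 for _, w in self.background_otus):
            raise TableError("background weights must be > 0")
        if self.reference_otu_id not in ids:
            raise TableError("reference_otu_id must be a background OTU")
        if self.dominant_otu_id is not None and self.dominant_otu_id not in ids:
            raise TableError("dominant_otu_id must be a background OTU")

    @property
    def weights(self) -> dict[str, float]:
        return dict(self.background_otus)

    @property
    def reference_weight(self) -> float:
        return self.weights[self.reference_otu_id]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of a simulated spike dilution experiment.

    Defaults reproduce the canned-food design: tenfold spore dilutions
    8.5e0–8.5e5 spores/sample of five species, three replicates per level
    plus unspiked controls, sequencing depth ~ N(6203, 2980²) truncated at
    one read, 0.85 ml sample volume.
    """

    species: tuple[SpeciesSpikeModel, ...]
    background: BackgroundModel
    dilution_levels: tuple[float, ...] = DEFAULT_DILUTION_LEVELS
    replicates_per_level: int = 3
    control_replicates: int = 3
    depth_mean: float = 6203.0
    depth_sd: float = 2980.0
    volume_ml: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise TableError("at least one spike species required")
        levels = np.asarray(self.dilution_levels, float)
        if levels.size < 1 or np.any(levels <= 0) or np.any(np.diff(levels) <= 0):
            raise TableError("dilution_levels must be positive and strictly increasing")
        if self.replicates_per_level < 1 or self.control_replicates < 0:
            raise TableError("replicate counts out of range")
        if self.depth_mean <= 0 or self.depth_sd < 0:
            raise TableError("depth_mean must be > 0 and depth_sd >= 0")
        if self.volume_ml <= 0:
            raise TableError("volume_ml must be > 0")
        ids = [o for o, _ in self.background.background_otus]
        for sp in self.species:
            ids.extend(sp.otu_ids)
        if len(set(ids)) != len(ids):
            raise TableError("OTU ids must be unique across species and background")

    @property
    def otu_ids(self) -> list[str]:
        out = [o for o, _ in self.background.background_otus]
        for sp in self.species:
            out.extend(sp.otu_ids)
        return out

    def spike_otu_ids(self) -> list[str]:
        out: list[str] = []
        for sp in self.species:
            out.extend(sp.otu_ids)
        return out

    def species_of(self, otu_id: str) -> SpeciesSpikeModel:
        for sp in self.species:
            if otu_id in sp.otu_ids:
                return sp
        raise SpikeQuantError(f"OTU {otu_id!r} is not a spiked OTU")


@dataclass(frozen=True)
class SimulationTruth:
    """Closed-form generative quantities emitted with every simulated table.

    ``otu_coefficients`` maps each spike OTU to efficiency × copy number ×
    OTU split, i.e. its template weight per spore; background weights are
    constant per sample.
    """

    otu_coefficients: dict[str, float]
    background_weights: dict[str, float]
    reference_otu_id: str
    config: SimulationConfig

    def expected_weights(self, spores_per_sample: float) -> pd.Series:
        w = dict(self.background_weights)
        for otu, coeff in self.otu_coefficients.items():
            w[otu] = coeff * spores_per_sample
        return pd.Series(w, dtype=float)[self.config.otu_ids]

    def expected_proportion(self, otu_id: str, spores_per_sample: float) -> float:
        w = self.expected_weights(spores_per_sample)
        return float(w[otu_id] / w.sum())

    def expected_normalized_reads(
        self,
        otu_id: str,
        spores_per_sample: float,
        reference_value: float = DEFAULT_REFERENCE_VALUE,
    ) -> float:
        """Expected reads after reference anchoring: value × w_otu / w_ref."""
        w = self.expected_weights(spores_per_sample)
        return float(reference_value * w[otu_id] / w[self.reference_otu_id])

    def true_limits(
        self,
        read_threshold: float = 1.0,
        reference_value: float = DEFAULT_REFERENCE_VALUE,
    ) -> dict[str, float]:
        return {
            otu: true_detection_limit(
                self.config, otu, read_threshold=read_threshold,
                reference_value=reference_value,
            )
            for otu in self.config.spike_otu_ids()
        }


def true_detection_limit(
    config: SimulationConfig,
    otu_id: str,
    read_threshold: float = 1.0,
    reference_value: float = DEFAULT_REFERENCE_VALUE,
) -> float:
    """Spore count at which expected reference-normalized reads hit the threshold.

    Solves reference_value · w_otu(n*) / w_ref = read_threshold, giving
    n* = read_threshold · w_ref / (reference_value · efficiency · copies · split).
    Linear in the threshold, like the empirical limit.
    """
    sp = config.species_of(otu_id)  # raises for non-spiked OTUs
    if read_threshold <= 0 or reference_value <= 0:
        raise TableError("read_threshold and reference_value must be > 0")
    coeff = sp.extraction_efficiency * sp.copy_number * sp.otu_split(otu_id)
    return read_threshold * config.background.reference_weight / (
        reference_value * coeff
    )


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    # one stream per sample, derived from the top-level seed by index, so
    # changing replicate counts never perturbs earlier samples
    return np.random.default_rng(np.random.SeedSequence([int(seed), sample_index]))


def _draw_depth(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(max(1, round(rng.normal(mean, sd))))


def simulate_spike_experiment(
    config: SimulationConfig,
) -> tuple[OtuTable, dict[str, SampleMetadata], SimulationTruth]:
    """Draw a raw OTU table for the spike dilution design.

    Sample order: unspiked controls first, then dilution levels ascending,
    replicates within level.  Same config (and seed) → identical output.
    """
    truth = SimulationTruth(
        otu_coefficients={
            otu: sp.extraction_efficiency * sp.copy_number * sp.otu_split(otu)
            for sp in config.species
            for otu in sp.otu_ids
        },
        background_weights=config.background.weights,
        reference_otu_id=config.background.reference_otu_id,
        config=config,
    )
    plan: list[tuple[str, float, int]] = []
    for rep in range(1, config.control_replicates + 1):
        plan.append((f"control_r{rep}", 0.0, rep))
    for li, level in enumerate(config.dilution_levels, start=1):
        for rep in range(1, config.replicates_per_level + 1):
            plan.append((f"spike_L{li}_r{rep}", float(level), rep))

    columns: dict[str, np.ndarray] = {}
    metadata: dict[str, SampleMetadata] = {}
    otu_ids = config.otu_ids
    for index, (sid, level, rep) in enumerate(plan):
        rng = _sample_rng(config.seed, index)
        depth = _draw_depth(rng, config.depth_mean, config.depth_sd)
        weights = truth.expected_weights(level).to_numpy()
        counts = rng.multinomial(depth, weights / weights.sum())
        columns[sid] = counts
        metadata[sid] = SampleMetadata(
            sample_id=sid,
            group="control" if level == 0 else "spiked",
            spike_spores_per_sample=level,
            replicate=rep,
            volume_ml=config.volume_ml,
        )
    table = OtuTable(
        counts=pd.DataFrame(columns, index=pd.Index(otu_ids, name="otu_id")),
        state="raw",
    )
    return table, metadata, truth


def default_canned_food_config(
    seed: int = 0,
    depth_mean: float = 6203.0,
    depth_sd: float = 2980.0,
    replicates_per_level: int = 3,
    control_replicates: int = 3,
) -> SimulationConfig:
    """Five-species spore panel emulating the canned-food spike experiment.

    Efficiencies span 1000-fold; copy numbers sit in the 8–14 range; two
    strains carry two OTUs.  The background holds a dominant endogenous OTU
    at 100× the reference (internal-standard) OTU's weight, so the reference
    contributes ~1 % of the reads; its absolute weight is placed so that,
    anchored at the control-derived reference value, every spike OTU's true
    detection limit falls inside the simulated dilution range and a single
    raw read maps below the >5-normalized-reads fit cutoff (as it does in
    the real calibration, where one read is worth ~1.6 normalized reads).
    """
    species = (
        SpeciesSpikeModel(
            "G. stearothermophilus", ("OTU6",), extraction_efficiency=0.3, copy_number=9
        ),
        SpeciesSpikeModel(
            "G. thermoglucosidans", ("OTU3", "OTU5"),
            extraction_efficiency=1.0, copy_number=10,
        ),
        SpeciesSpikeModel(
            "B. sporothermodurans", ("OTU4",), extraction_efficiency=0.02, copy_number=10
        ),
        SpeciesSpikeModel(
            "B. cereus", ("OTU2",), extraction_efficiency=0.001, copy_number=13
        ),
        SpeciesSpikeModel(
            "B. subtilis", ("OTU7", "OTU9"), extraction_efficiency=0.01, copy_number=10
        ),
    )
    background = BackgroundModel(
        background_otus=(("OTU1", 1.0e6), ("OTU8", 1.0e4)),
        reference_otu_id="OTU8",
        dominant_otu_id="OTU1",
    )
    return SimulationConfig(
        species=species,
        background=background,
        replicates_per_level=replicates_per_level,
        control_replicates=control_replicates,
        depth_mean=depth_mean,
        depth_sd=depth_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# RTE spoilage time series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RteConfig:
    """Per-genus template-weight trajectories over storage timepoints."""

    trajectories: tuple[tuple[str, tuple[float, ...]], ...]
    timepoints_days: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    treatment: str = "untreated"
    replicates_per_timepoint: int = 2
    depth_mean: float = 4091.0
    depth_sd: float = 1364.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.trajectories:
            raise TableError("at least one genus trajectory required")
        tp = np.asarray(self.timepoints_days, float)
        if np.any(np.diff(tp) <= 0):
            raise TableError("timepoints_days must increase strictly")
        genera = [g for g, _ in self.trajectories]
        if len(set(genera)) != len(genera):
            raise TableError("duplicate genus trajectory")
        for genus, weights in self.trajectories:
            if len(weights) != len(self.timepoints_days):
                raise TableError(f"{genus}: one weight per timepoint required")
            if any(w < 0 for w in weights):
                raise TableError(f"{genus}: negative trajectory weight")
            if all(w == 0 for w in weights):
                raise TableError(f"{genus}: all-zero trajectory")
        if self.replicates_per_timepoint < 1:
            raise TableError("replicates_per_timepoint must be >= 1")
        if self.depth_mean <= 0 or self.depth_sd < 0:
            raise TableError("depth_mean must be > 0 and depth_sd >= 0")


def simulate_rte_timeseries(
    config: RteConfig,
) -> tuple[OtuTable, dict[str, SampleMetadata]]:
    """Multinomial genus-count table for a spoilage storage experiment.

    One row per genus (with a minimal lineage so genus aggregation applies),
    ``replicates_per_timepoint`` samples per timepoint, depth ~ normal
    truncated at one read.  Deterministic for a fixed config.
    """
    genera = [g for g, _ in config.trajectories]
    weight_matrix = np.asarray([w for _, w in config.trajectories], float)

    columns: dict[str, np.ndarray] = {}
    metadata: dict[str, SampleMetadata] = {}
    index = 0
    for ti, t in enumerate(config.timepoints_days):
        weights = weight_matrix[:, ti]
        if weights.sum() <= 0:
            raise TableError(f"timepoint {t}: all trajectory weights zero")
        for rep in range(1, config.replicates_per_timepoint + 1):
            sid = f"{config.treatment}_t{t:04.1f}_r{rep}"
            rng = _sample_rng(config.seed, index)
            depth = _draw_depth(rng, config.depth_mean, config.depth_sd)
            columns[sid] = rng.multinomial(depth, weights / weights.sum())
            metadata[sid] = SampleMetadata(
                sample_id=sid,
                group=config.treatment,
                timepoint_days=float(t),
                replicate=rep,
            )
            index += 1
    taxonomy = {
        g: f"Bacteria;phylum;class;order;family;{g}" for g in genera
    }
    table = OtuTable(
        counts=pd.DataFrame(columns, index=pd.Index(genera, name="otu_id")),
        taxonomy=taxonomy,
        state="raw",
    )
    return table, metadata


def default_rte_config(treatment: str = "untreated", seed: int = 0) -> RteConfig:
    """Seven-timepoint spoilage community emulating a refrigerated RTE meal.

    Untreated: Leuconostoc rises first (day 6–8), then Bacillus and
    especially Paenibacillus take over while the plant-derived Streptophyta
    and Pseudomonas signal declines in relative terms.  Sorbate: only
    Leuconostoc grows out.
    """
    flat = lambda w: (w,) * 7  # noqa: E731 - tiny local shorthand
    if treatment == "untreated":
        trajectories = (
            ("Pseudomonas", flat(4500.0)),
            ("Streptophyta", flat(3500.0)),
            ("Leuconostoc", (50.0, 50.0, 50.0, 150.0, 1500.0, 5000.0, 3000.0)),
            ("Bacillus", (20.0, 20.0, 20.0, 20.0, 100.0, 2000.0, 4000.0)),
            ("Paenibacillus", (10.0, 10.0, 10.0, 10.0, 200.0, 5000.0, 20000.0)),
            ("Streptococcus", flat(30.0)),
            ("Enterobacter", flat(1900.0)),
        )
    elif treatment == "sorbate":
        trajectories = (
            ("Pseudomonas", flat(4500.0)),
            ("Streptophyta", flat(3500.0)),
            ("Leuconostoc", (50.0, 50.0, 50.0, 150.0, 1500.0, 5000.0, 6000.0)),
            ("Bacillus", flat(20.0)),
            ("Paenibacillus", flat(10.0)),
            ("Streptococcus", flat(30.0)),
            ("Enterobacter", flat(1900.0)),
        )
    else:
        raise TableError(f"no default trajectories for treatment {treatment!r}")
    return RteConfig(trajectories=trajectories, treatment=treatment, seed=seed)


# ---------------------------------------------------------------------------
# Config (de)serialization for the CLI
# ---------------------------------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "species": [
            {
                "species_label": sp.species_label,
                "otu_ids": list(sp.otu_ids),
                "extraction_efficiency": sp.extraction_efficiency,
                "copy_number": sp.copy_number,
                "otu_weights": list(sp.otu_weights),
            }
            for sp in config.species
        ],
        "background": {
            "background_otus": [[o, w] for o, w in config.background.background_otus],
            "reference_otu_id": config.background.reference_otu_id,
            "dominant_otu_id": config.background.dominant_otu_id,
        },
        "dilution_levels": list(config.dilution_levels),
        "replicates_per_level": config.replicates_per_level,
        "control_replicates": config.control_replicates,
        "depth_mean": config.depth_mean,
        "depth_sd": config.depth_sd,
        "volume_ml": config.volume_ml,
        "seed": config.seed,
    }


def config_from_dict(data: Mapping) -> SimulationConfig:
    try:
        species = tuple(
            SpeciesSpikeModel(
                species_label=sp["species_label"],
                otu_ids=tuple(sp["otu_ids"]),
                extraction_efficiency=float(sp["extraction_efficiency"]),
                copy_number=int(sp["copy_number"]),
                otu_weights=(
                    tuple(float(w) for w in sp["otu_weights"])
                    if sp.get("otu_weights")
                    else None
                ),
            )
            for sp in data["species"]
        )
        bg = data["background"]
        background = BackgroundModel(
            background_otus=tuple((o, float(w)) for o, w in bg["background_otus"]),
            reference_otu_id=bg["reference_otu_id"],
            dominant_otu_id=bg.get("dominant_otu_id"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise TableError(f"malformed simulation config: {exc}") from exc
    kwargs = {}
    for key in (
        "replicates_per_level",
        "control_replicates",
        "seed",
    ):
        if key in data:
            kwargs[key] = int(data[key])
    for key in ("depth_mean", "depth_sd", "volume_ml"):
        if key in data:
            kwargs[key] = float(data[key])
    if "dilution_levels" in data:
        kwargs["dilution_levels"] = tuple(float(x) for x in data["dilution_levels"])
    return SimulationConfig(species=species, background=background, **kwargs)
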