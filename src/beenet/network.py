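"""Quantitative pollen-transport networks from individual pollen-load records.

A pollen-transport network is a bipartite bee × plant matrix for one plot.
Entry (x, y) counts the *individuals* of bee species x that carried at least
``min_grains`` grains of plant y's pollen morphotype — the detection rule used
to decide that a captured bee is a potential pollinator of a plant.  Bee and
plant species without any interaction partner are pruned after thresholding.

Alongside the count matrix each network records, per retained bee species, the
number of distinct captured individuals that went into building the network
(including individuals whose pollen loads all fell below the grain threshold);
this specimen count is the abundance divisor used later when interaction
strengths are equalized for the apparent-competition index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns a pollen-load record table must carry.
POLLEN_COLUMNS = (
    "individual_id",
    "bee_species",
    "plot_id",
    "plot_type",
    "survey_round",
    "plant_species",
    "grain_count",
)

PLOT_TYPES = ("nearby", "distant")


class EmptyNetworkError(ValueError):
    """No bee–plant pair survived the grain threshold."""


class ValidationError(ValueError):
    """Input records violate the pollen-load schema or its invariants."""


@dataclass
class InteractionMatrix:
    """Bee × plant interaction counts for one plot (or one pooled plot type).

    Attributes
    ----------
    plot_id : str
        Plot label, or a pooled label such as ``"pooled_nearby"``.
    plot_type : str
        ``"nearby"`` (close to apiaries) or ``"distant"``.
    counts : pandas.DataFrame
        Integer matrix, bee species on rows, plant species on columns,
        lexicographically ordered labels.
    specimens : pandas.Series
        Per bee species, the number of distinct individuals captured in the
        plot, indexed like ``counts.index``.
    survey_block : int or None
        Set when the network covers a block of survey rounds rather than the
        whole season; ``None`` for season-combined networks.
    """

    plot_id: str
    plot_type: str
    counts: pd.DataFrame
    specimens: pd.Series
    survey_block: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.plot_type not in PLOT_TYPES:
            raise ValidationError(
                f"plot_type must be one of {PLOT_TYPES}, got {self.plot_type!r}"
            )
        if not self.counts.index.equals(self.specimens.index):
            raise ValidationError("counts rows and specimens index differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative interaction count")
        over = self.counts.gt(self.specimens, axis=0)
        if over.to_numpy().any():
            bad = self.counts.index[over.any(axis=1)].tolist()
            raise ValidationError(f"counts exceed specimen totals for {bad}")

    @property
    def bee_species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def plant_species(self) -> list[str]:
        return list(self.counts.columns)

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(
            self.plot_id,
            self.plot_type,
            self.counts.copy(),
            self.specimens.copy(),
            self.survey_block,
        )


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise EmptyNetworkError("no pollen-load records supplied")
    missing = [c for c in POLLEN_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"pollen-load table missing column(s): {missing}")
    if (records["grain_count"] < 0).any():
        rows = records.index[records["grain_count"] < 0].tolist()[:5]
        raise ValidationError(f"negative grain_count at row(s) {rows}")
    dup = records.duplicated(subset=["individual_id", "plant_species"])
    if dup.any():
        rows = records.index[dup].tolist()[:5]
        raise ValidationError(
            f"duplicate (individual_id, plant_species) pair at row(s) {rows}"
        )
    plots = records["plot_id"].unique()
    if len(plots) != 1:
        raise ValidationError(f"records span multiple plots: {sorted(plots)}")
    types = records["plot_type"].unique()
    if len(types) != 1:
        raise ValidationError(
            f"plot {plots[0]!r} carries inconsistent plot_type labels: {sorted(types)}"
        )
    unknown = records["plant_species"].isna() | (records["plant_species"] == "")
    if unknown.any():
        logger.warning(
            "dropping %d record(s) with unidentified pollen morphotype",
            int(unknown.sum()),
        )
        records = records[~unknown]
        if len(records) == 0:
            raise EmptyNetworkError("all records had unidentified morphotypes")
    return records


def build_network(
    records: pd.DataFrame, min_grains: int = 3, survey_block: int | None = None
) -> InteractionMatrix:
    """Build the quantitative pollen-transport network for one plot.

    Parameters
    ----------
    records : pandas.DataFrame
        One row per (captured individual, pollen morphotype) with the columns
        in :data:`POLLEN_COLUMNS`; all rows must share one ``plot_id``.
    min_grains : int
        Minimum grain count for a pollen load to count as an interaction
        (default 3 grains of the same morphotype).
    survey_block : int, optional
        Tag the network as covering a survey block (used for diet profiles).

    Returns
    -------
    InteractionMatrix
        Thresholded, pruned network with per-species specimen totals.

    Raises
    ------
    EmptyNetworkError
        If no records are given or no interaction passes the threshold.
    ValidationError
        On schema violations, negative grain counts, duplicated
        (individual, plant) pairs, or mixed plot labels.
    """
    if min_grains < 1:
        raise ValidationError("min_grains must be >= 1")
    records = _validate_records(records)

    plot_id = records["plot_id"].iloc[0]
    plot_type = records["plot_type"].iloc[0]

    # Specimen totals count every captured individual, interacting or not.
    specimens_all = (
        records.groupby("bee_species", sort=True)["individual_id"]
        .nunique()
        .rename("specimens")
    )

    hits = records[records["grain_count"] >= min_grains]
    if len(hits) == 0:
        raise EmptyNetworkError(
            f"plot {plot_id!r}: no pollen load reached {min_grains} grains"
        )
    counts = (
        hits.groupby(["bee_species", "plant_species"], sort=True)["individual_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    counts = _prune(counts)
    specimens = specimens_all.loc[counts.index].astype(int)
    return InteractionMatrix(
        str(plot_id), str(plot_type), counts.astype(int), specimens, survey_block
    )


def _prune(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop all-zero rows and columns and sort labels lexicographically."""
    counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if counts.empty:
        raise EmptyNetworkError("network empty after pruning isolated species")
    return counts.sort_index(axis=0).sort_index(axis=1)


def build_block_networks(
    records: pd.DataFrame, min_grains: int = 3, block_size: int = 2
) -> list[InteractionMatrix]:
    """Split one plot's records into consecutive survey-round blocks.

    Rounds 1..R are grouped into blocks of ``block_size`` consecutive rounds
    (block b covers rounds b*size+1 .. (b+1)*size) and one network is built
    per non-empty block.  Blocks in which nothing passes the grain threshold
    are skipped with a log message.
    """
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    records = _validate_records(records)
    blocks = (records["survey_round"].astype(int) - 1) // block_size
    nets: list[InteractionMatrix] = []
    for b, sub in records.groupby(blocks, sort=True):
        try:
            nets.append(build_network(sub, min_grains=min_grains, survey_block=int(b)))
        except EmptyNetworkError:
            logger.info(
                "plot %s block %d: no interactions above threshold, skipped",
                records["plot_id"].iloc[0],
                b,
            )
    return nets


def pool_or_split_networks(
    plot_networks: list[InteractionMatrix], mode: str = "per_plot"
) -> list[InteractionMatrix]:
    """Return per-plot networks unchanged, or pool them by plot type.

    ``pooled_by_type`` sums counts and specimen totals across the plots of
    each plot type and re-applies the zero-row/column pruning, yielding one
    network per plot type present in the input.
    """
    if mode == "per_plot":
        return list(plot_networks)
    if mode != "pooled_by_type":
        raise ValidationError(f"unknown pooling mode {mode!r}")
    if not plot_networks:
        raise ValidationError("no networks to pool")

    pooled: list[InteractionMatrix] = []
    for ptype in PLOT_TYPES:
        nets = [n for n in plot_networks if n.plot_type == ptype]
        if not nets:
            continue
        counts = nets[0].counts
        specimens = nets[0].specimens
        for n in nets[1:]:
            counts = counts.add(n.counts, fill_value=0).fillna(0)
            specimens = specimens.add(n.specimens, fill_value=0)
        counts = _prune(counts.astype(int))
        pooled.append(
            InteractionMatrix(
                f"pooled_{ptype}",
                ptype,
                counts,
                specimens.loc[counts.index].astype(int),
            )
        )
    return pooled
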