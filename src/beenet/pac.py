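"""Abundance-adjusted Müller's-index perceived apparent competition (PAC).

Müller's index for a quantitative bipartite matrix with entries ``a[i, k]``
(consumer i on resource k) is

    d_ij = sum_k (a_ik / sum_l a_il) * (a_jk / sum_m a_mk),

the share of consumer i's resource use that flows through resources also used
by consumer j, weighted by j's share of each resource.  Rows of d sum to one
over all partners (including d_ii).

Because the raw index is sensitive to the relative abundance of the two
species, interaction counts P_xy are first equalized by the number of
specimens A_x that built each network: N_xy = P_xy / A_x.  PAC between a
native bee and the introduced honeybee is then Müller's index computed on a
two-row matrix holding only those two adjusted rows — the native bee is the
focal row, so PAC measures the fraction of the native's (equalized) resource
use recaptured through plants the honeybee also exploits.  The reverse
direction (honeybee focal) is computed and reported alongside; because the
two-row construction works on diet proportions (equal abundances), the two
directions coincide numerically, and the column pair documents that.

PAC_C pairs each native's *nearby*-plot diet with the honeybee; PAC_D pairs
the native's *distant*-plot (undisturbed) diet with the honeybee's
nearby-derived profile, which is injected unchanged into every network since
the honeybee is absent from distant plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import InteractionMatrix

logger = logging.getLogger(__name__)

HONEYBEE = "Apis_mellifera"


class UndefinedIndexError(ValueError):
    """Müller's index is undefined (zero focal row sum or zero divisor)."""


@dataclass
class AdjustedMatrix:
    """Abundance-equalized interaction strengths N_xy = P_xy / A_x."""

    plot_id: str
    plot_type: str
    values: pd.DataFrame  # non-negative reals, bees x plants

    @property
    def bee_species(self) -> list[str]:
        return list(self.values.index)


@dataclass
class HoneybeeProfile:
    """The honeybee's interaction profile shared by all six networks.

    ``row`` holds the (unadjusted) interaction counts P_hb,y over plants —
    by default the pooled sum of the honeybee rows of the nearby networks —
    and ``a_hb`` the mean number of honeybee specimens across those networks.
    The adjusted row ``row / a_hb`` is identical wherever it is injected.
    """

    row: pd.Series
    a_hb: float

    def __post_init__(self) -> None:
        if self.a_hb <= 0:
            raise UndefinedIndexError("honeybee mean specimen count must be > 0")
        if not (self.row > 0).any():
            raise UndefinedIndexError("honeybee profile has no positive entry")

    @property
    def adjusted(self) -> pd.Series:
        return self.row / self.a_hb


def honeybee_profile(
    nearby_networks: list[InteractionMatrix],
    species: str = HONEYBEE,
    row_mode: str = "pooled",
) -> HoneybeeProfile:
    """Derive the honeybee profile from the nearby-plot networks.

    ``row_mode="pooled"`` sums the honeybee row over the nearby networks
    (default); ``"mean"`` averages it.  The abundance divisor is always the
    mean specimen count across the networks that contain the species.
    """
    rows, specs = [], []
    for net in nearby_networks:
        if net.plot_type != "nearby":
            raise ValueError(f"network {net.plot_id!r} is not a nearby network")
        if species in net.counts.index:
            rows.append(net.counts.loc[species])
            specs.append(float(net.specimens.loc[species]))
    if not rows:
        raise UndefinedIndexError(f"{species!r} absent from all nearby networks")
    stacked = pd.concat(rows, axis=1).fillna(0)
    row = stacked.sum(axis=1) if row_mode == "pooled" else stacked.mean(axis=1)
    if row_mode not in ("pooled", "mean"):
        raise ValueError(f"unknown honeybee row mode {row_mode!r}")
    return HoneybeeProfile(row=row.sort_index(), a_hb=float(np.mean(specs)))


def adjust_matrix(
    P: InteractionMatrix, honeybee: HoneybeeProfile | None = None
) -> AdjustedMatrix:
    """Equalize interaction strengths by specimen counts (N_xy = P_xy / A_x).

    Native rows are divided by the plot's own specimen count for the species;
    the honeybee row, when a profile is given, is replaced by the shared
    profile row divided by its cross-plot mean specimen count — injected even
    into networks (distant plots) where the honeybee was never captured.
    """
    zero = P.specimens[P.specimens <= 0]
    if len(zero):
        raise UndefinedIndexError(
            f"zero specimen count for {list(zero.index)} in plot {P.plot_id!r}"
        )
    values = P.counts.div(P.specimens, axis=0).astype(float)
    if honeybee is not None:
        hb = honeybee.adjusted
        cols = values.columns.union(hb.index[hb > 0]).sort_values()
        values = values.reindex(columns=cols, fill_value=0.0)
        values.loc[HONEYBEE] = hb.reindex(cols, fill_value=0.0)
        values = values.sort_index(axis=0)
    return AdjustedMatrix(P.plot_id, P.plot_type, values)


def muller_index(M: AdjustedMatrix | pd.DataFrame, i: str, j: str) -> float:
    """Müller's index d_ij on a full adjusted matrix (focal row i)."""
    values = M.values if isinstance(M, AdjustedMatrix) else M
    a = values.to_numpy(dtype=float)
    rows = list(values.index)
    ri, rj = rows.index(i), rows.index(j)
    row_sum = a[ri].sum()
    if row_sum <= 0:
        raise UndefinedIndexError(f"row {i!r} has zero total interaction strength")
    col_sum = a.sum(axis=0)
    use = a[ri] > 0
    return float(np.sum((a[ri, use] / row_sum) * (a[rj, use] / col_sum[use])))


def muller_matrix(M: AdjustedMatrix | pd.DataFrame) -> pd.DataFrame:
    """All pairwise d_ij for a matrix; rows sum to 1 over partners."""
    values = M.values if isinstance(M, AdjustedMatrix) else M
    a = values.to_numpy(dtype=float)
    row_sum = a.sum(axis=1, keepdims=True)
    if (row_sum <= 0).any():
        bad = values.index[(row_sum <= 0).ravel()].tolist()
        raise UndefinedIndexError(f"zero row sum for {bad}")
    col_sum = a.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(col_sum > 0, a / col_sum, 0.0)
    d = (a / row_sum) @ shares.T
    return pd.DataFrame(d, index=values.index, columns=values.index)


def pairwise_pac(native_row: pd.Series, honeybee_row: pd.Series) -> float:
    """PAC from a two-species matrix restricted to jointly relevant plants.

    Both rows must already be abundance-adjusted.  Each row is reduced to its
    diet proportions (the two-species matrix is built "under conditions of
    equal abundances", so only relative resource use matters and the result
    is invariant to rescaling either row), columns where neither row is
    positive are dropped (they would create 0/0 resource shares), and
    Müller's index d_{native→honeybee} is evaluated on the 2-row matrix.
    Identical diets give exactly 0.5; disjoint support gives 0.
    """
    cols = native_row.index.union(honeybee_row.index)
    n = native_row.reindex(cols, fill_value=0.0).to_numpy(dtype=float)
    h = honeybee_row.reindex(cols, fill_value=0.0).to_numpy(dtype=float)
    if n.sum() <= 0:
        raise UndefinedIndexError("native row has zero total interaction strength")
    if h.sum() <= 0:
        logger.info("honeybee row all zero: PAC = 0 (no shared resources)")
        return 0.0
    sn, sh = n.sum(), h.sum()
    keep = (n > 0) | (h > 0)
    n, h = n[keep], h[keep]
    if np.array_equal(n * sh, h * sn):
        return 0.5  # proportional diets share every column share equally
    # d = sum_k (n/sn) * (h/sh) / (n/sn + h/sh); zeros in either row
    # contribute nothing, so disjoint diets give exactly 0.
    return float(np.sum(n * ((h * sn) / (n * sh + h * sn))) / sn)


def pac_table(
    nearby_nets: list[AdjustedMatrix],
    distant_nets: list[AdjustedMatrix],
    honeybee: HoneybeeProfile,
) -> pd.DataFrame:
    """Per native species PAC_C (nearby) and PAC_D (distant).

    For each native species and each plot type, the pairwise PAC against the
    honeybee profile is computed in every network that contains the species
    and averaged arithmetically over those plots.  Species absent from all
    plots of a type get a missing value, not zero.  The reverse-direction
    index (honeybee focal) is stored alongside.

    Returns a DataFrame indexed by bee species with columns
    ``pac_c, pac_d, pac_c_reverse, pac_d_reverse, n_plots_c, n_plots_d``.
    """
    hb_adj = honeybee.adjusted
    natives = sorted(
        {
            sp
            for net in [*nearby_nets, *distant_nets]
            for sp in net.bee_species
            if sp != HONEYBEE
        }
    )
    out = {}
    for sp in natives:
        rec: dict[str, float] = {}
        for tag, nets in (("c", nearby_nets), ("d", distant_nets)):
            fwd, rev = [], []
            for net in nets:
                if sp not in net.values.index:
                    continue
                row = net.values.loc[sp]
                fwd.append(pairwise_pac(row, hb_adj))
                rev.append(pairwise_pac(hb_adj, row))
            rec[f"pac_{tag}"] = float(np.mean(fwd)) if fwd else np.nan
            rec[f"pac_{tag}_reverse"] = float(np.mean(rev)) if rev else np.nan
            rec[f"n_plots_{tag}"] = len(fwd)
        out[sp] = rec
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "bee_species"
    return table[
        ["pac_c", "pac_d", "pac_c_reverse", "pac_d_reverse", "n_plots_c", "n_plots_d"]
    ]
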