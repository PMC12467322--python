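"""Diet-niche shift tests: Bray-Curtis dissimilarity, PERMANOVA, NMDS.

Diet preference of a bee species in a sample is the proportion of its
network links going to each plant.  Samples (plot x survey block) are
compared with Bray-Curtis dissimilarity; a one-way PERMANOVA (pseudo-F on
among/within sums of squared dissimilarities, label permutations) tests
whether nearby- and distant-plot diets differ, and nonmetric MDS gives a
2-D ordination.  The same machinery doubles for the flowering-community
similarity check, with plots as samples and per-species flower abundance as
features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from sklearn.manifold import MDS

from .network import InteractionMatrix

logger = logging.getLogger(__name__)


class DegenerateDesignError(ValueError):
    """The grouping cannot support a permutation test."""


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples x 2, centered at the origin
    stress: float  # Kruskal stress-1 of the returned configuration
    converged: bool


def diet_profiles(
    networks: list[InteractionMatrix],
    species: set[str] | list[str],
    combine_adjacent: bool = True,
) -> pd.DataFrame:
    """Per-sample diet proportions for the requested bee species.

    ``networks`` are per-plot-per-block networks (see
    :func:`beenet.network.build_block_networks`).  With ``combine_adjacent``
    consecutive blocks within a plot are merged pairwise (counts summed)
    before proportioning, trading temporal resolution for samples with
    non-zero totals.  Samples in which a species has no links are omitted
    for that species, with a log message.

    Returns a long-format DataFrame with columns
    ``bee_species, sample_id, plot_id, plot_type, plant_species, proportion``;
    proportions sum to 1 within each (species, sample).
    """
    species = set(species)
    found = {sp for net in networks for sp in net.bee_species}
    missing = species - found
    if missing:
        raise ValueError(f"species absent from every network: {sorted(missing)}")

    merged: list[InteractionMatrix] = networks
    if combine_adjacent:
        merged = _merge_adjacent_blocks(networks)

    rows = []
    for net in merged:
        block = net.survey_block if net.survey_block is not None else 0
        sample_id = f"{net.plot_id}:b{block}"
        for sp in sorted(species & set(net.bee_species)):
            row = net.counts.loc[sp]
            total = row.sum()
            if total <= 0:
                logger.info("species %s has no links in sample %s", sp, sample_id)
                continue
            for plant, links in row[row > 0].items():
                rows.append(
                    {
                        "bee_species": sp,
                        "sample_id": sample_id,
                        "plot_id": net.plot_id,
                        "plot_type": net.plot_type,
                        "plant_species": plant,
                        "proportion": links / total,
                    }
                )
    return pd.DataFrame(rows)


def _merge_adjacent_blocks(
    networks: list[InteractionMatrix],
) -> list[InteractionMatrix]:
    """Sum counts of consecutive block pairs (0+1, 2+3, ...) within plots."""
    merged = []
    by_plot: dict[str, list[InteractionMatrix]] = {}
    for net in networks:
        by_plot.setdefault(net.plot_id, []).append(net)
    for plot_id, nets in sorted(by_plot.items()):
        nets = sorted(nets, key=lambda n: n.survey_block or 0)
        pairs: dict[int, list[InteractionMatrix]] = {}
        for net in nets:
            pairs.setdefault((net.survey_block or 0) // 2, []).append(net)
        for pair_idx, group in sorted(pairs.items()):
            counts = group[0].counts
            specimens = group[0].specimens
            for net in group[1:]:
                counts = counts.add(net.counts, fill_value=0).fillna(0)
                specimens = specimens.add(net.specimens, fill_value=0)
            merged.append(
                InteractionMatrix(
                    plot_id,
                    group[0].plot_type,
                    counts.astype(int).sort_index(axis=0).sort_index(axis=1),
                    specimens.astype(int).sort_index(),
                    survey_block=pair_idx,
                )
            )
    return merged


def profiles_to_matrix(profiles: pd.DataFrame, species: str) -> pd.DataFrame:
    """Wide sample x plant proportion matrix for one species."""
    sub = profiles[profiles["bee_species"] == species]
    wide = sub.pivot_table(
        index="sample_id", columns="plant_species", values="proportion", fill_value=0.0
    )
    meta = sub.drop_duplicates("sample_id").set_index("sample_id")["plot_type"]
    wide.attrs["plot_type"] = meta.reindex(wide.index)
    return wide


def bray_curtis(p: np.ndarray, q: np.ndarray) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum p + sum q), in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("Bray-Curtis requires non-negative vectors")
    if p.sum() == 0 and q.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(p, q))


def dissimilarity_matrix(abundances: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis matrix over the rows of a sample x feature table."""
    X = abundances.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return pd.DataFrame(D, index=abundances.index, columns=abundances.index)


def permanova(
    D: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Partitions the total sum of squared dissimilarities (SS_T = sum of
    squared pairwise values / n) into among- and within-group parts and
    forms pseudo-F = (SS_A/(a-1)) / (SS_W/(n-a)); this is equivalent to the
    trace form on the Gower-centered matrix.  Group labels are permuted
    freely (no strata); the p-value counts permuted statistics at least as
    large as the observed one, p = (1 + #{F* >= F}) / (1 + n_permutations).
    """
    D = np.asarray(D, dtype=float)
    groups = np.asarray(groups)
    n = D.shape[0]
    if D.shape != (n, n) or len(groups) != n:
        raise ValueError("dissimilarity matrix and grouping sizes disagree")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity matrix is not symmetric")
    labels, inv = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2:
        raise DegenerateDesignError("need at least two groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        small = labels[sizes < 2].tolist()
        raise DegenerateDesignError(f"group(s) of size < 2: {small}")

    D2 = D**2
    ss_total = D2.sum() / (2 * n)

    def ss_within(label_rows: np.ndarray) -> np.ndarray:
        """SS_W for each row of label assignments (batched via einsum)."""
        ss_w = np.zeros(label_rows.shape[0])
        for g in range(a):
            member = (label_rows == g).astype(float)
            within = np.einsum("pi,ij,pj->p", member, D2, member)
            ss_w += within / (2 * sizes[g])
        return ss_w

    def pseudo_f(ss_w: np.ndarray) -> np.ndarray:
        return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    ss_w_obs = float(ss_within(inv[None, :])[0])
    ss_a = ss_total - ss_w_obs
    f_obs = float(pseudo_f(np.array([ss_w_obs]))[0])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=inv.dtype)
    for r in range(n_permutations):
        perms[r] = rng.permutation(inv)
    f_perm = pseudo_f(ss_within(perms))
    count = int(np.sum(f_perm >= f_obs))
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(ss_a / ss_total),
        p_value=float(p),
        n_permutations=n_permutations,
        n_samples=n,
        n_groups=a,
    )


def _stress1(D: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Disparities are the isotonic (primary/weak-tie) regression of the
    configuration distances on the rank order of the dissimilarities.
    """
    from scipy.spatial.distance import pdist
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices_from(D, k=1)
    diss = D[iu]
    dist = pdist(coords)
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    disp = np.empty_like(dist)
    disp[order] = iso.fit_transform(np.arange(len(order)), dist[order])
    denom = np.sum(dist**2)
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def nmds(
    D: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
) -> NmdsResult:
    """Nonmetric MDS of a dissimilarity matrix by isotonic stress majorization.

    Runs ``n_restarts`` random initializations of Kruskal-style nonmetric
    MDS, keeps the configuration with the lowest stress-1 (recomputed
    independently of the optimizer), and centers it at the origin.
    Non-convergence across all restarts is flagged, not raised.
    """
    labels = list(D.index) if isinstance(D, pd.DataFrame) else None
    Dm = np.asarray(D, dtype=float)
    n = Dm.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for a {k}-D ordination")
    best = None
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_restarts):
            rs = int(rng.integers(2**31 - 1))
            model = MDS(
                n_components=k,
                metric_mds=False,
                metric="precomputed",
                n_init=1,
                init="random",
                random_state=rs,
                max_iter=max_iter,
                eps=1e-9,
                normalized_stress=True,
            )
            coords = model.fit_transform(Dm)
            stress = _stress1(Dm, coords)
            converged = model.n_iter_ < max_iter
            if best is None or stress < best[0]:
                best = (stress, coords, converged)
    stress, coords, converged = best
    coords = coords - coords.mean(axis=0)
    frame = pd.DataFrame(
        coords,
        index=labels if labels is not None else range(n),
        columns=[f"nmds{i + 1}" for i in range(k)],
    )
    if not converged:
        logger.warning("NMDS did not converge within %d iterations", max_iter)
    return NmdsResult(coordinates=frame, stress=stress, converged=bool(converged))
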