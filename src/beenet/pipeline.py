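"""End-to-end pipeline: records in, networks / PAC / models / ordination out.

`run_pipeline` stitches the stages together with one configuration object,
writes every result table as CSV into an output directory, and records a
manifest (config, seed, package and library versions, output hashes) so a
rerun with the same inputs and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    abundance_change_table,
    fit_change_model,
    species_glm_table,
    CHANGE_MODELS,
)
from .network import build_block_networks, build_network, pool_or_split_networks
from .nicheshift import (
    diet_profiles,
    dissimilarity_matrix,
    nmds,
    permanova,
    profiles_to_matrix,
)
from .pac import HONEYBEE, adjust_matrix, honeybee_profile, pac_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Defaults reproduce the analysis choices documented in docs/methods.md."""

    pollen_path: str | Path = "pollen_records.csv"
    sweep_path: str | Path = "sweep_counts.csv"
    flower_path: str | Path | None = "flower_surveys.csv"
    out_dir: str | Path = "results"
    min_grains: int = 3
    honeybee_row_mode: str = "pooled"  # or "mean"
    pac_aggregation: str = "per_plot"  # or "pooled_by_type"
    replication_unit: str = "plot_survey"  # or "plot_total"
    diet_block_size: int = 2
    n_common_species: int = 6
    n_permutations: int = 999
    nmds_restarts: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("pollen_path", "sweep_path", "flower_path", "out_dir"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d


@dataclass
class PipelineResult:
    networks: list
    pac: pd.DataFrame
    abundance_change: pd.DataFrame
    species_glms: pd.DataFrame
    change_models: pd.DataFrame
    diet_permanova: pd.DataFrame
    flower_permanova: pd.DataFrame | None
    manifest: dict = field(repr=False, default=None)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_pac_change(
    pollen_records: pd.DataFrame,
    sweep_counts: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Networks -> PAC table -> abundance change, joined per species.

    The in-memory core of the pipeline (no files written): builds per-plot
    networks, computes PAC_C/PAC_D against the honeybee profile, and joins
    them with the sweep-derived relative abundance change.  Returns
    ``(joined, pac)`` where ``joined`` carries ``relative_change``,
    ``abundance_distant``, ``pac_c`` and ``pac_d`` — the table the Gaussian
    change models consume.
    """
    cfg = config or PipelineConfig()
    networks = [
        build_network(sub, min_grains=cfg.min_grains)
        for _, sub in pollen_records.groupby("plot_id", sort=True)
    ]
    nearby = [n for n in networks if n.plot_type == "nearby"]
    distant = [n for n in networks if n.plot_type == "distant"]
    if cfg.pac_aggregation == "pooled_by_type":
        nearby = pool_or_split_networks(nearby, "pooled_by_type")
        distant = pool_or_split_networks(distant, "pooled_by_type")
    hb = honeybee_profile(nearby, row_mode=cfg.honeybee_row_mode)
    pac = pac_table(
        [adjust_matrix(n, hb) for n in nearby],
        [adjust_matrix(n, hb) for n in distant],
        hb,
    )
    natives = sweep_counts[sweep_counts["bee_species"] != HONEYBEE]
    change = abundance_change_table(natives, unit=cfg.replication_unit)
    joined = change.join(pac[["pac_c", "pac_d"]], how="left").rename(
        columns={"mean_abundance_distant": "abundance_distant"}
    )
    return joined, pac


def run_pipeline(
    pollen_records: pd.DataFrame,
    sweep_counts: pd.DataFrame,
    flower_surveys: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory tables and write the results.

    Stages: per-plot network construction (>= min_grains rule), honeybee
    profile + abundance-adjusted PAC_C/PAC_D, per-species negative-binomial
    abundance GLMs, the four Gaussian relative-change models, the diet-shift
    PERMANOVA/NMDS for the most common species, and (when flower surveys are
    given) the flowering-community similarity PERMANOVA/NMDS.
    """
    cfg = config or PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in ("diet_permanova", "diet_nmds", "flower_permanova", "flower_nmds")
    }

    # --- networks -------------------------------------------------------
    try:
        networks = [
            build_network(sub, min_grains=cfg.min_grains)
            for _, sub in pollen_records.groupby("plot_id", sort=True)
        ]
    except Exception as err:
        raise RuntimeError(f"stage network_build failed: {err}") from err
    from .io import write_network

    for net in networks:
        write_network(net, out / f"network_{net.plot_id}.csv")

    # --- PAC ------------------------------------------------------------
    try:
        nearby = [n for n in networks if n.plot_type == "nearby"]
        distant = [n for n in networks if n.plot_type == "distant"]
        if cfg.pac_aggregation == "pooled_by_type":
            nearby = pool_or_split_networks(nearby, "pooled_by_type")
            distant = pool_or_split_networks(distant, "pooled_by_type")
        hb = honeybee_profile(nearby, row_mode=cfg.honeybee_row_mode)
        nearby_adj = [adjust_matrix(n, hb) for n in nearby]
        distant_adj = [adjust_matrix(n, hb) for n in distant]
        pac = pac_table(nearby_adj, distant_adj, hb)
    except Exception as err:
        raise RuntimeError(f"stage niche_overlap failed: {err}") from err
    pac.to_csv(out / "pac_table.csv")

    # --- abundance models ----------------------------------------------
    try:
        natives = sweep_counts[sweep_counts["bee_species"] != HONEYBEE]
        change = abundance_change_table(natives, unit=cfg.replication_unit)
        glms = species_glm_table(natives, unit=cfg.replication_unit)
        joined = change.join(pac[["pac_c", "pac_d"]], how="left").rename(
            columns={"mean_abundance_distant": "abundance_distant"}
        )
        joined.to_csv(out / "pac_change_joined.csv")
        model_rows = []
        for name in CHANGE_MODELS:
            try:
                fit = fit_change_model(joined, predictors=name)
            except Exception as err:  # e.g. too few complete cases
                logger.warning("change model %s skipped: %s", name, err)
                continue
            for term in fit.params.index:
                model_rows.append(
                    {
                        "model": name,
                        "term": term,
                        "estimate": fit.params[term],
                        "se": fit.bse[term],
                        "p": fit.pvalues[term],
                        "df_resid": fit.df_resid,
                        "n": fit.nobs,
                        "adj_r_squared": fit.adj_rsquared,
                    }
                )
        change_models = pd.DataFrame(model_rows)
    except Exception as err:
        raise RuntimeError(f"stage abundance_models failed: {err}") from err
    change.to_csv(out / "abundance_change.csv")
    glms.to_csv(out / "species_glms.csv")
    change_models.to_csv(out / "change_models.csv", index=False)

    # --- diet-niche shift ----------------------------------------------
    try:
        common = (
            natives.groupby("bee_species")["count"].sum().nlargest(
                cfg.n_common_species
            ).index
        )
        block_nets = []
        for _, sub in pollen_records.groupby("plot_id", sort=True):
            block_nets.extend(
                build_block_networks(
                    sub, min_grains=cfg.min_grains, block_size=cfg.diet_block_size
                )
            )
        available = {sp for net in block_nets for sp in net.bee_species}
        profiles = diet_profiles(
            block_nets, set(common) & available, combine_adjacent=True
        )
        diet_rows = []
        for sp in sorted(set(common) & available):
            wide = profiles_to_matrix(profiles, sp)
            groups = wide.attrs["plot_type"]
            if groups.nunique() < 2 or groups.value_counts().min() < 2:
                logger.info("species %s lacks samples in both plot types", sp)
                continue
            D = dissimilarity_matrix(wide)
            res = permanova(
                D, groups.to_numpy(), cfg.n_permutations,
                seed=stage_seeds["diet_permanova"],
            )
            ord_ = (
                nmds(D, n_restarts=cfg.nmds_restarts, seed=stage_seeds["diet_nmds"])
                if len(wide) >= 3
                else None
            )
            diet_rows.append(
                {
                    "bee_species": sp,
                    "pseudo_f": res.pseudo_f,
                    "r_squared": res.r_squared,
                    "p": res.p_value,
                    "n_samples": res.n_samples,
                    "stress": ord_.stress if ord_ else np.nan,
                }
            )
        diet_permanova = pd.DataFrame(diet_rows)
    except Exception as err:
        raise RuntimeError(f"stage niche_shift failed: {err}") from err
    diet_permanova.to_csv(out / "diet_permanova.csv", index=False)

    # --- flowering-community similarity ---------------------------------
    flower_permanova = None
    if flower_surveys is not None:
        try:
            wide = flower_surveys.pivot_table(
                index=["plot_id", "plot_type", "survey_round"],
                columns="plant_species",
                values="flower_count",
                aggfunc="sum",
                fill_value=0,
            )
            # Samples are plot x survey compositions; the test asks whether
            # the six communities (plots) differ, as in the field analysis.
            groups = wide.index.get_level_values("plot_id").to_numpy()
            D = dissimilarity_matrix(wide.reset_index(drop=True))
            res = permanova(
                D, groups, cfg.n_permutations, seed=stage_seeds["flower_permanova"]
            )
            ord_ = nmds(D, n_restarts=cfg.nmds_restarts, seed=stage_seeds["flower_nmds"])
            flower_permanova = pd.DataFrame(
                [
                    {
                        "pseudo_f": res.pseudo_f,
                        "r_squared": res.r_squared,
                        "p": res.p_value,
                        "n_samples": res.n_samples,
                        "stress": ord_.stress,
                    }
                ]
            )
            flower_permanova.to_csv(out / "flower_permanova.csv", index=False)
            coords = ord_.coordinates.copy()
            coords.insert(0, "plot_type", groups)
            coords.to_csv(out / "flower_nmds.csv", index_label="sample")
        except Exception as err:
            raise RuntimeError(f"stage niche_shift (flowers) failed: {err}") from err

    # --- manifest -------------------------------------------------------
    outputs = sorted(p for p in out.glob("*.csv"))
    manifest = {
        "beenet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": cfg.to_dict(),
        "stage_seeds": stage_seeds,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        networks=networks,
        pac=pac,
        abundance_change=change,
        species_glms=glms,
        change_models=change_models,
        diet_permanova=diet_permanova,
        flower_permanova=flower_permanova,
        manifest=manifest,
    )
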