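"""Synthetic plant-bee communities with known ground truth.

The generator emulates a paired field design: three plots near apiaries
("nearby", honeybees present) and three far from them ("distant", honeybees
absent), a shared flowering community, sweep-net abundance surveys, and
individual pollen-load sampling.  Ground truth — each species' floral
preference vector, its Müller-index overlap with the honeybee, and its
expected abundances — is recorded so that every downstream estimate can be
checked against what generated the data.

Generative model
----------------
* Plant relative flower abundances ``w`` are drawn once from a Dirichlet and
  shared by all plots up to small lognormal plot noise, so flowering
  composition is similar everywhere.
* Each native bee draws a floral preference from Dirichlet(c_i * n_plants * w)
  with per-species concentration c_i spanning specialists (small c) to
  generalists (large c); the honeybee uses a large concentration and is broad.
* Distant-plot expected abundance per plot per sweep survey is lognormal.
  Nearby expectation declines multiplicatively with honeybee overlap and
  rarity: lambda_nearby = lambda_distant * exp(-beta * overlap - gamma /
  lambda_distant).
* Sweep counts are negative binomial (gamma-Poisson) around the expectations;
  honeybee counts are zero in distant plots.
* Pollen-load sampling captures individuals per species per plot at a rate
  proportional to local abundance, but — as in quota-based field collecting —
  tops captures up to a minimum of 15 individuals whenever the species is
  captured at all.  Each individual visits a Poisson number of plants drawn
  from its species' preference, and each visited plant leaves a
  zero-truncated negative-binomial grain count, so the >=3-grain detection
  rule removes a known fraction of true visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .pac import HONEYBEE


class DegenerateConfigError(ValueError):
    """The configuration cannot produce any captures."""


@dataclass
class SimulationConfig:
    """Knobs of the community generator; defaults emulate the field design."""

    n_plants: int = 53
    n_native_bees: int = 15
    n_plots_per_type: int = 3
    n_pollen_surveys: int = 10
    n_sweep_surveys: int = 5
    #: Per-bee Dirichlet concentrations (None: geometric ramp 0.02..5.0,
    #: specialists to generalists).
    preference_concentration: np.ndarray | None = None
    honeybee_generalism: float = 1.0
    #: Overlap -> decline slope (beta) and rarity penalty (gamma) in
    #: lambda_nearby = lambda_distant * exp(-beta*overlap - gamma/lambda).
    decline_slope: float = 2.0
    rarity_penalty: float = 30.0
    decline_mode: str = "multiplicative"  # or "additive"
    #: Lognormal parameters of distant-plot expected counts per plot per
    #: sweep survey.
    abundance_mean_log: float = 2.2
    abundance_sd_log: float = 0.7
    honeybee_abundance: float = 25.0
    nb_dispersion: float = 0.08  # NB2 alpha: var = mu + alpha*mu^2
    #: Pollen-load capture rate per plot (Poisson mean = effort * lambda);
    #: captures are topped up to min_specimens when nonzero, capped above.
    pollen_effort: float = 3.0
    min_specimens: int = 15
    max_specimens: int = 25
    visits_mean: float = 3.0  # plants visited per individual (>=1)
    grain_mean: float = 8.0  # zero-truncated NB grain count per visit
    grain_shape: float = 2.0
    flower_total: float = 1500.0  # expected flowers per plot per survey
    flower_alpha: float = 0.8
    flower_plot_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in ("preference_concentration", "decline_mode", "seed"):
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        for name in ("n_plants", "n_native_bees", "n_plots_per_type",
                     "n_pollen_surveys", "n_sweep_surveys"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.decline_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown decline_mode {self.decline_mode!r}")
        if self.preference_concentration is None:
            self.preference_concentration = np.geomspace(
                0.02, 5.0, self.n_native_bees
            )
        self.preference_concentration = np.asarray(
            self.preference_concentration, dtype=float
        )
        if len(self.preference_concentration) != self.n_native_bees:
            raise ValueError("need one preference concentration per native bee")


@dataclass
class SimulatedCommunity:
    """Generator output: the three input tables plus ground truth."""

    pollen_records: pd.DataFrame
    sweep_counts: pd.DataFrame
    flower_surveys: pd.DataFrame
    truth: pd.DataFrame  # per native species: overlap, expectations, lost flag
    preferences: pd.DataFrame  # species x plants, rows sum to 1
    config: SimulationConfig = field(repr=False, default=None)


def truth_overlap(preferences_i: np.ndarray, preferences_honeybee: np.ndarray) -> float:
    """Pairwise Müller index of two exact preference vectors (focal = i).

    On a two-row matrix of probability vectors the index reduces to
    sum_k p_k * h_k / (p_k + h_k); identical vectors give 0.5, disjoint 0.
    """
    p = np.asarray(preferences_i, dtype=float)
    h = np.asarray(preferences_honeybee, dtype=float)
    if p.sum() <= 0 or h.sum() <= 0:
        raise ValueError("preference vectors must have positive mass")
    p = p / p.sum()
    h = h / h.sum()
    keep = (p > 0) | (h > 0)
    p, h = p[keep], h[keep]
    with np.errstate(invalid="ignore"):
        terms = np.where(p + h > 0, p * h / (p + h), 0.0)
    return float(terms.sum())


def _neg_binomial(rng: np.random.Generator, mean, alpha: float, size=None):
    """NB2 counts via gamma-Poisson mixing; Poisson when alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(mean, size=size)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean, size=size)
    return rng.poisson(lam)

def _zt_neg_binomial(rng: np.random.Generator, mean: float, shape: float, n: int):
    """Zero-truncated NB draws (resample zeros; falls back to 1 if needed)."""
    out = np.zeros(n, dtype=int)
    todo = np.arange(n)
    p = shape / (shape + mean)
    for _ in range(50):
        if len(todo) == 0:
            break
        draw = rng.negative_binomial(shape, p, size=len(todo))
        out[todo] = draw
        todo = todo[draw == 0]
    out[out == 0] = 1
    return out


def simulate_community(config: SimulationConfig) -> SimulatedCommunity:
    """Draw one community and its survey data; seeded and reproducible."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    plants = [f"Plant_{i + 1:02d}" for i in range(cfg.n_plants)]
    natives = [f"Native_{i + 1:02d}" for i in range(cfg.n_native_bees)]
    bees = natives + [HONEYBEE]
    plots = [
        (f"{ptype}_{i + 1}", ptype)
        for ptype in ("nearby", "distant")
        for i in range(cfg.n_plots_per_type)
    ]

    # (i) Shared flowering community.
    w = rng.dirichlet(np.full(cfg.n_plants, cfg.flower_alpha))
    w = np.maximum(w, 1e-9)
    w = w / w.sum()

    # (ii) Floral preferences: natives on a specialist..generalist ramp,
    # honeybee broad.
    prefs = np.empty((cfg.n_native_bees + 1, cfg.n_plants))
    for i, conc in enumerate(cfg.preference_concentration):
        prefs[i] = rng.dirichlet(conc * cfg.n_plants * w + 1e-6)
    prefs[-1] = rng.dirichlet(cfg.honeybee_generalism * cfg.n_plants * w + 1e-6)
    preferences = pd.DataFrame(prefs, index=bees, columns=plants)

    overlap = np.array(
        [truth_overlap(prefs[i], prefs[-1]) for i in range(cfg.n_native_bees)]
    )

    # (iii) Expected abundances per plot per sweep survey.
    lam_distant = rng.lognormal(
        cfg.abundance_mean_log, cfg.abundance_sd_log, cfg.n_native_bees
    )
    if cfg.decline_mode == "multiplicative":
        lam_nearby = lam_distant * np.exp(
            -cfg.decline_slope * overlap - cfg.rarity_penalty / lam_distant
        )
    else:
        lam_nearby = np.maximum(
            lam_distant
            - cfg.decline_slope * overlap
            - cfg.rarity_penalty / lam_distant,
            0.0,
        )
    lam_by_type = {"distant": lam_distant, "nearby": lam_nearby}

    if cfg.pollen_effort * max(lam_distant.max(), cfg.honeybee_abundance) < 1e-8:
        raise DegenerateConfigError("expected zero captures for every species")

    # (iv) Sweep-net counts (explicit zeros kept: the survey grid is part of
    # the data).
    sweep_rows = []
    for plot_id, ptype in plots:
        lam = lam_by_type[ptype]
        for survey in range(1, cfg.n_sweep_surveys + 1):
            counts = _neg_binomial(rng, lam, cfg.nb_dispersion)
            for sp, c in zip(natives, counts):
                sweep_rows.append((plot_id, ptype, survey, sp, int(c)))
            hb = (
                int(_neg_binomial(rng, cfg.honeybee_abundance, cfg.nb_dispersion))
                if ptype == "nearby"
                else 0
            )
            sweep_rows.append((plot_id, ptype, survey, HONEYBEE, hb))
    sweep_counts = pd.DataFrame(
        sweep_rows,
        columns=["plot_id", "plot_type", "survey_round", "bee_species", "count"],
    )

    # (v) Pollen-load individuals and their grain counts.
    pollen_rows = []
    nearby_pollen_captured = {sp: 0 for sp in natives}
    for plot_id, ptype in plots:
        lam = lam_by_type[ptype]
        for b_idx, sp in enumerate(bees):
            if sp == HONEYBEE:
                if ptype == "distant":
                    continue
                rate = cfg.pollen_effort * cfg.honeybee_abundance
            else:
                rate = cfg.pollen_effort * lam[b_idx]
            raw = int(rng.poisson(rate))
            if raw == 0:
                continue
            n_cap = int(np.clip(raw, cfg.min_specimens, cfg.max_specimens))
            if sp != HONEYBEE and ptype == "nearby":
                nearby_pollen_captured[sp] += n_cap
            n_visits = 1 + rng.poisson(max(cfg.visits_mean - 1.0, 0.0), size=n_cap)
            for ind in range(n_cap):
                individual_id = f"{plot_id}:{sp}:{ind + 1}"
                visited = np.unique(
                    rng.choice(cfg.n_plants, size=n_visits[ind], p=prefs[b_idx])
                )
                grains = _zt_neg_binomial(
                    rng, cfg.grain_mean, cfg.grain_shape, len(visited)
                )
                survey = int(rng.integers(1, cfg.n_pollen_surveys + 1))
                for k, g in zip(visited, grains):
                    pollen_rows.append(
                        (
                            individual_id,
                            sp,
                            plot_id,
                            ptype,
                            survey,
                            plants[k],
                            int(g),
                        )
                    )
    pollen_records = pd.DataFrame(
        pollen_rows,
        columns=[
            "individual_id",
            "bee_species",
            "plot_id",
            "plot_type",
            "survey_round",
            "plant_species",
            "grain_count",
        ],
    )

    # (vi) Flower-abundance surveys (five rounds, shared composition with
    # small per-plot noise).
    flower_rows = []
    for plot_id, ptype in plots:
        for survey in range(1, 6):
            # Survey-level noise only: composition is shared across plots, so
            # the six communities are exchangeable (no real plot differences).
            noise = rng.lognormal(0.0, cfg.flower_plot_noise_sd, cfg.n_plants)
            counts = rng.poisson(cfg.flower_total * w * noise)
            for k, c in zip(plants, counts):
                flower_rows.append((plot_id, ptype, survey, k, int(c)))
    flower_surveys = pd.DataFrame(
        flower_rows,
        columns=["plot_id", "plot_type", "survey_round", "plant_species",
                 "flower_count"],
    )

    # Ground truth, with the realized "lost" flag: a species is lost when the
    # nearby plots produced neither a sweep record nor a pollen capture.
    nearby_sweep = (
        sweep_counts[sweep_counts["plot_type"] == "nearby"]
        .groupby("bee_species")["count"]
        .sum()
    )
    lost = [
        nearby_sweep.get(sp, 0) == 0 and nearby_pollen_captured[sp] == 0
        for sp in natives
    ]
    truth = pd.DataFrame(
        {
            "bee_species": natives,
            "true_overlap": overlap,
            "expected_distant": lam_distant,
            "expected_nearby": lam_nearby,
            "lost": lost,
        }
    ).set_index("bee_species")

    return SimulatedCommunity(
        pollen_records=pollen_records,
        sweep_counts=sweep_counts,
        flower_surveys=flower_surveys,
        truth=truth,
        preferences=preferences,
        config=cfg,
    )
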