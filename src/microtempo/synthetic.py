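"""Synthetic longitudinal amplicon datasets with planted, recoverable structure.

The generator emulates a two-year, four-season *Populus* common-garden
design: 10 genotypes (8 *P. trichocarpa*, 2 *P. deltoides*), three
plant-associated habitats, two microbial domains, eight sample dates
(two years x four seasons, matched ~1 year apart), and 3-5 replicate
plants per genotype per date.  Leaf-endosphere samples are omitted in
winter (deciduous hosts).

Per-ASV latent log-abundance for sample ``s`` collected at date ``t``:

    eta_is = base_i
           + A_iy * cos(2*pi*(doy(t) - phase_i)/365.25)   [seasonal ASVs]
           + b_i * t_days                                 [drifting ASVs]
           + g_i(genotype(s))
           + eps_is

where ``A_iy`` is the seasonal amplitude of ASV i in year y: the common
``season_amplitude`` in the first year, modulated per ASV in later years
(``interaction_sd``) so that seasonal patterns depend on year — the
season-by-year interaction the emulated study design exhibits.

with ``eps`` drawn from a multivariate normal whose sparse precision
matrix encodes the planted co-occurrence edges.  Counts are multinomial
per sample with ``softmax(eta)`` composition and lognormal depth, so
sparsity arises from finite sequencing depth rather than an explicit
zero-inflation component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .io import CountTable, SEASONS

# The study's printed sample dates: winter/spring/summer/fall in each year.
DEFAULT_DATES: tuple[Date, ...] = (
    Date(2018, 2, 19),
    Date(2018, 6, 7),
    Date(2018, 8, 22),
    Date(2018, 10, 4),
    Date(2019, 2, 7),
    Date(2019, 5, 30),
    Date(2019, 8, 29),
    Date(2019, 10, 14),
)
DEFAULT_SEASONS: tuple[str, ...] = (
    "winter", "spring", "summer", "fall",
    "winter", "spring", "summer", "fall",
)

GUILDS = (
    "saprotroph",
    "plant_pathogen",
    "ectomycorrhizal",
    "arbuscular_mycorrhizal",
    "endophyte",
    "unclassified",
)

DEFAULT_GUILD_PROPORTIONS = {
    "saprotroph": 0.30,
    "plant_pathogen": 0.15,
    "ectomycorrhizal": 0.15,
    "arbuscular_mycorrhizal": 0.05,
    "endophyte": 0.15,
    "unclassified": 0.20,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; defaults mirror the field design.

    ``drift_rate`` is the per-day change in log-abundance of drifting ASVs
    (sign drawn at random per ASV); ``season_amplitude`` the log-scale
    amplitude of the annual cosine; ``genotype_sd`` is kept small because
    host effects in this system explain only a few percent of variation.
    """

    n_asvs: int = 200
    habitat: str = "rhizosphere"
    domain: str = "bacteria_archaea"
    n_genotypes: int = 10
    reps_min: int = 3
    reps_max: int = 5
    dates: tuple[Date, ...] = DEFAULT_DATES
    seasons: tuple[str, ...] = DEFAULT_SEASONS
    seasonal_frac: float = 0.30
    drift_frac: float = 0.30
    drift_rate: float = 0.003
    season_amplitude: float = 1.0
    interaction_sd: float = 0.8
    genotype_sd: float = 0.25
    noise_sd: float = 0.5
    base_sd: float = 2.5
    depth_log_mean: float = 8.5
    depth_log_sd: float = 0.3
    network_edges: tuple[tuple[int, int], ...] | None = None
    network_strength: float = 2.5
    seasonal_phase_choices: tuple[float, ...] | None = None
    asv_prefix: str = "ASV"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asvs <= 0:
            raise ValueError("n_asvs must be positive")
        if len(self.dates) == 0:
            raise ValueError("at least one sample date is required")
        if len(self.dates) != len(self.seasons):
            raise ValueError("dates and seasons must align")
        for frac in (self.seasonal_frac, self.drift_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for sd in (self.genotype_sd, self.noise_sd, self.depth_log_sd,
                   self.base_sd, self.interaction_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        if not set(self.seasons) <= set(SEASONS):
            raise ValueError(f"seasons must be drawn from {SEASONS}")
        if self.reps_min < 1 or self.reps_max < self.reps_min:
            raise ValueError("replicate range invalid")


@dataclass
class SynthTruth:
    """Planted ground truth recorded alongside a generated dataset."""

    asv: pd.DataFrame           # per-ASV flags, phases, rates, baselines
    latent: pd.DataFrame        # ASV x sample latent log-abundance eta
    edges: tuple[tuple[str, str], ...]  # planted precision-structure edges


def _genotype_names(n: int) -> list[str]:
    return [f"G{i + 1:02d}" for i in range(n)]


def _species_of(genotypes: list[str]) -> dict[str, str]:
    # 8 P. trichocarpa + 2 P. deltoides in the 10-genotype design; for other
    # sizes the last fifth (at least one) is P. deltoides.
    n = len(genotypes)
    n_deltoides = 2 if n == 10 else max(1, n // 5)
    return {
        g: ("P_deltoides" if i >= n - n_deltoides else "P_trichocarpa")
        for i, g in enumerate(genotypes)
    }


def _day_of_year(d: Date) -> int:
    return d.timetuple().tm_yday


def _noise_covariance(config: SynthConfig) -> np.ndarray:
    """Sparse-precision noise covariance with unit-free diagonal noise_sd^2."""
    p = config.n_asvs
    if not config.network_edges:
        return np.eye(p) * config.noise_sd**2
    omega = np.eye(p)
    deg = np.zeros(p)
    for i, j in config.network_edges:
        if not (0 <= i < p and 0 <= j < p) or i == j:
            raise ValueError(f"invalid planted edge ({i}, {j})")
        omega[i, j] = omega[j, i] = -config.network_strength
        deg[i] += 1
        deg[j] += 1
    # diagonal dominance keeps the precision matrix positive definite
    np.fill_diagonal(omega, 1.0 + config.network_strength * deg)
    sigma = np.linalg.inv(omega)
    scale = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(scale, scale) * config.noise_sd**2
    return sigma


def _draw_asv_params(rng: np.random.Generator, config: SynthConfig) -> dict:
    """Per-ASV planted parameters; one draw sequence shared by the
    generator and the noise-free oracles so both see the same truth."""
    p = config.n_asvs
    base = rng.normal(0.0, config.base_sd, size=p)
    is_seasonal = rng.random(p) < config.seasonal_frac
    if config.seasonal_phase_choices is not None:
        phase = rng.choice(np.asarray(config.seasonal_phase_choices, dtype=float), size=p)
    else:
        phase = rng.uniform(0.0, 365.25, size=p)
    phase = np.where(is_seasonal, phase, np.nan)
    is_drifting = rng.random(p) < config.drift_frac
    drift = np.where(
        is_drifting, rng.choice([-1.0, 1.0], size=p) * config.drift_rate, 0.0
    )
    years = sorted({d.year for d in config.dates})
    amp_factor = {years[0]: np.ones(p)} if years else {}
    for year in years[1:]:
        factor = 1.0 + rng.normal(0.0, config.interaction_sd, size=p)
        amp_factor[year] = np.where(is_seasonal, factor, 1.0)
    return {
        "base": base,
        "is_seasonal": is_seasonal,
        "phase": phase,
        "is_drifting": is_drifting,
        "drift": drift,
        "amp_factor": amp_factor,
    }


def generate_dataset(
    config: SynthConfig,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Generate a count table, metadata, taxonomy and recorded ground truth."""
    rng = np.random.default_rng(config.seed)
    p = config.n_asvs
    asv_ids = [f"{config.asv_prefix}{i + 1:04d}" for i in range(p)]

    params = _draw_asv_params(rng, config)
    base = params["base"]
    is_seasonal = params["is_seasonal"]
    phase = params["phase"]
    is_drifting = params["is_drifting"]
    drift = params["drift"]
    amp_factor = params["amp_factor"]

    genotypes = _genotype_names(config.n_genotypes)
    species = _species_of(genotypes)
    geno_effect = {g: rng.normal(0.0, config.genotype_sd, size=p) for g in genotypes}

    sigma = _noise_covariance(config)
    chol = np.linalg.cholesky(sigma) if config.noise_sd > 0 else None

    t0 = config.dates[0]
    rows_meta = []
    etas = []
    counts_cols = []
    sample_ids = []
    sample_counter = 0
    for d, season in zip(config.dates, config.seasons):
        if config.habitat == "leaf_endosphere" and season == "winter":
            continue
        t_days = (d - t0).days
        doy = _day_of_year(d)
        seasonal_term = np.where(
            is_seasonal,
            config.season_amplitude
            * amp_factor.get(d.year, np.ones(p))
            * np.cos(2.0 * np.pi * (doy - np.nan_to_num(phase)) / 365.25),
            0.0,
        )
        for g in genotypes:
            n_rep = int(rng.integers(config.reps_min, config.reps_max + 1))
            for rep in range(n_rep):
                sample_counter += 1
                sid = f"S{sample_counter:04d}"
                eps = (
                    chol @ rng.standard_normal(p)
                    if chol is not None
                    else np.zeros(p)
                )
                eta = base + seasonal_term + drift * t_days + geno_effect[g] + eps
                depth = max(
                    1,
                    int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sd))),
                )
                prob = np.exp(eta - eta.max())
                prob /= prob.sum()
                counts_cols.append(rng.multinomial(depth, prob))
                etas.append(eta)
                sample_ids.append(sid)
                rows_meta.append(
                    {
                        "sample_id": sid,
                        "habitat": config.habitat,
                        "domain": config.domain,
                        "season": season,
                        "year": d.year,
                        "date": pd.Timestamp(d),
                        "genotype": g,
                        "species": species[g],
                        "block": (rep % 3) + 1,
                    }
                )

    counts = pd.DataFrame(
        np.array(counts_cols).T, index=asv_ids, columns=sample_ids
    )
    # multinomial sampling can in principle leave a sample with zero reads
    # only at depth 0, which is excluded above, so column sums are positive
    metadata = pd.DataFrame(rows_meta).set_index("sample_id")
    taxonomy = _synthetic_taxonomy(asv_ids, config.domain)

    # planted-core flag: ASVs with high expected occupancy (large baseline)
    core_cut = np.quantile(base, 0.8)
    truth_asv = pd.DataFrame(
        {
            "asv_id": asv_ids,
            "is_seasonal": is_seasonal,
            "phase": phase,
            "is_drifting": is_drifting,
            "drift_rate": drift,
            "is_core_planted": base >= core_cut,
            "base": base,
        }
    ).set_index("asv_id")
    latent = pd.DataFrame(np.array(etas).T, index=asv_ids, columns=sample_ids)
    edges = tuple(
        (asv_ids[i], asv_ids[j]) for i, j in (config.network_edges or ())
    )
    truth = SynthTruth(asv=truth_asv, latent=latent, edges=edges)
    table = CountTable(counts, habitat=config.habitat, domain=config.domain)
    return table, metadata, taxonomy, truth


def _synthetic_taxonomy(asv_ids: list[str], domain: str) -> pd.DataFrame:
    kingdom = "Fungi" if domain == "fungi" else "Bacteria"
    rows = []
    for i, asv in enumerate(asv_ids):
        rows.append(
            {
                "asv_id": asv,
                "kingdom": kingdom,
                "phylum": f"Phylum{i % 6 + 1}",
                "class": f"Class{i % 12 + 1}",
                "order": f"Order{i % 20 + 1}",
                "family": f"Family{i // 6 + 1}",
                "genus": f"Genus{i // 3 + 1}",
            }
        )
    return pd.DataFrame(rows).set_index("asv_id")


def expected_decay_slope(
    config: SynthConfig,
    n_mc: int = 400,
    mc_seed: int = 987_654_321,
    depth: int | None = None,
) -> float:
    """Planted dissimilarity-time slope implied by the generative model.

    The estimand of the downstream decay regression is the slope of
    E[Bray-Curtis between two same-genotype samples] against elapsed time
    under the full generative process — replicate noise and finite
    sequencing depth compress the latent signal nonlinearly, so the
    noise-free latent slope is NOT the regression's target.  This routine
    computes that expectation directly by Monte-Carlo enumeration: for
    every date pair it draws ``n_mc`` independent within-genotype sample
    pairs from the model (shared genotype effect, independent residual
    noise and multinomial counts) and regresses the mean dissimilarity on
    elapsed time (per 365 days).

    The per-ASV planted parameters are reproduced from ``config.seed``;
    ``mc_seed`` only controls the Monte-Carlo precision.  Dissimilarity is
    taken between per-sample proportion vectors at each sample's realized
    (lognormal) depth: SRS rescales counts to a common depth while keeping
    proportions essentially unchanged, so this matches the quantity the
    analysis computes.  Passing ``depth`` fixes every sample's depth
    instead of drawing it.
    """
    rng_params = np.random.default_rng(config.seed)
    params = _draw_asv_params(rng_params, config)
    base, drift, phase = params["base"], params["drift"], params["phase"]
    is_seasonal, amp_factor = params["is_seasonal"], params["amp_factor"]
    p = config.n_asvs
    # replay the dataset's realized genotype effects (same draw order as
    # generate_dataset) so the truth is conditional on them, matching the
    # genotype-mean structure of the decay regression
    geno_effects = [
        rng_params.normal(0.0, config.genotype_sd, size=p)
        for _ in _genotype_names(config.n_genotypes)
    ]

    sigma = _noise_covariance(config)
    chol = np.linalg.cholesky(sigma) if config.noise_sd > 0 else None
    fixed_depth = depth

    t0 = config.dates[0]
    etas = {}
    for d, season in zip(config.dates, config.seasons):
        if config.habitat == "leaf_endosphere" and season == "winter":
            continue
        doy = _day_of_year(d)
        seasonal_term = np.where(
            is_seasonal,
            config.season_amplitude
            * amp_factor.get(d.year, np.ones(p))
            * np.cos(2.0 * np.pi * (doy - np.nan_to_num(phase)) / 365.25),
            0.0,
        )
        etas[d] = base + seasonal_term + drift * (d - t0).days

    rng = np.random.default_rng(mc_seed)

    def draw(eta, g):
        eps = chol @ rng.standard_normal(p) if chol is not None else 0.0
        full = eta + g + eps
        prob = np.exp(full - full.max())
        depth = fixed_depth or max(
            1, int(round(rng.lognormal(config.depth_log_mean, config.depth_log_sd)))
        )
        counts = rng.multinomial(depth, prob / prob.sum()).astype(float)
        return counts / counts.sum()

    per_geno = max(1, n_mc // len(geno_effects))
    dts, bcs = [], []
    for d1, d2 in itertools.combinations(sorted(etas), 2):
        acc = 0.0
        for g in geno_effects:
            for _ in range(per_geno):
                x, y = draw(etas[d1], g), draw(etas[d2], g)
                acc += np.abs(x - y).sum() / (x + y).sum()
        bcs.append(acc / (per_geno * len(geno_effects)))
        dts.append(abs((d2 - d1).days) / 365.0)
    slope = np.polyfit(np.asarray(dts), np.asarray(bcs), 1)[0]
    return float(slope)


@dataclass
class ClimateConfig:
    """Annual-sinusoid parameters per climate variable (mean, amplitude, peak doy)."""

    tmax: tuple[float, float, float] = (22.0, 12.0, 200.0)
    tmin_offset: float = 8.0
    day_length: tuple[float, float, float] = (43200.0, 10800.0, 172.0)
    srad: tuple[float, float, float] = (250.0, 150.0, 172.0)
    precip: tuple[float, float, float] = (3.0, 1.5, 100.0)
    vapor_pressure: tuple[float, float, float] = (1500.0, 900.0, 200.0)
    noise_frac: float = 0.05
    pad_days: int = 14


def generate_climate(
    dates,
    seed: int = 0,
    config: ClimateConfig | None = None,
) -> pd.DataFrame:
    """Daily climate with consistent annual cycles covering the sample window.

    Each variable is an annual sinusoid (period 365.25 d) plus small daily
    noise, so identical calendar dates in consecutive years differ only by
    noise — mirroring a site whose climate is strongly correlated between
    years.  ``tmin`` is ``tmax`` minus a positive diurnal offset.
    """
    if len(dates) == 0:
        raise ValueError("at least one date is required")
    cfg = config or ClimateConfig()
    rng = np.random.default_rng(seed)
    dates = [pd.Timestamp(d) for d in dates]
    start = min(dates) - pd.Timedelta(days=cfg.pad_days)
    end = max(dates) + pd.Timedelta(days=cfg.pad_days)
    days = pd.date_range(start, end, freq="D")
    t = np.array([(d - pd.Timestamp(year=2018, month=1, day=1)).days for d in days])

    def sinusoid(mean, amp, peak_doy):
        vals = mean + amp * np.cos(2 * np.pi * (t - (peak_doy - 1)) / 365.25)
        return vals + rng.normal(0.0, cfg.noise_frac * amp, size=len(t))

    tmax = sinusoid(*cfg.tmax)
    offset = np.abs(
        cfg.tmin_offset
        + rng.normal(0.0, cfg.noise_frac * cfg.tmin_offset, size=len(t))
    )
    tmin = tmax - np.maximum(offset, 1e-6)
    climate = pd.DataFrame(
        {
            "date": days,
            "tmin": tmin,
            "tmax": tmax,
            "day_length": np.clip(sinusoid(*cfg.day_length), 0, None),
            "srad": np.clip(sinusoid(*cfg.srad), 0, None),
            "precip": np.clip(sinusoid(*cfg.precip), 0, None),
            "vapor_pressure": np.clip(sinusoid(*cfg.vapor_pressure), 0, None),
        }
    )
    return climate


def generate_guild_table(
    taxonomy: pd.DataFrame,
    seed: int = 0,
    proportions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Assign each genus in a fungal taxonomy one functional guild.

    Stands in for a curated guild database lookup; proportions control the
    guild mix (defaults loosely follow temperate forest soil surveys).
    """
    props = dict(DEFAULT_GUILD_PROPORTIONS if proportions is None else proportions)
    guilds = list(props)
    weights = np.array([props[g] for g in guilds], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("guild proportions must sum to a positive value")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    genera = sorted(set(taxonomy["genus"].dropna()) - {"unclassified", ""})
    assigned = rng.choice(guilds, size=len(genera), p=weights)
    return pd.DataFrame(
        {"taxon": genera, "rank": "genus", "guild": assigned}
    ).set_index("taxon")
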