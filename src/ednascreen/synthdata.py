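"""Synthetic rice-paddy monitoring experiments with known causal truth.

Emulates the statistical structure of a season-long, multi-plot eDNA
monitoring campaign: many taxa with nonlinear coupled dynamics (discrete
logistic-type maps, the conventional benchmark for attractor-reconstruction
causality methods), a seasonal air-temperature driver, a rice growth-rate
series causally driven by temperature and a known subset of taxa at known
lags, and read tables generated from latent copy numbers through per-sample
sequencing-depth factors plus spike-in standards. Because the generating
network is known, every downstream stage (calibration, transfer-entropy
screening) can be validated against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrueNetwork",
    "TrueTrajectories",
    "SpikeInDesign",
    "StudyDesign",
    "make_network",
    "simulate_temperature",
    "simulate_community",
    "simulate_rice_growth",
    "simulate_experiment",
    "generate_read_table",
    "generate_manifest",
    "generate_seedling_manifest",
]

logger = logging.getLogger(__name__)

START_DATE = "2017-05-23"  # first monitoring day of the emulated season


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class TrueNetwork:
    """Known generating network: who influences whom, and rice's drivers.

    ``interaction_matrix[i, j]`` is the effect of taxon j on taxon i in the
    coupled map; ``growth_drivers`` lists ``(taxon index, lag days, effect
    coefficient)`` acting on rice growth; ``climate_driver`` is ``(lag,
    coefficient)`` for temperature. A taxon is a true cause of rice growth
    iff its effect coefficient is nonzero.
    """

    n_taxa: int
    interaction_matrix: np.ndarray
    growth_drivers: list[tuple[int, int, float]] = field(default_factory=list)
    climate_driver: tuple[int, float] = (0, 0.0)
    intrinsic_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=float)
        if self.interaction_matrix.shape != (self.n_taxa, self.n_taxa):
            raise ValueError("interaction_matrix must be n_taxa x n_taxa")
        if self.intrinsic_rates is None:
            self.intrinsic_rates = np.full(self.n_taxa, 3.8)
        self.intrinsic_rates = np.asarray(self.intrinsic_rates, dtype=float)
        if self.intrinsic_rates.shape != (self.n_taxa,):
            raise ValueError("intrinsic_rates must have length n_taxa")
        for taxon, lag, _ in self.growth_drivers:
            if not (0 <= taxon < self.n_taxa):
                raise ValueError(f"growth driver taxon {taxon} out of range")
            if lag < 0 or int(lag) != lag:
                raise ValueError("driver lags must be non-negative integers")
        if self.climate_driver[0] < 0:
            raise ValueError("climate lag must be non-negative")

    @property
    def true_causes(self) -> list[int]:
        """Indices of taxa with a nonzero effect on rice growth."""
        return sorted({t for t, _, c in self.growth_drivers if c != 0})


@dataclass
class TrueTrajectories:
    """Latent multi-plot daily truth.

    ``states`` are the dimensionless map states in [0, 1]; ``abundances``
    are the same scaled to copies/ml water. Arrays are (n_plots, n_days[,
    n_taxa]); dates are consecutive calendar days from ``start``.
    """

    plots: list[str]
    dates: pd.DatetimeIndex
    states: np.ndarray       # (n_plots, n_days, n_taxa)
    abundances: np.ndarray   # copies/ml water
    temperature: np.ndarray  # (n_plots, n_days), deg C
    growth_rate: np.ndarray | None = None  # (n_plots, n_days), cm/day

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def n_taxa(self) -> int:
        return self.states.shape[2]


@dataclass
class SpikeInDesign:
    """Internal standard DNAs added to every library.

    Default five standards spanning roughly an order of magnitude in
    copies/ul, mirroring the gradient a quantitative metabarcoding run
    spikes in.
    """

    standard_ids: list[str] = field(default_factory=lambda: [f"STD{i+1}" for i in range(5)])
    copies_per_ul: np.ndarray = field(default_factory=lambda: np.array([5.0, 10.0, 25.0, 50.0, 100.0]))

    def __post_init__(self) -> None:
        self.copies_per_ul = np.asarray(self.copies_per_ul, dtype=float)
        if len(self.standard_ids) != len(self.copies_per_ul):
            raise ValueError("standard ids and copies differ in length")
        if len(self.copies_per_ul) < 2:
            raise ValueError("need at least 2 standards")
        if (self.copies_per_ul <= 0).any():
            raise ValueError("standard copies must be strictly positive")
        if len(np.unique(self.copies_per_ul)) != len(self.copies_per_ul):
            raise ValueError("standard copies must be distinct")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"standard_id": self.standard_ids,
                             "copies_per_ul": self.copies_per_ul})


@dataclass
class StudyDesign:
    """Water-sampling design: one sample per (day x plot x filter type)."""

    n_days: int = 122
    n_plots: int = 5
    filter_types: tuple[str, ...] = ("0.22um", "0.45um")
    n_field_negatives: int = 0
    n_pcr_negatives: int = 0
    n_positives: int = 0
    water_ml: float = 200.0
    elution_ul: float = 100.0
    start_date: str = START_DATE

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.n_plots < 1 or not self.filter_types:
            raise ValueError("design counts must be positive")
        if self.water_ml <= 0 or self.elution_ul <= 0:
            raise ValueError("volumes must be strictly positive")


# ---------------------------------------------------------------------------
# generators


def make_network(n_taxa: int = 20, n_causes: int = 3,
                 driver_lags: tuple[int, ...] = (1, 2, 3),
                 driver_effect: float = 0.8,
                 climate_lag: int = 2, climate_effect: float = 0.08,
                 coupling_density: float = 0.1, coupling_strength: float = 0.05,
                 seed: int | None = 0) -> TrueNetwork:
    """Random sparse community network with planted rice-growth drivers.

    The first ``n_causes`` taxa drive rice growth at ``driver_lags`` days
    with coefficient ``driver_effect`` (cm/day per unit map state);
    temperature drives growth at ``climate_lag`` days. Off-diagonal taxon
    couplings are drawn sparsely at ``coupling_strength``.
    """
    rng = np.random.default_rng(seed)
    if n_causes > n_taxa:
        raise ValueError("n_causes cannot exceed n_taxa")
    C = np.zeros((n_taxa, n_taxa))
    mask = rng.random((n_taxa, n_taxa)) < coupling_density
    np.fill_diagonal(mask, False)
    C[mask] = coupling_strength * rng.uniform(0.5, 1.5, mask.sum())
    rates = rng.uniform(3.4, 3.9, n_taxa)
    drivers = [(i, int(driver_lags[i % len(driver_lags)]), driver_effect)
               for i in range(n_causes)]
    return TrueNetwork(n_taxa=n_taxa, interaction_matrix=C,
                       growth_drivers=drivers,
                       climate_driver=(climate_lag, climate_effect),
                       intrinsic_rates=rates)


def simulate_temperature(n_days: int, seed: int | np.random.Generator | None = None,
                         mean: float = 25.0, amplitude: float = 6.0,
                         noise_sd: float = 1.5, ar: float = 0.7) -> np.ndarray:
    """Daily mean air temperature: centred seasonal half-sine + AR(1) noise.

    ``mean`` is the season-average temperature; the half-sine bump (rising
    to mid-season, falling toward harvest) is centred so the configured
    mean is also the expected series mean. Noise is a stationary AR(1)
    process with marginal standard deviation ``noise_sd``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, n_days) if n_days > 1 else np.array([0.5])
    seasonal = mean + amplitude * (np.sin(np.pi * u) - 2.0 / np.pi)
    if noise_sd == 0:
        return seasonal
    eps = rng.normal(0.0, noise_sd * np.sqrt(max(1 - ar ** 2, 1e-12)), n_days)
    noise = np.empty(n_days)
    noise[0] = rng.normal(0.0, noise_sd)
    for t in range(1, n_days):
        noise[t] = ar * noise[t - 1] + eps[t]
    return seasonal + noise


def simulate_community(network: TrueNetwork, n_days: int = 100, n_plots: int = 3,
                       seed: int | None = 0, noise_sd: float = 0.01,
                       copies_scale: float = 1e5,
                       temperature: np.ndarray | None = None) -> TrueTrajectories:
    """Iterate coupled logistic-type maps per plot.

    Update rule for taxon i:

        x_{t+1,i} = x_{t,i} * (r_i - r_i x_{t,i} - sum_j c_ij x_{t,j}) + eps

    with Gaussian process noise (sd ``noise_sd``) and states clipped to
    [0, 1]. Plots share the network and differ only in seed-derived initial
    conditions and noise realisations. Latent abundances are the states
    linearly scaled to [0, ``copies_scale``] copies/ml water.
    """
    if network.n_taxa < 1:
        raise ValueError("need at least one taxon")
    if n_days < 10:
        raise ValueError("n_days must be >= 10")
    ss = np.random.SeedSequence(seed)
    plot_seeds = ss.spawn(n_plots + 1)
    r = network.intrinsic_rates
    C = network.interaction_matrix
    states = np.empty((n_plots, n_days, network.n_taxa))
    clip_events = 0
    for p in range(n_plots):
        rng = np.random.default_rng(plot_seeds[p])
        x = rng.uniform(0.2, 0.8, network.n_taxa)
        for t in range(n_days):
            states[p, t] = x
            nxt = x * (r - r * x - C @ x)
            if noise_sd > 0:
                nxt = nxt + rng.normal(0.0, noise_sd, network.n_taxa)
            out = (nxt < 0) | (nxt > 1)
            clip_events += int(out.sum())
            x = np.clip(nxt, 0.0, 1.0)
    if clip_events > 0.5 * n_plots * n_days * network.n_taxa:
        logger.warning("community map clipped on %d state updates: parameters "
                       "may be diverging", clip_events)
    dates = pd.date_range(START_DATE, periods=n_days, freq="D")
    if temperature is None:
        temperature = np.stack([
            simulate_temperature(n_days, seed=np.random.default_rng(s))
            for s in plot_seeds[n_plots].spawn(n_plots)
        ])
    return TrueTrajectories(
        plots=[f"Plot{p+1}" for p in range(n_plots)],
        dates=dates,
        states=states,
        abundances=states * copies_scale,
        temperature=np.asarray(temperature, dtype=float),
    )


def _baseline_growth(n_days: int, peak: float = 1.2, peak_day: int = 40) -> np.ndarray:
    """Seasonal baseline growth curve (cm/day): fast vegetative growth
    peaking in early summer, declining to ~0 by heading."""
    t = np.arange(1, n_days + 1, dtype=float)
    return peak * (t / peak_day) * np.exp(1.0 - t / peak_day)


def simulate_rice_growth(trajectories: TrueTrajectories, network: TrueNetwork,
                         seed: int | None = 0, noise_sd: float = 0.1,
                         baseline_peak: float = 1.2, baseline_peak_day: int = 40) -> np.ndarray:
    """Daily rice growth rate per plot (cm/day).

    growth_t = baseline_t + climate_coef * (temp_{t-lag} - mean temp)
             + sum over drivers coef * state_{t-lag, taxon} + noise.

    For the first ``max(lag)`` days the lagged value is taken from day 1
    (burn-in). Modifies ``trajectories.growth_rate`` in place and returns it.
    """
    n_plots, n_days = trajectories.temperature.shape
    lags = [lag for _, lag, _ in network.growth_drivers] + [network.climate_driver[0]]
    if lags and max(lags) >= n_days:
        raise ValueError("driver lag exceeds series length")
    rng = np.random.default_rng(seed)
    base = _baseline_growth(n_days, baseline_peak, baseline_peak_day)
    growth = np.tile(base, (n_plots, 1))
    clag, ccoef = network.climate_driver
    for p in range(n_plots):
        temp = trajectories.temperature[p]
        if ccoef != 0:
            idx = np.maximum(np.arange(n_days) - clag, 0)
            growth[p] += ccoef * (temp[idx] - temp.mean())
        for taxon, lag, coef in network.growth_drivers:
            if coef == 0:
                continue
            idx = np.maximum(np.arange(n_days) - lag, 0)
            growth[p] += coef * trajectories.states[p, idx, taxon]
    if noise_sd > 0:
        growth = growth + rng.normal(0.0, noise_sd, growth.shape)
    trajectories.growth_rate = growth
    return growth


def simulate_experiment(network: TrueNetwork | None = None, n_days: int = 100,
                        n_plots: int = 3, seed: int | None = 0,
                        noise_sd: float = 0.01, growth_noise_sd: float = 0.1,
                        copies_scale: float = 1e5) -> tuple[TrueTrajectories, TrueNetwork]:
    """Convenience wrapper: temperature + community + rice growth."""
    ss = np.random.SeedSequence(seed)
    s_comm, s_growth, s_net = ss.spawn(3)
    if network is None:
        network = make_network(seed=np.random.default_rng(s_net))
    traj = simulate_community(network, n_days, n_plots,
                              seed=int(s_comm.generate_state(1)[0] % (2**31)),
                              noise_sd=noise_sd, copies_scale=copies_scale)
    simulate_rice_growth(traj, network, seed=np.random.default_rng(s_growth),
                         noise_sd=growth_noise_sd)
    return traj, network


# ---------------------------------------------------------------------------
# observation model: read tables and manifests


def generate_read_table(trajectories: TrueTrajectories,
                        design: SpikeInDesign | None = None,
                        depth_factor: float = 10.0,
                        noise_model: str = "poisson",
                        seed: int | None = 0,
                        depth_sd_log: float = 0.3,
                        water_ml: float = 200.0,
                        elution_ul: float = 100.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequence a synthetic experiment: latent copies -> read table.

    One library per (plot, date). The sample-specific slope (reads per
    copies/ul) is ``depth_factor`` times a lognormal factor (sd of log =
    ``depth_sd_log``) emulating library-size variation; spike-in standards
    receive reads from their known copies through the same slope, which is
    exactly the structure the calibration regression inverts.

    noise_model: "none" (exact proportional reads, float), "round"
    (rounded to integers), or "poisson" (reads ~ Poisson(slope * copies)).

    Returns (reads, manifest): reads indexed by sample_id with taxa then
    standard columns; manifest with one row per sample.
    """
    if depth_factor <= 0:
        raise ValueError("depth_factor must be > 0")
    if noise_model not in ("none", "round", "poisson"):
        raise ValueError(f"unknown noise_model: {noise_model!r}")
    design = design or SpikeInDesign()
    rng = np.random.default_rng(seed)
    taxa = [f"Taxa{i+1:03d}" for i in range(trajectories.n_taxa)]
    reads_rows, man_rows, ids = [], [], []
    for p, plot in enumerate(trajectories.plots):
        for d, date in enumerate(trajectories.dates):
            sid = f"{plot}_{date.date().isoformat()}"
            slope = depth_factor * (rng.lognormal(0.0, depth_sd_log) if depth_sd_log > 0 else 1.0)
            copies_ml = trajectories.abundances[p, d]
            copies_ul = copies_ml * water_ml / elution_ul
            lam = np.concatenate([slope * copies_ul, slope * design.copies_per_ul])
            if noise_model == "none":
                row = lam
            elif noise_model == "round":
                row = np.round(lam)
            else:
                row = rng.poisson(lam).astype(float)
            reads_rows.append(row)
            ids.append(sid)
            man_rows.append({"sample_id": sid, "plot": plot,
                             "date": date.date().isoformat(),
                             "filter_type": "0.22um", "sample_class": "sample",
                             "water_ml": water_ml, "elution_ul": elution_ul})
    reads = pd.DataFrame(reads_rows, index=pd.Index(ids, name="sample_id"),
                         columns=taxa + list(design.standard_ids))
    manifest = pd.DataFrame(man_rows)
    return reads, manifest


def generate_manifest(design: StudyDesign) -> pd.DataFrame:
    """Water-sampling manifest: one row per (day x plot x filter type),
    plus configured control rows.

    The season-long, five-plot, two-filter design yields 122 x 2 x 5 = 1220
    field samples.
    """
    dates = pd.date_range(design.start_date, periods=design.n_days, freq="D")
    rows = []
    for date in dates:
        for p in range(design.n_plots):
            for ft in design.filter_types:
                sid = f"Plot{p+1}_{date.date().isoformat()}_{ft}"
                rows.append({"sample_id": sid, "plot": f"Plot{p+1}",
                             "date": date.date().isoformat(), "filter_type": ft,
                             "sample_class": "sample",
                             "water_ml": design.water_ml,
                             "elution_ul": design.elution_ul})
    controls = [("field-negative", design.n_field_negatives),
                ("pcr-negative", design.n_pcr_negatives),
                ("positive", design.n_positives)]
    for cls, n in controls:
        for i in range(n):
            rows.append({"sample_id": f"{cls}-{i+1:02d}", "plot": "NA",
                         "date": dates[min(i, len(dates) - 1)].date().isoformat(),
                         "filter_type": design.filter_types[0],
                         "sample_class": cls,
                         "water_ml": design.water_ml,
                         "elution_ul": design.elution_ul})
    man = pd.DataFrame(rows)
    if man["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in manifest")
    return man


def generate_seedling_manifest(n_treatments: int = 3, n_replicates: int = 3,
                               n_pots: int = 3, n_seedlings_per_pot: int = 3) -> pd.DataFrame:
    """Manipulation-experiment seedling layout.

    Default 3 treatments x 3 replicate plots x 3 pots x 3 seedlings = 81
    seedlings in nine plots.
    """
    if min(n_treatments, n_replicates, n_pots, n_seedlings_per_pot) < 1:
        raise ValueError("design counts must be positive")
    rows = []
    treatments = [f"T{i+1}" for i in range(n_treatments)]
    plot_no = 0
    for tr in treatments:
        for rep in range(1, n_replicates + 1):
            plot_no += 1
            for pot in range(1, n_pots + 1):
                for s in range(1, n_seedlings_per_pot + 1):
                    rows.append({"seedling_id": f"{tr}_R{rep}_P{pot}_S{s}",
                                 "treatment": tr, "replicate": rep,
                                 "plot": f"Plot{plot_no}", "pot": pot, "seedling": s})
    return pd.DataFrame(rows)
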