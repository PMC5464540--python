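"""Truth-known synthetic incubation experiments and environmental tables.

The generator embodies the verbal population model behind dilution-style
virus production experiments: at sampling time a complex prokaryotic
community carries cohorts of cells in different stages of lytic infection.
Each cohort lyses after its latency period, spread uniformly over a short
window, releasing ``burst`` free viruses per cell; free viruses decay and
(in undiluted water) adsorb to uninfected hosts, starting new infections
after a delay.  Cohorts staggered in latency produce the characteristic
non-monotonic "sawtooth" viral abundance that motivates piece-wise rate
estimation.

Five treatments are emitted per experiment, mirroring the standard design:

* ``undiluted`` / ``undiluted+mitC`` — whole water, reinfection possible;
  mitomycin C induces an extra cohort of lysogens.
* ``dilution`` / ``dilution+mitC`` — prokaryotes returned at a recovery
  factor of in situ density, free viruses reduced to a small fraction,
  reinfection suppressed.
* ``decay`` — virus concentrate in cell- and particle-free water, governed
  by the intrinsic decay rate alone.

Observations carry multiplicative lognormal noise (mean 1) per replicate.
All randomness flows from ``SimConfig.seed``; identical configs give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .series import IncubationSeries, InvalidSeriesError
from .stats import EnvSample

__all__ = [
    "SimTaxonCohort",
    "SimConfig",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_decay_only",
    "simulate_env_table",
]

DEFAULT_SAMPLING = tuple(float(t) for t in range(0, 45, 5))


@dataclass(frozen=True)
class SimTaxonCohort:
    """A cohort of host cells in the same infection stage at t0.

    The cohort lyses uniformly over ``[latency, latency + lysis_spread]``
    hours, each cell releasing ``burst`` viruses.
    """

    n_infected: float  # cells mL^-1 at t0
    latency: float  # h
    lysis_spread: float  # h; 0 => instantaneous lysis at `latency`
    burst: float  # viruses per lysed cell

    def __post_init__(self) -> None:
        if min(self.n_infected, self.latency, self.lysis_spread, self.burst) < 0:
            raise InvalidSeriesError("cohort parameters must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic incubation experiment.

    Defaults emulate a brackish redoxcline sample: ~7e5 prokaryotes mL^-1,
    ~1.5e7 viruses mL^-1, two staggered infected cohorts with burst size 10
    (~8% of cells infected), slow prokaryotic growth, measurable
    in-incubation viral decay but no intrinsic decay, 132% prokaryote
    recovery and 30% virus carry-over in the dilution treatment, and 5%
    lognormal counting noise at 5 h sampling over 40 h in duplicate.
    """

    cohorts: tuple[SimTaxonCohort, ...] = (
        SimTaxonCohort(n_infected=3.5e4, latency=8.0, lysis_spread=4.0, burst=10.0),
        SimTaxonCohort(n_infected=2.6e4, latency=22.0, lysis_spread=5.0, burst=10.0),
    )
    p0_uninfected: float = 6.7e5  # uninfected cells mL^-1 in situ
    v0: float = 1.5e7  # free viruses mL^-1 in situ
    prok_growth_rate: float = 0.006  # h^-1
    viral_decay_rate: float = 0.004  # h^-1, whole-water incubations
    intrinsic_decay_rate: float = 0.0  # h^-1, ultra-filtered water
    adsorption_coefficient: float = 4e-10  # mL h^-1; 0 in dilution treatments
    reinfection_latency: float = 10.0  # h
    reinfection_spread: float = 5.0  # h
    reinfection_burst: float = 10.0
    dilution_virus_fraction: float = 0.30
    dilution_prok_recovery: float = 1.32
    mitc_extra_induction: float = 2.0e4  # lysogens induced, cells mL^-1
    mitc_latency: float = 10.0  # h
    mitc_spread: float = 10.0  # h
    decay_inoculum_factor: float = 2.0  # concentrate strength vs in situ
    noise_cv: float = 0.05
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING
    n_replicates: int = 2
    dt: float = 0.1  # h, Euler step
    seed: int = 0
    station: str = "sim"
    zone: str = "anoxic"

    def __post_init__(self) -> None:
        if not 0 <= self.dilution_virus_fraction <= 1:
            raise InvalidSeriesError("dilution_virus_fraction must be in [0, 1]")
        if not 0 <= self.dilution_prok_recovery <= 3:
            raise InvalidSeriesError("dilution_prok_recovery must be in [0, 3]")
        if self.noise_cv < 0 or self.dt <= 0 or self.n_replicates < 1:
            raise InvalidSeriesError("invalid noise_cv, dt or n_replicates")
        if min(
            self.p0_uninfected,
            self.v0,
            self.prok_growth_rate,
            self.viral_decay_rate,
            self.intrinsic_decay_rate,
            self.adsorption_coefficient,
            self.mitc_extra_induction,
        ) < 0:
            raise InvalidSeriesError("rates and abundances must be non-negative")
        if len(self.sampling_times) < 3:
            raise InvalidSeriesError("need at least 3 sampling times")
        object.__setattr__(self, "cohorts", tuple(self.cohorts))
        object.__setattr__(
            self, "sampling_times", tuple(float(t) for t in self.sampling_times)
        )


@dataclass(frozen=True)
class SimulatedExperiment:
    """Series for all treatments/replicates plus the ground-truth record."""

    series: tuple[IncubationSeries, ...]
    truth: dict
    config: SimConfig

    def get(self, treatment: str, population: str, replicate: int) -> IncubationSeries:
        for s in self.series:
            if (
                s.treatment == treatment
                and s.population == population
                and s.replicate == replicate
            ):
                return s
        raise KeyError((treatment, population, replicate))


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _integrate(
    cohorts: tuple[SimTaxonCohort, ...],
    p_uninfected: float,
    v0: float,
    growth: float,
    decay: float,
    adsorption: float,
    reinf_latency: float,
    reinf_spread: float,
    reinf_burst: float,
    horizon: float,
    dt: float,
) -> dict:
    """Euler bookkeeping of the cohort-lysis model on a fixed grid.

    Returns the dense trajectories of total prokaryotes (uninfected plus
    intact infected) and free viruses, and the conservation totals.
    """
    n_steps = int(round(horizon / dt)) + 1
    # lysis rate (cells mL^-1 h^-1) per step, built from rate-change deltas
    lysis_delta = np.zeros(n_steps + 1)
    burst_weighted_delta = np.zeros(n_steps + 1)

    def schedule(amount: float, start: float, spread: float, burst: float) -> None:
        if amount <= 0:
            return
        if spread <= dt:  # effectively instantaneous within one step
            i = min(int(round(start / dt)), n_steps - 1)
            lysis_delta[i] += amount / dt
            lysis_delta[i + 1] -= amount / dt
            burst_weighted_delta[i] += amount * burst / dt
            burst_weighted_delta[i + 1] -= amount * burst / dt
            return
        i0 = int(round(start / dt))
        i1 = int(round((start + spread) / dt))
        rate = amount / spread
        if i0 < n_steps:
            lysis_delta[i0] += rate
            burst_weighted_delta[i0] += rate * burst
            j = min(i1, n_steps)
            lysis_delta[j] -= rate
            burst_weighted_delta[j] -= rate * burst

    for c in cohorts:
        schedule(c.n_infected, c.latency, c.lysis_spread, c.burst)

    p_total = np.empty(n_steps)
    v_free = np.empty(n_steps)
    p_u = p_uninfected
    infected_pool = float(sum(c.n_infected for c in cohorts))
    v = v0
    lysis_rate = 0.0
    burst_rate = 0.0
    total_lysed = 0.0
    total_released = 0.0
    total_new_infections = 0.0

    for i in range(n_steps):
        lysis_rate += lysis_delta[i]
        burst_rate += burst_weighted_delta[i]
        p_total[i] = p_u + infected_pool
        v_free[i] = v

        if i == n_steps - 1:
            break
        t = i * dt
        if lysis_rate > 0:
            lysed = min(lysis_rate * dt, infected_pool)
            released = lysed * (burst_rate / lysis_rate)
        else:
            lysed = released = 0.0
        new_inf = adsorption * v * p_u * dt
        new_inf = min(new_inf, p_u)
        if new_inf > 0:
            schedule(new_inf, t + reinf_latency, reinf_spread, reinf_burst)
        p_u += growth * p_u * dt - new_inf
        infected_pool += new_inf - lysed
        v += released - decay * v * dt - new_inf  # one virion per infection
        v = max(v, 0.0)
        total_lysed += lysed
        total_released += released
        total_new_infections += new_inf

    return {
        "prok": p_total,
        "virus": v_free,
        "total_lysed": total_lysed,
        "total_released": total_released,
        "total_new_infections": total_new_infections,
    }


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate one full experiment: 5 treatments x replicates x 2 populations.

    The underlying dynamics are deterministic per treatment (duplicates share
    the same water); replicates differ only by observation noise.  The truth
    record stores, per treatment, the total lysed cells, viruses released,
    new infections, and the implied gross rates over the incubation.
    """
    horizon = config.sampling_times[-1] - config.sampling_times[0]
    n_steps_idx = [
        int(round((t - config.sampling_times[0]) / config.dt))
        for t in config.sampling_times
    ]
    rng = np.random.default_rng(config.seed)

    mitc_cohort = SimTaxonCohort(
        n_infected=config.mitc_extra_induction,
        latency=config.mitc_latency,
        lysis_spread=config.mitc_spread,
        burst=config.reinfection_burst,
    )
    rec = config.dilution_prok_recovery

    def scaled_cohorts(scale: float, with_mitc: bool) -> tuple[SimTaxonCohort, ...]:
        base = tuple(
            replace(c, n_infected=c.n_infected * scale) for c in config.cohorts
        )
        if with_mitc:
            base += (replace(mitc_cohort, n_infected=mitc_cohort.n_infected * scale),)
        return base

    setups = {
        "undiluted": dict(
            cohorts=scaled_cohorts(1.0, False),
            p_u=config.p0_uninfected,
            v0=config.v0,
            adsorption=config.adsorption_coefficient,
            decay=config.viral_decay_rate,
        ),
        "undiluted+mitC": dict(
            cohorts=scaled_cohorts(1.0, True),
            p_u=config.p0_uninfected,
            v0=config.v0,
            adsorption=config.adsorption_coefficient,
            decay=config.viral_decay_rate,
        ),
        "dilution": dict(
            cohorts=scaled_cohorts(rec, False),
            p_u=config.p0_uninfected * rec,
            v0=config.v0 * config.dilution_virus_fraction,
            adsorption=0.0,
            decay=config.viral_decay_rate,
        ),
        "dilution+mitC": dict(
            cohorts=scaled_cohorts(rec, True),
            p_u=config.p0_uninfected * rec,
            v0=config.v0 * config.dilution_virus_fraction,
            adsorption=0.0,
            decay=config.viral_decay_rate,
        ),
        "decay": dict(
            cohorts=(),
            p_u=0.0,
            v0=config.v0 * config.decay_inoculum_factor,
            adsorption=0.0,
            decay=config.intrinsic_decay_rate,
        ),
    }

    series: list[IncubationSeries] = []
    truth: dict = {
        "in_situ_prokaryotes": config.p0_uninfected
        + sum(c.n_infected for c in config.cohorts),
        "in_situ_viruses": config.v0,
        "treatments": {},
    }
    for treatment, kw in setups.items():
        traj = _integrate(
            cohorts=kw["cohorts"],
            p_uninfected=kw["p_u"],
            v0=kw["v0"],
            growth=config.prok_growth_rate if kw["p_u"] > 0 else 0.0,
            decay=kw["decay"],
            adsorption=kw["adsorption"],
            reinf_latency=config.reinfection_latency,
            reinf_spread=config.reinfection_spread,
            reinf_burst=config.reinfection_burst,
            horizon=horizon,
            dt=config.dt,
        )
        duration = horizon if horizon > 0 else 1.0
        truth["treatments"][treatment] = {
            "total_lysed": traj["total_lysed"],
            "total_released": traj["total_released"],
            "total_new_infections": traj["total_new_infections"],
            "true_vp": traj["total_released"] / duration,
            "true_mortality": traj["total_lysed"] / duration,
            "t0_prokaryotes": float(traj["prok"][0]),
            "t0_viruses": float(traj["virus"][0]),
            "decay_rate": kw["decay"],
        }
        prok_obs = traj["prok"][n_steps_idx]
        virus_obs = traj["virus"][n_steps_idx]
        for rep in range(1, config.n_replicates + 1):
            for population, values in (
                ("prokaryote", prok_obs),
                ("virus", virus_obs),
            ):
                if treatment == "decay" and population == "prokaryote":
                    continue  # cell-free incubation
                noisy = values * _mean_one_lognormal(
                    rng, config.noise_cv, len(values)
                )
                series.append(
                    IncubationSeries(
                        station=config.station,
                        zone=config.zone,
                        treatment=treatment,
                        replicate=rep,
                        population=population,
                        times=config.sampling_times,
                        abundances=tuple(noisy),
                    )
                )
    return SimulatedExperiment(series=tuple(series), truth=truth, config=config)


def simulate_decay_only(
    v0: float,
    decay_rate: float,
    noise_cv: float = 0.05,
    sampling_times=DEFAULT_SAMPLING,
    seed: int = 0,
    station: str = "sim",
    zone: str = "anoxic",
) -> IncubationSeries:
    """Exponentially decaying viral series with lognormal observation noise."""
    if v0 <= 0:
        raise InvalidSeriesError("v0 must be > 0")
    t = np.asarray(sampling_times, dtype=float)
    rng = np.random.default_rng(seed)
    values = v0 * np.exp(-decay_rate * (t - t[0]))
    values = values * _mean_one_lognormal(rng, noise_cv, len(t))
    return IncubationSeries(
        station=station,
        zone=zone,
        treatment="decay",
        replicate=1,
        population="virus",
        times=tuple(t),
        abundances=tuple(values),
    )


def simulate_env_table(
    n_samples: int, gradient_strength: float = 1.0, seed: int = 0, noise: float = 1.0
) -> list[EnvSample]:
    """Depth-ordered environmental samples with a redox-gradient structure.

    O2 decreases and H2S/NH4 increase with depth, scaled by
    ``gradient_strength`` (0 gives pure noise); values falling below the
    detection thresholds (O2 0.5 uM, H2S/NH4/NO2 0.1 uM) are censored to
    None, emulating "n.d." table entries.  ``noise`` scales all noise terms
    (0 gives a deterministic monotone gradient).
    """
    if n_samples < 3:
        raise InvalidSeriesError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    depths = np.linspace(70.0, 110.0, n_samples)
    x = (depths - depths[0]) / (depths[-1] - depths[0])  # 0..1
    g = gradient_strength

    def censor(v: float, threshold: float) -> float | None:
        return None if v < threshold else float(v)

    samples = []
    for i in range(n_samples):
        o2 = 40.0 * (1.0 - x[i]) * g + rng.normal(0, 2.0 * noise)
        h2s = 4.5 * x[i] * g + rng.normal(0, 0.3 * noise)
        nh4 = 4.0 * x[i] * g + rng.normal(0, 0.3 * noise)
        no2 = 0.3 + rng.normal(0, 0.15 * noise)
        prok = 7e5 * (1.0 + 0.5 * x[i] * g) * float(
            np.exp(rng.normal(0, 0.15 * noise))
        )
        virus = 1.5e7 * float(np.exp(rng.normal(0, 0.1 * noise)))
        samples.append(
            EnvSample(
                station="sim",
                zone="anoxic" if h2s > 0.1 else ("oxic" if o2 > 30 else "suboxic"),
                depth=float(depths[i]),
                temperature=4.8 + 0.7 * x[i] * g + float(rng.normal(0, 0.05 * noise)),
                salinity=9.3 + 1.0 * x[i] * g + float(rng.normal(0, 0.05 * noise)),
                turbidity=max(
                    0.05, 0.1 + 0.3 * x[i] * g + float(rng.normal(0, 0.05 * noise))
                ),
                PO4=float(max(2.0 + 1.5 * x[i] * g + rng.normal(0, 0.2 * noise), 0.1)),
                NO2=censor(no2, 0.1),
                NO3=censor(rng.normal(1.0, 1.0), 0.1),
                NH4=censor(nh4, 0.1),
                O2=censor(o2, 0.5),
                H2S=censor(h2s, 0.1),
                prok_abundance=prok,
                viral_abundance=virus,
            )
        )
    return samples
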