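"""Daisyworld agent-based model with a luminosity-sweep harness.

Lovelock's Gaia-hypothesis toy world: black daisies (albedo 0.25) warm
their patch, white daisies (albedo 0.75) cool it, bare ground sits at
albedo 0.4.  Local temperature follows the classic NetLogo formulation —
absorbed luminosity heats each patch as ``72*ln(absorbed) + 80`` blended
50/50 with the current temperature, then 50% of each patch's heat
diffuses equally to its 8 Moore neighbours on a toroidal grid.  Daisies
age and die at ``max_age`` ticks, and each survivor sprouts a
same-coloured daisy into a random empty neighbour with probability
``0.1457*T - 0.0032*T^2 - 0.6443`` (positive only for local temperatures
roughly within [5, 40] °C, which is what confines daisy viability to
that band).

Sweeping the solar luminosity and running many replicates per value
yields, at each luminosity, an ensemble of final temperature
distributions and species-count distributions.  The incoherence of those
ensembles spikes at the model's tipping points — luminosities where
replicates split between qualitatively different attractor states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .ensemble import Ensemble, Sample, analyse_ensemble

__all__ = [
    "EMPTY",
    "BLACK",
    "WHITE",
    "DaisyworldConfig",
    "WorldState",
    "RunResult",
    "SweepReport",
    "init_world",
    "step",
    "run",
    "luminosity_sweep",
    "detect_peaks",
]

EMPTY, BLACK, WHITE = 0, 1, 2


@dataclass(frozen=True)
class DaisyworldConfig:
    """Model constants; defaults follow the standard NetLogo model."""

    width: int = 29
    height: int = 29
    albedo_black: float = 0.25
    albedo_white: float = 0.75
    albedo_surface: float = 0.40
    luminosity: float = 1.0
    solar_constant: float = 1.0
    max_age: int = 25
    start_black: float = 0.30
    start_white: float = 0.30
    steps: int = 400
    seed: int | None = None
    #: kill daisies whose local temperature leaves [5, 40] °C outright,
    #: instead of relying on the sprouting parabola's support alone
    hard_kill: bool = False
    #: "interleaved" visits daisies in one random order, each ageing,
    #: dying or sprouting before the next is processed (NetLogo's agent
    #: scheduler); "phased" applies all deaths before any sprouting
    scheduler: str = "interleaved"
    #: bounded world by default: edge patches have truncated Moore
    #: neighbourhoods and keep the undistributed share of diffused heat;
    #: set True for a toroidal (wrap-around) grid
    wrap: bool = False

    def __post_init__(self) -> None:
        for a in (self.albedo_black, self.albedo_white, self.albedo_surface):
            if not 0.0 <= a <= 1.0:
                raise ValueError("albedos must lie in [0, 1]")
        if self.start_black + self.start_white > 1.0 + 1e-9:
            raise ValueError("start fractions exceed 1")
        if self.steps < 1 or self.max_age < 1:
            raise ValueError("steps and max_age must be positive")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n_patches(self) -> int:
        return self.width * self.height


@dataclass
class WorldState:
    """Flat per-patch arrays; index = row * width + column."""

    species: np.ndarray  # int8, EMPTY/BLACK/WHITE
    ages: np.ndarray  # int32, 0 for empty patches
    temperature: np.ndarray  # float64, °C
    tick: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "black": int((self.species == BLACK).sum()),
            "white": int((self.species == WHITE).sum()),
            "empty": int((self.species == EMPTY).sum()),
        }


@dataclass
class RunResult:
    """Final state diagnostics of one simulation run."""

    temperatures: np.ndarray
    counts: dict[str, int]
    count_series: list[dict[str, int]] | None = None


_SHIFTS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


@lru_cache(maxsize=8)
def _neighbour_table(width: int, height: int, wrap: bool) -> tuple[np.ndarray, np.ndarray]:
    """Moore neighbourhoods as a (patches, 8) index matrix plus a matching
    boolean validity mask (all-true when toroidal; truncated at the edges
    of a bounded world)."""
    idx = np.arange(width * height).reshape(height, width)
    cols = []
    valid = []
    for dr, dc in _SHIFTS:
        cols.append(np.roll(idx, (dr, dc), axis=(0, 1)).ravel())
        if wrap:
            valid.append(np.ones(width * height, dtype=bool))
        else:
            ok = np.ones((height, width), dtype=bool)
            if dr == 1:
                ok[0, :] = False
            elif dr == -1:
                ok[-1, :] = False
            if dc == 1:
                ok[:, 0] = False
            elif dc == -1:
                ok[:, -1] = False
            valid.append(ok.ravel())
    return np.stack(cols, axis=1), np.stack(valid, axis=1)


@lru_cache(maxsize=8)
def _neighbour_lists(width: int, height: int, wrap: bool) -> tuple[np.ndarray, ...]:
    """Per-patch arrays of valid Moore-neighbour indices (sprout targets)."""
    nbrs, valid = _neighbour_table(width, height, wrap)
    return tuple(nbrs[i][valid[i]] for i in range(nbrs.shape[0]))


def init_world(config: DaisyworldConfig, rng: np.random.Generator) -> WorldState:
    """Random dispersion of daisies by the start fractions; ages uniform
    below max_age; temperature 0 °C everywhere."""
    n = config.n_patches
    u = rng.random(n)
    species = np.full(n, EMPTY, dtype=np.int8)
    species[u < config.start_black] = BLACK
    species[(u >= config.start_black) & (u < config.start_black + config.start_white)] = WHITE
    ages = np.zeros(n, dtype=np.int32)
    living = species != EMPTY
    ages[living] = rng.integers(0, config.max_age, size=int(living.sum()))
    return WorldState(species, ages, np.zeros(n), tick=0)


def _albedo(species: np.ndarray, config: DaisyworldConfig) -> np.ndarray:
    alb = np.full(species.shape, config.albedo_surface)
    alb[species == BLACK] = config.albedo_black
    alb[species == WHITE] = config.albedo_white
    return alb


def step(state: WorldState, config: DaisyworldConfig, rng: np.random.Generator) -> WorldState:
    """Advance one tick in place: heat, diffuse, age/die, sprout."""
    species, ages, temp = state.species, state.ages, state.temperature
    nbrs, valid = _neighbour_table(config.width, config.height, config.wrap)
    nlists = _neighbour_lists(config.width, config.height, config.wrap)

    # solar heating
    absorbed = (1.0 - _albedo(species, config)) * config.luminosity * config.solar_constant
    heating = np.where(absorbed > 0, 72.0 * np.log(np.where(absorbed > 0, absorbed, 1.0)) + 80.0, 80.0)
    temp += heating
    temp *= 0.5

    # diffusion: each patch offers half its heat split 8 ways; shares
    # toward missing neighbours (bounded world edges) stay on the patch
    n_valid = valid.sum(axis=1)
    incoming = (temp[nbrs] * valid).sum(axis=1)
    state.temperature = temp - n_valid * temp / 16.0 + incoming / 16.0
    temp = state.temperature

    if config.hard_kill:
        doomed = (species != EMPTY) & ((temp < 5.0) | (temp > 40.0))
        species[doomed] = EMPTY
        ages[doomed] = 0

    if config.scheduler == "interleaved":
        # one shuffled pass over the daisies present at the start of the
        # phase; each agent ages, then dies or (with the temperature
        # parabola's probability) seeds an empty Moore neighbour before
        # the next agent acts, as NetLogo's scheduler does
        living = np.flatnonzero(species != EMPTY)
        rng.shuffle(living)
        thresholds = rng.random(living.size)
        picks = rng.random(living.size)
        newborn = np.zeros(species.size, dtype=bool)
        for u, pick, patch in zip(thresholds, picks, living):
            if species[patch] == EMPTY or newborn[patch]:
                # died earlier in this pass, possibly reseeded by a child
                continue
            ages[patch] += 1
            if ages[patch] >= config.max_age:
                species[patch] = EMPTY
                ages[patch] = 0
                continue
            t = temp[patch]
            p = 0.1457 * t - 0.0032 * t * t - 0.6443
            if u < p:
                cand = nlists[patch]
                empties = cand[species[cand] == EMPTY]
                if empties.size:
                    child = empties[int(pick * empties.size)]
                    species[child] = species[patch]
                    ages[child] = 0
                    newborn[child] = True
    elif config.scheduler == "phased":
        # ageing and death first, then all sprouting
        living = np.flatnonzero(species != EMPTY)
        ages[living] += 1
        dead = living[ages[living] >= config.max_age]
        species[dead] = EMPTY
        ages[dead] = 0
        alive = np.flatnonzero(species != EMPTY)
        if alive.size:
            t = temp[alive]
            p = np.clip(0.1457 * t - 0.0032 * t * t - 0.6443, 0.0, 1.0)
            sprouters = alive[rng.random(alive.size) < p]
            rng.shuffle(sprouters)
            picks = rng.random(sprouters.size)
            for u, parent in zip(picks, sprouters):
                cand = nlists[parent]
                empties = cand[species[cand] == EMPTY]
                if empties.size:
                    child = empties[int(u * empties.size)]
                    species[child] = species[parent]
                    ages[child] = 0
    else:
        raise ValueError(f"unknown scheduler {config.scheduler!r}")

    state.tick += 1
    return state


def run(
    config: DaisyworldConfig,
    rng: np.random.Generator | None = None,
    record_series: bool = False,
) -> RunResult:
    """Run from a fresh world for ``config.steps`` ticks."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = init_world(config, rng)
    series: list[dict[str, int]] | None = [] if record_series else None
    for _ in range(config.steps):
        step(state, config, rng)
        if series is not None:
            series.append(state.counts())
    return RunResult(state.temperature.copy(), state.counts(), series)


@dataclass
class SweepReport:
    """Per-luminosity ensemble diagnostics over replicate runs."""

    luminosities: list[float]
    replicates: int
    temp_incoherence: list[float]
    temp_cohesion: list[float]
    counts_incoherence: list[float]
    counts_cohesion: list[float]
    mean_of_means: list[float]
    pooled_mean: list[float]
    sd_of_means: list[float]
    sd_of_sds: list[float]
    species_means: list[dict[str, float]]
    results: list[list[RunResult]] | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "luminosities": self.luminosities,
            "replicates": self.replicates,
            "temp_incoherence": self.temp_incoherence,
            "temp_cohesion": self.temp_cohesion,
            "counts_incoherence": self.counts_incoherence,
            "counts_cohesion": self.counts_cohesion,
            "mean_of_means": self.mean_of_means,
            "pooled_mean": self.pooled_mean,
            "sd_of_means": self.sd_of_means,
            "sd_of_sds": self.sd_of_sds,
            "species_means": self.species_means,
            "config": self.config,
        }


def luminosity_sweep(
    base_config: DaisyworldConfig | None = None,
    l_min: float = 0.45,
    l_max: float = 1.45,
    l_step: float = 0.05,
    replicates: int = 30,
    seed: int | None = None,
    keep_results: bool = False,
    temperature_estimator: str = "density_variance",
    temperature_raw_k: float = 100.0,
) -> SweepReport:
    """Replicate ensembles across a luminosity grid.

    For each luminosity, ``replicates`` independently seeded runs are
    executed; incoherence and cohesion are computed for the ensemble of
    final per-patch temperature distributions (continuous; by default
    with the density-variance entropy at the canonical decay k=100 on
    range-scaled data, which is insensitive to the micro-scale
    temperature texture of near-identical replicates that histogram
    estimators resolve as spurious spread) and for the species-count
    distributions (categorical over black/white/empty).  Replicate seeds
    are spawned from the master seed, so the whole sweep reproduces end
    to end.
    """
    if base_config is None:
        base_config = DaisyworldConfig()
    if not l_min < l_max:
        raise ValueError("l_min must be below l_max")
    if replicates < 2:
        raise ValueError("need at least 2 replicates per luminosity")
    n_lum = int(round((l_max - l_min) / l_step)) + 1
    lums = [round(l_min + i * l_step, 10) for i in range(n_lum)]
    children = np.random.SeedSequence(seed).spawn(n_lum * replicates)

    report = SweepReport(
        luminosities=lums,
        replicates=replicates,
        temp_incoherence=[],
        temp_cohesion=[],
        counts_incoherence=[],
        counts_cohesion=[],
        mean_of_means=[],
        pooled_mean=[],
        sd_of_means=[],
        sd_of_sds=[],
        species_means=[],
        results=[] if keep_results else None,
        config={
            "steps": base_config.steps,
            "width": base_config.width,
            "height": base_config.height,
            "l_min": l_min,
            "l_max": l_max,
            "l_step": l_step,
            "replicates": replicates,
            "seed": seed,
        },
    )
    for li, lum in enumerate(lums):
        cfg = replace(base_config, luminosity=lum)
        runs = [
            run(cfg, rng=np.random.default_rng(children[li * replicates + r]))
            for r in range(replicates)
        ]
        temp_samples = tuple(
            Sample(id=f"r{r}", observations=tuple(res.temperatures))
            for r, res in enumerate(runs)
        )
        count_samples = tuple(
            Sample(id=f"r{r}", counts={k: float(v) for k, v in res.counts.items()})
            for r, res in enumerate(runs)
        )
        temp_rep = analyse_ensemble(
            Ensemble(temp_samples),
            estimator=temperature_estimator,
            raw_k=temperature_raw_k,
        )
        count_rep = analyse_ensemble(Ensemble(count_samples))

        means = np.array([res.temperatures.mean() for res in runs])
        sds = np.array([res.temperatures.std() for res in runs])
        pooled = np.concatenate([res.temperatures for res in runs])
        report.temp_incoherence.append(temp_rep.incoherence)
        report.temp_cohesion.append(temp_rep.cohesion)
        report.counts_incoherence.append(count_rep.incoherence)
        report.counts_cohesion.append(count_rep.cohesion)
        report.mean_of_means.append(float(means.mean()))
        report.pooled_mean.append(float(pooled.mean()))
        report.sd_of_means.append(float(means.std()))
        report.sd_of_sds.append(float(sds.std()))
        report.species_means.append(
            {
                k: float(np.mean([res.counts[k] for res in runs]))
                for k in ("black", "white", "empty")
            }
        )
        if report.results is not None:
            report.results.append(runs)
    return report


def detect_peaks(
    trace: list[float] | np.ndarray,
    luminosities: list[float] | None = None,
    robust: bool = False,
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive points exceeding a threshold over the
    trace.  Returns (start, end) bounds per region, in luminosity units if
    a grid is supplied, else index units.

    The default threshold is mean + 1 sd.  With ``robust=True`` it is
    median + 1 scaled MAD (median absolute deviation times 1.4826, the
    normal-consistent scale): a single dominant peak inflates the mean
    and sd enough to mask every secondary peak, whereas the robust
    location and scale are insensitive to the peaks being detected.
    """
    t = np.asarray(trace, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 trace points")
    x = np.asarray(luminosities, dtype=float) if luminosities is not None else np.arange(t.size, dtype=float)
    if x.size != t.size:
        raise ValueError("trace and luminosity grid lengths differ")
    if robust:
        med = float(np.median(t))
        threshold = med + 1.4826 * float(np.median(np.abs(t - med)))
    else:
        threshold = t.mean() + t.std()
    above = t > threshold
    regions: list[tuple[float, float]] = []
    start: int | None = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((float(x[start]), float(x[i - 1])))
            start = None
    if start is not None:
        regions.append((float(x[start]), float(x[t.size - 1])))
    return regions
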