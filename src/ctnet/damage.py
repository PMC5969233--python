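"""Virtual-lesion experiments: graded white-matter, cortical, thalamic damage.

Three separate damage schedules are simulated, each linear in the damage
fraction from zero to its empirically motivated maximum:

* white matter — between-unit structural connections at predilection-site
  edges are scaled down by up to 14% (the structural connectivity strength
  loss observed in patients relative to controls);
* cortical — each region's within-cortical-unit synaptic densities
  (nu_ee, nu_ei, nu_ie, nu_ii) are scaled down by up to that region's
  fractional cortical-thickness loss (regional atrophy map);
* thalamic — the within-thalamic-unit densities (nu_sr, nu_rs) are scaled
  down globally by up to 11% (the relative thalamic volume loss
  1 - 18.50/20.78 in longstanding disease).

Damage always scales the *original* baseline value by (1 - f), so the final
iteration lands exactly on the stated maximum; within-unit corticothalamic
densities (es, se, re, is) belong to no schedule. Every (iteration,
realization) cell is simulated with its own deterministic seed, then reduced
to the four outcome measures (mean activity, mean PLV, tree diameter, leaf
fraction); mean and standard deviation across realizations summarise each
iteration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, DamageMaps, delay_matrix
from .integrator import SimulationBlowupError, euler_maruyama_run
from .model import ModelParameters
from .mst import mst_summary
from .observables import bandpass_alpha, plv_matrix

__all__ = [
    "DamageSchedule",
    "DamageTrajectory",
    "apply_wm_damage",
    "apply_cortical_damage",
    "apply_thalamic_damage",
    "thalamic_reduction_from_volumes",
    "run_experiment",
    "run_all_experiments",
    "cell_seed",
]

logger = logging.getLogger(__name__)

MEASURES = ("mean_activity", "mean_plv", "diameter", "leaf_fraction")
SCHEDULE_KINDS = ("white_matter", "cortical", "thalamic")


def thalamic_reduction_from_volumes(patient: float, control: float) -> float:
    """Maximal thalamic damage fraction from group-mean volumes (ml).

    1 - patient/control; e.g. volumes 18.50 vs 20.78 give ~0.11.
    """
    if control <= 0 or patient < 0:
        raise ValueError("volumes must be positive")
    return 1.0 - patient / control


@dataclass
class DamageSchedule:
    """A linear damage schedule of one kind."""

    kind: str
    maps: DamageMaps
    n_iterations: int = 20

    def __post_init__(self) -> None:
        if self.kind not in SCHEDULE_KINDS:
            raise ValueError(f"kind must be one of {SCHEDULE_KINDS}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def step_fractions(self) -> np.ndarray:
        """Fraction-of-maximum per iteration: linear 0 -> 1."""
        if self.n_iterations == 1:
            return np.zeros(1)
        return np.linspace(0.0, 1.0, self.n_iterations)


@dataclass
class DamageTrajectory:
    """Per-cell outcome measures and their across-realization aggregates."""

    kind: str
    step_fractions: np.ndarray
    cells: dict[str, np.ndarray]          # measure -> (n_iter, n_real)
    seeds: np.ndarray                     # (n_iter, n_real)
    failed: np.ndarray                    # boolean (n_iter, n_real)
    params: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.step_fractions)

    def aggregate(self, measure: str) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) across realizations per iteration, ignoring failures."""
        x = np.where(self.failed, np.nan, self.cells[measure])
        return np.nanmean(x, axis=1), np.nanstd(x, axis=1)

    def to_cell_frame(self) -> pd.DataFrame:
        rows = []
        n_iter, n_real = self.seeds.shape
        for i in range(n_iter):
            for r in range(n_real):
                row = {"iteration": i, "realization": r,
                       "fraction_of_max": self.step_fractions[i],
                       "seed": int(self.seeds[i, r]),
                       "failed": bool(self.failed[i, r])}
                for m in MEASURES:
                    row[m] = self.cells[m][i, r]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_aggregate_frame(self) -> pd.DataFrame:
        out = {"iteration": np.arange(self.n_iterations),
               "fraction_of_max": self.step_fractions}
        for m in MEASURES:
            mean, sd = self.aggregate(m)
            out[f"{m}_mean"] = mean
            out[f"{m}_sd"] = sd
        return pd.DataFrame(out)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_cell_frame().to_csv(
            directory / f"{self.kind}_cells.tsv", sep="\t", index=False)
        self.to_aggregate_frame().to_csv(
            directory / f"{self.kind}_aggregate.tsv", sep="\t", index=False)


# -- damage application ----------------------------------------------------

def apply_wm_damage(connectome: Connectome, maps: DamageMaps,
                    fraction: float) -> Connectome:
    """Scale predilection-site edges by (1 - fraction); others untouched."""
    if not 0.0 <= fraction <= maps.wm_max_fraction + 1e-12:
        raise ValueError(
            f"fraction {fraction} outside [0, {maps.wm_max_fraction}]")
    damaged = connectome.copy()
    damaged.adjacency[maps.wm_mask] *= (1.0 - fraction)
    return damaged


def apply_cortical_damage(p: ModelParameters, maps: DamageMaps,
                          step_fraction_of_max: float) -> ModelParameters:
    """Region-wise scaling of intracortical densities by the atrophy map.

    Region j's {nu_ee, nu_ei, nu_ie, nu_ii} are multiplied by
    ``1 - step_fraction_of_max * cortical_map[j]``; all other densities are
    untouched. Returns parameters with per-region arrays for those gains.
    """
    if not 0.0 <= step_fraction_of_max <= 1.0:
        raise ValueError("step_fraction_of_max outside [0, 1]")
    scale = 1.0 - step_fraction_of_max * np.asarray(maps.cortical_map, float)
    return p.with_nu(**{k: np.asarray(p.nu[k], float) * scale
                        for k in ("ee", "ei", "ie", "ii")})


def apply_thalamic_damage(p: ModelParameters, step_fraction_of_max: float,
                          max_fraction: float = 0.11) -> ModelParameters:
    """Global scaling of intrathalamic densities {nu_sr, nu_rs}."""
    if not 0.0 <= step_fraction_of_max <= 1.0:
        raise ValueError("step_fraction_of_max outside [0, 1]")
    scale = 1.0 - step_fraction_of_max * max_fraction
    return p.with_nu(sr=np.asarray(p.nu["sr"], float) * scale,
                     rs=np.asarray(p.nu["rs"], float) * scale)


def cell_seed(base_seed: int, iteration: int, realization: int) -> int:
    """Deterministic per-cell seed, independent across cells (< 2^31)."""
    ss = np.random.SeedSequence([int(base_seed), int(iteration),
                                 int(realization)])
    return int(ss.generate_state(1)[0] % (2**31))


def _damaged_system(schedule: DamageSchedule, p: ModelParameters,
                    connectome: Connectome, f: float):
    if schedule.kind == "white_matter":
        return p, apply_wm_damage(connectome, schedule.maps,
                                  f * schedule.maps.wm_max_fraction)
    if schedule.kind == "cortical":
        return apply_cortical_damage(p, schedule.maps, f), connectome
    return (apply_thalamic_damage(p, f, schedule.maps.thalamic_max_fraction),
            connectome)


def run_experiment(
    schedule: DamageSchedule,
    base_params: ModelParameters,
    connectome: Connectome,
    n_realizations: int = 50,
    base_seed: int = 0,
    duration: float = 16.0,
    transient: float = 2.0,
    velocity: float = 10.0,
    band: tuple[float, float] = (8.0, 13.0),
) -> DamageTrajectory:
    """Run one full damage schedule across stochastic realizations.

    For every iteration x realization: apply the damage at that iteration's
    cumulative fraction, simulate, band-pass filter, and compute the four
    outcome measures. Iteration 0 applies zero damage, so its statistics are
    identical across schedule kinds given the same ``base_seed``. A
    simulation blow-up marks its cell failed (NaN) and the run continues.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    fractions = schedule.step_fractions
    n_iter, n_real = len(fractions), n_realizations
    cells = {m: np.full((n_iter, n_real), np.nan) for m in MEASURES}
    seeds = np.zeros((n_iter, n_real), dtype=np.int64)
    failed = np.zeros((n_iter, n_real), dtype=bool)

    for i, f in enumerate(fractions):
        params_i, connectome_i = _damaged_system(
            schedule, base_params, connectome, float(f))
        tau = delay_matrix(connectome_i, velocity=velocity)
        for r in range(n_real):
            seed = cell_seed(base_seed, i, r)
            seeds[i, r] = seed
            t0 = time.perf_counter()
            try:
                res = euler_maruyama_run(
                    params_i, connectome_i, tau=tau, duration=duration,
                    transient=transient, seed=seed)
                filtered = bandpass_alpha(res.data, res.fs, band=band)
                net = plv_matrix(filtered)
                tree = mst_summary(net.plv)
            except SimulationBlowupError as err:
                failed[i, r] = True
                logger.warning("%s iter=%d real=%d failed: %s",
                               schedule.kind, i, r, err)
                continue
            cells["mean_activity"][i, r] = net.mean_activity
            cells["mean_plv"][i, r] = net.mean_plv
            cells["diameter"][i, r] = tree.diameter
            cells["leaf_fraction"][i, r] = tree.leaf_fraction
            logger.info("%s iter=%d real=%d seed=%d %.2fs plv=%.3f",
                        schedule.kind, i, r, seed,
                        time.perf_counter() - t0, net.mean_plv)

    return DamageTrajectory(
        kind=schedule.kind,
        step_fractions=fractions,
        cells=cells,
        seeds=seeds,
        failed=failed,
        params=base_params.snapshot(),
    )


def run_all_experiments(
    connectome: Connectome,
    maps: DamageMaps,
    params: ModelParameters,
    n_iterations: int = 20,
    n_realizations: int = 50,
    base_seed: int = 0,
    duration: float = 16.0,
    **kwargs,
) -> dict[str, DamageTrajectory]:
    """All three damage schedules under identical baseline conditions."""
    out = {}
    for kind in SCHEDULE_KINDS:
        schedule = DamageSchedule(kind=kind, maps=maps,
                                  n_iterations=n_iterations)
        out[kind] = run_experiment(schedule, params, connectome,
                                   n_realizations=n_realizations,
                                   base_seed=base_seed, duration=duration,
                                   **kwargs)
    return out
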