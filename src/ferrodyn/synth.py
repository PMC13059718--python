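"""Ground-truth-known synthetic datasets emulating the live-cell experiments.

The experimental designs being emulated: mouse embryonic fibroblasts seeded
at three densities (LD/MD/HD) in multi-well plates, imaged every 2 h for
confluence, dead-cell counts (nuclear dye) and the oxidized/reduced
lipid-peroxidation reporter ratio; treatments are the GPX4 inhibitor RSL3
(modelled as a reduction of the lipid-ROS death threshold r0), galactose
medium forcing OXPHOS (raising the ROS yield per division a), and a
restricted-growth-space variant (same cell number in half the area, i.e.
doubled initial confluence, mirroring a 24- vs 12-well comparison).

Every generated dataset carries its ground-truth parameters and noiseless
trajectories, so parameter-recovery and image round-trip checks need no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .fitting import ObservationModel, TimecourseDataset, predict_observables
from .model import ModelParams, ModelState, Trajectory, simulate
from .observables import ChannelFrame

__all__ = [
    "NoiseParams",
    "Scenario",
    "SyntheticDataset",
    "ImageSpec",
    "RenderedFrame",
    "DENSITY_FRACTIONS",
    "RSL3_R0_MULTIPLIER",
    "GALACTOSE_A_MULTIPLIER",
    "preset_scenarios",
    "dose_r0_multiplier",
    "generate",
    "generate_dataset",
    "render_frames",
]

#: Default initial confluence fractions for the three seeding densities.
#: The emulated design seeds 25k / 55k / 120k cells per well; at roughly
#: 1260 cells per percent confluence (a spread-fibroblast footprint of
#: ~1500 um^2 in a 1.9 cm^2 well) those counts map to ~20%, ~44% and ~95%.
DENSITY_FRACTIONS = {"LD": 0.20, "MD": 0.44, "HD": 0.95}

#: Default treatment effect sizes (directions are established biology:
#: GPX4 inhibition lowers the death threshold, galactose raises ROS yield).
RSL3_R0_MULTIPLIER = 0.4
GALACTOSE_A_MULTIPLIER = 1.8

#: Half-saturating RSL3 dose (ng per percent confluence) of the graded
#: dose -> r0 map; calibrated so the LD dose of 1.8 ng/%conf reproduces the
#: default RSL3 multiplier 0.4.
DOSE_HALF_SAT = 1.2


def dose_r0_multiplier(dose_ng_per_pct: float) -> float:
    """Graded r0 reduction for an RSL3 dose given per percent confluence.

    A saturating map 1 / (1 + dose / d50): zero dose leaves r0 unchanged,
    increasing dose suppresses the death threshold toward zero.
    """
    if dose_ng_per_pct < 0:
        raise ValueError("dose must be >= 0")
    return 1.0 / (1.0 + dose_ng_per_pct / DOSE_HALF_SAT)


@dataclass(frozen=True)
class NoiseParams:
    """Measurement-noise model for the three imaging observables.

    Confluence gets multiplicative lognormal noise (relative sigma),
    the reporter ratio additive Gaussian noise truncated at zero, and dead
    counts Poisson noise at ``dead_count_scale`` counts per unit of the
    normalised dead observable (``None`` or 0 disables it).
    """

    confluence_sigma: float = 0.05
    ratio_sigma: float = 0.05
    dead_count_scale: float | None = 400.0

    def __post_init__(self) -> None:
        if self.confluence_sigma < 0 or self.ratio_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.dead_count_scale is not None and self.dead_count_scale < 0:
            raise ValueError("dead_count_scale must be >= 0 or None")

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(confluence_sigma=0.0, ratio_sigma=0.0, dead_count_scale=None)


@dataclass(frozen=True)
class Scenario:
    """One experimental condition to emulate."""

    name: str
    seeding: str  # LD / MD / HD
    initial_confluence: float
    r0_multiplier: float = 1.0  # RSL3 / dose effect
    a_multiplier: float = 1.0  # galactose effect
    space_multiplier: float = 1.0  # restricted space rescales initial n
    interval_h: float = 2.0
    duration_h: float = 72.0
    replicates: int = 3
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.initial_confluence < 1:
            raise ValueError("initial_confluence must lie in (0, 1)")
        if self.interval_h <= 0 or self.duration_h <= 0:
            raise ValueError("interval and duration must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for m in (self.r0_multiplier, self.a_multiplier, self.space_multiplier):
            if m <= 0:
                raise ValueError("modifiers must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_h + 0.5 * self.interval_h, self.interval_h)

    def apply_to(self, params: ModelParams) -> ModelParams:
        return params.with_(r0=params.r0 * self.r0_multiplier, a=params.a * self.a_multiplier)

    @property
    def initial_state(self) -> ModelState:
        return ModelState(n=min(self.initial_confluence * self.space_multiplier, 0.95), r=0.0)


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated data with its ground truth attached."""

    scenarios: dict[str, Scenario]
    true_params: dict[str, ModelParams]
    observation: ObservationModel
    trajectories: dict[str, Trajectory]
    noiseless: TimecourseDataset
    noisy: TimecourseDataset


def preset_scenarios(
    noise: NoiseParams | None = None, seed: int = 0, replicates: int = 3
) -> dict[str, Scenario]:
    """The full preset battery of emulated conditions.

    LD/MD/HD x {DMSO, RSL3} x {glucose, galactose} x {unrestricted,
    restricted space}, plus the dose-per-confluence variants in which LD-
    and HD-seeded cultures receive the LD dose (1.8 ng/%conf) or HD dose
    (0.79 ng/%conf) of RSL3.
    """
    noise = noise or NoiseParams()
    out: dict[str, Scenario] = {}
    for dens, frac in DENSITY_FRACTIONS.items():
        for treat, r0m in (("DMSO", 1.0), ("RSL3", RSL3_R0_MULTIPLIER)):
            for medium, am in (("glucose", 1.0), ("galactose", GALACTOSE_A_MULTIPLIER)):
                for space, sm in (("unrestricted", 1.0), ("restricted", 2.0)):
                    name = f"{dens}-{treat}-{medium}-{space}"
                    out[name] = Scenario(
                        name=name, seeding=dens, initial_confluence=frac,
                        r0_multiplier=r0m, a_multiplier=am, space_multiplier=sm,
                        replicates=replicates, noise=noise, seed=seed,
                    )
    for dens in ("LD", "HD"):
        for dose_label, dose in (("LDdose", 1.8), ("HDdose", 0.79)):
            name = f"{dens}-{dose_label}"
            out[name] = Scenario(
                name=name, seeding=dens, initial_confluence=DENSITY_FRACTIONS[dens],
                r0_multiplier=dose_r0_multiplier(dose),
                replicates=replicates, noise=noise, seed=seed,
            )
    return out


def _noisy_values(
    obs_name: str, values: np.ndarray, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    if obs_name == "confluence_pct":
        if noise.confluence_sigma == 0:
            return values.copy()
        out = values * rng.lognormal(0.0, noise.confluence_sigma, size=values.shape)
        return np.minimum(out, 100.0)
    if obs_name == "lipid_ros_ratio":
        if noise.ratio_sigma == 0:
            return values.copy()
        # additive Gaussian truncated so the noisy ratio stays >= 0
        lo = -values / noise.ratio_sigma
        eps = truncnorm.rvs(lo, np.inf, size=values.shape, random_state=rng)
        return values + noise.ratio_sigma * eps
    if obs_name == "dead_per_confluence":
        scale = noise.dead_count_scale
        if not scale:
            return values.copy()
        return rng.poisson(scale * values).astype(float) / scale
    raise ValueError(f"unknown observable {obs_name!r}")


def generate(
    scenario: Scenario,
    base_params: ModelParams | None = None,
    observation: ObservationModel | None = None,
) -> SyntheticDataset:
    """Generate one condition; see :func:`generate_dataset` for joint designs."""
    return generate_dataset({scenario.name: scenario}, base_params, observation)


def generate_dataset(
    scenarios: dict[str, Scenario],
    base_params: ModelParams | None = None,
    observation: ObservationModel | None = None,
) -> SyntheticDataset:
    """Simulate every scenario and attach noiseless plus noisy observations.

    All randomness derives from each scenario's seed (plus a stable
    per-condition offset), so identical inputs give identical datasets.
    """
    base_params = base_params or ModelParams()
    observation = observation or ObservationModel()
    true_params: dict[str, ModelParams] = {}
    trajectories: dict[str, Trajectory] = {}
    clean_rows = []
    noisy_rows = []
    for k, (name, sc) in enumerate(scenarios.items()):
        p = sc.apply_to(base_params)
        true_params[name] = p
        times = sc.times
        trajectories[name] = simulate(p, sc.initial_state, times)
        pred = predict_observables(p, observation, sc.initial_state, times, rtol=1e-8, atol=1e-10)
        rng = np.random.default_rng(np.random.SeedSequence([sc.seed, k]))
        for obs_name in ("confluence_pct", "lipid_ros_ratio", "dead_per_confluence"):
            clean = pred[obs_name].to_numpy()
            for rep in range(1, sc.replicates + 1):
                noisy = _noisy_values(obs_name, clean, sc.noise, rng)
                for t, v_clean, v_noisy in zip(times, clean, noisy):
                    clean_rows.append((name, rep, t, obs_name, v_clean))
                    noisy_rows.append((name, rep, t, obs_name, v_noisy))
    cols = list(TimecourseDataset.COLUMNS)
    meta = {name: {"seeding": sc.seeding, "scenario": sc} for name, sc in scenarios.items()}
    return SyntheticDataset(
        scenarios=dict(scenarios),
        true_params=true_params,
        observation=observation,
        trajectories=trajectories,
        noiseless=TimecourseDataset(pd.DataFrame(clean_rows, columns=cols), metadata=meta),
        noisy=TimecourseDataset(pd.DataFrame(noisy_rows, columns=cols), metadata=meta),
    )


@dataclass(frozen=True)
class ImageSpec:
    """Geometry of rendered synthetic microscopy frames."""

    shape: tuple[int, int] = (512, 512)
    cell_radius_px: tuple[float, float] = (6.0, 10.0)
    margin_px: int = 3  # guaranteed gap between cells
    max_attempts: int = 4000  # consecutive rejected placements before jamming
    cell_intensity_cv: float = 0.1  # per-cell brightness variation (ratio-neutral)


@dataclass(frozen=True)
class RenderedFrame:
    """A rendered frame plus its ground truth."""

    frame: ChannelFrame
    labels: np.ndarray  # 0 background, 1 live cell, 2 dead cell
    true_live_fraction: float
    true_dead_fraction: float
    true_ratio: float


def _place_cells(
    target_fraction: float, spec: ImageSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Place non-overlapping ellipses until their area fraction is reached.

    Returns the occupancy mask and per-cell pixel-index masks.  Raises if
    the target cannot be packed with the required margins.
    """
    h, w = spec.shape
    cell_union = np.zeros((h, w), dtype=bool)
    halo_union = np.zeros((h, w), dtype=bool)  # cells expanded by the margin
    cells: list[tuple[tuple[slice, slice], np.ndarray]] = []
    area = 0
    target_px = target_fraction * h * w
    m = spec.margin_px
    rejects = 0
    while area < target_px:
        if rejects > spec.max_attempts:
            raise ValueError(
                f"cannot pack area fraction {target_fraction:.3f} "
                f"with margins; packing limit reached"
            )
        ry, rx = rng.uniform(*spec.cell_radius_px, size=2)
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(ry, h - ry)
        cx = rng.uniform(rx, w - rx)
        # work inside the halo's bounding box only
        rad = max(rx, ry) + m
        y0, y1 = max(int(cy - rad) - 1, 0), min(int(cy + rad) + 2, h)
        x0, x1 = max(int(cx - rad) - 1, 0), min(int(cx + rad) + 2, w)
        box = (slice(y0, y1), slice(x0, x1))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        cell = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        halo = (u / (rx + m)) ** 2 + (v / (ry + m)) ** 2 <= 1.0
        # margin gap between any two cells: my halo misses your cells and
        # my cells miss your halos
        if (halo_union[box] & cell).any() or (cell_union[box] & halo).any():
            rejects += 1
            continue
        rejects = 0
        cell_union[box] |= cell
        halo_union[box] |= halo
        cells.append((box, cell))
        area += int(cell.sum())
    return cell_union, cells


def render_frames(
    dataset: SyntheticDataset,
    condition: str,
    times: np.ndarray | list[float],
    spec: ImageSpec | None = None,
    seed: int = 0,
) -> list[RenderedFrame]:
    """Render multi-channel frames matching the trajectory of a condition.

    Cells are ellipses placed without overlap (with a margin so dead-mask
    dilation cannot eat live-cell pixels); the fraction of dead-marked
    cells tracks the cumulative dead area D(t), coverage tracks n(t) + D(t),
    and the ox/red channel intensities encode the reporter ratio of r(t).
    """
    spec = spec or ImageSpec()
    if condition not in dataset.trajectories:
        raise KeyError(f"unknown condition {condition!r}")
    sc = dataset.scenarios[condition]
    p = dataset.true_params[condition]
    obs = dataset.observation
    times = np.asarray(times, dtype=float)
    pred = predict_observables(p, obs, sc.initial_state, np.unique(times), rtol=1e-8, atol=1e-10)
    pred = pred.set_index("time_h")
    traj = simulate(p, sc.initial_state, np.unique(times))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))

    out: list[RenderedFrame] = []
    for i, t in enumerate(np.unique(times)):
        n_t = float(traj.n[i])
        ratio_t = float(pred.loc[t, "lipid_ros_ratio"])
        dead_area = float(pred.loc[t, "dead_per_confluence"]) * n_t  # = D(t)
        total = n_t + dead_area
        _, cells = _place_cells(total, spec, rng) if total > 0 else (None, [])
        n_dead = int(round(len(cells) * (dead_area / total))) if total > 0 else 0
        dead_idx = set(rng.choice(len(cells), size=n_dead, replace=False)) if n_dead else set()

        shape = spec.shape
        coverage = np.zeros(shape, dtype=bool)
        dead_ch = np.zeros(shape, dtype=float)
        ox = np.zeros(shape, dtype=float)
        red = np.zeros(shape, dtype=float)
        labels = np.zeros(shape, dtype=np.uint8)
        for j, (box, cell) in enumerate(cells):
            coverage[box] |= cell
            bright = rng.lognormal(0.0, spec.cell_intensity_cv)
            if j in dead_idx:
                labels[box][cell] = 2
                dead_ch[box][cell] = bright
                # dead cells are fully oxidised; excluded downstream anyway
                ox[box][cell] = 3.0 * ratio_t * bright
                red[box][cell] = bright
            else:
                labels[box][cell] = 1
                ox[box][cell] = ratio_t * bright
                red[box][cell] = bright
        frame = ChannelFrame(
            coverage=coverage, dead=dead_ch, oxidized=ox, reduced=red, time_h=float(t)
        )
        out.append(
            RenderedFrame(
                frame=frame,
                labels=labels,
                true_live_fraction=float(np.mean(labels == 1)),
                true_dead_fraction=float(np.mean(labels == 2)),
                true_ratio=ratio_t,
            )
        )
    return out
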