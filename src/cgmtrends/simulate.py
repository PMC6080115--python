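"""Synthetic clinical-study generator.

Emulates the design of a 14-day, 20-participant CGM wear study: each
participant wears two sensors of each of two systems (5-min and 15-min
storage cadence), attends three ~48 h study-site visits on days 0-2, 5-7 and
12-14, records the displayed trend arrow of all four sensors at every
reference blood-glucose measurement (hourly 0600-2400 plus one at 0300), and
undergoes a "dynamic phase" (0800-1300 on days 1, 6 and 13) with a high
glycemic-index breakfast, a delayed and increased insulin bolus, and 15-min
recording cadence.

The true glucose trajectory is baseline + gamma-shaped meal pulses - delayed
gamma-shaped bolus responses + mean-reverting (Ornstein-Uhlenbeck) noise,
clamped to the physiological display range.  Sensors sample the trajectory
at their storage cadence with a constant physiological lag and independent
Gaussian noise.  Displayed arrows are emulated as the least-squares slope of
the stored readings over a backward-looking window, classified with the
device's own taxonomy — real devices keep their algorithms proprietary, and
a backward-looking slope is the minimal mechanism that reproduces the
characteristic failure mode: around meals and boluses the recent past says
"steady" while the next 30 min do not.

Everything is reproducible bit-for-bit from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.signal import lfilter

from .concordance import DiaryRecord, visit_label
from .errors import CgmTrendsError
from .events import TherapyEvent
from .profiles import PROFILES, DeviceProfile, TrendCategory, classify_rate
from .traces import GlucoseTrace, default_max_gap, forward_rate

__all__ = [
    "StudyConfig",
    "Study",
    "generate_trajectory",
    "sample_device",
    "emulate_arrow",
    "generate_study",
]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of the synthetic study.  Defaults reproduce the study
    design; trajectory and noise parameters are realistic type 1 diabetes
    day profiles (see package docs for rationale)."""

    n_participants: int = 20
    systems: tuple[str, ...] = ("DG5", "FL")
    sensors_per_system: int = 2

    # Schedule (minutes within a day unless noted).
    visit_days: tuple[tuple[int, ...], ...] = ((0, 1, 2), (5, 6, 7), (12, 13, 14))
    dynamic_days: tuple[int, ...] = (1, 6, 13)
    night_record_min: float = 180.0          # 0300
    day_record_start_min: float = 360.0      # 0600
    day_record_end_min: float = 1440.0       # 2400
    day_record_step_min: float = 60.0
    dynamic_start_min: float = 480.0         # 0800
    dynamic_end_min: float = 780.0           # 1300
    dynamic_step_min: float = 15.0

    # True-glucose trajectory.
    baseline_mean_mgdl: float = 130.0
    baseline_sd_mgdl: float = 15.0
    meal_times_min: tuple[float, ...] = (420.0, 720.0, 1080.0)  # 07:00, 12:00, 18:00
    meal_amp_mean_mgdl: float = 70.0
    meal_amp_sd_mgdl: float = 15.0
    meal_peak_min: float = 45.0
    pulse_shape: float = 2.0
    bolus_amp_frac: float = 0.9
    bolus_peak_min: float = 90.0
    dynamic_meal_boost: float = 1.5
    dynamic_breakfast_min: float = 480.0
    dynamic_bolus_delay_min: float = 30.0
    noise_sd_mgdl: float = 15.0
    noise_tau_min: float = 60.0
    glucose_range_mgdl: tuple[float, float] = (40.0, 400.0)

    # Sensing.
    sensor_noise_sd_mgdl: float = 8.0
    sensor_lag_min: float = 7.0
    bg_noise_sd_mgdl: float = 3.0

    # Arrow emulation.
    arrow_lookback_min: float = 15.0
    arrow_mode: str = "emulate"  # "emulate" (backward slope) or "oracle"
    horizon_min: float = 30.0    # used by oracle mode

    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrow_mode not in ("emulate", "oracle"):
            raise ValueError(f"arrow_mode must be 'emulate' or 'oracle', got {self.arrow_mode!r}")
        for name in ("meal_amp_mean_mgdl", "meal_amp_sd_mgdl", "noise_sd_mgdl",
                     "sensor_noise_sd_mgdl", "bg_noise_sd_mgdl", "baseline_sd_mgdl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def all_days(self) -> tuple[int, ...]:
        return tuple(sorted({d for visit in self.visit_days for d in visit}))

    @property
    def end_min(self) -> float:
        # Cover the last possible diary record (2400 of the last visit day)
        # plus the forward horizon and a small buffer.
        last = (max(self.all_days) + 1) * MINUTES_PER_DAY
        return last + self.horizon_min + 30.0


@dataclass
class Study:
    """A complete in-memory synthetic (or loaded) study."""

    diary: list[DiaryRecord]
    traces: dict[str, GlucoseTrace]
    trace_meta: dict[str, tuple[str, str]]  # sensor_id -> (participant_id, system)
    bg: dict[str, GlucoseTrace]             # participant_id -> BG reference trace
    events: list[TherapyEvent]
    manifest: dict = field(default_factory=dict)

    def diary_for(self, system: str) -> list[DiaryRecord]:
        return [r for r in self.diary if r.system == system]


def _gamma_pulse(t: np.ndarray, onset: float, amp: float, peak: float, shape: float) -> np.ndarray:
    """Gamma-shaped pulse normalized to peak ``amp`` at ``onset + peak``."""
    tau = (t - onset) / peak
    out = np.zeros_like(t)
    m = tau > 0
    out[m] = amp * tau[m] ** shape * np.exp(shape * (1.0 - tau[m]))
    return out


def _schedule_events(config: StudyConfig, rng: np.random.Generator) -> list[tuple[float, float, float, str]]:
    """(time, meal_amp, bolus_time, tag) for every meal of every study day."""
    plan = []
    for day in range(max(config.all_days) + 1):
        day0 = day * MINUTES_PER_DAY
        dynamic = day in config.dynamic_days
        for k, mt in enumerate(config.meal_times_min):
            amp = max(0.0, rng.normal(config.meal_amp_mean_mgdl, config.meal_amp_sd_mgdl))
            t_meal = day0 + mt
            t_bolus = t_meal
            tag = "meal"
            if dynamic and k == 0:
                # High glycemic-index breakfast with a delayed, increased bolus.
                amp *= config.dynamic_meal_boost
                t_meal = day0 + config.dynamic_breakfast_min
                t_bolus = t_meal + config.dynamic_bolus_delay_min
                tag = "dynamic_breakfast"
            plan.append((t_meal, amp, t_bolus, tag))
    return plan


def generate_trajectory(
    config: StudyConfig, participant_seed: np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float, float, str]]]:
    """Simulate one participant's true glucose at 1-min resolution.

    Returns ``(t_grid, glucose, meal_plan)`` where ``meal_plan`` holds
    (meal time, meal amplitude, bolus time, tag) tuples that
    :func:`generate_study` turns into the therapy-event log.
    """
    rng = np.random.default_rng(participant_seed)
    t = np.arange(0.0, config.end_min + 1.0)
    baseline = rng.normal(config.baseline_mean_mgdl, config.baseline_sd_mgdl)
    plan = _schedule_events(config, rng)

    g = np.full_like(t, baseline)
    for t_meal, amp, t_bolus, _tag in plan:
        g += _gamma_pulse(t, t_meal, amp, config.meal_peak_min, config.pulse_shape)
        g -= _gamma_pulse(
            t, t_bolus, amp * config.bolus_amp_frac, config.bolus_peak_min, config.pulse_shape
        )

    if config.noise_sd_mgdl > 0:
        # Exact AR(1) discretization of an OU process on the 1-min grid.
        a = math.exp(-1.0 / config.noise_tau_min)
        eps = rng.standard_normal(t.size) * config.noise_sd_mgdl * math.sqrt(1.0 - a * a)
        eps[0] = rng.normal(0.0, config.noise_sd_mgdl)  # stationary start
        g += lfilter([1.0], [1.0, -a], eps)

    lo, hi = config.glucose_range_mgdl
    return t, np.clip(g, lo, hi), plan


def sample_device(
    t_grid: np.ndarray,
    glucose: np.ndarray,
    profile: DeviceProfile,
    config: StudyConfig,
    sensor_seed: np.random.SeedSequence,
    sensor_id: str,
) -> GlucoseTrace:
    """Sample a trajectory the way a device stores it.

    Readings at the device's storage cadence equal the trajectory value
    ``sensor_lag_min`` minutes earlier (interstitial lag) plus independent
    Gaussian sensor noise, clamped to the device display range.
    """
    rng = np.random.default_rng(sensor_seed)
    times = np.arange(0.0, t_grid[-1] + 1e-9, profile.storage_interval)
    values = np.interp(times - config.sensor_lag_min, t_grid, glucose)
    if config.sensor_noise_sd_mgdl > 0:
        values = values + rng.normal(0.0, config.sensor_noise_sd_mgdl, size=times.size)
    lo, hi = config.glucose_range_mgdl
    return GlucoseTrace(sensor_id=sensor_id, times=times, values=np.clip(values, lo, hi))


def emulate_arrow(
    trace: GlucoseTrace,
    t: float,
    profile: DeviceProfile,
    lookback: float = 15.0,
) -> TrendCategory | None:
    """Backward-looking arrow: least-squares slope of the stored readings in
    ``[t - lookback, t]``, classified with the profile's bands.

    Returns ``None`` (no arrow displayed) when fewer than two stored
    readings fall in the window, mirroring a device that momentarily shows
    no trend.
    """
    lo = np.searchsorted(trace.times, t - lookback, side="left")
    hi = np.searchsorted(trace.times, t, side="right")
    tt = trace.times[lo:hi]
    vv = trace.values[lo:hi]
    if tt.size < 2:
        return None
    tc = tt - tt.mean()
    slope = float(np.dot(tc, vv - vv.mean()) / np.dot(tc, tc))
    return classify_rate(slope, profile)


def _diary_times(config: StudyConfig) -> np.ndarray:
    times: set[float] = set()
    for day in config.all_days:
        day0 = day * MINUTES_PER_DAY
        times.add(day0 + config.night_record_min)
        times.update(
            day0 + m
            for m in np.arange(
                config.day_record_start_min,
                config.day_record_end_min + 1e-9,
                config.day_record_step_min,
            )
        )
        if day in config.dynamic_days:
            times.update(
                day0 + m
                for m in np.arange(
                    config.dynamic_start_min,
                    config.dynamic_end_min + 1e-9,
                    config.dynamic_step_min,
                )
            )
    return np.array(sorted(times))


def generate_study(config: StudyConfig | None = None) -> Study:
    """Generate a full synthetic study from a config.

    Per participant: one true trajectory; two sensor traces per system;
    reference BG readings (trajectory plus small meter noise) at every diary
    time; diary records with arrows for all four sensors at every diary time
    (omitted when the device shows no arrow or, in oracle mode, when the
    forward rate is not computable); and the therapy-event log.  The same
    config and seed reproduce the study bit-for-bit.
    """
    config = config or StudyConfig()
    master = np.random.SeedSequence(config.seed)
    part_seeds = master.spawn(config.n_participants)

    diary: list[DiaryRecord] = []
    traces: dict[str, GlucoseTrace] = {}
    trace_meta: dict[str, tuple[str, str]] = {}
    bg: dict[str, GlucoseTrace] = {}
    events: list[TherapyEvent] = []
    diary_times = _diary_times(config)

    for p, pseed in enumerate(part_seeds):
        pid = f"P{p + 1:02d}"
        n_sensors = len(config.systems) * config.sensors_per_system
        traj_seed, bg_seed, *sensor_seeds = pseed.spawn(2 + n_sensors)
        t_grid, glucose, plan = generate_trajectory(config, traj_seed)

        for t_meal, amp, t_bolus, _tag in plan:
            grams = round(amp * 0.8, 1)  # nominal CHO content scaling with excursion size
            events.append(TherapyEvent(pid, t_meal, "CHO", grams))
            events.append(TherapyEvent(pid, t_bolus, "insulin_bolus", round(grams / 10.0, 1)))

        si = iter(sensor_seeds)
        for system in config.systems:
            profile = PROFILES[system]
            for s in range(config.sensors_per_system):
                sensor_id = f"{pid}-{system}-{s + 1}"
                trace = sample_device(t_grid, glucose, profile, config, next(si), sensor_id)
                traces[sensor_id] = trace
                trace_meta[sensor_id] = (pid, system)
                for t in diary_times:
                    arrow = _displayed_arrow(trace, float(t), profile, config)
                    if arrow is None:
                        continue
                    diary.append(
                        DiaryRecord(
                            participant_id=pid,
                            system=system,
                            sensor_id=sensor_id,
                            time=float(t),
                            recorded=arrow,
                            visit=visit_label(float(t)),
                        )
                    )

        bg_rng = np.random.default_rng(bg_seed)
        bg_vals = np.interp(diary_times, t_grid, glucose)
        if config.bg_noise_sd_mgdl > 0:
            bg_vals = bg_vals + bg_rng.normal(0.0, config.bg_noise_sd_mgdl, diary_times.size)
        lo, hi = config.glucose_range_mgdl
        bg[pid] = GlucoseTrace(
            sensor_id=f"{pid}-BG", times=diary_times.copy(), values=np.clip(bg_vals, lo, hi)
        )

    manifest = {"config": _config_dict(config), "n_diary_records": len(diary)}
    return Study(diary=diary, traces=traces, trace_meta=trace_meta, bg=bg,
                 events=events, manifest=manifest)


def _displayed_arrow(
    trace: GlucoseTrace, t: float, profile: DeviceProfile, config: StudyConfig
) -> TrendCategory | None:
    if config.arrow_mode == "oracle":
        try:
            rate = forward_rate(
                trace, t, horizon=config.horizon_min,
                max_gap=default_max_gap(profile.storage_interval),
            )
        except CgmTrendsError:
            return None
        return classify_rate(rate, profile)
    return emulate_arrow(trace, t, profile, lookback=config.arrow_lookback_min)


def _config_dict(config: StudyConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    # Tuples -> lists for clean YAML round-tripping.
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def oracle_config(base: StudyConfig | None = None, **overrides) -> StudyConfig:
    """A config whose diaries are written by the analysis itself: the
    recorded arrow equals the category of the realized forward rate, so a
    correct pipeline must report a 100% match."""
    base = base or StudyConfig()
    return replace(base, arrow_mode="oracle", **overrides)
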