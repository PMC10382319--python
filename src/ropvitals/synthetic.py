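"""Synthetic neonatal cohort and monitor-trace generator.

Clinical monitor data from preterm infants are not publicly deposited, so
every downstream stage (feature extraction, cluster permutation testing,
classification) is exercised on synthetic cohorts that emulate the study
population: ~15% of infants develop retinopathy of prematurity severe enough
to require laser treatment, each infant contributes 30 days of SpO2 / heart
rate / FiO2 samples, and the laser group differs from the non-laser group in
configurable, signed ways (oxygen requirement, hyperoxia exposure,
desaturation incidence, heart-rate skewness, ...).

Signals are built from latent generators — per-infant setpoints, AR(1)
fluctuations, and Poisson event overlays (desaturations, bradycardias,
tachycardias, minor sub-threshold excursions) — and the group effects are
injected on those latents, never on extracted features, so the feature
extraction stage is genuinely tested. Effect sizes are expressed in units of
the between-infant standard deviation of the targeted daily feature under
the default parameters (the ``scale`` column of :data:`FAMILY_KNOBS`).
"""

from __future__ import annotations


from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "EffectWindow",
    "GeneratorConfig",
    "VitalTrace",
    "generate_cohort",
    "apply_missingness",
    "DEFAULT_EFFECT_WINDOWS",
]

SECONDS_PER_DAY = 86400


class EffectWindow(NamedTuple):
    """A signed group effect on one feature family over a day window.

    ``effect`` is in within-group SD units of the daily feature; positive
    means higher in the laser group. Days are 1-based and inclusive.
    """

    feature_family: str
    day_start: int
    day_end: int
    effect: float


# feature family -> (latent knob, knob shift per 1 SD of feature effect).
# The scale is the approximate between-infant SD of the daily feature under
# default parameters, mapped back onto the latent that drives it.
FAMILY_KNOBS: dict[str, tuple[str, float]] = {
    "mean_fio2": ("fio2_set", 0.04),
    "mean_sf_ratio": ("fio2_set", -0.04),
    "mean_spo2": ("spo2_set", 1.0),
    "pct_time_gt_95": ("spo2_set", 1.0),
    "auc_above_95": ("spo2_set", 1.0),
    # SpO2 skewness is dominated by desaturation burden: shallower dips pull
    # the daily skewness toward zero, so the depth latent is its lever.
    "skew_spo2": ("desat_depth", 3.0),
    "mean_hr": ("hr_set", 7.0),
    "skew_hr": ("hr_skew_bal", 7.0),
    "n_desaturations": ("desat_rate", 1.5),
    "pct_time_le_80": ("desat_dur_log", 1.5),
    "auc_below_80": ("desat_depth", -8.0),
    "n_bradycardia": ("brady_rate", 0.8),
    "n_tachycardia": ("tachy_rate", 0.5),
}

_KNOB_NAMES = sorted({knob for knob, _ in FAMILY_KNOBS.values()} | {"spo2_skew_bal"})

# Default group contrasts: the laser group requires more oxygen, spends more
# time hyperoxic, desaturates more often (but with shorter/shallower dips),
# and has lower heart-rate skewness — concentrated in the first weeks.
DEFAULT_EFFECT_WINDOWS: tuple[EffectWindow, ...] = (
    EffectWindow("mean_fio2", 5, 30, 1.0),
    EffectWindow("pct_time_gt_95", 5, 25, 0.8),
    EffectWindow("n_desaturations", 5, 20, 0.8),
    EffectWindow("skew_hr", 5, 15, -0.8),
    EffectWindow("pct_time_le_80", 10, 25, -0.5),
    EffectWindow("auc_below_80", 10, 25, -0.5),
)


def default_effect_windows(days: int = 30) -> tuple[EffectWindow, ...]:
    """The default group contrasts, clipped to a shorter trace horizon."""
    return tuple(
        EffectWindow(w.feature_family, w.day_start, min(w.day_end, days), w.effect)
        for w in DEFAULT_EFFECT_WINDOWS if w.day_start <= days
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``effect_windows`` defaults to the study's group contrasts; pass an
    empty sequence for a null cohort (groups identical in law).
    ``exact_positive_count`` forces the outcome count instead of drawing it
    Binomial(n, prevalence). ``low_availability_fraction`` is the share of
    infants whose first days of monitoring are missing (transferred in from
    another hospital), which the inclusion filter later removes.
    """

    n_infants: int
    prevalence: float = 0.15
    sampling_interval: int = 60  # seconds
    days: int = 30
    effect_windows: Sequence[EffectWindow] = DEFAULT_EFFECT_WINDOWS
    missingness_rate: float = 0.02
    low_availability_fraction: float = 0.0
    exact_positive_count: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_infants < 1:
            raise ValueError("n_infants must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.days < 1:
            raise ValueError("days must be positive")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must lie in [0, 1]")
        windows = [EffectWindow(*w) for w in self.effect_windows]
        for w in windows:
            if w.feature_family not in FAMILY_KNOBS:
                raise ValueError(f"unknown feature family {w.feature_family!r}")
            if not 1 <= w.day_start <= w.day_end <= self.days:
                raise ValueError(f"invalid effect window days {w.day_start}..{w.day_end}")
        object.__setattr__(self, "effect_windows", tuple(windows))
        if self.exact_positive_count is not None and not (
            0 < self.exact_positive_count < self.n_infants
        ):
            raise ValueError("exact_positive_count must leave both classes non-empty")


@dataclass
class VitalTrace:
    """One infant's monitor samples over the observation period.

    Timestamps are seconds since birth, strictly increasing. Invalid samples
    are flagged, never encoded as sentinel values. ``nominal_dt`` is the
    monitor sampling interval in seconds; it is retained through validity
    filtering so that time-denominated features keep correct denominators.
    """

    infant_id: int
    t: np.ndarray
    spo2: np.ndarray
    hr: np.ndarray
    fio2: np.ndarray
    valid: np.ndarray
    nominal_dt: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.int64)
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.fio2 = np.asarray(self.fio2, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not all(len(a) == n for a in (self.spo2, self.hr, self.fio2, self.valid)):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.nominal_dt is None:
            self.nominal_dt = float(np.median(np.diff(self.t))) if n > 1 else 60.0

    def __len__(self) -> int:
        return len(self.t)

    def signal(self, name: str) -> np.ndarray:
        if name == "sf_ratio":
            return self.spo2 / self.fio2
        try:
            return {"spo2": self.spo2, "hr": self.hr, "fio2": self.fio2}[name]
        except KeyError:
            raise ValueError(f"unknown signal {name!r}") from None


def _overlay_events(
    rng: np.random.Generator,
    signal: np.ndarray,
    interval: int,
    rate_per_day: np.ndarray,
    dur_min_s: float,
    dur_scale_s: np.ndarray,
    value_mu: np.ndarray,
    value_sd: float,
    mode: str,
) -> None:
    """Overlay Poisson events onto a cohort of signals in place.

    ``signal`` is (n_infants, n_samples); ``rate_per_day`` is
    (n_infants, days) while ``dur_scale_s`` and ``value_mu`` are per-day
    arrays shared across infants (group shifts enter through the caller).
    Each event inherits the parameters of its onset day. ``mode='set'``
    replaces the signal during the event (desaturation / bradycardia
    plateaus), ``mode='add'`` superimposes the excursion.
    """
    n_inf, n = signal.shape
    days = rate_per_day.shape[1]
    counts = rng.poisson(np.clip(rate_per_day, 0.0, None))
    total = int(counts.sum())
    if total == 0:
        return
    flat_counts = counts.ravel()
    cell = np.repeat(np.arange(n_inf * days), flat_counts)
    infant_of_event = cell // days
    day_of_event = cell % days
    starts_s = day_of_event * SECONDS_PER_DAY + rng.uniform(0, SECONDS_PER_DAY, total)
    durs_s = dur_min_s + rng.exponential(dur_scale_s[infant_of_event, day_of_event])
    start_idx = (starts_s // interval).astype(np.int64)
    lens = np.maximum(1, (durs_s // interval).astype(np.int64))
    lens = np.minimum(lens, n - start_idx)  # events never cross infants
    values = rng.normal(value_mu[infant_of_event, day_of_event], value_sd)

    # per-sample row/col indices for all events without a Python loop
    cum = np.cumsum(lens)
    cols = np.arange(cum[-1]) - np.repeat(cum - lens, lens) + np.repeat(start_idx, lens)
    rows = np.repeat(infant_of_event, lens)
    vals = np.repeat(values, lens) + rng.normal(0.0, 1.0, cum[-1])
    if mode == "set":
        signal[rows, cols] = vals
    elif mode == "add":
        np.add.at(signal, (rows, cols), vals)  # overlapping events accumulate
    else:
        raise ValueError(mode)


def _ar1(rng: np.random.Generator, shape: tuple[int, int], phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) deviations, one row per infant, marginal SD ``sd``."""
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), shape)
    x0 = rng.normal(0.0, sd, (shape[0], 1))
    out, _ = lfilter([1.0], [1.0, -phi], eps, axis=1, zi=phi * x0)
    return out


def _zero_shifts(days: int) -> dict[str, np.ndarray]:
    return {k: np.zeros(days) for k in _KNOB_NAMES}


def _laser_shifts(config: GeneratorConfig) -> dict[str, np.ndarray]:
    shifts = _zero_shifts(config.days)
    for w in config.effect_windows:
        knob, scale = FAMILY_KNOBS[w.feature_family]
        shifts[knob][w.day_start - 1 : w.day_end] += w.effect * scale
    return shifts


def _simulate_traces(
    rng: np.random.Generator,
    config: GeneratorConfig,
    laser: np.ndarray,
) -> list[VitalTrace]:
    """Simulate all infants' signals at once (one filter pass per signal)."""
    interval = config.sampling_interval
    days = config.days
    n_inf = config.n_infants
    n = days * SECONDS_PER_DAY // interval
    t = np.arange(n, dtype=np.int64) * interval
    day = (t // SECONDS_PER_DAY).astype(np.int64)

    S = _laser_shifts(config)  # per-day knob shifts, applied to laser rows
    L = laser.astype(float)[:, None]  # (n_inf, 1)

    def day_shift(knob: str) -> np.ndarray:
        # (n_inf, days): shift for laser infants, zero otherwise
        return L * S[knob][None, :]

    # per-infant latent setpoints and event rates
    b_fio2 = np.clip(rng.normal(0.29, 0.04, n_inf), 0.21, 0.80)
    s_spo2 = np.clip(rng.normal(93.0, 1.0, n_inf), 88.0, 96.5)
    h_hr = rng.normal(160.0, 7.0, n_inf)
    lam_desat = np.clip(rng.normal(4.0, 1.5, n_inf), 0.1, None)
    lam_brady = np.clip(rng.normal(2.0, 0.8, n_inf), 0.0, None)
    lam_tachy = np.clip(rng.normal(1.0, 0.5, n_inf), 0.0, None)

    phi = 0.95 ** (interval / 60.0)  # keep the autocorrelation timescale fixed

    # FiO2: slow step function (care adjustments every ~4 h) plus group shift
    seg = max(1, 4 * 3600 // interval)
    n_seg = -(-n // seg)
    steps = b_fio2[:, None] + rng.normal(0.0, 0.02, (n_inf, n_seg))
    fio2 = np.repeat(steps, seg, axis=1)[:, :n]
    fio2 += day_shift("fio2_set")[:, day]

    ones = np.ones((n_inf, days))

    # SpO2: AR(1) around setpoint, desaturation dips, minor excursions
    spo2 = s_spo2[:, None] + day_shift("spo2_set")[:, day] + _ar1(rng, (n_inf, n), phi, 2.0)
    bal = day_shift("spo2_skew_bal")
    _overlay_events(rng, spo2, interval,
                    lam_desat[:, None] + day_shift("desat_rate"),
                    20.0, 60.0 * np.exp(day_shift("desat_dur_log")),
                    70.0 + day_shift("desat_depth"), 4.0, "set")
    # skew lever: rate imbalance plus amplitude asymmetry (cubic in the
    # third moment, so modest amplitude changes move skewness strongly)
    _overlay_events(rng, spo2, interval, 4.0 + bal / 2.0,
                    30.0, 90.0 * ones, 4.0 * np.exp(bal / 12.0), 1.0, "add")
    _overlay_events(rng, spo2, interval, 4.0 - bal / 2.0,
                    30.0, 90.0 * ones, -4.0 * np.exp(-bal / 12.0), 1.0, "add")

    # heart rate: AR(1) around setpoint, brady/tachy plateaus, minor swings
    hr = h_hr[:, None] + day_shift("hr_set")[:, day] + _ar1(rng, (n_inf, n), phi, 5.0)
    hbal = day_shift("hr_skew_bal")
    _overlay_events(rng, hr, interval, lam_brady[:, None] + day_shift("brady_rate"),
                    15.0, 25.0 * ones, 85.0 * ones, 5.0, "set")
    _overlay_events(rng, hr, interval, lam_tachy[:, None] + day_shift("tachy_rate"),
                    15.0, 30.0 * ones, 210.0 * ones, 5.0, "set")
    _overlay_events(rng, hr, interval, 8.0 + hbal / 2.0,
                    30.0, 90.0 * ones, 18.0 * np.exp(hbal / 12.0), 4.0, "add")
    _overlay_events(rng, hr, interval, 8.0 - hbal / 2.0,
                    30.0, 90.0 * ones, -18.0 * np.exp(-hbal / 12.0), 4.0, "add")

    np.clip(spo2, 0.0, 100.0, out=spo2)
    np.clip(hr, 30.0, 260.0, out=hr)
    np.clip(fio2, 0.21, 1.0, out=fio2)

    return [
        VitalTrace(infant_id=i, t=t, spo2=spo2[i], hr=hr[i], fio2=fio2[i],
                   valid=np.ones(n, dtype=bool), nominal_dt=float(interval))
        for i in range(n_inf)
    ]


def _draw_outcomes(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    n = config.n_infants
    if config.exact_positive_count is not None:
        y = np.zeros(n, dtype=np.int64)
        y[rng.choice(n, size=config.exact_positive_count, replace=False)] = 1
        return y
    for _ in range(100):
        y = (rng.random(n) < config.prevalence).astype(np.int64)
        if n < 20 or 0 < y.sum() < n:
            return y
    raise ValueError("could not draw a cohort with both outcome classes present")


def _draw_demographics(rng: np.random.Generator, y: np.ndarray) -> dict[str, np.ndarray]:
    """Demographics and clinical covariates correlated with the outcome.

    Laser-treated infants are younger and lighter at birth and more often
    received inotropes and dexamethasone, mirroring the published baseline
    contrasts of such cohorts.
    """
    n = len(y)
    laser = y == 1

    ga = np.where(laser,
                  np.clip(rng.normal(25.2, 1.0, n), 23.5, 29.5),
                  np.clip(rng.normal(26.9, 1.7, n), 24.0, 31.9))
    bw = np.clip(150.0 * (ga - 21.0) + rng.normal(0.0, 110.0, n), 400, 1800)

    def bern(p0: float, p1: float) -> np.ndarray:
        return (rng.random(n) < np.where(laser, p1, p0)).astype(np.int64)

    return {
        "gestational_age": np.round(ga, 1),
        "birth_weight": np.round(bw).astype(np.int64),
        "sex": bern(0.73, 0.47),  # 1 = male
        "multiple_birth": bern(0.26, 0.13),
        "prenatal_steroid_doses": rng.binomial(2, 0.75, n),
        "delivery_route": bern(0.59, 0.73),  # 1 = caesarean section
        "apgar_1min": np.clip(np.round(rng.normal(np.where(laser, 6.0, 5.0), 1.8, n)), 0, 10).astype(np.int64),
        "apgar_5min": np.clip(np.round(rng.normal(8.0, 1.0, n)), 0, 10).astype(np.int64),
        "surfactant": bern(0.76, 0.93),
        "inotropes": bern(0.29, 0.67),
        "doxapram": bern(0.48, 0.53),
        "dexamethasone": bern(0.26, 0.80),
        "rbc_transfusion": bern(0.81, 0.97),
        "ino": bern(0.12, 0.33),
        "nec": bern(0.13, 0.13),
        "sepsis": bern(0.65, 0.87),
        "ivh": bern(0.19, 0.20),
        "pda": bern(0.45, 0.53),
    }


def generate_cohort(config: GeneratorConfig):
    """Generate a cohort table and one trace per infant.

    Returns ``(cohort, traces)`` where ``cohort`` is a pandas DataFrame with
    one row per infant (column ``outcome`` = 1 for laser treatment) and
    ``traces`` is a list of :class:`VitalTrace`. Identical configs (same
    seed) give identical output.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    y = _draw_outcomes(rng, config)
    demo = _draw_demographics(rng, y)

    cohort = pd.DataFrame({"infant_id": np.arange(config.n_infants), "outcome": y, **demo})

    trace_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    traces = _simulate_traces(trace_rng, config, y == 1)

    low_avail = rng.random(config.n_infants) < config.low_availability_fraction
    for i, trace in enumerate(traces):
        if config.missingness_rate > 0:
            drop = trace_rng.random(len(trace)) < config.missingness_rate
            trace.valid &= ~drop
        if low_avail[i]:
            # admitted elsewhere first: the opening days carry no valid data
            cutoff = trace_rng.uniform(3.0, 10.0) * SECONDS_PER_DAY
            trace.valid &= trace.t >= cutoff
    return cohort, traces


def apply_missingness(
    trace: VitalTrace,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> VitalTrace:
    """Flag a random fraction ``rate`` of samples invalid (timestamps kept)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0:
        return trace
    if rng is None:
        rng = np.random.default_rng(seed)
    drop = rng.random(len(trace)) < rate
    return replace(trace, valid=trace.valid & ~drop)
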