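"""Synthetic truck-driver study generator.

Emulates the data streams of an occupational fatigue study — resting RR
interval recordings taken pre- and post-shift, subjective fatigue (VAS),
daily driving hours and automotive warning events — with the statistical
structure the downstream analysis assumes, so the whole pipeline is testable
without field data.

Generative model
----------------
* Each driver carries a latent standardised fatigue process over successive
  measurement occasions (pre_1, post_1, pre_2, post_2, ...) following an
  AR(1) chain with stationary N(0, 1) marginals.  The step coefficient from
  post-shift day *d* to pre-shift day *d+1* is ``rho_crossday``, so the
  cross-day lag-1 correlation of LF deviation scores equals that parameter
  by construction; within-day (pre -> post) coupling is ``rho_withinday``.
* The target LF deviation score is ``50 + 10 z``; the recording's LF
  sinusoid amplitude is chosen so its analytic band power ``A^2/2`` inverts
  the score formula through the same norm table the analysis uses.
* VAS is an affine function of the same-condition LF score plus noise,
  clipped to [0, 100].
* Daily driving hours WT are lognormal around ``mean_wt_hours`` with an
  occasional short shift (to exercise the < 3 h exclusion).
* Warning-event counts are Poisson: risk events at rate
  ``base_risk_rate_per_hr * exp(beta_risk * (LF_post_prev - 50)/10)`` per
  hour (so ``beta_risk`` is the log-linear slope linking previous-day
  post-shift fatigue to next-day risk exposure), non-risk events at a
  constant rate.  Event speed traces are sampled from feature regions that
  satisfy (risk) or violate (non-risk) the published rules with a
  configurable margin, and emitted labels are flipped with probability
  ``label_noise``.

All randomness derives from one root seed via ``numpy.random.SeedSequence``
spawning (streams: demographics, latent fatigue, physiology, VAS, work
time, events — in that fixed order), so identical specs reproduce identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .hrv import NormTable, default_norm_table
from .risk import WarningEvent, extract_features, rule_classify

__all__ = [
    "CohortSpec",
    "GeneratedEvent",
    "CohortData",
    "generate_rri",
    "generate_events",
    "generate_cohort",
]

START_DATE = "2019-04-01"


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the study conditions the pipeline is meant to emulate:
    33 drivers over 17 shift-days (~530 cross-day score pairs), ages 24-65,
    cross-day score correlation 0.29, a median daily risk index near
    3.2 events/hour, and annotation noise calibrated to ~84% best achievable
    classification accuracy.
    """

    n_drivers: int = 33
    n_days: int = 17
    age_range: Tuple[int, int] = (24, 65)
    seed: int = 0
    rho_crossday: float = 0.29
    beta_risk: float = 0.2
    label_noise: float = 0.16
    mean_wt_hours: float = 8.0
    # generator conventions (not study-reported quantities)
    rho_withinday: float = 0.5
    base_risk_rate_per_hr: float = 3.2
    nonrisk_rate_per_hr: float = 19.6
    wt_log_sd: float = 0.25
    p_short_day: float = 0.05
    vas_base: float = 40.0
    vas_slope: float = 0.8
    vas_noise_sd: float = 10.0
    p_female: float = 2.0 / 33.0
    rri_base_range: Tuple[float, float] = (700.0, 1000.0)
    rri_jitter_sd: float = 30.0
    hf_power_median: float = 300.0
    hf_power_log_sd: float = 0.5
    rri_noise_sd_ms: float = 5.0
    lf_freq_hz: float = 0.10
    hf_freq_hz: float = 0.25
    rri_duration_s: float = 90.0
    event_margin: float = 1.0
    event_sd_margin: float = 0.1

    def __post_init__(self) -> None:
        if self.n_drivers < 1:
            raise ValueError("n_drivers must be >= 1")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2 (cross-day lag needs 2 days)")
        if not -1.0 <= self.rho_crossday <= 1.0:
            raise ValueError("rho_crossday must lie in [-1, 1]")
        if not -1.0 <= self.rho_withinday <= 1.0:
            raise ValueError("rho_withinday must lie in [-1, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        if self.mean_wt_hours <= 0:
            raise ValueError("mean_wt_hours must be positive")


def generate_rri(
    duration_s: float,
    mean_rri_ms: float,
    lf_amp_ms: float,
    hf_amp_ms: float,
    lf_freq_hz: float = 0.10,
    hf_freq_hz: float = 0.25,
    noise_sd_ms: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Beat-interval series with additive sinusoidal LF/HF modulation.

    The instantaneous interval at elapsed time *t* is
    ``mean + lf_amp sin(2 pi f_lf t) + hf_amp sin(2 pi f_hf t) + noise``;
    beats are emitted until the cumulative time reaches ``duration_s``.
    A pure sinusoidal modulation of amplitude A contributes band power
    A^2/2 ms^2, which is the analytic oracle used throughout the tests.

    Returns intervals in milliseconds.
    """
    if not (0.04 <= lf_freq_hz < 0.15 <= hf_freq_hz <= 0.4):
        raise ValueError(
            "band frequencies must satisfy 0.04 <= f_LF < 0.15 <= f_HF <= 0.4 Hz"
        )
    if not 300.0 <= mean_rri_ms <= 2000.0:
        raise ValueError("mean_rri_ms must lie in [300, 2000] ms")
    if lf_amp_ms < 0 or hf_amp_ms < 0 or noise_sd_ms < 0:
        raise ValueError("amplitudes and noise SD must be nonnegative")
    if lf_amp_ms + hf_amp_ms >= 0.9 * mean_rri_ms:
        raise ValueError("modulation amplitudes too large for the mean interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    two_pi = 2.0 * math.pi
    t = 0.0
    out: List[float] = []
    while t < duration_s:
        rri = (
            mean_rri_ms
            + lf_amp_ms * math.sin(two_pi * lf_freq_hz * t)
            + hf_amp_ms * math.sin(two_pi * hf_freq_hz * t)
        )
        if noise_sd_ms > 0:
            rri += noise_sd_ms * rng.standard_normal()
        rri = max(rri, 1.0)
        out.append(rri)
        t += rri / 1000.0
    return np.asarray(out)


# --------------------------------------------------------------------------
# warning-event synthesis


def _block_trace(mean: float, amp: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Speed trace cycling mean, mean+A, mean, mean-A at 1 Hz.

    Over full 4 s cycles this pattern has exact max/min mean +- A, exact
    mean, and population SD A/sqrt(2); truncation effects are O(A/n).
    """
    pattern = np.array([0.0, 1.0, 0.0, -1.0])
    reps = int(np.ceil((n + 4) / 4.0))
    base = np.tile(pattern, reps)
    start = int(rng.integers(0, 4))
    return mean + amp * base[start : start + n]


def _sample_event_trace(
    risky: bool, rng: np.random.Generator, margin: float, sd_margin: float
) -> np.ndarray:
    """Sample a 1 Hz speed trace from a rule-consistent feature region.

    Risk traces satisfy one of the two published rules with at least
    ``margin`` clearance in duration/speed and ``sd_margin`` inside the
    speed-deviation window; non-risk traces violate both rules with the
    same clearances.
    """
    # Speeds are integer km/h (vehicle-network speed signals are quantized)
    # and durations integer seconds clustering just past their rule
    # thresholds — alarm episodes are mostly short-lived, and boundary-
    # adjacent values occur in any moderately sized sample, which pins the
    # split points a tree trained on these events can learn.  Speed
    # statistics come from one of two traffic regimes (congested low-speed
    # / free-flowing high-speed) shared across risk and non-risk classes,
    # so that within a regime only the rule features — duration, maximum
    # speed, speed deviation — separate the labels.
    sqrt2 = math.sqrt(2.0)

    # durations are whole oscillation cycles (multiples of 4 s), so every
    # speed statistic of the emitted trace is exact rather than truncated
    def dur_above(thr: float, scale: float, cap: int) -> int:
        n = int(math.ceil(thr + margin)) + int(rng.exponential(scale))
        return min(-(-n // 4) * 4, (cap // 4) * 4)

    def dur_short() -> int:
        n = int(math.floor(42.5 - margin)) - int(rng.exponential(8.0))
        return max((n // 4) * 4, 4)

    def low_speed() -> Tuple[int, int]:
        # peak speed creeps up to (but clears) the rule boundary, with the
        # same distribution for risk and non-risk classes; stop-and-go
        # oscillation is large, and skips the amplitude band whose speed
        # deviation would fall in the highway-rule window
        vmax = int(math.floor(39.0 - margin)) - min(int(rng.exponential(2.0)), 20)
        amps = [a for a in (7, 8) if vmax - 2 * a >= 2]
        amp = int(rng.choice(amps)) if amps else max(1, (vmax - 2) // 2)
        return vmax - amp, amp

    def smooth_amp() -> int:
        # capped below the low-regime oscillation band so each class keeps
        # a disjoint speed-deviation signature
        return int(rng.integers(1, min(6, max(1, int((5.8 - sd_margin) * sqrt2))) + 1))

    if risky:
        if rng.random() < 0.5:  # sustained highway alarm
            n = dur_above(79.0, 12.0, 160)
            amp_lo = int(math.ceil((5.8 + sd_margin) * sqrt2))
            amp_hi = max(amp_lo, int(math.floor((6.5 - sd_margin) * sqrt2)))
            amp = int(rng.integers(amp_lo, amp_hi + 1))
            mean = int(rng.integers(55, 96))
        else:  # congestion alarm: peak speed stays below the split
            n = dur_above(42.5, 5.0, 120)
            mean, amp = low_speed()
    else:
        kind = rng.random()
        if kind < 0.25:  # short alarm in congested traffic
            n = dur_short()
            mean, amp = low_speed()
        elif kind < 0.5:  # short alarm at speed
            n = dur_short()
            mean = int(rng.integers(55, 96))
            amp = smooth_amp()
        elif kind < 0.8:  # long but smooth, at speed or just above the split
            n = dur_above(42.5, 25.0, 160)
            if rng.random() < 0.3:  # slow free flow just above the boundary
                vmax = int(math.ceil(39.0 + margin)) + min(int(rng.exponential(3.0)), 20)
                amp = int(rng.integers(1, max(2, min(smooth_amp(), (vmax - 2) // 2)) + 1))
                mean = vmax - amp
            else:
                mean = int(rng.integers(55, 96))
                amp = smooth_amp()
        else:  # long and jerky at speed
            n = dur_above(79.0, 12.0, 160)
            mean = int(rng.integers(55, 96))
            amp = int(rng.integers(max(int(math.ceil((6.5 + sd_margin) * sqrt2)), 11), 17))
    return _block_trace(float(mean), float(amp), n, rng)


@dataclass(frozen=True)
class GeneratedEvent:
    """A synthetic warning event with its emitted and pre-noise labels."""

    event: WarningEvent
    label: int        # emitted (possibly noise-flipped) annotation
    rule_label: int   # pre-noise truth from the published rules


def _random_start_time(rng: np.random.Generator) -> str:
    sec = int(rng.integers(6 * 3600, 20 * 3600))
    return f"{sec // 3600:02d}:{(sec % 3600) // 60:02d}:{sec % 60:02d}"


def _margin_ok(f, margin: float, sd_margin: float) -> bool:
    """True when every extracted feature clears every rule threshold.

    Enforced on the *extracted* features (not the sampling targets) so that
    no emitted event lies inside the margin band around any decision
    boundary; with zero margins the check is vacuous.
    """
    return (
        abs(f.duration_s - 42.5) >= margin
        and abs(f.duration_s - 79.0) >= margin
        and abs(f.max_speed_kmh - 39.0) >= margin
        and abs(f.speed_sd_kmh - 5.8) >= sd_margin
        and abs(f.speed_sd_kmh - 6.5) >= sd_margin
    )


def _make_event(
    risky: bool,
    rng: np.random.Generator,
    margin: float,
    sd_margin: float,
    driver_id: str = "",
    date: str = "",
) -> Tuple[WarningEvent, int]:
    for _ in range(50):
        trace = _sample_event_trace(risky, rng, margin, sd_margin)
        ev = WarningEvent(
            speed_samples=trace,
            duration_s=float(trace.size),
            driver_id=driver_id,
            date=date,
            start_time=_random_start_time(rng),
        )
        f = extract_features(ev)
        if rule_classify(f) == int(risky) and _margin_ok(f, margin, sd_margin):
            return ev, int(risky)
    raise RuntimeError("failed to sample a rule-consistent event trace")


def generate_events(
    n_events: int,
    risk_fraction: float,
    label_noise: float,
    seed: int | np.random.Generator = 0,
    margin: float = 1.0,
    sd_margin: float = 0.1,
) -> List[GeneratedEvent]:
    """Sample annotated warning events.

    ``round(n_events * risk_fraction)`` events are drawn from rule-satisfying
    regions and the rest from rule-violating regions (both with the given
    margins); each emitted label is flipped with probability ``label_noise``,
    and the pre-noise rule label is kept alongside.
    """
    if not 0.0 <= risk_fraction <= 1.0:
        raise ValueError("risk_fraction must lie in [0, 1]")
    if not 0.0 <= label_noise <= 1.0:
        raise ValueError("label_noise must lie in [0, 1]")
    if n_events == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_risk = int(round(n_events * risk_fraction))
    risky_flags = np.zeros(n_events, dtype=bool)
    risky_flags[:n_risk] = True
    rng.shuffle(risky_flags)
    out: List[GeneratedEvent] = []
    for flag in risky_flags:
        ev, rule_label = _make_event(bool(flag), rng, margin, sd_margin)
        label = rule_label ^ int(rng.random() < label_noise)
        out.append(GeneratedEvent(event=ev, label=label, rule_label=rule_label))
    return out


# --------------------------------------------------------------------------
# full cohort


@dataclass
class CohortData:
    """All emitted tables of one synthetic study, plus aligned truth tables."""

    drivers: pd.DataFrame            # driver_id, age, sex
    daily: pd.DataFrame              # per driver-day scores, VAS, WT, R, r_1hr
    vas: pd.DataFrame                # long: driver_id, date, condition, vas
    rri: pd.DataFrame | None         # long: per-beat intervals
    events: pd.DataFrame | None      # long: per-sample speed traces
    annotations: pd.DataFrame | None # emitted per-event labels
    truth_recordings: pd.DataFrame   # true band powers per recording
    truth_events: pd.DataFrame | None  # pre-noise rule labels per event
    truth_days: pd.DataFrame         # true expected risk rate per driver-day


def _latent_chain(
    n_days: int, rho_within: float, rho_cross: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """AR(1) fatigue chain over (pre, post) x days with N(0,1) marginals."""
    z_pre = np.empty(n_days)
    z_post = np.empty(n_days)
    z = rng.standard_normal()
    for d in range(n_days):
        if d > 0:
            z = rho_cross * z + math.sqrt(1.0 - rho_cross**2) * rng.standard_normal()
        z_pre[d] = z
        z = rho_within * z + math.sqrt(1.0 - rho_within**2) * rng.standard_normal()
        z_post[d] = z
    return z_pre, z_post


def generate_cohort(
    spec: CohortSpec,
    norms: NormTable | None = None,
    include_rri: bool = True,
    include_events: bool = True,
) -> CohortData:
    """Generate a full synthetic study.

    ``include_rri`` / ``include_events`` switch off the per-beat and
    per-sample trace synthesis (the heavy parts) for large replicate runs;
    the daily table and all truth tables are identical either way because
    scores and daily risk counts are drawn before any trace is rendered.
    """
    norms = norms or default_norm_table()
    root = np.random.SeedSequence(spec.seed)
    ss_demo, ss_latent, ss_phys, ss_vas, ss_wt, ss_events = root.spawn(6)
    rng_demo = np.random.default_rng(ss_demo)
    rng_latent = np.random.default_rng(ss_latent)
    rng_phys = np.random.default_rng(ss_phys)
    rng_vas = np.random.default_rng(ss_vas)
    rng_wt = np.random.default_rng(ss_wt)
    rng_events = np.random.default_rng(ss_events)

    dates = pd.date_range(START_DATE, periods=spec.n_days).strftime("%Y-%m-%d")
    driver_ids = [f"D{i + 1:03d}" for i in range(spec.n_drivers)]
    ages = rng_demo.integers(spec.age_range[0], spec.age_range[1] + 1, spec.n_drivers)
    sexes = np.where(rng_demo.random(spec.n_drivers) < spec.p_female, "F", "M")
    drivers = pd.DataFrame({"driver_id": driver_ids, "age": ages, "sex": sexes})

    daily_rows, vas_rows, rri_rows, event_rows = [], [], [], []
    ann_rows, tr_rec_rows, tr_ev_rows, tr_day_rows = [], [], [], []

    for di, drv in enumerate(driver_ids):
        age = float(ages[di])
        mu, sig = norms.lookup(age)
        z_pre, z_post = _latent_chain(
            spec.n_days, spec.rho_withinday, spec.rho_crossday, rng_latent
        )
        rri_base = rng_phys.uniform(*spec.rri_base_range)
        lf_prev_post = 50.0  # stationary mean before the first observed day
        for d, date in enumerate(dates):
            scores = {}
            for cond, z in (("pre_shift", z_pre[d]), ("post_shift", z_post[d])):
                score = 50.0 + 10.0 * z
                x = mu + sig * z
                mean_rri = float(
                    np.clip(
                        rri_base + rng_phys.normal(0.0, spec.rri_jitter_sd),
                        400.0,
                        1500.0,
                    )
                )
                lf_true = mean_rri * math.exp(x)
                hf_true = spec.hf_power_median * math.exp(
                    rng_phys.normal(0.0, spec.hf_power_log_sd)
                )
                lf_amp = math.sqrt(2.0 * lf_true)
                hf_amp = math.sqrt(2.0 * hf_true)
                scores[cond] = (score, lf_true, hf_true, mean_rri)
                tr_rec_rows.append(
                    {
                        "driver_id": drv,
                        "date": date,
                        "condition": cond,
                        "lf_power_true": lf_true,
                        "hf_power_true": hf_true,
                        "mean_rri_ms": mean_rri,
                        "lf_score_true": score,
                    }
                )
                if include_rri:
                    intervals = generate_rri(
                        spec.rri_duration_s,
                        mean_rri,
                        lf_amp,
                        hf_amp,
                        spec.lf_freq_hz,
                        spec.hf_freq_hz,
                        spec.rri_noise_sd_ms,
                        rng_phys,
                    )
                    rri_rows.append(
                        pd.DataFrame(
                            {
                                "driver_id": drv,
                                "date": date,
                                "condition": cond,
                                "beat_index": np.arange(intervals.size),
                                "rri_ms": intervals,
                            }
                        )
                    )
            vas_pre = float(
                np.clip(
                    spec.vas_base
                    + spec.vas_slope * (scores["pre_shift"][0] - 50.0)
                    + rng_vas.normal(0.0, spec.vas_noise_sd),
                    0.0,
                    100.0,
                )
            )
            vas_post = float(
                np.clip(
                    spec.vas_base
                    + spec.vas_slope * (scores["post_shift"][0] - 50.0)
                    + rng_vas.normal(0.0, spec.vas_noise_sd),
                    0.0,
                    100.0,
                )
            )
            vas_rows.append((drv, date, "pre_shift", vas_pre))
            vas_rows.append((drv, date, "post_shift", vas_post))

            if rng_wt.random() < spec.p_short_day:
                wt = float(rng_wt.uniform(1.0, 3.0))
            else:
                wt = float(
                    rng_wt.lognormal(
                        math.log(spec.mean_wt_hours) - spec.wt_log_sd**2 / 2.0,
                        spec.wt_log_sd,
                    )
                )
            lam_risk = spec.base_risk_rate_per_hr * math.exp(
                spec.beta_risk * (lf_prev_post - 50.0) / 10.0
            )
            n_risk = int(rng_events.poisson(lam_risk * wt))
            n_nonrisk = int(rng_events.poisson(spec.nonrisk_rate_per_hr * wt))
            if include_events:
                eid = 0
                for risky in [True] * n_risk + [False] * n_nonrisk:
                    ev, rule_label = _make_event(
                        risky,
                        rng_events,
                        spec.event_margin,
                        spec.event_sd_margin,
                        driver_id=drv,
                        date=date,
                    )
                    label = rule_label ^ int(rng_events.random() < spec.label_noise)
                    event_id = f"{drv}-{date}-{eid:04d}"
                    eid += 1
                    event_rows.append(
                        pd.DataFrame(
                            {
                                "driver_id": drv,
                                "date": date,
                                "event_id": event_id,
                                "start_time": ev.start_time,
                                "sample_index": np.arange(ev.speed_samples.size),
                                "speed_kmh": ev.speed_samples,
                            }
                        )
                    )
                    ann_rows.append((drv, date, event_id, label))
                    tr_ev_rows.append((drv, date, event_id, rule_label))
            daily_rows.append(
                {
                    "driver_id": drv,
                    "date": date,
                    "age": age,
                    "vas_pre": vas_pre,
                    "vas_post": vas_post,
                    "lf_score_pre": scores["pre_shift"][0],
                    "lf_score_post": scores["post_shift"][0],
                    "lf_hf_pre": scores["pre_shift"][1] / scores["pre_shift"][2],
                    "lf_hf_post": scores["post_shift"][1] / scores["post_shift"][2],
                    "wt_hours": wt,
                    "n_events": n_risk + n_nonrisk,
                    "R": n_risk,
                    "r_1hr": n_risk / wt,
                    "included": wt >= 3.0,
                }
            )
            tr_day_rows.append(
                {
                    "driver_id": drv,
                    "date": date,
                    "risk_rate_per_hr_true": lam_risk,
                    "lf_score_post_prev_true": lf_prev_post,
                }
            )
            lf_prev_post = scores["post_shift"][0]

    daily = pd.DataFrame(daily_rows)
    vas = pd.DataFrame(vas_rows, columns=["driver_id", "date", "condition", "vas"])
    rri = pd.concat(rri_rows, ignore_index=True) if include_rri else None
    events = pd.concat(event_rows, ignore_index=True) if include_events and event_rows else None
    annotations = (
        pd.DataFrame(ann_rows, columns=["driver_id", "date", "event_id", "label"])
        if include_events
        else None
    )
    truth_events = (
        pd.DataFrame(tr_ev_rows, columns=["driver_id", "date", "event_id", "rule_label"])
        if include_events
        else None
    )
    return CohortData(
        drivers=drivers,
        daily=daily,
        vas=vas,
        rri=rri,
        events=events,
        annotations=annotations,
        truth_recordings=pd.DataFrame(tr_rec_rows),
        truth_events=truth_events,
        truth_days=pd.DataFrame(tr_day_rows),
    )


def lagged_score_pairs(daily: pd.DataFrame) -> pd.DataFrame:
    """(post-shift day d, pre-shift day d+1) LF-score pairs per driver.

    Pairs are formed between consecutive calendar dates within a driver;
    this is the quantity whose Pearson correlation the generator calibrates
    to ``rho_crossday``.
    """
    df = daily[["driver_id", "date", "lf_score_pre", "lf_score_post"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    nxt = df[["driver_id", "date", "lf_score_pre"]].copy()
    nxt["date"] = nxt["date"] - pd.Timedelta(days=1)
    merged = df.merge(
        nxt, on=["driver_id", "date"], suffixes=("", "_next")
    ).dropna(subset=["lf_score_post", "lf_score_pre_next"])
    return merged[["driver_id", "date", "lf_score_post", "lf_score_pre_next"]]
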