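"""Synthetic cohorts, task sessions, spike trains, LFP, and node time series.

Every generator in this module is a pure function of its specification and a
seed, so downstream statistics can be validated against known ground truth.
The emulated study design is a cued Go/No-Go (GNG) task: each trial runs
precue (variable 9-24 s, house light on) -> auditory cue (Go or No-Go, 10 s)
-> reward/no reward -> 10 s inter-trial interval.  A poke in the final 3 s of
the precue period aborts the trial.  Animals carry a latent impulsivity trait
``theta`` in [0, 1] that monotonically drives their precue poke rate (waiting
impulsivity) and false-alarm probability (stopping impulsivity), producing a
high-impulsive / low-impulsive (HI/LI) contrast with known labels.

Electrophysiology is emulated as inhomogeneous-Poisson spike trains with
event-locked multiplicative gain windows (gain > 1 excited, < 1 inhibited,
= 1 non-responder), and LFP channels as 1/f background noise plus narrowband
oscillations whose envelopes can be modulated around task events (e.g. a
theta/beta/gamma power drop preceding precue pokes).  Resting-state imaging
is emulated as AR(1) multivariate node series with a controlled covariance,
into which group and treatment-by-group coupling effects can be injected at
a single node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "MotionProfile",
    "AgentSpec",
    "UnitSpec",
    "LFPSpec",
    "BandComponent",
    "EventModulation",
    "NetworkSpec",
    "SessionLog",
    "InvalidCohortError",
    "ConfigurationError",
    "GenerationError",
    "simulate_cohort",
    "simulate_session",
    "simulate_spike_trains",
    "simulate_lfp",
    "simulate_node_timeseries",
    "gain_for_z_shift",
    "compound_symmetric_covariance",
]


class InvalidCohortError(ValueError):
    """Raised when a cohort request cannot define a valid study population."""


class ConfigurationError(ValueError):
    """Raised when a simulation spec references unknown labels or bad values."""


class GenerationError(RuntimeError):
    """Raised when a requested construct cannot be realized (e.g. non-PSD)."""


# ---------------------------------------------------------------------------
# Task and agent specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one GNG session.

    Defaults follow the emulated protocol: precue period uniform on 9-24 s
    with a 3 s terminal abort window, 10 s cue, 10 s ITI, 30 Go + 30 No-Go
    trials in random order, a 40 min session cap, and a 20 ul milk reward.
    """

    precue_min_s: float = 9.0
    precue_max_s: float = 24.0
    abort_window_s: float = 3.0
    cue_duration_s: float = 10.0
    iti_s: float = 10.0
    reward_period_s: float = 3.0
    n_go: int = 30
    n_ng: int = 30
    session_cap_min: float = 40.0
    reward_volume_ul: float = 20.0
    replace_aborted: bool = True

    def __post_init__(self) -> None:
        if not self.precue_min_s < self.precue_max_s:
            raise ConfigurationError("precue_min_s must be < precue_max_s")
        if not 0 < self.abort_window_s < self.precue_min_s:
            raise ConfigurationError("abort_window_s must lie inside the shortest precue")
        if self.n_go < 0 or self.n_ng < 0:
            raise ConfigurationError("trial counts must be non-negative")
        for name in ("precue_min_s", "cue_duration_s", "iti_s", "session_cap_min",
                     "reward_period_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass(frozen=True)
class MotionProfile:
    """Parameters of the bounded 0-100 motion-measure process.

    The trace sits at ``active_level`` while the animal moves and drops to
    ``still_level`` during immobility bouts (the motion measure is low when
    the animal is still).  Bouts arrive as a Poisson process and have
    exponential durations with a floor.  ``fs_hz`` is the emission rate of
    the trace.
    """

    active_level: float = 35.0
    still_level: float = 5.0
    noise_sd: float = 4.0
    bout_rate_hz: float = 1.0 / 60.0
    bout_duration_mean_s: float = 8.0
    bout_duration_min_s: float = 2.0
    fs_hz: float = 10.0


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def default_precue_rate_fn(theta: float) -> float:
    """Default trait->poke-rate map: logistic, saturating at 0.5 pokes/s."""
    return 0.5 * _logistic(6.0 * (theta - 0.5))


def default_fa_prob_fn(theta: float) -> float:
    """Default trait->false-alarm-probability map (logistic, 0.05-0.45)."""
    return 0.05 + 0.4 * _logistic(6.0 * (theta - 0.5))


@dataclass(frozen=True)
class AgentSpec:
    """One simulated animal: identity, latent trait, and behavior maps.

    ``latent_group`` records the ground-truth HI/LI label used to score
    trait-split recovery; analysis code never reads it.
    """

    animal_id: str
    trait_theta: float
    precue_poke_rate_fn: Callable[[float], float] = default_precue_rate_fn
    fa_prob_fn: Callable[[float], float] = default_fa_prob_fn
    go_hit_prob: float = 0.9
    lick_rate_hz: float = 6.0
    motion_profile: MotionProfile = field(default_factory=MotionProfile)
    latent_group: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.trait_theta <= 1.0:
            raise ConfigurationError("trait_theta must lie in [0, 1]")
        if not 0.0 <= self.go_hit_prob <= 1.0:
            raise ConfigurationError("go_hit_prob must be a probability")
        fa = self.fa_prob_fn(self.trait_theta)
        if not 0.0 <= fa <= 1.0:
            raise ConfigurationError("fa_prob_fn must return a probability")
        if self.precue_poke_rate_fn(self.trait_theta) < 0:
            raise ConfigurationError("precue poke rate must be non-negative")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_animals: int,
    trait_distribution: Mapping | None = None,
    seed: int = 0,
) -> list[AgentSpec]:
    """Draw a cohort of agents with latent impulsivity traits.

    Parameters
    ----------
    n_animals
        Cohort size; at least 2.
    trait_distribution
        ``{"kind": "bimodal", "low": 0.2, "high": 0.8, "sd": 0.05,
        "weight_high": 0.5}`` (default) draws a stratified two-mode cohort:
        exactly ``round(n * weight_high)`` animals from the high mode, the
        rest from the low mode, in shuffled order, so the latent HI/LI
        composition matches the mode weights exactly.
        ``{"kind": "point", "value": v}`` gives every animal the same trait
        (degenerate cohort; downstream splits must flag ties).
        ``{"kind": "uniform", "low": a, "high": b}`` draws i.i.d. uniforms.
    seed
        Seed for the cohort RNG; the call is deterministic given it.
    """
    if n_animals < 2:
        raise InvalidCohortError("a cohort needs at least 2 animals")
    dist = dict(trait_distribution or {"kind": "bimodal"})
    kind = dist.get("kind", "bimodal")
    rng = np.random.default_rng(seed)

    if kind == "bimodal":
        low = float(dist.get("low", 0.2))
        high = float(dist.get("high", 0.8))
        sd = float(dist.get("sd", 0.05))
        w_high = float(dist.get("weight_high", 0.5))
        n_high = int(round(n_animals * w_high))
        modes = np.array([1] * n_high + [0] * (n_animals - n_high))
        rng.shuffle(modes)
        centers = np.where(modes == 1, high, low)
        thetas = np.clip(rng.normal(centers, sd), 0.0, 1.0)
        groups = np.where(modes == 1, "HI", "LI")
    elif kind == "point":
        value = float(dist.get("value", 0.5))
        thetas = np.full(n_animals, value)
        groups = np.array(["unknown"] * n_animals)
    elif kind == "uniform":
        thetas = rng.uniform(float(dist.get("low", 0.0)),
                             float(dist.get("high", 1.0)), n_animals)
        groups = np.where(thetas >= np.median(thetas), "HI", "LI")
    else:
        raise ConfigurationError(f"unknown trait distribution kind: {kind!r}")

    return [
        AgentSpec(animal_id=f"m{i:03d}", trait_theta=float(thetas[i]),
                  latent_group=str(groups[i]))
        for i in range(n_animals)
    ]


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------

#: Event labels a session may contain; IO validation checks against this set.
KNOWN_EVENT_LABELS = frozenset({
    "precue_onset", "precue_poke", "abort_poke", "cue_go_onset",
    "cue_ng_onset", "go_poke", "fa_poke", "cue_offset", "reward", "lick",
    "iti_onset", "trial_end",
})

TRIAL_OUTCOMES = ("CorrectGo", "Omission", "CorrectNoGo", "FalseAlarm", "Aborted")


@dataclass
class SessionLog:
    """One simulated animal-session.

    Attributes
    ----------
    trials
        One row per trial: ``index, trial_type, precue_onset_s,
        precue_duration_s, cue_onset_s, outcome, response_latency_s,
        n_precue_pokes, lick_count``.
    events
        Long-format timestamped events: ``time_s, event_label, trial_index``.
    motion
        Motion-measure trace: ``time_s, motion`` on a 0-100 scale at
        ``motion_fs_hz``.
    immobility_truth
        Ground-truth immobility intervals ``[(start, end), ...]`` used for
        validating the extraction algorithm; analysis code never reads it.
    """

    animal_id: str
    trials: pd.DataFrame
    events: pd.DataFrame
    motion: pd.DataFrame
    duration_s: float
    motion_fs_hz: float = 10.0
    task: TaskConfig | None = None
    immobility_truth: list[tuple[float, float]] = field(default_factory=list)

    def event_times(self, label: str) -> np.ndarray:
        """Times of all events with the given label, sorted ascending."""
        if label not in KNOWN_EVENT_LABELS:
            raise ConfigurationError(f"unknown event label: {label!r}")
        sel = self.events.loc[self.events["event_label"] == label, "time_s"]
        return np.sort(sel.to_numpy(dtype=float))


def _truncated_exp(rng: np.random.Generator, scale: float, upper: float) -> float:
    # inverse-CDF sampling of Exp(scale) truncated to (0, upper)
    u = rng.uniform()
    return -scale * math.log1p(-u * (1.0 - math.exp(-upper / scale)))


def simulate_session(agent: AgentSpec, task: TaskConfig | None = None,
                     seed: int = 0) -> SessionLog:
    """Simulate one GNG session for one agent.

    Trial types are a shuffled sequence of ``n_go`` Go and ``n_ng`` No-Go
    trials.  Precue pokes are a Poisson process at the agent's trait-mapped
    rate; the first poke inside the final ``abort_window_s`` of the precue
    aborts the trial (outcome ``Aborted``, jump to ITI).  By default an
    aborted trial is replaced by appending a new trial of the same type so
    completed-trial denominators stay at ``n_go``/``n_ng``
    (``task.replace_aborted=False`` disables this).  Go cues are answered
    with probability ``go_hit_prob`` (outcome ``CorrectGo``, first poke ends
    the cue, reward follows) else ``Omission``; No-Go cues elicit a false
    alarm with probability ``fa_prob_fn(theta)`` (poke ends the trial,
    unrewarded) else ``CorrectNoGo`` (full withhold, rewarded at cue end).
    The session stops at ``session_cap_min`` even if trials remain.
    """
    task = task or TaskConfig()
    rng = np.random.default_rng(seed)
    poke_rate = agent.precue_poke_rate_fn(agent.trait_theta)
    fa_prob = agent.fa_prob_fn(agent.trait_theta)

    queue = ["Go"] * task.n_go + ["NG"] * task.n_ng
    rng.shuffle(queue)
    queue = list(queue)

    cap_s = task.session_cap_min * 60.0
    trials: list[dict] = []
    events: list[tuple[float, str, int]] = []
    t = 0.0
    idx = 0
    qpos = 0
    while qpos < len(queue):
        if t >= cap_s:
            break
        trial_type = queue[qpos]
        qpos += 1
        precue_onset = t
        d = rng.uniform(task.precue_min_s, task.precue_max_s)
        events.append((precue_onset, "precue_onset", idx))

        # Poisson precue pokes over [0, d); first poke in the abort window
        # terminates the trial at that moment.
        n_pokes = rng.poisson(poke_rate * d)
        poke_offsets = np.sort(rng.uniform(0.0, d, n_pokes))
        abort_start = d - task.abort_window_s
        abort_mask = poke_offsets >= abort_start
        aborted = bool(abort_mask.any())
        if aborted:
            abort_at = float(poke_offsets[abort_mask][0])
            poke_offsets = poke_offsets[poke_offsets < abort_at]
        for off in poke_offsets:
            events.append((precue_onset + off, "precue_poke", idx))

        row = {
            "index": idx,
            "trial_type": trial_type,
            "precue_onset_s": precue_onset,
            "precue_duration_s": d,
            "cue_onset_s": np.nan,
            "outcome": "Aborted",
            "response_latency_s": np.nan,
            "n_precue_pokes": int(len(poke_offsets)),
            "lick_count": 0,
        }

        if aborted:
            events.append((precue_onset + abort_at, "abort_poke", idx))
            t = precue_onset + abort_at
            events.append((t, "iti_onset", idx))
            t += task.iti_s
            events.append((t, "trial_end", idx))
            trials.append(row)
            if task.replace_aborted:
                queue.append(trial_type)
            idx += 1
            continue

        cue_onset = precue_onset + d
        row["cue_onset_s"] = cue_onset
        label = "cue_go_onset" if trial_type == "Go" else "cue_ng_onset"
        events.append((cue_onset, label, idx))

        rewarded = False
        if trial_type == "Go":
            if rng.uniform() < agent.go_hit_prob:
                lat = _truncated_exp(rng, 1.5, task.cue_duration_s)
                row["outcome"] = "CorrectGo"
                row["response_latency_s"] = lat
                events.append((cue_onset + lat, "go_poke", idx))
                events.append((cue_onset + lat, "cue_offset", idx))
                t = cue_onset + lat
                rewarded = True
            else:
                row["outcome"] = "Omission"
                events.append((cue_onset + task.cue_duration_s, "cue_offset", idx))
                t = cue_onset + task.cue_duration_s
        else:
            if rng.uniform() < fa_prob:
                lat = _truncated_exp(rng, 2.0, task.cue_duration_s)
                row["outcome"] = "FalseAlarm"
                row["response_latency_s"] = lat
                events.append((cue_onset + lat, "fa_poke", idx))
                events.append((cue_onset + lat, "cue_offset", idx))
                t = cue_onset + lat
            else:
                row["outcome"] = "CorrectNoGo"
                events.append((cue_onset + task.cue_duration_s, "cue_offset", idx))
                t = cue_onset + task.cue_duration_s
                rewarded = True

        if rewarded:
            events.append((t, "reward", idx))
            n_licks = rng.poisson(agent.lick_rate_hz * task.reward_period_s)
            lick_times = np.sort(rng.uniform(t, t + task.reward_period_s, n_licks))
            for lt in lick_times:
                events.append((float(lt), "lick", idx))
            row["lick_count"] = int(n_licks)
            t += task.reward_period_s

        events.append((t, "iti_onset", idx))
        t += task.iti_s
        events.append((t, "trial_end", idx))
        trials.append(row)
        idx += 1

    duration = t
    motion_df, truth = _simulate_motion(agent.motion_profile, duration, rng)

    trials_df = pd.DataFrame(
        trials, columns=["index", "trial_type", "precue_onset_s",
                         "precue_duration_s", "cue_onset_s", "outcome",
                         "response_latency_s", "n_precue_pokes", "lick_count"])
    events_df = pd.DataFrame(events, columns=["time_s", "event_label", "trial_index"])
    events_df = events_df.sort_values("time_s", kind="stable").reset_index(drop=True)

    return SessionLog(
        animal_id=agent.animal_id, trials=trials_df, events=events_df,
        motion=motion_df, duration_s=duration,
        motion_fs_hz=agent.motion_profile.fs_hz, task=task,
        immobility_truth=truth)


def _simulate_motion(profile: MotionProfile, duration_s: float,
                     rng: np.random.Generator):
    """Motion trace with embedded immobility bouts; returns (df, truth)."""
    fs = profile.fs_hz
    n = max(int(round(duration_s * fs)), 1)
    tt = np.arange(n) / fs
    level = np.full(n, profile.active_level)
    truth: list[tuple[float, float]] = []
    t = 0.0
    while True:
        gap = rng.exponential(1.0 / profile.bout_rate_hz) if profile.bout_rate_hz > 0 else np.inf
        t += gap
        if t >= duration_s:
            break
        dur = profile.bout_duration_min_s + rng.exponential(
            max(profile.bout_duration_mean_s - profile.bout_duration_min_s, 1e-9))
        end = min(t + dur, duration_s)
        i0, i1 = int(round(t * fs)), int(round(end * fs))
        level[i0:i1] = profile.still_level
        truth.append((i0 / fs, i1 / fs))
        t = end
    motion = np.clip(level + rng.normal(0.0, profile.noise_sd, n), 0.0, 100.0)
    df = pd.DataFrame({"time_s": tt, "motion": motion})
    # merge truth bouts that became contiguous after rounding
    merged: list[tuple[float, float]] = []
    for s, e in truth:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return df, merged


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSpec:
    """One simulated unit: baseline rate plus event-locked gain windows.

    Each coupling is ``(event_label, gain, latency_s, duration_s)``: within
    ``[t_event + latency, t_event + latency + duration)`` the firing rate is
    multiplied by ``gain`` (gain < 1 inhibition, > 1 excitation, = 1
    non-responder).  Overlapping windows multiply.
    """

    unit_id: str
    baseline_rate_hz: float = 10.0
    couplings: tuple[tuple[str, float, float, float], ...] = ()
    refractory_s: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0:
            raise ConfigurationError("baseline_rate_hz must be >= 0")
        for label, gain, _lat, dur in self.couplings:
            if gain < 0:
                raise ConfigurationError(f"gain for {label!r} must be >= 0")
            if dur <= 0:
                raise ConfigurationError(f"duration for {label!r} must be > 0")


def gain_for_z_shift(delta_z: float, baseline_rate_hz: float,
                     bin_width_s: float = 0.25) -> float:
    """Gain that shifts the binned-rate Z score of a Poisson unit by ``delta_z``.

    For a homogeneous Poisson unit the session-wide SD of the binned rate is
    ``sqrt(rate / bin_width)``, so a rate increment of ``delta_z`` SDs needs
    ``gain = 1 + delta_z * sqrt(1 / (rate * bin_width))``.
    """
    if baseline_rate_hz <= 0:
        raise ConfigurationError("baseline rate must be positive")
    return 1.0 + delta_z / math.sqrt(baseline_rate_hz * bin_width_s)


def _piecewise_rate(baseline: float, couplings, event_lookup, duration_s: float):
    """Breakpoints and rates of the piecewise-constant intensity function."""
    times = [0.0, duration_s]
    for label, gain, lat, dur in couplings:
        if label not in event_lookup:
            raise ConfigurationError(f"unknown event label: {label!r}")
        for te in event_lookup[label]:
            a = te + lat
            b = a + dur
            if b <= 0 or a >= duration_s:
                continue
            times.extend((max(a, 0.0), min(b, duration_s)))
    edges = np.unique(np.asarray(times))
    rates = np.full(len(edges) - 1, baseline)
    for label, gain, lat, dur in couplings:
        for te in event_lookup[label]:
            a = max(te + lat, 0.0)
            b = min(te + lat + dur, duration_s)
            if b <= a:
                continue
            sel = (edges[:-1] >= a - 1e-12) & (edges[:-1] < b - 1e-12)
            rates[sel] *= gain
    return edges, rates


def simulate_spike_trains(session: SessionLog, units: Sequence[UnitSpec],
                          seed: int = 0) -> list:
    """Inhomogeneous-Poisson spike trains for all units of one session.

    The intensity of each unit is its baseline rate times the product of the
    gains of all active event-locked windows; spikes are drawn exactly on
    the piecewise-constant intensity and a refractory period, if requested,
    is enforced by thinning (sequential deletion of spikes closer than
    ``refractory_s`` to the last retained spike).  Deterministic given seed.
    """
    from .ephys import SpikeTrain  # container lives with the analysis code

    labels_present = set(session.events["event_label"].unique())
    lookup = {lab: session.event_times(lab) for lab in labels_present}
    duration = session.duration_s
    ss = np.random.SeedSequence(seed)
    out = []
    for child, unit in zip(ss.spawn(len(units)), units):
        rng = np.random.default_rng(child)
        for label, *_ in unit.couplings:
            if label not in lookup:
                raise ConfigurationError(
                    f"unit {unit.unit_id}: unknown event label {label!r}")
        edges, rates = _piecewise_rate(unit.baseline_rate_hz, unit.couplings,
                                       lookup, duration)
        seg_lens = np.diff(edges)
        counts = rng.poisson(rates * seg_lens)
        total = int(counts.sum())
        if total:
            u = rng.uniform(size=total)
            starts = np.repeat(edges[:-1], counts)
            lens = np.repeat(seg_lens, counts)
            spikes = np.sort(starts + u * lens)
        else:
            spikes = np.empty(0)
        if unit.refractory_s > 0 and len(spikes) > 1:
            keep = [0]
            last = spikes[0]
            for i in range(1, len(spikes)):
                if spikes[i] - last >= unit.refractory_s:
                    keep.append(i)
                    last = spikes[i]
            spikes = spikes[keep]
        out.append(SpikeTrain(unit_id=unit.unit_id, spike_times_s=spikes,
                              span=(0.0, duration)))
    return out


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandComponent:
    """One narrowband oscillation: band edges in Hz and base RMS amplitude."""
    name: str
    low_hz: float
    high_hz: float
    amplitude: float


@dataclass(frozen=True)
class EventModulation:
    """Relative band-power change in a window around an event.

    ``window_s`` may be a scalar ``w`` (meaning the pre-event interval
    ``[t - w, t)``) or an explicit ``(start, end)`` offset pair relative to
    the event.  ``rel_power_change = -0.5`` halves band power (amplitude
    scaled by ``sqrt(0.5)``).
    """
    event_label: str
    band_name: str
    rel_power_change: float
    window_s: float | tuple[float, float] = 2.0

    def offsets(self) -> tuple[float, float]:
        if isinstance(self.window_s, tuple):
            return self.window_s
        return (-float(self.window_s), 0.0)


@dataclass(frozen=True)
class LFPSpec:
    """LFP generator spec: sampling rate, band components, 1/f background."""

    fs_hz: float = 1000.0
    bands: tuple[BandComponent, ...] = (
        BandComponent("theta", 4.0, 12.0, 1.0),
        BandComponent("beta", 15.0, 30.0, 1.0),
        BandComponent("gamma", 30.0, 90.0, 0.7),
    )
    noise_exponent: float = 1.0
    noise_amplitude: float = 0.5
    event_modulations: tuple[EventModulation, ...] = ()

    def __post_init__(self) -> None:
        for b in self.bands:
            if not 0 < b.low_hz < b.high_hz:
                raise ConfigurationError(f"band {b.name!r}: need 0 < low < high")
            if b.high_hz > self.fs_hz / 2:
                raise ConfigurationError(
                    f"band {b.name!r} exceeds the Nyquist frequency")
        names = {b.name for b in self.bands}
        for m in self.event_modulations:
            if m.band_name not in names:
                raise ConfigurationError(f"unknown band: {m.band_name!r}")
            if m.rel_power_change < -1.0:
                raise ConfigurationError("rel_power_change must be >= -1")


def _shaped_noise(rng, n_channels, n, fs, shaping_fn, dtype=np.float64):
    """Unit-RMS Gaussian noise rows with the given spectral shaping.

    Channels are generated in one batched FFT (padded to an FFT-friendly
    length, then truncated).
    """
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    m = next_fast_len(n)
    white = rng.standard_normal((n_channels, m), dtype=dtype)
    spec = rfft(white, axis=1)
    f = rfftfreq(m, 1.0 / fs)
    x = irfft(spec * shaping_fn(f).astype(spec.real.dtype)[None, :], m,
              axis=1)[:, :n]
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _bandlimited_noise(rng, n_channels, n, fs, low, high, dtype=np.float64):
    """Unit-RMS Gaussian noise confined to [low, high] Hz (FFT masking)."""
    return _shaped_noise(rng, n_channels, n, fs,
                         lambda f: ((f >= low) & (f <= high)).astype(float),
                         dtype=dtype)


def _one_over_f_noise(rng, n_channels, n, fs, exponent, dtype=np.float64):
    """Unit-RMS noise with power spectral density ~ 1/f**exponent."""
    def shaping(f):
        s = np.zeros_like(f)
        s[1:] = f[1:] ** (-exponent / 2.0)
        return s

    return _shaped_noise(rng, n_channels, n, fs, shaping, dtype=dtype)


def simulate_lfp(session: SessionLog, spec: LFPSpec, n_channels: int = 1,
                 seed: int = 0, dtype=np.float64) -> list:
    """Simulate LFP channels for one session.

    Each channel is independent 1/f background noise plus the spec's
    narrowband components; event modulations scale a band's amplitude
    envelope by ``sqrt(1 + rel_power_change)`` inside the stated window
    around every event with the given label.  Deterministic given seed.
    """
    from .lfp import LFPRecord

    fs = spec.fs_hz
    n = int(round(session.duration_s * fs))
    labels_present = set(session.events["event_label"].unique())
    for m in spec.event_modulations:
        if m.event_label not in labels_present:
            raise ConfigurationError(
                f"modulation references absent event label {m.event_label!r}")

    # precompute per-band envelopes (shared across channels)
    envelopes: dict[str, np.ndarray] = {}
    for band in spec.bands:
        env = np.ones(n)
        for m in spec.event_modulations:
            if m.band_name != band.name:
                continue
            a_off, b_off = m.offsets()
            scale = math.sqrt(1.0 + m.rel_power_change)
            for te in session.event_times(m.event_label):
                i0 = max(int(round((te + a_off) * fs)), 0)
                i1 = min(int(round((te + b_off) * fs)), n)
                if i1 > i0:
                    env[i0:i1] *= scale
        envelopes[band.name] = env

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = spec.noise_amplitude * _one_over_f_noise(rng, n_channels, n, fs,
                                                 spec.noise_exponent,
                                                 dtype=dtype)
    for band in spec.bands:
        if band.amplitude == 0:
            continue
        comp = band.amplitude * _bandlimited_noise(rng, n_channels, n, fs,
                                                   band.low_hz, band.high_hz,
                                                   dtype=dtype)
        x += comp * envelopes[band.name][None, :].astype(dtype)
    passband = (3.0, min(200.0, fs / 2.0))
    return [LFPRecord(channel_id=f"ch{ch:02d}", samples=x[ch], fs_hz=fs,
                      passband=passband)
            for ch in range(n_channels)]


# ---------------------------------------------------------------------------
# Node time series
# ---------------------------------------------------------------------------

def compound_symmetric_covariance(n_nodes: int, rho: float = 0.3) -> np.ndarray:
    """Unit-variance covariance with constant off-diagonal coupling ``rho``."""
    cov = np.full((n_nodes, n_nodes), rho)
    np.fill_diagonal(cov, 1.0)
    return cov


@dataclass(frozen=True)
class NetworkSpec:
    """Spec of the multivariate node-series generator.

    ``group_effect = (node, delta)`` adds ``delta`` to every off-diagonal
    coupling of that node's row/column for HI animals (all treatments);
    ``interaction_effect`` does the same but only in the
    ``interaction_treatment`` x HI cell.  Series are AR(1) with coefficient
    ``ar_coefficient`` and stationary covariance equal to the modified
    matrix; the process is initialized at stationarity and the first
    ``burn_in`` samples are additionally discarded.
    """

    n_nodes: int = 51
    n_timepoints: int = 230
    base_covariance: np.ndarray | None = None
    group_effect: tuple[int, float] | None = None
    interaction_effect: tuple[int, float] | None = None
    interaction_treatment: str = "treatment"
    ar_coefficient: float = 0.3
    burn_in: int = 10

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ConfigurationError("ar_coefficient must lie in (-1, 1)")
        for eff in (self.group_effect, self.interaction_effect):
            if eff is not None and not 0 <= eff[0] < self.n_nodes:
                raise ConfigurationError("effect node index out of range")
        if self.base_covariance is not None:
            cov = np.asarray(self.base_covariance)
            if cov.shape != (self.n_nodes, self.n_nodes):
                raise ConfigurationError("base_covariance shape mismatch")
            if not np.allclose(cov, cov.T):
                raise ConfigurationError("base_covariance must be symmetric")

    def covariance_for(self, group: str, treatment: str) -> np.ndarray:
        """Ground-truth covariance for one group x treatment cell."""
        cov = (np.array(self.base_covariance, dtype=float)
               if self.base_covariance is not None
               else compound_symmetric_covariance(self.n_nodes))
        if self.group_effect is not None and group == "HI":
            cov = _apply_row_delta(cov, *self.group_effect)
        if (self.interaction_effect is not None and group == "HI"
                and treatment == self.interaction_treatment):
            cov = _apply_row_delta(cov, *self.interaction_effect)
        return cov


def _apply_row_delta(cov: np.ndarray, node: int, delta: float) -> np.ndarray:
    out = cov.copy()
    out[node, :] += delta
    out[:, node] += delta
    out[node, node] = cov[node, node]
    return out


@dataclass
class NodeTimeseriesSet:
    """Node x time series per animal x treatment, with ground-truth groups."""

    series: dict[tuple[str, str], np.ndarray]  # (animal_id, treatment) -> (nodes, T)
    node_names: list[str]
    groups: dict[str, str]  # animal_id -> latent group
    treatments: list[str]

    def animals(self) -> list[str]:
        return sorted({a for a, _ in self.series})


def simulate_node_timeseries(cohort: Sequence[AgentSpec], spec: NetworkSpec,
                             treatments: Sequence[str] = ("vehicle",),
                             seed: int = 0) -> NodeTimeseriesSet:
    """AR(1) multivariate node series for every animal x treatment cell.

    The stationary covariance of each cell is ``spec.covariance_for(group,
    treatment)``; innovations are scaled by ``(1 - a^2)`` so the marginal
    covariance equals it exactly.  Raises :class:`GenerationError` when an
    injected effect makes the covariance non-PSD.
    """
    if not treatments:
        raise ConfigurationError("treatments must be nonempty")
    node_names = [f"node{i:02d}" for i in range(spec.n_nodes)]
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(cohort) * len(treatments)))
    series: dict[tuple[str, str], np.ndarray] = {}
    groups: dict[str, str] = {}
    chol_cache: dict[bytes, np.ndarray] = {}
    a = spec.ar_coefficient
    for agent in cohort:
        groups[agent.animal_id] = agent.latent_group
        for tr in treatments:
            rng = np.random.default_rng(next(children))
            cov = spec.covariance_for(agent.latent_group, tr)
            key = cov.tobytes()
            if key not in chol_cache:
                w = np.linalg.eigvalsh(cov)
                if w.min() < -1e-8:
                    raise GenerationError(
                        f"covariance for ({agent.latent_group}, {tr}) is not "
                        f"positive semidefinite (min eigenvalue {w.min():.3g})")
                chol_cache[key] = np.linalg.cholesky(
                    cov + 1e-9 * np.eye(spec.n_nodes))
            L = chol_cache[key]
            n_total = spec.n_timepoints + spec.burn_in
            innov = rng.standard_normal((n_total, spec.n_nodes)) @ L.T
            x = np.empty((n_total, spec.n_nodes))
            x[0] = innov[0]  # stationary start: marginal N(0, cov)
            scale = math.sqrt(1.0 - a * a)
            for tpt in range(1, n_total):
                x[tpt] = a * x[tpt - 1] + scale * innov[tpt]
            series[(agent.animal_id, tr)] = x[spec.burn_in:].T.copy()
    return NodeTimeseriesSet(series=series, node_names=node_names,
                             groups=groups, treatments=list(treatments))
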