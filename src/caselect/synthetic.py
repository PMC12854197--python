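"""Seeded synthetic elevated-zero-maze sessions with known ground truth.

The generator emulates the structure of a 20 min miniscope session: an
animal alternates between open-arm (OA) and closed-arm (CA) occupancy in
exponentially distributed bouts while moving forward around the ring; each
neuron emits discrete calcium events as a state-dependent Bernoulli process
per neural frame, and its continuous trace is the event train convolved with
an exponential indicator kernel plus slow drift and white noise.

Ground-truth selectivity is analytic: for per-state event rates
``(rate_oa, rate_ca)`` the true selectivity index is
``(rate_oa - rate_ca) / (rate_oa + rate_ca)``.

Two deliberate realism choices shape the downstream analyses:

* the rate-driving task state is *head-centric*: threat exposure in the maze
  begins when the head extends into an open arm, so neurons follow the head
  position, which leads the body by ``head_lead_s`` at every transition;
* event rates carry a slow multiplicative modulation (an
  Ornstein-Uhlenbeck process on the log rate), mimicking the slow network
  fluctuations of cortical activity that make autocorrelation-preserving
  null models behave differently from full randomization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behavior import Arena

_LABELS = ("OA", "CA", "NS")


@dataclass
class SimConfig:
    """Study conditions for one synthetic session.

    Durations in seconds, rates in Hz or events/s, lengths in cm.
    """

    session_duration: float = 1200.0
    neural_rate_hz: float = 20.0
    behavior_rate_hz: float = 18.96
    mean_bout_s: float = 16.0  # mean of the OA and CA mean dwell times
    oa_time_fraction: float = 0.25
    n_neurons: int = 20
    rate_oa: np.ndarray | float = 0.3
    rate_ca: np.ndarray | float = 0.3
    amplitude_dist: str = "lognormal"  # or "constant"
    amplitude_sigma: float = 0.4
    tau_gcamp: float = 0.7
    drift_amplitude: float = 0.4
    drift_period_s: float = 400.0
    noise_sd: float = 0.12
    rate_modulation_sd: float = 0.25
    rate_modulation_tau_s: float = 120.0
    transition_gain: float = 1.5
    head_lead_s: float = 1.0
    head_body_cm: float = 4.04
    head_jitter_deg: float = 0.0   # angular tracking noise of the head point
    body_jitter_deg: float = 0.0   # angular tracking noise of the body centroid
    ns_band: float = 0.05
    arena: Arena = field(default_factory=Arena)

    def __post_init__(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("zero-duration session")
        for name in ("neural_rate_hz", "behavior_rate_hz", "mean_bout_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.oa_time_fraction < 1.0:
            raise ValueError("oa_time_fraction must lie in (0, 1)")

    @property
    def mean_bout_oa_s(self) -> float:
        # per-state means scaled so the expected OA time fraction matches target
        return 2.0 * self.mean_bout_s * self.oa_time_fraction

    @property
    def mean_bout_ca_s(self) -> float:
        return 2.0 * self.mean_bout_s * (1.0 - self.oa_time_fraction)

    @property
    def n_neural_frames(self) -> int:
        return int(round(self.session_duration * self.neural_rate_hz))

    @property
    def neural_times(self) -> np.ndarray:
        return np.arange(self.n_neural_frames) / self.neural_rate_hz


@dataclass
class BehaviorTruth:
    """Generated track plus the ground-truth state schedule."""

    track: pd.DataFrame  # time, head_x, head_y, body_x, body_y (behavior clock)
    bout_times: np.ndarray  # body-state transition times, starts at 0
    head_bout_times: np.ndarray  # head-state transitions (lead the body's)
    bout_is_oa: np.ndarray  # state of bout k over [bout_times[k], bout_times[k+1])
    head_lead_s: float

    def zone_is_oa(self, times: np.ndarray, which: str = "head") -> np.ndarray:
        """Ground-truth zone at arbitrary times; the head schedule leads the
        body schedule by a variable per-transition stretch-attend duration."""
        t = np.asarray(times, dtype=float)
        bt = self.head_bout_times if which == "head" else self.bout_times
        idx = np.clip(np.searchsorted(bt, t, side="right") - 1, 0, None)
        idx = np.minimum(idx, self.bout_is_oa.size - 1)
        return self.bout_is_oa[idx]


@dataclass
class SyntheticSession:
    """A fully simulated session with per-neuron ground truth."""

    config: SimConfig
    seed: int
    behavior: BehaviorTruth
    events_pos: list[np.ndarray]  # event frame indices per neuron
    events_amp: list[np.ndarray]  # event amplitudes per neuron
    raw_traces: np.ndarray  # (n_neurons, n_frames) float32
    zone_oa_neural: np.ndarray  # ground-truth exposure state per neural frame
    truth: pd.DataFrame  # neuron_id, truth_label, truth_si, rate_oa, rate_ca, n_events

    @property
    def track(self) -> pd.DataFrame:
        return self.behavior.track

    @property
    def arena(self) -> Arena:
        return self.config.arena

    @property
    def neural_rate_hz(self) -> float:
        return self.config.neural_rate_hz

    @property
    def n_frames(self) -> int:
        return self.raw_traces.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.raw_traces.shape[0]

    @property
    def neural_times(self) -> np.ndarray:
        return self.config.neural_times

    def events_matrix(self) -> np.ndarray:
        """Dense (n_neurons, n_frames) event-amplitude matrix."""
        out = np.zeros((self.n_neurons, self.n_frames), dtype=np.float32)
        for i, (p, a) in enumerate(zip(self.events_pos, self.events_amp)):
            out[i, p] = a
        return out


def true_si(rate_oa: float, rate_ca: float) -> float:
    tot = rate_oa + rate_ca
    return 0.0 if tot == 0 else (rate_oa - rate_ca) / tot


def truth_label(rate_oa: float, rate_ca: float, ns_band: float) -> str:
    si = true_si(rate_oa, rate_ca)
    if abs(si) <= ns_band:
        return "NS"
    return "OA" if si > 0 else "CA"


def generate_behavior(config: SimConfig, seed: int) -> BehaviorTruth:
    """Simulate the track and state schedule.

    The body moves forward around the ring at constant speed within each
    bout, crossing a quadrant boundary exactly at each state transition; the
    head is the body path advanced by ``head_lead_s`` seconds (so the head
    enters the next arm first), displaced radially so that the head-to-body
    distance has median ``head_body_cm``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x_BE]))
    dur = config.session_duration

    # bout schedule; session starts in an open arm (animals are placed there)
    times, states = [0.0], [True]
    t = 0.0
    while t < dur:
        mean = config.mean_bout_oa_s if states[-1] else config.mean_bout_ca_s
        t += rng.exponential(mean)
        times.append(t)
        states.append(not states[-1])
    bout_times = np.asarray(times[:-1])
    bout_is_oa = np.asarray(states[:-1], dtype=bool)

    arena = config.arena
    quad = 90.0  # deg per quadrant
    nb = bout_times.size

    # the head crosses each boundary before the body by a variable
    # stretch-attend duration (mean head_lead_s), clamped so schedules
    # stay ordered
    if config.head_lead_s > 0:
        leads = config.head_lead_s * rng.uniform(0.3, 1.7, nb)
    else:
        leads = np.zeros(nb)
    head_bout_times = bout_times - leads
    head_bout_times[0] = bout_times[0]
    for k in range(1, nb):
        lo = head_bout_times[k - 1] + 0.05
        if head_bout_times[k] < lo:
            head_bout_times[k] = min(lo, bout_times[k])

    # each schedule advances one quadrant per bout at constant within-bout
    # angular speed
    bout_ends = np.append(bout_times[1:], dur)
    head_ends = np.append(head_bout_times[1:], dur)
    start_angles = arena.open_quadrants[0][0] + quad * np.arange(nb)

    tb = np.arange(0.0, dur, 1.0 / config.behavior_rate_hz)

    def angle_at(t: np.ndarray, btimes: np.ndarray, bends: np.ndarray) -> np.ndarray:
        k = np.clip(np.searchsorted(btimes, t, side="right") - 1, 0, nb - 1)
        # frac stays strictly inside (0, 1) so sampled angles never sit exactly
        # on a quadrant boundary (crossings happen between samples)
        eps = 0.005
        dwell = bends[k] - btimes[k]
        frac = np.clip((t - btimes[k]) / np.maximum(dwell, 1e-9), 0.0, 1.0)
        frac = eps + frac * (1.0 - 2.0 * eps)
        return start_angles[k] + quad * frac

    ang_body = angle_at(tb, bout_times, bout_ends)
    ang_head = angle_at(tb, head_bout_times, head_ends)
    # optional centroid tracking noise in angle
    if config.body_jitter_deg > 0:
        ang_body = ang_body + rng.normal(0.0, config.body_jitter_deg, tb.size)
    if config.head_jitter_deg > 0:
        ang_head = ang_head + rng.normal(0.0, config.head_jitter_deg, tb.size)

    # radial placement: body walks slightly inside the center line with a slow
    # wobble; the head is displaced outward so that the total head-body
    # distance matches a lognormal sample around the configured median
    r_body = (arena.centerline_radius - 1.5) + 0.5 * np.sin(
        2 * np.pi * tb / 37.0 + rng.uniform(0, 2 * np.pi)
    )
    arc = np.deg2rad(np.abs(ang_head - ang_body)) * arena.centerline_radius
    d_target = config.head_body_cm * np.exp(rng.normal(0.0, 0.08, tb.size))
    radial = np.sqrt(np.maximum(d_target**2 - arc**2, 0.0))
    r_head = np.minimum(r_body + radial, arena.outer_radius - 0.05)

    track = pd.DataFrame(
        {
            "time": tb,
            "head_x": r_head * np.cos(np.deg2rad(ang_head)),
            "head_y": r_head * np.sin(np.deg2rad(ang_head)),
            "body_x": r_body * np.cos(np.deg2rad(ang_body)),
            "body_y": r_body * np.sin(np.deg2rad(ang_body)),
        }
    )
    return BehaviorTruth(
        track=track,
        bout_times=bout_times,
        head_bout_times=head_bout_times,
        bout_is_oa=bout_is_oa,
        head_lead_s=config.head_lead_s,
    )


def generate_neurons(
    config: SimConfig,
    zone_oa: np.ndarray,
    seed: int,
    transition_mask: np.ndarray | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray, pd.DataFrame]:
    """Draw event trains and raw traces given a per-neural-frame state truth.

    Events are Bernoulli per frame with probability ``rate_state / rate_hz``
    (times the slow modulation); amplitudes are i.i.d.; the raw trace is the
    event train convolved with ``exp(-t / tau_gcamp)`` plus sinusoidal drift,
    a slow random walk and white noise.  ``transition_mask`` marks the
    head-lead (risk-assessment) epochs in which rates are multiplied by
    ``transition_gain``.
    """
    zone_oa = np.asarray(zone_oa, dtype=bool)
    T = zone_oa.size
    rate = config.neural_rate_hz
    n = config.n_neurons
    r_oa = np.broadcast_to(np.asarray(config.rate_oa, dtype=float), (n,))
    r_ca = np.broadcast_to(np.asarray(config.rate_ca, dtype=float), (n,))
    if np.any(r_oa / rate >= 1.0) or np.any(r_ca / rate >= 1.0):
        raise ValueError("event rate per frame must be < 1 (probability overflow)")

    kernel = np.exp(
        -np.arange(int(round(5 * config.tau_gcamp * rate))) / (config.tau_gcamp * rate)
    )
    dt = 1.0 / rate
    a_mod = np.exp(-dt / config.rate_modulation_tau_s)
    sd = config.rate_modulation_sd

    events_pos, events_amp = [], []
    traces = np.empty((n, T), dtype=np.float32)
    truth_rows = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, i]))
        base_p = np.where(zone_oa, r_oa[i], r_ca[i]) / rate
        if transition_mask is not None and config.transition_gain != 1.0:
            base_p = np.where(transition_mask, base_p * config.transition_gain, base_p)
        if sd > 0:
            eps = rng.normal(0.0, sd * np.sqrt(1 - a_mod**2), T)
            eps[0] = rng.normal(0.0, sd)  # stationary start
            g = lfilter([1.0], [1.0, -a_mod], eps)
            p = np.minimum(base_p * np.exp(g - sd**2 / 2.0), 0.99)
        else:
            p = base_p
        pos = np.flatnonzero(rng.random(T) < p)
        if config.amplitude_dist == "constant":
            amp = np.ones(pos.size)
        else:
            amp = rng.lognormal(0.0, config.amplitude_sigma, pos.size)
        train = np.zeros(T)
        train[pos] = amp
        trace = np.convolve(train, kernel)[:T]
        times = np.arange(T) / rate
        drift = config.drift_amplitude * np.sin(
            2 * np.pi * times / config.drift_period_s + rng.uniform(0, 2 * np.pi)
        )
        walk = np.cumsum(rng.normal(0.0, config.drift_amplitude / np.sqrt(T) / 4.0, T))
        trace = trace + drift + walk + rng.normal(0.0, config.noise_sd, T)
        events_pos.append(pos.astype(np.int64))
        events_amp.append(amp.astype(np.float64))
        traces[i] = trace.astype(np.float32)
        truth_rows.append(
            {
                "neuron_id": i,
                "truth_label": truth_label(r_oa[i], r_ca[i], config.ns_band),
                "truth_si": true_si(r_oa[i], r_ca[i]),
                "rate_oa": r_oa[i],
                "rate_ca": r_ca[i],
                "n_events": pos.size,
            }
        )
    return events_pos, events_amp, traces, pd.DataFrame(truth_rows)


def generate_session(config: SimConfig, seed: int) -> SyntheticSession:
    """Behavior + neurons for one session, fully determined by the seed."""
    behavior = generate_behavior(config, seed)
    # ground truth at neural frames follows the nearest track sample so the
    # truth coincides exactly with head-centric relabeling of the track
    from .behavior import nearest_sample_index

    t_track = behavior.track["time"].to_numpy()
    idx = nearest_sample_index(t_track, config.neural_times)
    zone_oa = behavior.zone_is_oa(t_track[idx], which="head")
    zone_body = behavior.zone_is_oa(t_track[idx], which="body")
    pos, amp, traces, truth = generate_neurons(
        config, zone_oa, seed, transition_mask=zone_oa != zone_body
    )
    return SyntheticSession(
        config=config,
        seed=int(seed),
        behavior=behavior,
        events_pos=pos,
        events_amp=amp,
        raw_traces=traces,
        zone_oa_neural=zone_oa,
        truth=truth,
    )


def cohort_rates(
    rng: np.random.Generator,
    n_total: int = 692,
    n_oa_template: int = 7,
    n_ca_template: int = 13,
    n_ns_template: int = 13,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron (rate_oa, rate_ca) for a study-like cohort.

    Template neurons are extreme (|SI| ~ 0.9-0.98) or exactly flat; the
    remainder draw SIs from a centered distribution of weak-to-moderate
    effects.  Returns (rate_oa, rate_ca, is_template_flags).
    """
    n_non = n_total - n_oa_template - n_ca_template - n_ns_template
    if n_non < 0:
        raise ValueError("template counts exceed cohort size")
    # the non-template pool is a mixture of a near-flat majority and a
    # clearly selective minority, the bimodal structure typical of this assay
    n_sel = int(round(0.45 * n_non))
    si_non = np.concatenate(
        [
            np.clip(rng.normal(0.0, 0.08, n_non - n_sel), -0.3, 0.3),
            rng.choice([-1.0, 1.0], n_sel) * rng.uniform(0.35, 0.65, n_sel),
        ]
    )
    # sparse, mPFC-like event rates; the selective minority carries moderate
    # rates (clear detection margins), the flat majority can be sparser
    rate_non = np.concatenate(
        [
            np.exp(rng.uniform(np.log(0.03), np.log(0.3), n_non - n_sel)),
            np.exp(rng.uniform(np.log(0.1), np.log(0.4), n_sel)),
        ]
    )
    shuf = rng.permutation(n_non)
    si = np.concatenate(
        [
            rng.uniform(0.90, 0.98, n_oa_template),
            -rng.uniform(0.90, 0.98, n_ca_template),
            np.zeros(n_ns_template),
            si_non[shuf],
        ]
    )
    mean_rate = np.concatenate(
        [
            rng.uniform(0.05, 0.12, n_oa_template + n_ca_template),
            rng.uniform(0.2, 0.5, n_ns_template),
            rate_non[shuf],
        ]
    )
    rate_oa = mean_rate * (1.0 + si)
    rate_ca = mean_rate * (1.0 - si)
    kinds = np.array(
        ["OA"] * n_oa_template + ["CA"] * n_ca_template + ["NS"] * n_ns_template
        + ["none"] * n_non
    )
    return rate_oa, rate_ca, kinds


def make_study_cohort(
    config: SimConfig | None = None,
    seed: int = 0,
    n_total: int = 692,
    template_counts: tuple[int, int, int] = (7, 13, 13),
) -> SyntheticSession:
    """A session with a study-like composition: 692 neurons of which 33 are
    extreme templates (7 OA, 13 CA, 13 nonselective)."""
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    rate_oa, rate_ca, kinds = cohort_rates(rng, n_total, *template_counts)
    from dataclasses import replace

    config = replace(config, n_neurons=n_total, rate_oa=rate_oa, rate_ca=rate_ca)
    session = generate_session(config, seed)
    session.truth["template_kind"] = kinds
    return session


# ---------------------------------------------------------------------------
# plain-text serialization


def write_session(session: SyntheticSession, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t = session.neural_times
    ev = pd.DataFrame(session.events_matrix().T)
    ev.insert(0, "time", t)
    ev.to_csv(out / "events.csv", index=False)
    tr = pd.DataFrame(session.raw_traces.T)
    tr.insert(0, "time", t)
    tr.to_csv(out / "traces.csv", index=False)
    session.track.to_csv(out / "track.csv", index=False)
    session.truth.to_csv(out / "truth.csv", index=False)
    cfg = asdict(session.config)
    cfg["arena"] = asdict(session.config.arena)
    for k, v in list(cfg.items()):
        if isinstance(v, np.ndarray):
            cfg[k] = v.tolist()
    with open(out / "session.json", "w") as fh:
        json.dump({"seed": session.seed, "config": cfg}, fh, indent=1)
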