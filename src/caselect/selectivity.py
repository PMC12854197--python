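"""Selectivity index, shuffle null distributions, and label assignment.

For each neuron the selectivity index is

    SI = (avg(OA) - avg(CA)) / (avg(OA) + avg(CA)),

where avg(S) is the mean per-frame activity while the animal occupies state
S.  Statistical inference is purely permutation-based: the neural side of
the data is shuffled (behavior fixed), SI is recomputed per iteration, and a
neuron is OA-selective if its true SI exceeds the 97.5th percentile of the
null, CA-selective if it falls below the 2.5th percentile, nonselective
otherwise (strict comparisons; ties are nonselective).

Four shuffling methods are supported:

``randperm``
    uniform permutation of event frames (for convolved datatypes the events
    are permuted first and then re-convolved); destroys all temporal
    structure.  Not applicable to raw traces.
``circshift``
    cyclic rotation of the signal by a random offset in {1, ..., T-1};
    preserves local structure.
``full_ecm``
    the signal is cut at every event onset (plus the leading segment) and
    the inter-event segments are permuted.
``partial_ecm``
    fixed-length chunks anchored at event onsets (2 s / 4 s / 3 s depending
    on datatype, truncated at the next onset) are permuted among the chunk
    slots; frames outside chunks are set to zero.

Shuffle randomness is drawn as explicit *plans* (positions, shifts, segment
orders) separated from the deterministic application of a plan to a signal;
this keeps the reference implementation here and the vectorized batch engine
exactly reproducible against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import StateSequence
from .settings import CHUNK_SECONDS, ParameterSetting
from .transforms import Kernel, bin_signal

TAUS = {"conv2s": 2.0, "conv4s": 4.0}
METHOD_CODE = {"randperm": 1, "partial_ecm": 2, "full_ecm": 3, "circshift": 4}
DATATYPE_CODE = {"events": 1, "conv2s": 2, "conv4s": 3, "traces": 4}


class SilentNeuronError(ValueError):
    """avg(OA) + avg(CA) = 0: the SI is undefined."""


class UnmatchedBoutError(ValueError):
    """Some open-arm bout is longer than every closed-arm bout."""


def compute_si(avg_oa: float, avg_ca: float) -> float:
    if avg_oa < 0 or avg_ca < 0:
        raise ValueError("state activities must be nonnegative")
    tot = avg_oa + avg_ca
    if tot == 0:
        raise SilentNeuronError("SI undefined (silent neuron)")
    return (avg_oa - avg_ca) / tot


def assign_label(true_si: float, null_si: np.ndarray) -> str:
    """OA/CA/NS from strict order-statistic quantile comparisons.

    The upper cutoff is the rank-ceil(0.975 n) order statistic, the lower
    cutoff the rank-(floor(0.025 n)+1) order statistic of the sorted null.
    """
    arr = np.sort(np.asarray(null_si, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("empty null distribution")
    hi = arr[int(np.ceil(0.975 * n)) - 1]
    lo = arr[int(np.floor(0.025 * n))]
    if true_si > hi:
        return "OA"
    if true_si < lo:
        return "CA"
    return "NS"


# ---------------------------------------------------------------------------
# matched closed-arm sampling


@dataclass
class MatchedLayout:
    """Bout geometry, in *compacted* coordinates (valid frames only).

    For each OA bout of length L a matched draw samples a uniformly random
    contiguous L-frame segment from a uniformly chosen CA bout long enough
    to contain it.
    """

    valid_idx: np.ndarray  # original indices of valid frames
    oa_starts: np.ndarray
    oa_lens: np.ndarray
    ca_starts: np.ndarray
    ca_lens: np.ndarray
    eligible: list[np.ndarray] = field(default_factory=list)  # CA bout ids per OA bout
    n_oa: int = 0
    n_ca: int = 0

    @property
    def ok(self) -> bool:
        return all(e.size > 0 for e in self.eligible) and self.oa_starts.size > 0

    @classmethod
    def from_states(cls, states: StateSequence) -> "MatchedLayout":
        va = np.flatnonzero(states.valid)
        if va.size == 0:
            empty = np.zeros(0, dtype=np.int64)
            return cls(va, empty, empty, empty, empty, [], 0, 0)
        sv = states.is_oa[va]
        change = np.flatnonzero(np.diff(sv.astype(np.int8))) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [sv.size]))
        is_oa_run = sv[starts]
        lens = ends - starts
        oa_starts, oa_lens = starts[is_oa_run], lens[is_oa_run]
        ca_starts, ca_lens = starts[~is_oa_run], lens[~is_oa_run]
        eligible = [np.flatnonzero(ca_lens >= L) for L in oa_lens]
        return cls(
            valid_idx=va,
            oa_starts=oa_starts,
            oa_lens=oa_lens,
            ca_starts=ca_starts,
            ca_lens=ca_lens,
            eligible=eligible,
            n_oa=int(oa_lens.sum()),
            n_ca=int(ca_lens.sum()),
        )


def draw_matched_plan(
    rng: np.random.Generator, layout: MatchedLayout, n_draws: int
) -> np.ndarray:
    """(n_draws, n_oa_bouts) compacted start indices of sampled CA segments."""
    if not layout.ok:
        raise UnmatchedBoutError("unmatched bout: an OA bout exceeds every CA bout")
    cols = []
    for b, L in enumerate(layout.oa_lens):
        elig = layout.eligible[b]
        c = elig[rng.integers(0, elig.size, n_draws)]
        offset = rng.integers(0, layout.ca_lens[c] - L + 1)
        cols.append(layout.ca_starts[c] + offset)
    return np.stack(cols, axis=1)


def matched_avg_from_plan(
    compact_signal: np.ndarray, layout: MatchedLayout, plan: np.ndarray
) -> np.ndarray:
    """Per-draw matched CA activity (per-frame mean over all sampled segments)."""
    cs = np.concatenate(([0.0], np.cumsum(compact_signal, dtype=np.float64)))
    seg = cs[plan + layout.oa_lens[None, :]] - cs[plan]
    return seg.sum(axis=1) / layout.n_oa


def matched_ca_activity(
    signal: np.ndarray,
    states: StateSequence,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
    plan: np.ndarray | None = None,
) -> float:
    """Mean matched closed-arm activity over ``n_draws`` duration-matched draws."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    layout = MatchedLayout.from_states(states)
    if plan is None:
        plan = draw_matched_plan(rng, layout, n_draws)
    compact = np.asarray(signal, dtype=float)[layout.valid_idx]
    return float(matched_avg_from_plan(compact, layout, plan).mean())


# ---------------------------------------------------------------------------
# shuffle plans and their application


@dataclass
class ShuffleSpec:
    """How to build the null for one (datatype, method) pairing."""

    method: str  # randperm | partial_ecm | full_ecm | circshift
    datatype: str  # events | conv2s | conv4s | traces
    rate_hz: float
    n_iterations: int = 1000
    chunk_x: float | None = None  # seconds; defaults to the datatype's value

    def __post_init__(self) -> None:
        if self.method == "randperm" and self.datatype == "traces":
            raise ValueError("invalid setting (randperm on traces)")
        if self.chunk_x is None:
            self.chunk_x = CHUNK_SECONDS[self.datatype]

    @property
    def chunk_frames(self) -> int:
        return int(np.ceil(self.chunk_x * self.rate_hz))


def full_ecm_boundaries(onsets: np.ndarray, T: int) -> np.ndarray:
    """Cut points: leading segment, one segment per inter-event span, trailer."""
    return np.concatenate(([0], np.asarray(onsets, dtype=np.int64), [T]))


def partial_ecm_chunks(
    onsets: np.ndarray, T: int, chunk_frames: int
) -> tuple[np.ndarray, np.ndarray]:
    """Chunk (starts, lengths): chunk_frames after each onset, truncated at the
    next onset and the end of the session, so chunks never overlap."""
    onsets = np.asarray(onsets, dtype=np.int64)
    nxt = np.append(onsets[1:], T)
    lens = np.minimum(chunk_frames, nxt - onsets)
    return onsets, lens


def draw_plans(
    rng: np.random.Generator,
    spec: ShuffleSpec,
    T: int,
    onsets: np.ndarray,
    n_events: int,
):
    """All per-iteration shuffle randomness, drawn upfront in a fixed order."""
    n = spec.n_iterations
    if spec.method == "randperm":
        return np.stack([rng.choice(T, n_events, replace=False) for _ in range(n)])
    if spec.method == "circshift":
        if T < 2:
            raise ValueError("circshift requires at least two frames")
        return rng.integers(1, T, n)
    if spec.method == "full_ecm":
        n_seg = len(onsets) + 1
        return np.stack([rng.permutation(n_seg) for _ in range(n)])
    if spec.method == "partial_ecm":
        n_chunks = len(onsets)
        if n_chunks == 0:
            return np.zeros((n, 0), dtype=np.int64)
        return np.stack([rng.permutation(n_chunks) for _ in range(n)])
    raise ValueError(f"unknown shuffle method {spec.method!r}")


def apply_randperm(
    positions: np.ndarray,
    amplitudes: np.ndarray,
    T: int,
    datatype: str,
    rate_hz: float,
) -> np.ndarray:
    out = np.zeros(T)
    out[positions] = amplitudes
    if datatype in TAUS:
        kernel = Kernel(TAUS[datatype]).values(rate_hz)
        out = np.convolve(out, kernel)[:T]
    return out


def apply_circshift(signal: np.ndarray, shift: int) -> np.ndarray:
    return np.roll(signal, int(shift))


def apply_full_ecm(signal: np.ndarray, boundaries: np.ndarray, perm: np.ndarray) -> np.ndarray:
    segs = [signal[boundaries[i] : boundaries[i + 1]] for i in perm]
    return np.concatenate(segs) if segs else signal.copy()


def apply_partial_ecm(
    signal: np.ndarray,
    chunk_starts: np.ndarray,
    chunk_lens: np.ndarray,
    perm: np.ndarray,
) -> np.ndarray:
    out = np.zeros_like(np.asarray(signal, dtype=float))
    T = out.size
    n = chunk_starts.size
    for j in range(n):
        cap = (chunk_starts[j + 1] if j + 1 < n else T) - chunk_starts[j]
        src = perm[j]
        m = int(min(chunk_lens[src], cap))
        out[chunk_starts[j] : chunk_starts[j] + m] = signal[
            chunk_starts[src] : chunk_starts[src] + m
        ]
    return out


def shuffle(
    signal: np.ndarray,
    events_pos: np.ndarray,
    events_amp: np.ndarray,
    spec: ShuffleSpec,
    rng: np.random.Generator | int = 0,
    plan=None,
) -> np.ndarray:
    """One shuffled signal under ``spec``; draws a single plan unless given one.

    ``signal`` is the native-rate datatype signal; ``events_pos/amp`` is the
    underlying event train (required to re-convolve randperm shuffles and to
    anchor events-chunking methods).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    signal = np.asarray(signal, dtype=float)
    T = signal.size
    if plan is None:
        one = ShuffleSpec(spec.method, spec.datatype, spec.rate_hz, 1, spec.chunk_x)
        plan = draw_plans(rng, one, T, events_pos, len(events_pos))[0]
    if spec.method == "randperm":
        return apply_randperm(plan, events_amp, T, spec.datatype, spec.rate_hz)
    if spec.method == "circshift":
        return apply_circshift(signal, plan)
    if spec.method == "full_ecm":
        if len(events_pos) == 0:
            return signal.copy()  # no cuts possible; caller flags this
        return apply_full_ecm(signal, full_ecm_boundaries(events_pos, T), plan)
    if spec.method == "partial_ecm":
        if len(events_pos) == 0:
            return np.zeros_like(signal)  # caller flags this
        starts, lens = partial_ecm_chunks(events_pos, T, spec.chunk_frames)
        return apply_partial_ecm(signal, starts, lens, plan)
    raise ValueError(f"unknown shuffle method {spec.method!r}")


# ---------------------------------------------------------------------------
# null distribution and per-neuron results


@dataclass
class SelectivityResult:
    neuron_id: int
    setting_id: int
    true_si: float
    null_si: np.ndarray
    null_sd: float
    label: str
    flags: tuple[str, ...] = ()


def _state_sums(compact_signal: np.ndarray, layout: MatchedLayout) -> tuple[float, float]:
    cs = np.concatenate(([0.0], np.cumsum(compact_signal, dtype=np.float64)))
    oa = float((cs[layout.oa_starts + layout.oa_lens] - cs[layout.oa_starts]).sum())
    ca = float((cs[layout.ca_starts + layout.ca_lens] - cs[layout.ca_starts]).sum())
    return oa, ca


def null_distribution(
    signal: np.ndarray,
    events_pos: np.ndarray,
    events_amp: np.ndarray,
    states: StateSequence,
    setting: ParameterSetting,
    rate_hz: float,
    n_iterations: int = 1000,
    seed: int = 0,
    matched_draws: int = 1000,
    matched_plan: np.ndarray | None = None,
    plans=None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Reference (per-iteration loop) null SI distribution for one neuron.

    Shuffles the neural side only, re-bins, recomputes state activities under
    the setting's matching rule, and records SI; shuffles in which the neuron
    is silent contribute SI = 0 with a flag.  The batch engine reproduces
    this exactly for identical seeds.
    """
    signal = np.asarray(signal, dtype=float)
    T = signal.size
    spec = ShuffleSpec(setting.shuffle, setting.neural_datatype, rate_hz, n_iterations)
    if plans is None:
        rng_shuf = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        plans = draw_plans(rng_shuf, spec, T, events_pos, len(events_pos))
    layout = MatchedLayout.from_states(states)
    flags: set[str] = set()
    matching = setting.matching
    if matching == "matched" and not layout.ok:
        flags.add("unmatched_bout")
        matching = "nonmatched"
    if matching == "matched" and matched_plan is None:
        rng_match = np.random.default_rng(np.random.SeedSequence([seed, 12]))
        matched_plan = draw_matched_plan(
            rng_match, layout, n_iterations * matched_draws
        ).reshape(n_iterations, matched_draws, -1)
    if len(events_pos) == 0 and spec.method in ("full_ecm", "partial_ecm"):
        flags.add("no_events")

    out = np.empty(n_iterations)
    for i in range(n_iterations):
        shuf = shuffle(signal, events_pos, events_amp, spec, plan=plans[i])
        binned = bin_signal(shuf, rate_hz, setting.bin_width)
        compact = binned[layout.valid_idx]
        oa_sum, ca_sum = _state_sums(compact, layout)
        avg_oa = oa_sum / layout.n_oa
        if matching == "matched":
            avg_ca = float(
                matched_avg_from_plan(compact, layout, matched_plan[i]).mean()
            )
        else:
            avg_ca = ca_sum / layout.n_ca
        try:
            out[i] = compute_si(avg_oa, avg_ca)
        except SilentNeuronError:
            out[i] = 0.0
            flags.add("silent_shuffle")
    return out, tuple(sorted(flags))


def true_selectivity(
    signal: np.ndarray,
    states: StateSequence,
    setting: ParameterSetting,
    rate_hz: float,
    matched_draws: int = 1000,
    seed: int = 0,
    matched_plan: np.ndarray | None = None,
) -> tuple[float, tuple[str, ...]]:
    """True SI of one neuron under a setting (0.0 with a flag if silent)."""
    binned = bin_signal(np.asarray(signal, dtype=float), rate_hz, setting.bin_width)
    layout = MatchedLayout.from_states(states)
    compact = binned[layout.valid_idx]
    oa_sum, ca_sum = _state_sums(compact, layout)
    if layout.n_oa == 0 or layout.n_ca == 0:
        raise ValueError("state unobserved")
    avg_oa = oa_sum / layout.n_oa
    flags: set[str] = set()
    matching = setting.matching
    if matching == "matched" and not layout.ok:
        flags.add("unmatched_bout")
        matching = "nonmatched"
    if matching == "matched":
        if matched_plan is None:
            rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
            matched_plan = draw_matched_plan(rng, layout, matched_draws)
        avg_ca = float(matched_avg_from_plan(compact, layout, matched_plan).mean())
    else:
        avg_ca = ca_sum / layout.n_ca
    try:
        return compute_si(avg_oa, avg_ca), tuple(sorted(flags))
    except SilentNeuronError:
        flags.add("silent")
        return 0.0, tuple(sorted(flags))
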