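"""Vectorized cohort labeling across many settings.

Labeling a whole cohort under the full 120-setting grid with a permutation
null per neuron is the computational core of the pipeline.  This module
reproduces :func:`caselect.selectivity.null_distribution` exactly (same
plans, same arithmetic) but batches the ``n_iterations`` shuffled signals of
one neuron into a matrix and derives every state quantity from cumulative
sums:

* state sums over bouts are differences of the cumulative signal at bout
  boundaries;
* the 1 s moving-average binning is evaluated directly from the same
  cumulative sums;
* matched closed-arm draws are folded into a per-iteration weight vector
  over cumulative-sum positions (+1 at each sampled segment end, -1 at its
  start), so the thousands of segment sums per iteration reduce to one
  row-wise dot product.

Common random numbers: for a fixed (neural datatype, shuffle method) the
same shuffle realizations serve all settings that differ only in behavioral
datatype, bin width or matching, and one matched-sampling plan per
behavioral datatype serves all neurons.  This is a deliberate
variance-reduction choice (it removes spurious disagreement between
settings caused by independent shuffle noise) and is documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as sfft

from .behavior import StateSequence, label_states
from .selectivity import (
    TAUS,
    DATATYPE_CODE,
    METHOD_CODE,
    MatchedLayout,
    ShuffleSpec,
    draw_matched_plan,
    draw_plans,
    full_ecm_boundaries,
    partial_ecm_chunks,
)
from .settings import ParameterSetting, enumerate_settings
from .transforms import Kernel, one_second_window

LABEL_NAMES = {1: "OA", 0: "NS", -1: "CA"}
FLAG_SILENT = 1
FLAG_UNMATCHED = 2
FLAG_SILENT_SHUFFLE = 4
FLAG_NO_EVENTS = 8


@dataclass
class CohortLabels:
    """Per-(setting, neuron) selectivity results for a cohort."""

    settings: list[ParameterSetting]
    neuron_ids: np.ndarray
    labels: np.ndarray  # (S, N) int8: +1 OA, 0 NS, -1 CA
    true_si: np.ndarray  # (S, N) float64
    null_sd: np.ndarray  # (S, N) float64
    flags: np.ndarray  # (S, N) uint8 bitmask
    n_iterations: int = 0
    debug: dict = field(default_factory=dict)

    @property
    def n_settings(self) -> int:
        return len(self.settings)

    def setting_index(self, setting: ParameterSetting) -> int:
        ids = [s.setting_id for s in self.settings]
        return ids.index(setting.setting_id)

    def label_names(self, setting: ParameterSetting | int) -> np.ndarray:
        i = setting if isinstance(setting, int) else self.setting_index(setting)
        return np.array([LABEL_NAMES[int(v)] for v in self.labels[i]])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.settings):
            for j, nid in enumerate(self.neuron_ids):
                rows.append(
                    {
                        "setting_id": s.setting_id,
                        "neuron_id": int(nid),
                        "true_si": self.true_si[i, j],
                        "null_sd": self.null_sd[i, j],
                        "label": LABEL_NAMES[int(self.labels[i, j])],
                        "flags": int(self.flags[i, j]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# batched building blocks (each mirrors a reference op in `selectivity`)


def padded_cumsum(S: np.ndarray) -> np.ndarray:
    """cumsum with a leading zero, so sum over [p, q) = cs[q] - cs[p]."""
    out = np.zeros(S.shape[:-1] + (S.shape[-1] + 1,), dtype=np.float64)
    np.cumsum(S, axis=-1, out=out[..., 1:])
    return out


def binned_from_cumsum(csp: np.ndarray, rate_hz: float) -> np.ndarray:
    """1 s centered moving average from a padded cumsum (same arithmetic as
    transforms.bin_signal, evaluated with slices)."""
    T = csp.shape[-1] - 1
    w = one_second_window(rate_hz)
    h_lo, h_hi = w // 2, w - w // 2
    if T <= h_lo + h_hi:  # tiny signals: generic formula
        t = np.arange(T)
        lo = np.maximum(t - h_lo, 0)
        hi = np.minimum(t + h_hi, T)
        return (csp[..., hi] - csp[..., lo]) / (hi - lo)
    B = np.empty(csp.shape[:-1] + (T,), dtype=csp.dtype)
    B[..., h_lo : T - h_hi] = (csp[..., w:T] - csp[..., : T - w]) / w
    t_l = np.arange(h_lo)
    B[..., :h_lo] = csp[..., t_l + h_hi] / (t_l + h_hi)
    t_r = np.arange(T - h_hi, T)
    B[..., T - h_hi :] = (csp[..., T:] - csp[..., t_r - h_lo]) / (T - t_r + h_lo)
    return B


def batch_bin(S: np.ndarray, rate_hz: float, bin_width: str) -> np.ndarray:
    """Row-wise binning (native = identity); mirrors transforms.bin_signal."""
    if bin_width == "native":
        return S
    if bin_width != "one_second":
        raise ValueError(f"unknown bin width {bin_width!r}")
    return binned_from_cumsum(padded_cumsum(S), rate_hz)


def batch_randperm_events(plans: np.ndarray, amplitudes: np.ndarray, T: int) -> np.ndarray:
    E = np.zeros((plans.shape[0], T), dtype=np.float64)
    np.put_along_axis(E, plans, amplitudes[None, :], axis=1)
    return E


def batch_convolve(E: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution of each row with the kernel, right-truncated."""
    T = E.shape[1]
    n = sfft.next_fast_len(T + kernel.size - 1, real=True)
    out = sfft.irfft(sfft.rfft(E, n, axis=1) * sfft.rfft(kernel, n), n, axis=1)[:, :T]
    return np.maximum(out, 0.0)  # clip FFT roundoff; exact conv is nonnegative


def circshift_gather_index(shifts: np.ndarray, T: int) -> np.ndarray:
    return (np.arange(T, dtype=np.int32)[None, :] - shifts.astype(np.int32)[:, None]) % np.int32(T)


def batch_circshift(signal: np.ndarray, shifts: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
    if idx is None:
        idx = circshift_gather_index(shifts, signal.size)
    return signal[idx]


def full_ecm_gather_index(boundaries: np.ndarray, perms: np.ndarray, T: int) -> np.ndarray:
    """(n_iter, T) source index such that sig[idx] concatenates the permuted
    inter-event segments."""
    n_iter, n_seg = perms.shape
    lens = np.diff(boundaries)
    src_starts = boundaries[:-1][perms]  # (n_iter, n_seg)
    lens_p = lens[perms]
    out_starts = np.cumsum(lens_p, axis=1) - lens_p
    # running source index: +1 per frame, with a jump correction wherever a
    # new segment begins (zero-length segments compose additively)
    arr = np.ones((n_iter, T), dtype=np.int32)
    arr[:, 0] = src_starts[:, 0]
    if n_seg > 1:
        corr = src_starts[:, 1:] - (src_starts[:, :-1] + lens_p[:, :-1])
        posn = out_starts[:, 1:]
        rows = np.broadcast_to(np.arange(n_iter)[:, None], posn.shape)
        ok = posn < T
        np.add.at(arr, (rows[ok], posn[ok]), corr[ok])
    return np.cumsum(arr, axis=1)


def batch_full_ecm(signal: np.ndarray, boundaries: np.ndarray, perms: np.ndarray,
                   idx: np.ndarray | None = None) -> np.ndarray:
    if perms.shape[1] <= 1:
        return np.broadcast_to(signal, (perms.shape[0], signal.size)).copy()
    if idx is None:
        idx = full_ecm_gather_index(boundaries, perms, signal.size)
    return signal[idx]


@dataclass
class _PartialLayout:
    """Index template for scattering permuted chunks, shared across signals."""

    flat_dst: np.ndarray
    flat_src: np.ndarray

    @classmethod
    def build(cls, chunk_starts: np.ndarray, chunk_lens: np.ndarray,
              perms: np.ndarray, T: int) -> "_PartialLayout":
        n_iter = perms.shape[0]
        caps = np.append(np.diff(chunk_starts), T - chunk_starts[-1])
        Lc = int(chunk_lens.max())
        d = np.arange(Lc)
        m = np.minimum(chunk_lens[perms], caps[None, :])  # (n_iter, n)
        ok = d[None, None, :] < m[:, :, None]
        dst = np.broadcast_to(chunk_starts[None, :, None] + d[None, None, :], ok.shape)
        src = chunk_starts[perms][:, :, None] + d[None, None, :]
        rows = np.broadcast_to(np.arange(n_iter)[:, None, None], ok.shape)
        return cls(flat_dst=(rows[ok] * T + dst[ok]), flat_src=np.broadcast_to(src, ok.shape)[ok])


def batch_partial_ecm(signal: np.ndarray, chunk_starts: np.ndarray, chunk_lens: np.ndarray,
                      perms: np.ndarray, layout: _PartialLayout | None = None) -> np.ndarray:
    n_iter = perms.shape[0]
    T = signal.size
    out = np.zeros((n_iter, T), dtype=np.float64)
    if chunk_starts.size == 0:
        return out
    if layout is None:
        layout = _PartialLayout.build(chunk_starts, chunk_lens, perms, T)
    out.reshape(-1)[layout.flat_dst] = signal[layout.flat_src]
    return out


# ---------------------------------------------------------------------------
# per-behavior state structures
#
# Every quantity the null needs is linear in the shuffled signal:
#   avg(state)            = dot(SH, indicator/n)
#   avg(state) after 1 s binning = dot(SH, B^T indicator / n)
#   matched segment sums  = dot(SH, per-iteration segment-coverage counts)
# so each (datatype, method) block reduces to one matmul and two einsums
# against weights precomputed once per behavioral datatype.


def bin_adjoint(u: np.ndarray, rate_hz: float) -> np.ndarray:
    """Adjoint of the 1 s centered moving-average binning operator.

    Satisfies dot(bin(x), u) = dot(x, bin_adjoint(u)) for every signal x,
    including the edge renormalization.
    """
    u = np.asarray(u, dtype=np.float64)
    T = u.shape[-1]
    w = one_second_window(rate_hz)
    h_lo, h_hi = w // 2, w - w // 2
    t = np.arange(T)
    wt = np.minimum(t + h_hi, T) - np.maximum(t - h_lo, 0)
    z = u / wt
    czp = np.zeros(u.shape[:-1] + (T + 1,))
    np.cumsum(z, axis=-1, out=czp[..., 1:])
    upper = np.minimum(t + h_lo, T - 1) + 1
    lower = np.maximum(t - h_hi + 1, 0)
    return czp[..., upper] - czp[..., lower]


@dataclass
class _StateInfo:
    seq: StateSequence
    layout: MatchedLayout
    n_oa: int = 0
    n_ca: int = 0
    # weight vectors, keyed by bin width: (T, 2) columns = (OA, CA) indicators
    V: dict = field(default_factory=dict)


@dataclass
class _MatchedWeights:
    """Per-setting matched-draw plans, folded into weight vectors."""

    w_true: np.ndarray  # (T,)
    W_null: np.ndarray  # (n_iter, T)
    n_draws_true: int
    n_draws_null: int


def _coverage_counts(plan2d: np.ndarray, lens: np.ndarray, layout: MatchedLayout, T: int) -> np.ndarray:
    """Per-row frame-coverage counts of the sampled CA segments, on the
    original frame clock."""
    n_rows = plan2d.shape[0]
    Tc = layout.valid_idx.size
    delta = np.zeros((n_rows, Tc + 1))
    rows = np.broadcast_to(np.arange(n_rows)[:, None], plan2d.shape)
    np.add.at(delta, (rows.ravel(), plan2d.ravel()), 1.0)
    np.add.at(delta, (rows.ravel(), (plan2d + lens[None, :]).ravel()), -1.0)
    cover_c = np.cumsum(delta[:, :-1], axis=1)
    if Tc == T:
        return cover_c
    cover = np.zeros((n_rows, T))
    cover[:, layout.valid_idx] = cover_c
    return cover


def _build_info(seq: StateSequence, bins_needed: set[str], rate_hz: float) -> tuple["_StateInfo", bool]:
    lay = MatchedLayout.from_states(seq)
    if lay.n_oa == 0 or lay.n_ca == 0:
        raise ValueError("no valid frames for one state")
    info = _StateInfo(seq=seq, layout=lay, n_oa=lay.n_oa, n_ca=lay.n_ca)
    T = seq.n_frames
    ind = np.zeros((T, 2))
    ind[seq.is_oa & seq.valid, 0] = 1.0
    ind[~seq.is_oa & seq.valid, 1] = 1.0
    for bw in bins_needed:
        info.V[bw] = ind if bw == "native" else bin_adjoint(ind.T, rate_hz).T
    return info, not lay.ok


def _build_matched_weights(
    info: _StateInfo,
    setting_id: int,
    bin_width: str,
    n_iterations: int,
    matched_draws: int,
    matched_draws_null: int,
    seed: int,
    rate_hz: float,
    T: int,
) -> _MatchedWeights:
    """Independent matched-draw plans for one setting (seeded by setting id),
    folded into segment-coverage weight vectors."""
    lay = info.layout
    rng_t = np.random.default_rng(np.random.SeedSequence([seed, 13, setting_id]))
    plan_true = draw_matched_plan(rng_t, lay, matched_draws)
    rng_n = np.random.default_rng(np.random.SeedSequence([seed, 12, setting_id]))
    plan_null = draw_matched_plan(
        rng_n, lay, n_iterations * matched_draws_null
    ).reshape(n_iterations, matched_draws_null, -1)
    w_true = _coverage_counts(plan_true, lay.oa_lens, lay, T).sum(axis=0)
    W = _coverage_counts(
        plan_null.reshape(n_iterations, -1),
        np.tile(lay.oa_lens, matched_draws_null),
        lay,
        T,
    )
    if bin_width != "native":
        w_true = bin_adjoint(w_true, rate_hz)
        W = bin_adjoint(W, rate_hz)
    return _MatchedWeights(
        w_true=w_true,
        W_null=W,
        n_draws_true=matched_draws,
        n_draws_null=matched_draws_null,
    )


def _si(oa: np.ndarray, ca: np.ndarray) -> tuple[np.ndarray, bool]:
    tot = oa + ca
    silent = tot <= 0
    si = np.where(silent, 0.0, (oa - ca) / np.where(silent, 1.0, tot))
    return si, bool(np.any(silent))


def _label_from_null(true_si: float, null: np.ndarray) -> int:
    arr = np.sort(null)
    n = arr.size
    hi = arr[int(np.ceil(0.975 * n)) - 1]
    lo = arr[int(np.floor(0.025 * n))]
    if true_si > hi:
        return 1
    if true_si < lo:
        return -1
    return 0


def state_sequences(session, behavs=("head", "body")) -> dict[str, StateSequence]:
    return {
        b: label_states(
            session.track, session.arena, b, session.neural_times, session.neural_rate_hz
        )
        for b in behavs
    }


def preprocess_traces_batch(raw: np.ndarray, rate_hz: float) -> np.ndarray:
    from .transforms import preprocess_trace

    return preprocess_trace(np.asarray(raw, dtype=np.float64), rate_hz)


def label_cohort(
    session,
    settings: list[ParameterSetting] | None = None,
    n_iterations: int = 200,
    seed: int = 0,
    matched_draws: int = 1000,
    matched_draws_null: int = 1000,
    state_seqs: dict[str, StateSequence] | None = None,
    record: bool = False,
) -> CohortLabels:
    """True SI, null SD and selectivity label for every (setting, neuron).

    ``state_seqs`` may carry pre-masked sequences (e.g. after boundary
    exclusion); otherwise head/body sequences are derived from the session's
    track.  All randomness derives from ``seed``.
    """
    if settings is None:
        settings, _ = enumerate_settings()
    rate = session.neural_rate_hz
    T = session.n_frames
    N = session.n_neurons

    behavs = sorted({s.behavioral_datatype for s in settings})
    datatypes = sorted({s.neural_datatype for s in settings})
    bins_needed = {s.bin_width for s in settings}
    matched_needed = any(s.matching == "matched" for s in settings)

    if state_seqs is None:
        state_seqs = state_sequences(session, behavs)
    infos: dict[str, _StateInfo] = {}
    unmatched: dict[str, bool] = {}
    for b in behavs:
        infos[b], unmatched[b] = _build_info(state_seqs[b], bins_needed, rate)

    # independent matched-draw plans per matched setting (seeded by id)
    matched_w: dict[int, _MatchedWeights] = {}
    if matched_needed:
        for si_, s in enumerate(settings):
            b = s.behavioral_datatype
            if s.matching == "matched" and not unmatched[b]:
                matched_w[si_] = _build_matched_weights(
                    infos[b], s.setting_id, s.bin_width, n_iterations,
                    matched_draws, matched_draws_null, seed, rate, T,
                )

    traces_pre = (
        preprocess_traces_batch(session.raw_traces, rate) if "traces" in datatypes else None
    )
    kernels = {d: Kernel(TAUS[d]).values(rate) for d in ("conv2s", "conv4s") if d in datatypes}

    # one (T, K) weight stack for the nonmatched state sums of all
    # (behav, bin) combinations, shared by every (datatype, method) block
    v_cols = []
    v_index = {}
    for b in behavs:
        for bw in sorted(bins_needed):
            v_index[(b, bw)] = len(v_cols)
            v_cols.append(infos[b].V[bw])
    V_all = np.concatenate(v_cols, axis=1)  # (T, 2*len(v_index))

    S = len(settings)
    out = CohortLabels(
        settings=list(settings),
        neuron_ids=np.arange(N),
        labels=np.zeros((S, N), dtype=np.int8),
        true_si=np.zeros((S, N)),
        null_sd=np.zeros((S, N)),
        flags=np.zeros((S, N), dtype=np.uint8),
        n_iterations=n_iterations,
    )

    by_dt_method: dict[tuple[str, str], list[int]] = {}
    for si_, s in enumerate(settings):
        by_dt_method.setdefault((s.neural_datatype, s.shuffle), []).append(si_)
    methods = sorted({m for _, m in by_dt_method})

    def avgs_from(sums: np.ndarray, b: str, bw: str):
        k = 2 * v_index[(b, bw)]
        info = infos[b]
        return sums[..., k] / info.n_oa, sums[..., k + 1] / info.n_ca

    for j in range(N):
        pos = np.asarray(session.events_pos[j], dtype=np.int64)
        amp = np.asarray(session.events_amp[j], dtype=np.float64)
        sigs: dict[str, np.ndarray] = {}
        if "events" in datatypes or kernels or any(m != "circshift" for m in methods):
            e = np.zeros(T)
            e[pos] = amp
            sigs["events"] = e
        for d, k in kernels.items():
            sigs[d] = np.convolve(sigs["events"], k)[:T]
        if traces_pre is not None:
            sigs["traces"] = traces_pre[j]

        # --- true SI per (datatype, bin, behav, matching)
        sig_mat = np.stack([sigs[d] for d in datatypes])
        true_sums = sig_mat @ V_all  # (n_d, K)
        for si_, s in enumerate(settings):
            di = datatypes.index(s.neural_datatype)
            b = s.behavioral_datatype
            info = infos[b]
            oa, ca_non = avgs_from(true_sums[di], b, s.bin_width)
            flag = 0
            matching = s.matching
            if matching == "matched" and unmatched[b]:
                matching = "nonmatched"
                flag |= FLAG_UNMATCHED
            if matching == "matched":
                mw = matched_w[si_]
                ca = float(sig_mat[di] @ mw.w_true) / (
                    mw.n_draws_true * info.layout.n_oa
                )
            else:
                ca = float(ca_non)
            tot = float(oa) + ca
            if tot <= 0:
                out.true_si[si_, j] = 0.0
                flag |= FLAG_SILENT
            else:
                out.true_si[si_, j] = (float(oa) - ca) / tot
            out.flags[si_, j] |= flag

        # --- nulls per (method, datatype); plans independent per datatype
        for (d, m), sidx in sorted(by_dt_method.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [seed, 11, int(j), METHOD_CODE[m], DATATYPE_CODE[d]]
                )
            )
            spec = ShuffleSpec(m, d, rate, n_iterations)
            no_events = pos.size == 0 and m in ("full_ecm", "partial_ecm")
            plans = draw_plans(rng, spec, T, pos, pos.size)
            if m == "randperm":
                E = batch_randperm_events(plans, amp, T)
                SH = E if d == "events" else batch_convolve(E, kernels[d])
            elif m == "circshift":
                SH = batch_circshift(sigs[d], plans)
            elif m == "full_ecm":
                SH = batch_full_ecm(sigs[d], full_ecm_boundaries(pos, T), plans)
            else:  # partial_ecm
                starts, lens = partial_ecm_chunks(pos, T, spec.chunk_frames)
                SH = batch_partial_ecm(sigs[d], starts, lens, plans)
            if record:
                out.debug[(j, d, m)] = SH.copy()

            sums = SH @ V_all  # (n_iter, K)
            for i in sidx:
                s = settings[i]
                b = s.behavioral_datatype
                info = infos[b]
                matching = s.matching
                if matching == "matched" and unmatched[b]:
                    matching = "nonmatched"
                oa, ca_non = avgs_from(sums, b, s.bin_width)
                if matching == "matched":
                    mw = matched_w[i]
                    ca = np.einsum("it,it->i", SH, mw.W_null) / (
                        mw.n_draws_null * info.layout.n_oa
                    )
                else:
                    ca = ca_non
                null, any_silent = _si(oa, ca)
                if record:
                    out.debug[("null", j, s.setting_id)] = null.copy()
                out.null_sd[i, j] = float(np.std(null, ddof=1))
                out.labels[i, j] = _label_from_null(out.true_si[i, j], null)
                if any_silent:
                    out.flags[i, j] |= FLAG_SILENT_SHUFFLE
                if no_events:
                    out.flags[i, j] |= FLAG_NO_EVENTS
                if out.flags[i, j] & FLAG_SILENT:
                    out.labels[i, j] = 0
    return out
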