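"""The batch engine must reproduce the per-iteration reference exactly.

The engine and the reference implementation share the same plan-drawing
helpers, so for identical seeds their null SI vectors and true SI values
must agree to float accumulation error across every setting of the grid.
"""

import numpy as np
import pytest

import caselect as cs
from caselect.engine import (
    batch_bin,
    batch_circshift,
    batch_convolve,
    batch_full_ecm,
    batch_partial_ecm,
    batch_randperm_events,
    bin_adjoint,
    label_cohort,
    state_sequences,
)
from caselect.selectivity import (
    DATATYPE_CODE,
    METHOD_CODE,
    MatchedLayout,
    ShuffleSpec,
    apply_circshift,
    apply_full_ecm,
    apply_partial_ecm,
    apply_randperm,
    draw_matched_plan,
    draw_plans,
    full_ecm_boundaries,
    null_distribution,
    partial_ecm_chunks,
    true_selectivity,
)
from caselect.transforms import Kernel, bin_signal, convolve_events, preprocess_trace

RATE = 20.0


def test_batch_bin_matches_reference(rng):
    X = rng.random((5, 137))
    B = batch_bin(X, RATE, "one_second")
    for i in range(5):
        assert np.allclose(B[i], bin_signal(X[i], RATE, "one_second"), atol=1e-12)
    assert batch_bin(X, RATE, "native") is X


def test_bin_adjoint_property(rng):
    # dot(bin(x), u) == dot(x, bin_adjoint(u)) for arbitrary x, u
    for T in (37, 300):
        x = rng.random(T)
        u = rng.standard_normal(T)
        lhs = bin_signal(x, RATE, "one_second") @ u
        rhs = x @ bin_adjoint(u, RATE)
        assert lhs == pytest.approx(rhs, rel=1e-12)


def test_batch_constructors_match_single_apply(rng):
    T = 300
    pos = np.sort(rng.choice(T, 9, replace=False))
    amp = rng.lognormal(0, 0.4, 9)
    sig = np.zeros(T)
    sig[pos] = amp
    conv = convolve_events(sig, RATE, 2.0)
    n_iter = 8

    spec = ShuffleSpec("randperm", "conv2s", RATE, n_iter)
    plans = draw_plans(np.random.default_rng(0), spec, T, pos, 9)
    E = batch_randperm_events(plans, amp, T)
    SH = batch_convolve(E, Kernel(2.0).values(RATE))
    for i in range(n_iter):
        assert np.allclose(SH[i], apply_randperm(plans[i], amp, T, "conv2s", RATE), atol=1e-9)

    shifts = draw_plans(np.random.default_rng(1), ShuffleSpec("circshift", "events", RATE, n_iter), T, pos, 9)
    SH = batch_circshift(conv, shifts)
    for i in range(n_iter):
        assert np.array_equal(SH[i], apply_circshift(conv, shifts[i]))

    perms = draw_plans(np.random.default_rng(2), ShuffleSpec("full_ecm", "events", RATE, n_iter), T, pos, 9)
    bounds = full_ecm_boundaries(pos, T)
    SH = batch_full_ecm(conv, bounds, perms)
    for i in range(n_iter):
        assert np.array_equal(SH[i], apply_full_ecm(conv, bounds, perms[i]))

    spec_p = ShuffleSpec("partial_ecm", "conv2s", RATE, n_iter)
    perms = draw_plans(np.random.default_rng(3), spec_p, T, pos, 9)
    starts, lens = partial_ecm_chunks(pos, T, spec_p.chunk_frames)
    SH = batch_partial_ecm(conv, starts, lens, perms)
    for i in range(n_iter):
        assert np.array_equal(SH[i], apply_partial_ecm(conv, starts, lens, perms[i]))


def test_engine_reproduces_reference_across_full_grid(small_session):
    """Exact (to accumulation error) agreement of null SI vectors, true SI
    and labels between the vectorized engine and the per-iteration loop,
    for every valid setting."""
    sess = small_session
    settings, _ = cs.enumerate_settings()
    seed, n_iter = 7, 20
    res = label_cohort(sess, settings, n_iterations=n_iter, seed=seed,
                       matched_draws=50, matched_draws_null=10, record=True)
    seqs = state_sequences(sess)
    T = sess.n_frames
    behavs = ["body", "head"]  # engine's sorted order
    lays = {b: MatchedLayout.from_states(seqs[b]) for b in behavs}
    for j in range(sess.n_neurons):
        pos = sess.events_pos[j]
        amp = sess.events_amp[j]
        e = np.zeros(T)
        e[pos] = amp
        sigs = {
            "events": e,
            "conv2s": convolve_events(e, RATE, 2.0),
            "conv4s": convolve_events(e, RATE, 4.0),
            "traces": preprocess_trace(sess.raw_traces[j], RATE),
        }
        for i, s in enumerate(settings):
            bi = behavs.index(s.behavioral_datatype)
            st = seqs[s.behavioral_datatype]
            lay = lays[s.behavioral_datatype]
            spec = ShuffleSpec(s.shuffle, s.neural_datatype, RATE, n_iter)
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [seed, 11, j, METHOD_CODE[s.shuffle], DATATYPE_CODE[s.neural_datatype]]
                )
            )
            plans = draw_plans(rng, spec, T, pos, len(pos))
            mp = None
            if s.matching == "matched" and lay.ok:
                rng_n = np.random.default_rng(
                    np.random.SeedSequence([seed, 12, s.setting_id])
                )
                mp = draw_matched_plan(rng_n, lay, n_iter * 10).reshape(n_iter, 10, -1)
            ref_null, _ = null_distribution(
                sigs[s.neural_datatype], pos, amp, st, s, RATE, n_iter,
                matched_plan=mp, plans=plans,
            )
            np.testing.assert_allclose(
                res.debug[("null", j, s.setting_id)], ref_null, atol=1e-9,
                err_msg=f"null mismatch at setting {s.setting_id} {s.tuple}",
            )
            rng_t = np.random.default_rng(
                np.random.SeedSequence([seed, 13, s.setting_id])
            )
            tp = (
                draw_matched_plan(rng_t, lay, 50)
                if (s.matching == "matched" and lay.ok)
                else None
            )
            ref_si, _ = true_selectivity(
                sigs[s.neural_datatype], st, s, RATE, matched_plan=tp
            )
            assert res.true_si[i, j] == pytest.approx(ref_si, abs=1e-10)


def test_engine_determinism(small_session):
    settings, _ = cs.enumerate_settings()
    a = label_cohort(small_session, settings[:6], n_iterations=30, seed=3)
    b = label_cohort(small_session, settings[:6], n_iterations=30, seed=3)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.null_sd, b.null_sd)


def test_strongly_selective_neurons_recovered(small_session):
    # neuron 0: rate 1.0 vs 0.2 (SI=2/3); neuron 2 mirrored; neuron 1 flat
    s = [x for x in cs.enumerate_settings()[0]
         if x.tuple == ("conv2s", "head", "native", "nonmatched", "randperm")]
    res = label_cohort(small_session, s, n_iterations=500, seed=9)
    assert res.labels[0].tolist() == [1, 0, -1]
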