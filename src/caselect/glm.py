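"""Regression-based selectivity from instantaneous activity.

Instead of comparing session-averaged activity, the neuron's activity Y_t
at every frame is regressed on a binary state indicator X_t (1 = open arm):

* identity link (linear model):  Y_t = b0 + b1 X_t + noise
* log link (Poisson GLM):        Y_t ~ Poisson(lambda_t), log lambda_t = b0 + b1 X_t

With a single binary regressor and no history terms both fits have closed
forms — b1 is the state mean difference (identity) or the log rate ratio
(log link) — which are used directly; for continuous activity the log-link
"Poisson" fit is the quasi-likelihood solution of the same score equations.
Significance is a permutation test on X_t: the regressor is shuffled in
time, b1 refit, and the empirical p-value is the fraction of shuffled |b1|
at or above the observed |b1|.  Labels: nonselective if p >= 0.05, else OA
for positive b1 and CA for negative b1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import StateSequence
from .settings import ParameterSetting

#: cap for the log-link slope under separation (a state mean of zero)
SEPARATION_CAP = 100.0


@dataclass(frozen=True)
class GlmFit:
    beta0: float
    beta1: float
    link: str
    separation: bool = False


def _state_means(signal: np.ndarray, is_oa: np.ndarray, valid: np.ndarray | None):
    signal = np.asarray(signal, dtype=float)
    is_oa = np.asarray(is_oa, dtype=bool)
    v = np.ones_like(is_oa) if valid is None else np.asarray(valid, dtype=bool)
    oa, ca = is_oa & v, ~is_oa & v
    if not oa.any() or not ca.any():
        raise ValueError("both states must be observed")
    return float(signal[oa].mean()), float(signal[ca].mean())


def fit_state_regression(
    signal: np.ndarray,
    is_oa: np.ndarray,
    link: str = "identity",
    valid: np.ndarray | None = None,
) -> GlmFit:
    """Closed-form fit of activity on the binary state regressor."""
    m1, m0 = _state_means(signal, is_oa, valid)
    if link == "identity":
        return GlmFit(beta0=m0, beta1=m1 - m0, link=link)
    if link != "log":
        raise ValueError(f"unknown link {link!r}")
    if np.any(np.asarray(signal, dtype=float) < 0):
        raise ValueError("log link requires nonnegative activity")
    if m0 <= 0 or m1 <= 0:
        sign = 1.0 if m1 > m0 else -1.0
        return GlmFit(
            beta0=np.log(m0) if m0 > 0 else -SEPARATION_CAP,
            beta1=sign * SEPARATION_CAP,
            link=link,
            separation=True,
        )
    return GlmFit(beta0=float(np.log(m0)), beta1=float(np.log(m1 / m0)), link=link)


def _beta1_batch(
    signal: np.ndarray, X: np.ndarray, link: str
) -> np.ndarray:
    """b1 for each column of a (T, B) binary regressor matrix."""
    s = np.asarray(signal, dtype=float)
    n1 = X.sum(axis=0)
    n0 = s.size - n1
    tot = s.sum()
    s1 = s @ X
    m1 = s1 / n1
    m0 = (tot - s1) / n0
    if link == "identity":
        return m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.log(m1 / m0)
    bad = (m1 <= 0) | (m0 <= 0)
    b[bad] = np.where(m1[bad] > m0[bad], SEPARATION_CAP, -SEPARATION_CAP)
    return b


def permutation_pvalue(
    signal: np.ndarray,
    is_oa: np.ndarray,
    link: str = "identity",
    n_perm: int = 100,
    seed: int = 0,
    valid: np.ndarray | None = None,
) -> float:
    """p = fraction of frame-shuffled regressors with |b1| >= observed |b1|."""
    fit = fit_state_regression(signal, is_oa, link, valid)
    v = np.ones_like(np.asarray(is_oa, dtype=bool)) if valid is None else np.asarray(valid, bool)
    s = np.asarray(signal, dtype=float)[v]
    x = np.asarray(is_oa, dtype=bool)[v]
    rng = np.random.default_rng(seed)
    X = np.stack([x[rng.permutation(x.size)] for _ in range(n_perm)], axis=1)
    null = _beta1_batch(s, X.astype(np.float64), link)
    return float(np.mean(np.abs(null) >= abs(fit.beta1)))


def glm_label(beta1: float, p: float, alpha: float = 0.05) -> str:
    if p >= alpha:
        return "NS"
    return "OA" if beta1 > 0 else "CA"


def glm_labels_for_cohort(
    session,
    setting: ParameterSetting,
    link: str,
    states: StateSequence,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """GLM selectivity of every neuron under one setting's datatype/bin/behavior.

    One set of regressor permutations is shared across neurons (the
    permutation acts on the behavioral side, which is common to the cohort).
    """
    from .engine import batch_bin
    from .selectivity import TAUS
    from .transforms import Kernel, preprocess_trace

    rate = session.neural_rate_hz
    T = session.n_frames
    N = session.n_neurons
    d = setting.neural_datatype
    sig = np.zeros((N, T))
    if d in ("events", "conv2s", "conv4s"):
        for i, (p, a) in enumerate(zip(session.events_pos, session.events_amp)):
            sig[i, p] = a
        if d in TAUS:
            k = Kernel(TAUS[d]).values(rate)
            import scipy.fft as sfft

            n = sfft.next_fast_len(T + k.size - 1, real=True)
            sig = np.maximum(
                sfft.irfft(sfft.rfft(sig, n, axis=1) * sfft.rfft(k, n), n, axis=1)[:, :T],
                0.0,
            )
    else:
        for i in range(N):
            sig[i] = preprocess_trace(session.raw_traces[i], rate)
    sig = batch_bin(sig, rate, setting.bin_width)

    v = states.valid
    x = states.is_oa[v]
    sv = sig[:, v]
    rng = np.random.default_rng(seed)
    X = np.stack([x[rng.permutation(x.size)] for _ in range(n_perm)], axis=1).astype(float)

    n1, n0 = int(x.sum()), int((~x).sum())
    m1 = sv[:, x].mean(axis=1)
    m0 = sv[:, ~x].mean(axis=1)
    if link == "identity":
        b1 = m1 - m0
        b0 = m0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            b1 = np.log(m1 / m0)
            b0 = np.log(m0)
        bad = (m1 <= 0) | (m0 <= 0)
        b1[bad] = np.where(m1[bad] > m0[bad], SEPARATION_CAP, -SEPARATION_CAP)
        b0[~np.isfinite(b0)] = -SEPARATION_CAP
    null = np.empty((N, n_perm))
    tot = sv.sum(axis=1)
    s1 = sv @ X
    mm1 = s1 / X.sum(axis=0)[None, :]
    mm0 = (tot[:, None] - s1) / (x.size - X.sum(axis=0))[None, :]
    if link == "identity":
        null = mm1 - mm0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            null = np.log(mm1 / mm0)
        bad = (mm1 <= 0) | (mm0 <= 0)
        null[bad] = np.where(mm1[bad] > mm0[bad], SEPARATION_CAP, -SEPARATION_CAP)
    p = np.mean(np.abs(null) >= np.abs(b1)[:, None], axis=1)
    return pd.DataFrame(
        {
            "neuron_id": np.arange(N),
            "link": link,
            "beta0": b0,
            "beta1": b1,
            "p_perm": p,
            "label": [glm_label(b, q) for b, q in zip(b1, p)],
        }
    )


def glm_si_consistency(glm_labels, si_labels) -> float:
    """Fraction of neurons with the same label under the GLM and SI routes."""
    a = np.asarray(glm_labels)
    b = np.asarray(si_labels)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("label vectors must be non-empty and of equal length")
    return float(np.mean(a == b))
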