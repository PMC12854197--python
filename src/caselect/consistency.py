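"""Agreement of labels, SI values and null SDs across setting pairs.

Label consistency between two settings is the fraction of neurons assigned
the same selectivity label by both.  Each pairwise value carries a 95%
bootstrap confidence interval (neurons resampled with replacement), and the
lower CI bound is thresholded into effect tiers: *small* if it exceeds 0.9,
*medium* if it exceeds 0.8 but not 0.9, *large* otherwise.

Whether disagreement arises from the SI values themselves or from the width
of the null distribution is resolved by congruence analysis: a robust
(bisquare IRLS) regression of one setting's per-neuron values on another's,
with a bootstrap 99% CI on the slope; a pair is incongruent when that CI
excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .settings import ParameterSetting

TIERS = ("small", "medium", "large")


def label_consistency(labels_a, labels_b) -> float:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("label vectors must be non-empty and of equal length")
    return float(np.mean(a == b))


def bootstrap_consistency_ci(
    labels_a, labels_b, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Percentile 95% CI over neuron-resampled label-consistency values."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = a.size
    if n < 2:
        raise ValueError("need at least two neurons")
    rng = np.random.default_rng(seed)
    agree = (a == b).astype(np.float64)
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    vals = counts @ agree / n
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class ConsistencyMatrix:
    settings: list[ParameterSetting]
    value: np.ndarray  # (S, S), diagonal 1
    ci_low: np.ndarray
    ci_high: np.ndarray
    tier: np.ndarray  # (S, S) of {"small","medium","large"}; diagonal "small"

    @property
    def n(self) -> int:
        return len(self.settings)

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n, dtype=bool)

    def tier_fractions(self) -> dict[str, float]:
        m = self.offdiag_mask()
        tot = m.sum()
        return {t: float(np.sum(self.tier[m] == t)) / tot for t in TIERS}

    def fraction_below(self, cutoff: float) -> float:
        m = self.offdiag_mask()
        return float(np.mean(self.value[m] < cutoff))

    def to_frame(self) -> pd.DataFrame:
        ids = [s.setting_id for s in self.settings]
        return pd.DataFrame(self.value, index=ids, columns=ids)


def assign_tiers(
    ci_low: np.ndarray, small: float = 0.9, medium: float = 0.8
) -> np.ndarray:
    tier = np.full(ci_low.shape, "large", dtype=object)
    tier[ci_low > medium] = "medium"
    tier[ci_low > small] = "small"
    return tier


def build_consistency_matrix(
    labels: np.ndarray,
    settings: list[ParameterSetting],
    exclude: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    tier_small: float = 0.9,
    tier_medium: float = 0.8,
) -> ConsistencyMatrix:
    """Pairwise consistency with bootstrap CIs from a (settings x neurons)
    label matrix.

    ``exclude`` is an optional (S, N) boolean mask of neurons to drop
    per-setting (silent/unmatched flags); a neuron is dropped from a pair if
    it is excluded under either member.  One shared neuron-resampling scheme
    is used for every pair (a joint bootstrap over the cohort).
    """
    labels = np.asarray(labels)
    S, N = labels.shape
    if len(settings) != S:
        raise ValueError("settings/labels mismatch")
    if exclude is None:
        exclude = np.zeros((S, N), dtype=bool)
    ok = ~exclude
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(N, np.full(N, 1.0 / N), size=n_boot).T.astype(np.float64)

    value = np.ones((S, S))
    lo = np.ones((S, S))
    hi = np.ones((S, S))
    for i in range(S):
        agree = (labels[i][None, :] == labels[i + 1 :]) & ok[i][None, :] & ok[i + 1 :]
        den_pt = (ok[i][None, :] & ok[i + 1 :]).astype(np.float64)
        if agree.size == 0:
            continue
        num = agree.astype(np.float64) @ counts
        den = den_pt @ counts
        pt_num = agree.sum(axis=1)
        pt_den = den_pt.sum(axis=1)
        if np.any(pt_den == 0):
            bad = int(np.flatnonzero(pt_den == 0)[0]) + i + 1
            raise ValueError(f"no jointly valid neurons for setting pair ({i},{bad})")
        vals = num / np.where(den == 0, np.nan, den)
        li, hi_i = np.nanpercentile(vals, [2.5, 97.5], axis=1)
        value[i, i + 1 :] = value[i + 1 :, i] = pt_num / pt_den
        lo[i, i + 1 :] = lo[i + 1 :, i] = li
        hi[i, i + 1 :] = hi[i + 1 :, i] = hi_i
    tier = assign_tiers(lo, tier_small, tier_medium)
    np.fill_diagonal(tier, "small")
    return ConsistencyMatrix(list(settings), value, lo, hi, tier)


# ---------------------------------------------------------------------------
# robust slope congruence


def _irls_slope(
    x: np.ndarray, y: np.ndarray, c: float = 4.685, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Bisquare IRLS slope/intercept for each row of (B, n) arrays."""
    w = np.ones_like(x)
    a = np.zeros(x.shape[0])
    b = np.zeros(x.shape[0])
    for it in range(n_iter):
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)
        swy = (w * y).sum(axis=1)
        swxx = (w * x * x).sum(axis=1)
        swxy = (w * x * y).sum(axis=1)
        denom = sw * swxx - swx**2
        denom = np.where(np.abs(denom) < 1e-300, np.nan, denom)
        b = (sw * swxy - swx * swy) / denom
        a = (swy - b * swx) / sw
        r = y - a[:, None] - b[:, None] * x
        scale = np.median(np.abs(r), axis=1) / 0.6744897501960817
        scale = np.where(scale <= 0, 1e-12, scale)
        u = r / (c * scale[:, None])
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return b, a


def congruence_slope(
    x_values,
    y_values,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.99,
) -> tuple[float, tuple[float, float], bool]:
    """Robust slope of y on x with a percentile-bootstrap CI.

    Returns (slope, (ci_low, ci_high), incongruent) where ``incongruent``
    means the CI excludes 1.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    if x.size < 10:
        raise ValueError("need at least 10 finite pairs")
    if np.var(x) == 0:
        raise ValueError("degenerate x (zero variance)")
    slope = float(_irls_slope(x[None, :], y[None, :])[0][0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    bs = _irls_slope(x[idx], y[idx])[0]
    alpha = (1.0 - ci) / 2.0 * 100
    lo, hi = np.nanpercentile(bs, [alpha, 100 - alpha])
    incongruent = not (lo <= 1.0 <= hi)
    return slope, (float(lo), float(hi)), bool(incongruent)


@dataclass
class CongruenceMatrix:
    settings: list[ParameterSetting]
    slope: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    incongruent: np.ndarray  # bool


def build_congruence_matrix(
    values: np.ndarray,
    settings: list[ParameterSetting],
    exclude: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.99,
) -> CongruenceMatrix:
    """Pairwise robust-slope congruence of per-neuron values (SI or null SD)."""
    values = np.asarray(values, dtype=float)
    S, N = values.shape
    if exclude is None:
        exclude = np.zeros((S, N), dtype=bool)
    slope = np.ones((S, S))
    lo = np.ones((S, S))
    hi = np.ones((S, S))
    inc = np.zeros((S, S), dtype=bool)
    for i in range(S):
        for j in range(i + 1, S):
            okij = ~(exclude[i] | exclude[j])
            s, (l, h), f = congruence_slope(
                values[i, okij], values[j, okij], n_boot=n_boot,
                seed=seed + 7919 * i + j, ci=ci,
            )
            slope[i, j] = slope[j, i] = s
            lo[i, j] = lo[j, i] = l
            hi[i, j] = hi[j, i] = h
            inc[i, j] = inc[j, i] = f
    return CongruenceMatrix(list(settings), slope, lo, hi, inc)


MECHANISM_CODES = ("consistent", "si_only", "nullsd_only", "both", "neither")


def mechanism_matrix(
    consistency: ConsistencyMatrix,
    si_congruence: CongruenceMatrix,
    nullsd_congruence: CongruenceMatrix,
) -> tuple[np.ndarray, dict[str, float]]:
    """Attribute label inconsistency to SI changes, null-SD changes, or both.

    Pairs whose label-consistency tier is *small* are coded ``consistent``;
    the remaining (off-diagonal) pairs are coded by which of the two
    congruence tests failed.  Returns the coded matrix and the fractions of
    si_only / nullsd_only / both / neither over the filtered pairs.
    """
    S = consistency.n
    code = np.full((S, S), "consistent", dtype=object)
    filt = (consistency.tier != "small") & consistency.offdiag_mask()
    si_bad = si_congruence.incongruent
    sd_bad = nullsd_congruence.incongruent
    code[filt & si_bad & sd_bad] = "both"
    code[filt & si_bad & ~sd_bad] = "si_only"
    code[filt & ~si_bad & sd_bad] = "nullsd_only"
    code[filt & ~si_bad & ~sd_bad] = "neither"
    tot = int(filt.sum())
    fracs = {
        k: (float(np.sum(code[filt] == k)) / tot if tot else 0.0)
        for k in ("both", "si_only", "nullsd_only", "neither")
    }
    return code, fracs


def boundary_comparison(
    session,
    band_cm: float,
    settings: list[ParameterSetting],
    n_iterations: int = 200,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Small-tier fraction of the consistency matrix before vs after
    excluding near-boundary frames (body center within ``band_cm`` of an
    OA-CA boundary line)."""
    from .behavior import exclude_boundary
    from .engine import FLAG_SILENT, label_cohort, state_sequences

    seqs = state_sequences(session)
    masked = {
        b: exclude_boundary(session.track, session.arena, band_cm, seq, session.neural_times)
        for b, seq in seqs.items()
    }
    out = {}
    for tag, sq in (("before", seqs), ("after", masked)):
        res = label_cohort(
            session, settings, n_iterations=n_iterations, seed=seed, state_seqs=sq
        )
        excl = (res.flags & FLAG_SILENT) > 0
        mat = build_consistency_matrix(
            res.labels, settings, exclude=excl, n_boot=n_boot, seed=seed
        )
        out[tag] = mat
        out[f"small_fraction_{tag}"] = mat.tier_fractions()["small"]
    return out
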