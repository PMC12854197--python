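"""Objective selection of the optimal analysis setting.

*Accuracy* of a setting is the percentage of template neurons (neurons whose
raw event-rate disparity between arms is so extreme — or so flat — that
their label is beyond doubt) that the setting labels correctly.
*Robustness* is derived from the pairwise label-consistency matrix: each
level of each parameter gets an average robustness (mean consistency over
all setting pairs that both contain the level), and a setting's combined
robustness is the mean of its five levels' values, scaled to 0-100.

Settings are ranked lexicographically (accuracy first, then combined
robustness); the optimal set holds the settings with accuracy 100 and
combined robustness above the 95th percentile.  Stability of the selection
is validated by stratified bootstrap resampling of the cohort, and its
generalizability by repeated 60/40 stratified holdout splits scored by the
Spearman correlation between training- and testing-side rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .behavior import StateSequence
from .settings import ParameterSetting

LABEL_CODE = {"OA": 1, "NS": 0, "CA": -1}


@dataclass
class TemplateSet:
    oa_ids: np.ndarray
    ca_ids: np.ndarray
    ns_ids: np.ndarray
    criteria: tuple[float, float] = (0.85, 0.05)

    @property
    def all_ids(self) -> np.ndarray:
        return np.concatenate([self.oa_ids, self.ca_ids, self.ns_ids])

    @property
    def truth_codes(self) -> np.ndarray:
        return np.concatenate(
            [
                np.ones(self.oa_ids.size, dtype=np.int8),
                -np.ones(self.ca_ids.size, dtype=np.int8),
                np.zeros(self.ns_ids.size, dtype=np.int8),
            ]
        )

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.oa_ids.size, self.ca_ids.size, self.ns_ids.size)


def normalized_rate_difference(
    events_pos: list[np.ndarray], states: StateSequence
) -> np.ndarray:
    """Per-neuron (r_OA - r_CA)/(r_OA + r_CA) from raw event counts.

    Rates are event counts per valid in-state frame (head-centric states, no
    binning, no matching); silent neurons get NaN.
    """
    oa = states.is_oa & states.valid
    ca = ~states.is_oa & states.valid
    n_oa, n_ca = int(oa.sum()), int(ca.sum())
    if n_oa == 0 or n_ca == 0:
        raise ValueError("state unobserved")
    out = np.full(len(events_pos), np.nan)
    for i, pos in enumerate(events_pos):
        p = np.asarray(pos, dtype=np.int64)
        r_oa = float(oa[p].sum()) / n_oa
        r_ca = float(ca[p].sum()) / n_ca
        tot = r_oa + r_ca
        out[i] = np.nan if tot == 0 else (r_oa - r_ca) / tot
    return out


def find_templates(
    events_pos: list[np.ndarray],
    states: StateSequence,
    selective_threshold: float = 0.85,
    nonselective_threshold: float = 0.05,
) -> TemplateSet:
    """Neurons with incontrovertible label by raw rate disparity."""
    d = normalized_rate_difference(events_pos, states)
    with np.errstate(invalid="ignore"):
        oa = np.flatnonzero(d > selective_threshold)
        ca = np.flatnonzero(d < -selective_threshold)
        ns = np.flatnonzero(np.abs(d) <= nonselective_threshold)
    return TemplateSet(oa, ca, ns, (selective_threshold, nonselective_threshold))


def accuracy(
    label_codes: np.ndarray, templates: TemplateSet
) -> tuple[float, dict[str, float]]:
    """Percent of templates labeled with their template type, plus breakdown."""
    if templates.all_ids.size == 0:
        raise ValueError("empty template set")
    codes = np.asarray(label_codes)
    per_type = {}
    for name, ids, code in (
        ("OA", templates.oa_ids, 1),
        ("CA", templates.ca_ids, -1),
        ("NS", templates.ns_ids, 0),
    ):
        per_type[name] = (
            100.0 * float(np.mean(codes[ids] == code)) if ids.size else np.nan
        )
    total = 100.0 * float(np.mean(codes[templates.all_ids] == templates.truth_codes))
    return total, per_type


def level_robustness(
    values: np.ndarray, settings: list[ParameterSetting], level: str
) -> float:
    """Mean consistency over unordered setting pairs that both contain ``level``."""
    has = np.array([level in s.levels for s in settings])
    idx = np.flatnonzero(has)
    if idx.size < 2:
        raise ValueError(f"level {level!r} present in fewer than 2 settings")
    sub = np.asarray(values)[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def level_robustness_table(
    values: np.ndarray, settings: list[ParameterSetting]
) -> dict[str, float]:
    levels = sorted({lv for s in settings for lv in s.levels})
    return {lv: level_robustness(values, settings, lv) for lv in levels}


def combined_robustness(setting: ParameterSetting, table: dict[str, float]) -> float:
    """Mean of the five constituent level-robustness values, on a 0-100 scale."""
    return 100.0 * float(np.mean([table[lv] for lv in setting.levels]))


def score_settings(
    consistency_values: np.ndarray,
    labels: np.ndarray,
    settings: list[ParameterSetting],
    templates: TemplateSet,
) -> pd.DataFrame:
    """Accuracy + combined robustness per setting, ranked."""
    table = level_robustness_table(consistency_values, settings)
    rows = []
    for i, s in enumerate(settings):
        acc, per_type = accuracy(labels[i], templates)
        rows.append(
            {
                "setting_id": s.setting_id,
                "tuple": ",".join(s.tuple),
                "accuracy": acc,
                "combined_robustness": combined_robustness(s, table),
                **{f"accuracy_{k}": v for k, v in per_type.items()},
            }
        )
    df = pd.DataFrame(rows)
    return rank_settings(df)


def _composite(df: pd.DataFrame) -> np.ndarray:
    # accuracy dominates robustness; robustness < 1000 so this ordering is
    # exactly lexicographic
    return df["accuracy"].to_numpy() * 1000.0 + df["combined_robustness"].to_numpy()


def rank_settings(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["rank"] = rankdata(-_composite(df), method="min").astype(int)
    return df.sort_values(["rank", "setting_id"]).reset_index(drop=True)


def select_optimal(
    scores: pd.DataFrame, robustness_percentile: float = 95.0
) -> pd.DataFrame:
    """Settings with accuracy 100 and robustness above the given percentile."""
    cut = np.percentile(scores["combined_robustness"], robustness_percentile)
    return scores[
        (scores["accuracy"] == 100.0) & (scores["combined_robustness"] > cut)
    ].reset_index(drop=True)


def first_and_second(df: pd.DataFrame) -> tuple[int, int]:
    """Winning and runner-up setting ids; ties break to the smaller id."""
    order = np.lexsort((df["setting_id"].to_numpy(), -_composite(df)))
    ids = df["setting_id"].to_numpy()[order]
    return int(ids[0]), int(ids[1])


# ---------------------------------------------------------------------------
# resampling machinery shared by bootstrap validation and holdout CV


@dataclass
class _PairCache:
    """Per-pair agreement indicators for fast consistency on neuron subsets."""

    settings: list[ParameterSetting]
    pair_idx: np.ndarray  # (P, 2)
    agree: np.ndarray  # (P, N) float32
    ok: np.ndarray  # (P, N) float32 (pairwise inclusion)
    level_members: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        labels: np.ndarray,
        settings: list[ParameterSetting],
        exclude: np.ndarray | None,
    ) -> "_PairCache":
        S, N = labels.shape
        ok_s = np.ones((S, N), dtype=bool) if exclude is None else ~exclude
        pairs = np.array([(i, j) for i in range(S) for j in range(i + 1, S)])
        agree = np.empty((len(pairs), N), dtype=np.float32)
        ok = np.empty((len(pairs), N), dtype=np.float32)
        for p, (i, j) in enumerate(pairs):
            both = ok_s[i] & ok_s[j]
            agree[p] = ((labels[i] == labels[j]) & both).astype(np.float32)
            ok[p] = both.astype(np.float32)
        cache = cls(list(settings), pairs, agree, ok)
        levels = sorted({lv for s in settings for lv in s.levels})
        has = {lv: np.array([lv in s.levels for s in settings]) for lv in levels}
        for lv, h in has.items():
            cache.level_members[lv] = np.flatnonzero(h[pairs[:, 0]] & h[pairs[:, 1]])
        return cache

    def consistency_values(self, weights: np.ndarray) -> np.ndarray:
        """(P, B) consistency of each pair under B neuron-weight vectors."""
        num = self.agree @ weights
        den = self.ok @ weights
        return num / np.where(den == 0, np.nan, den)

    def combined_robustness(self, cons: np.ndarray) -> np.ndarray:
        """(S, B) combined robustness from (P, B) pairwise consistencies.

        Levels with no qualifying pair (possible on small setting subsets)
        contribute nothing to the mean of a setting's level values.
        """
        B = cons.shape[1]
        level_rob = {
            lv: (np.nanmean(cons[m], axis=0) if m.size else np.full(B, np.nan))
            for lv, m in self.level_members.items()
        }
        out = np.stack(
            [
                100.0 * np.nanmean(np.stack([level_rob[lv] for lv in s.levels]), axis=0)
                for s in self.settings
            ]
        )
        return out


def _strata(templates: TemplateSet, n_total: int) -> list[np.ndarray]:
    non = np.setdiff1d(np.arange(n_total), templates.all_ids)
    return [templates.oa_ids, templates.ca_ids, templates.ns_ids, non]


def _template_accuracy_batch(
    labels: np.ndarray, idx: np.ndarray, truth: np.ndarray
) -> np.ndarray:
    """(S,) accuracy over a resampled/selected template index vector."""
    return 100.0 * np.mean(labels[:, idx] == truth[None, :], axis=1)


def bootstrap_validate(
    labels: np.ndarray,
    settings: list[ParameterSetting],
    templates: TemplateSet,
    n_iter: int = 500,
    seed: int = 0,
    exclude: np.ndarray | None = None,
) -> dict:
    """Stability of the optimal setting under stratified cohort resampling.

    Each iteration resamples neurons with replacement within strata (each
    template type and the nontemplates, preserving counts), recomputes
    accuracy (templates only) and combined robustness (all neurons), and
    records the first- and second-ranked settings.  Returns frequency tables
    over iterations.
    """
    S, N = np.asarray(labels).shape
    cache = _PairCache.build(labels, settings, exclude)
    rng = np.random.default_rng(seed)
    strata = _strata(templates, N)
    firsts, seconds = [], []
    ids = np.array([s.setting_id for s in settings])
    for _ in range(n_iter):
        parts = [
            st[rng.integers(0, st.size, st.size)] if st.size else st for st in strata
        ]
        idx = np.concatenate(parts)
        t_idx = np.concatenate(parts[:3])
        truth = np.concatenate(
            [
                np.full(strata[0].size, 1, dtype=np.int8),
                np.full(strata[1].size, -1, dtype=np.int8),
                np.full(strata[2].size, 0, dtype=np.int8),
            ]
        )
        acc = _template_accuracy_batch(labels, t_idx, truth)
        w = np.bincount(idx, minlength=N).astype(np.float32)[:, None]
        rob = cache.combined_robustness(cache.consistency_values(w))[:, 0]
        comp = acc * 1000.0 + rob
        order = np.lexsort((ids, -comp))
        firsts.append(int(ids[order[0]]))
        seconds.append(int(ids[order[1]]))
    return {
        "first_counts": pd.Series(firsts).value_counts(),
        "second_counts": pd.Series(seconds).value_counts(),
        "n_iter": n_iter,
    }


def split_counts(sizes: list[int], train_frac: float = 0.6) -> list[tuple[int, int]]:
    """(train, test) sizes per stratum: nearest-integer training share,
    remainder to testing."""
    out = []
    for n in sizes:
        tr = int(np.floor(n * train_frac + 0.5))
        out.append((tr, n - tr))
    return out


def holdout_cv(
    labels: np.ndarray,
    settings: list[ParameterSetting],
    templates: TemplateSet,
    n_iter: int = 200,
    train_frac: float = 0.6,
    seed: int = 0,
    exclude: np.ndarray | None = None,
) -> dict:
    """Train/test generalizability of the setting ranking.

    Neurons are proportionally split per stratum; accuracy and robustness
    are computed independently on each side, settings ranked on each side
    (average ranks for ties), and the per-split Spearman rho between the two
    rankings is recorded.  ``train_frac = 1.0`` is the degenerate
    train-equals-test split used as a sanity check.
    """
    S, N = np.asarray(labels).shape
    cache = _PairCache.build(labels, settings, exclude)
    rng = np.random.default_rng(seed)
    strata = _strata(templates, N)
    degenerate = train_frac >= 1.0
    if not degenerate:
        for st in strata[:3]:
            if st.size < 2:
                raise ValueError("stratum too small to split: a template type has < 2 members")
    ids = np.array([s.setting_id for s in settings])
    rhos, first_tr, first_te, second_tr, second_te = [], [], [], [], []
    truth_all = {
        0: np.int8(1), 1: np.int8(-1), 2: np.int8(0)
    }
    for _ in range(n_iter):
        tr_parts, te_parts = [], []
        for st in strata:
            if st.size == 0:
                tr_parts.append(st)
                te_parts.append(st)
                continue
            if degenerate:
                tr_parts.append(st)
                te_parts.append(st)
                continue
            perm = st[rng.permutation(st.size)]
            n_tr = split_counts([st.size], train_frac)[0][0]
            tr_parts.append(perm[:n_tr])
            te_parts.append(perm[n_tr:])
        sides = {}
        for tag, parts in (("train", tr_parts), ("test", te_parts)):
            t_idx = np.concatenate(parts[:3])
            truth = np.concatenate(
                [np.full(parts[k].size, truth_all[k]) for k in range(3)]
            )
            acc = _template_accuracy_batch(labels, t_idx, truth)
            idx = np.concatenate(parts)
            w = np.bincount(idx, minlength=N).astype(np.float32)[:, None]
            rob = cache.combined_robustness(cache.consistency_values(w))[:, 0]
            comp = acc * 1000.0 + rob
            order = np.lexsort((ids, -comp))
            sides[tag] = comp
            if tag == "train":
                first_tr.append(int(ids[order[0]]))
                second_tr.append(int(ids[order[1]]))
            else:
                first_te.append(int(ids[order[0]]))
                second_te.append(int(ids[order[1]]))
        rho = spearmanr(sides["train"], sides["test"]).statistic
        rhos.append(float(rho))
    return {
        "rho": np.asarray(rhos),
        "median_rho": float(np.median(rhos)),
        "first_train": pd.Series(first_tr).value_counts(),
        "first_test": pd.Series(first_te).value_counts(),
        "second_train": pd.Series(second_tr).value_counts(),
        "second_test": pd.Series(second_te).value_counts(),
        "n_iter": n_iter,
    }
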