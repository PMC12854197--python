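"""Task-state sequences from tracking data.

The elevated zero maze is an annular platform split into four quadrants, two
walled ("closed arm", CA) and two exposed ("open arm", OA).  The task state
at any instant is which arm type the animal occupies, judged from a single
tracked coordinate — either the head centroid or the body centroid.  Because
the maze is effectively one-dimensional, zone membership reduces to the
angular position of the chosen centroid, and distances to the OA-CA boundary
lines are arc lengths along the ring's center line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Arena:
    """Ring geometry.  Angles in degrees, lengths in cm.

    ``open_quadrants`` are half-open angular sectors [lo, hi) that count as
    open arm; everything else on the ring is closed arm.  Defaults follow a
    40 cm inner-diameter maze with a 6.1 cm wide platform and boundaries at
    the four cardinal angles.
    """

    inner_diameter: float = 40.0
    platform_width: float = 6.1
    open_quadrants: tuple[tuple[float, float], ...] = ((0.0, 90.0), (180.0, 270.0))

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.platform_width

    @property
    def centerline_radius(self) -> float:
        return self.inner_radius + self.platform_width / 2.0

    @property
    def boundary_angles(self) -> tuple[float, ...]:
        out = []
        for lo, hi in self.open_quadrants:
            out.extend((lo % 360.0, hi % 360.0))
        return tuple(sorted(set(out)))

    def is_open(self, angles_deg: np.ndarray) -> np.ndarray:
        a = np.asarray(angles_deg, dtype=float) % 360.0
        out = np.zeros(a.shape, dtype=bool)
        for lo, hi in self.open_quadrants:
            lo, hi = lo % 360.0, hi % 360.0
            if lo <= hi:
                out |= (a >= lo) & (a < hi)
            else:  # wraps through 0
                out |= (a >= lo) | (a < hi)
        return out

    def boundary_arc_distance(self, angles_deg: np.ndarray) -> np.ndarray:
        """Arc distance (cm, along the center line) to the nearest OA-CA boundary."""
        a = np.asarray(angles_deg, dtype=float) % 360.0
        bounds = np.asarray(self.boundary_angles)
        diff = np.abs(a[..., None] - bounds[None, :])
        ang = np.minimum(diff, 360.0 - diff).min(axis=-1)
        return np.deg2rad(ang) * self.centerline_radius


@dataclass
class StateSequence:
    """Per-neural-frame task state with a validity mask."""

    is_oa: np.ndarray  # bool, True = open arm
    valid: np.ndarray  # bool, False = excluded frame
    source: str  # "head" | "body"
    rate_hz: float

    def __post_init__(self) -> None:
        self.is_oa = np.asarray(self.is_oa, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.is_oa.shape != self.valid.shape:
            raise ValueError("is_oa and valid must have equal length")

    @property
    def n_frames(self) -> int:
        return self.is_oa.size


@dataclass(frozen=True)
class Bout:
    """Maximal run of one state over the valid frames.

    ``start_frame``/``end_frame`` are half-open [start, end) indices of the
    first and one-past-last *valid* frame of the run on the original frame
    clock; when frames have been masked out, the run may skip masked frames
    in between, and ``n_frames`` (valid frames only) is what determines
    ``duration_s``.
    """

    state: str  # "OA" | "CA"
    start_frame: int
    end_frame: int
    n_frames: int
    duration_s: float


def nearest_sample_index(sample_times: np.ndarray, query_times: np.ndarray) -> np.ndarray:
    """Index of the sample nearest in time to each query; ties go to the earlier sample."""
    st = np.asarray(sample_times, dtype=float)
    qt = np.asarray(query_times, dtype=float)
    if st.size == 0:
        raise ValueError("empty track")
    pos = np.searchsorted(st, qt)
    pos = np.clip(pos, 1, st.size - 1)
    left, right = st[pos - 1], st[pos]
    take_right = (qt - left) > (right - qt)  # strict: ties resolve to the earlier sample
    idx = pos - 1 + take_right.astype(int)
    # queries before the first / after the last sample clamp naturally
    idx[qt <= st[0]] = 0
    idx[qt >= st[-1]] = st.size - 1
    return idx


def track_angles(track: pd.DataFrame, datatype: str) -> np.ndarray:
    if datatype not in ("head", "body"):
        raise ValueError(f"behavioral datatype must be 'head' or 'body', got {datatype!r}")
    x = track[f"{datatype}_x"].to_numpy(dtype=float)
    y = track[f"{datatype}_y"].to_numpy(dtype=float)
    return np.degrees(np.arctan2(y, x)) % 360.0


def label_states(
    track: pd.DataFrame,
    arena: Arena,
    datatype: str,
    neural_times: np.ndarray,
    rate_hz: float,
) -> StateSequence:
    """Assign OA/CA per neural frame from the nearest-in-time track sample.

    The track table must contain ``time`` plus ``head_x/head_y/body_x/body_y``
    columns.  Zone identity is categorical, so nearest-neighbor alignment is
    used rather than interpolation.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    t = track["time"].to_numpy(dtype=float)
    qt = np.asarray(neural_times, dtype=float)
    if qt.size and (qt[-1] < t[0] or qt[0] > t[-1]):
        raise ValueError("track and neural time ranges are disjoint")
    idx = nearest_sample_index(t, qt)
    angles = track_angles(track, datatype)[idx]
    return StateSequence(
        is_oa=arena.is_open(angles),
        valid=np.ones(qt.size, dtype=bool),
        source=datatype,
        rate_hz=rate_hz,
    )


def extract_bouts(states: StateSequence) -> list[Bout]:
    """Run-length encode the valid frames into alternating OA/CA bouts."""
    va = np.flatnonzero(states.valid)
    if va.size == 0:
        return []
    sv = states.is_oa[va]
    change = np.flatnonzero(np.diff(sv.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [sv.size]))
    bouts = []
    for s, e in zip(starts, ends):
        bouts.append(
            Bout(
                state="OA" if sv[s] else "CA",
                start_frame=int(va[s]),
                end_frame=int(va[e - 1]) + 1,
                n_frames=int(e - s),
                duration_s=float(e - s) / states.rate_hz,
            )
        )
    return bouts


def boundary_band_width(tracks: Sequence[pd.DataFrame]) -> float:
    """Median head-to-body centroid distance pooled over animals (cm).

    This distance is the minimum spatial scale at which head and body can
    occupy different arms, and therefore the natural half-width of the
    ambiguous near-boundary band.
    """
    dists = []
    for tr in tracks:
        dx = tr["head_x"].to_numpy(dtype=float) - tr["body_x"].to_numpy(dtype=float)
        dy = tr["head_y"].to_numpy(dtype=float) - tr["body_y"].to_numpy(dtype=float)
        dists.append(np.hypot(dx, dy))
    if not dists or sum(d.size for d in dists) == 0:
        raise ValueError("no frames")
    return float(np.median(np.concatenate(dists)))


def exclude_boundary(
    track: pd.DataFrame,
    arena: Arena,
    band_cm: float,
    states: StateSequence,
    neural_times: np.ndarray,
) -> StateSequence:
    """Mask frames whose body center lies within ``band_cm`` of an OA-CA boundary.

    Distances are arc lengths along the ring center line.  The mask only ever
    shrinks the valid set, so exclusions compose monotonically.
    """
    if band_cm < 0:
        raise ValueError("band_cm must be nonnegative")
    t = track["time"].to_numpy(dtype=float)
    idx = nearest_sample_index(t, np.asarray(neural_times, dtype=float))
    d = arena.boundary_arc_distance(track_angles(track, "body")[idx])
    near = d <= band_cm
    return replace(states, valid=states.valid & ~near)
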