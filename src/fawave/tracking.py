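"""Linking FA segments into trajectories (LAP tracker).

Frame-to-frame correspondence is posed as a linear assignment problem
(Jaqaman-style): the cost of linking segment i (frame t) to segment j
(frame t+1) is their squared centroid distance, gated at a maximum
displacement of 2 um; the alternative no-link (birth/death) cost is the
squared gate.  Merging of tracks is allowed — when a track ends next to a
segment already claimed by another track, the larger-area parent continues
through the merged segment and the other parent terminates.  Tracks whose
source segment splits, or that move excessively (path length > 5x net
displacement while netting > 2 um), are flagged and excluded.  Only tracks
spanning at least 7 consecutive frames are retained.  Gap closing is off:
retention is defined on consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import FASegment

MAX_DISPLACEMENT_UM = 2.0
MIN_TRACK_FRAMES = 7


@dataclass
class FATrack:
    """One FA trajectory: ordered segments on consecutive frames."""

    track_id: int
    segments: list[FASegment] = field(default_factory=list)
    excluded: set[str] = field(default_factory=set)  # {"split", "excessive_movement"}
    merged_from: list[int] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [s.frame for s in self.segments]

    @property
    def centroids_um(self) -> np.ndarray:
        return np.asarray([s.centroid_um for s in self.segments])

    @property
    def n_frames(self) -> int:
        return len(self.segments)

    def path_stats_um(self) -> tuple[float, float]:
        """(total path length, net displacement) of the centroid track."""
        c = self.centroids_um
        total = float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())
        net = float(np.linalg.norm(c[-1] - c[0]))
        return total, net


def _link_frame_pair(
    prev: list[FASegment], curr: list[FASegment], max_disp_um: float
) -> list[tuple[int, int]]:
    """Solve the gated LAP between two frames; returns (i_prev, j_curr)
    links.  Uses the augmented cost matrix with no-link cost = gate^2."""
    n, m = len(prev), len(curr)
    if n == 0 or m == 0:
        return []
    big = 1e12
    gate2 = max_disp_um**2
    pc = np.asarray([s.centroid_um for s in prev])
    cc = np.asarray([s.centroid_um for s in curr])
    d2 = ((pc[:, None, :] - cc[None, :, :]) ** 2).sum(-1)
    cost = np.full((n + m, n + m), big)
    link = np.where(d2 <= gate2, d2, big)
    cost[:n, :m] = link
    cost[np.arange(n) + 0, np.arange(n) + m] = gate2  # deaths
    cost[np.arange(m) + n, np.arange(m) + 0] = gate2  # births
    cost[n:, m:] = link.T  # lower-right completes the LAP (standard trick)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and d2[r, c] <= gate2
    ]


def track_fas(
    segments_per_frame: list[list[FASegment]],
    max_disp_um: float = MAX_DISPLACEMENT_UM,
    min_len_frames: int = MIN_TRACK_FRAMES,
    excessive_path_ratio: float = 5.0,
) -> list[FATrack]:
    """Link per-frame segment lists into retained FA tracks.

    Returns tracks spanning >= ``min_len_frames`` consecutive frames with
    no exclusion flags; merge events keep the larger-area parent (ties to
    the lower track id).
    """
    next_id = 0
    active: dict[int, FATrack] = {}  # track id -> track (last segment in prev frame)
    finished: list[FATrack] = []

    prev_segments: list[FASegment] = []
    prev_owner: list[int] = []  # track id owning each prev segment
    for t, curr in enumerate(segments_per_frame):
        links = _link_frame_pair(prev_segments, curr, max_disp_um)
        owner_of_curr: dict[int, int] = {}
        linked_prev: set[int] = set()
        for i_prev, j_curr in links:
            owner_of_curr[j_curr] = prev_owner[i_prev]
            linked_prev.add(i_prev)

        # merge detection: an unlinked dying track whose end lies within the
        # gate of an already-claimed current segment merges into it
        for i_prev in range(len(prev_segments)):
            if i_prev in linked_prev:
                continue
            tid = prev_owner[i_prev]
            pc = np.asarray(prev_segments[i_prev].centroid_um)
            for j_curr, other_tid in list(owner_of_curr.items()):
                d = np.linalg.norm(pc - np.asarray(curr[j_curr].centroid_um))
                if d <= max_disp_um:
                    # two parents -> one segment; larger-area parent continues
                    area_this = prev_segments[i_prev].area_um2
                    other_prev = active[other_tid].segments[-1]
                    keep_this = (
                        area_this > other_prev.area_um2
                        or (area_this == other_prev.area_um2 and tid < other_tid)
                    )
                    if keep_this:
                        owner_of_curr[j_curr] = tid
                        active[tid].merged_from.append(other_tid)
                        finished.append(active.pop(other_tid))
                        linked_prev.add(i_prev)
                    else:
                        active[other_tid].merged_from.append(tid)
                        finished.append(active.pop(tid))
                        linked_prev.add(i_prev)
                    break

        # split detection: a newborn segment near a parent that also has a
        # continuation flags the parent as split
        for j_curr in range(len(curr)):
            if j_curr in owner_of_curr:
                continue
            cc = np.asarray(curr[j_curr].centroid_um)
            for i_prev in linked_prev:
                d = np.linalg.norm(cc - np.asarray(prev_segments[i_prev].centroid_um))
                if d <= max_disp_um:
                    active[prev_owner[i_prev]].excluded.add("split")
                    break

        # retire tracks with no continuation
        surviving = set(owner_of_curr.values())
        for tid in list(active):
            if tid not in surviving:
                finished.append(active.pop(tid))

        # extend continued tracks, start new ones
        new_prev_owner: list[int] = [0] * len(curr)
        for j_curr, seg in enumerate(curr):
            tid = owner_of_curr.get(j_curr)
            if tid is None:
                tid = next_id
                next_id += 1
                active[tid] = FATrack(track_id=tid)
            active[tid].segments.append(seg)
            new_prev_owner[j_curr] = tid
        prev_segments, prev_owner = curr, new_prev_owner

    finished.extend(active.values())

    retained: list[FATrack] = []
    for tr in sorted(finished, key=lambda tr: tr.track_id):
        if tr.n_frames < min_len_frames:
            continue
        total, net = tr.path_stats_um()
        if net > MAX_DISPLACEMENT_UM and total > excessive_path_ratio * net:
            tr.excluded.add("excessive_movement")
        if tr.excluded:
            continue
        # retained tracks satisfy both gates by construction
        assert tr.n_frames >= min_len_frames
        steps = np.linalg.norm(np.diff(tr.centroids_um, axis=0), axis=1)
        assert np.all(steps <= max_disp_um + 1e-9)
        retained.append(tr)
    return retained


def nearest_neighbor_tracks(
    segments_per_frame: list[list[FASegment]],
    max_disp_um: float = MAX_DISPLACEMENT_UM,
    min_len_frames: int = MIN_TRACK_FRAMES,
) -> list[FATrack]:
    """Greedy nearest-neighbour linker: the independent oracle for regimes
    where every inter-object separation exceeds twice the largest per-frame
    displacement (links are then unambiguous)."""
    next_id = 0
    active: dict[int, FATrack] = {}
    finished: list[FATrack] = []
    prev_segments: list[FASegment] = []
    prev_owner: list[int] = []
    for curr in segments_per_frame:
        taken: set[int] = set()
        owner_of_curr: dict[int, int] = {}
        order = []
        for i, p in enumerate(prev_segments):
            for j, c in enumerate(curr):
                d = np.linalg.norm(np.asarray(p.centroid_um) - np.asarray(c.centroid_um))
                if d <= max_disp_um:
                    order.append((d, i, j))
        for d, i, j in sorted(order):
            if i in taken or j in owner_of_curr:
                continue
            taken.add(i)
            owner_of_curr[j] = prev_owner[i]
        surviving = set(owner_of_curr.values())
        for tid in list(active):
            if tid not in surviving:
                finished.append(active.pop(tid))
        new_owner = [0] * len(curr)
        for j, seg in enumerate(curr):
            tid = owner_of_curr.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
                active[tid] = FATrack(track_id=tid)
            active[tid].segments.append(seg)
            new_owner[j] = tid
        prev_segments, prev_owner = curr, new_owner
    finished.extend(active.values())
    return [tr for tr in sorted(finished, key=lambda tr: tr.track_id)
            if tr.n_frames >= min_len_frames]


def classify_assembly(
    track: FATrack,
    baseline_frames: int = 3,
    threshold: float = 0.30,
) -> str:
    """Assembly state from the normalized size index (area x brightness).

    The baseline is the mean size index over the first ``baseline_frames``;
    ``assembling`` if any later value rises more than 30% above baseline,
    ``disassembling`` if any falls more than 30% below, classified by
    whichever crossing happens first; otherwise ``stable``.  Invariant to
    global intensity rescaling.
    """
    if track.n_frames < baseline_frames + 1:
        raise ValueError(
            f"track too short to classify: {track.n_frames} frames "
            f"< baseline {baseline_frames} + 1"
        )
    idx = np.asarray([s.size_index for s in track.segments], dtype=float)
    base = idx[:baseline_frames].mean()
    if base == 0:
        return "stable"
    rel = idx[baseline_frames:] / base
    up = np.nonzero(rel > 1 + threshold)[0]
    dn = np.nonzero(rel < 1 - threshold)[0]
    if up.size and dn.size:
        return "assembling" if up[0] < dn[0] else "disassembling"
    if up.size:
        return "assembling"
    if dn.size:
        return "disassembling"
    return "stable"
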