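"""Calling ligand deposits from cytoneme line scans (kymographs).

A deposit is the release of a ligand punctum from the cytoneme tip onto
a receiving cell. It is called when a punctum is seen traversing the
cytoneme toward the tip, arrives within the tip zone, and then is
absent in the successive frame without retrograde movement.

Puncta are intensity maxima exceeding 1.5x the background cytoneme
fluorescence on a line scan (i.e. >50% above background); background is
the median of the line profile excluding detected puncta. Detections
are linked frame-to-frame by greedy nearest-neighbour association, and
tracks are classified anterograde / retrograde / stationary by their
net displacement toward the tip with a dead-band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError

__all__ = [
    "Kymograph",
    "PunctumTrack",
    "DepositEvent",
    "estimate_background",
    "detect_puncta",
    "link_tracks",
    "call_deposits",
    "deposits_from_kymograph",
]


@dataclass(frozen=True)
class Kymograph:
    """Line-scan intensity matrix: rows are time frames (``dt`` s apart),
    columns positions along the cytoneme (``dx`` um apart). ``tip_index``
    is the column of the cytoneme tip."""

    data: np.ndarray
    dt: float
    dx: float
    tip_index: int
    background: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dx <= 0:
            raise ParameterError("dt and dx must be positive")
        if not 0 <= self.tip_index < self.data.shape[1]:
            raise ParameterError("tip_index outside the position axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def tip_position(self) -> float:
        return self.tip_index * self.dx

    @property
    def length(self) -> float:
        return (self.data.shape[1] - 1) * self.dx


@dataclass
class PunctumTrack:
    """A linked punctum trajectory along the cytoneme."""

    frames: list[int]
    positions: list[float]      # um from the cell body
    intensities: list[float]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def direction(self, tip_position: float, dead_band: float = 0.5) -> str:
        """Classify by net displacement toward the tip.

        Movement reducing the distance to the tip by more than
        ``dead_band`` um is anterograde; increasing it, retrograde;
        anything within the dead-band, stationary.
        """
        d0 = abs(tip_position - self.positions[0])
        d1 = abs(tip_position - self.positions[-1])
        net_toward_tip = d0 - d1
        if net_toward_tip > dead_band:
            return "anterograde"
        if net_toward_tip < -dead_band:
            return "retrograde"
        return "stationary"


@dataclass(frozen=True)
class DepositEvent:
    """A called tip-release event, in seconds."""

    t_deposit: float
    cytoneme_id: str
    track_index: int


def estimate_background(
    profile: np.ndarray, factor: float = 1.5, exclusion_radius: int = 2
) -> float:
    """Median line-scan fluorescence excluding detected puncta.

    Two-pass: an initial median seeds detection, then pixels within
    ``exclusion_radius`` of any detected punctum are dropped and the
    median recomputed.
    """
    profile = np.asarray(profile, dtype=float)
    med = float(np.median(profile))
    if med <= 0:
        return med
    peaks = detect_puncta(profile, med, factor)
    keep = np.ones(profile.size, dtype=bool)
    for idx, _ in peaks:
        lo = max(0, idx - exclusion_radius)
        keep[lo : idx + exclusion_radius + 1] = False
    if keep.any():
        med = float(np.median(profile[keep]))
    return med


def detect_puncta(
    profile: np.ndarray, background: float, factor: float = 1.5
) -> list[tuple[int, float]]:
    """Detect puncta on one line-scan row.

    Local maxima with intensity strictly greater than
    ``factor x background``; maxima closer than 2 pixels are merged to
    the brighter one. Returns ``(pixel_index, intensity)`` pairs.
    """
    if background <= 0:
        raise ParameterError(f"background must be positive, got {background}")
    if factor <= 1:
        raise ParameterError(f"factor must exceed 1, got {factor}")
    profile = np.asarray(profile, dtype=float)
    # height uses the next float above the threshold: the criterion is
    # strictly greater than factor x background
    peaks, props = sps.find_peaks(
        profile, height=np.nextafter(factor * background, np.inf), distance=3
    )
    # an isolated bright first/last pixel is not a local max for find_peaks;
    # include edges explicitly
    out = [(int(i), float(profile[i])) for i in peaks]
    for edge in (0, profile.size - 1):
        neighbor = 1 if edge == 0 else profile.size - 2
        if (
            profile.size >= 2
            and profile[edge] > factor * background
            and profile[edge] > profile[neighbor]
            and all(abs(edge - i) >= 3 for i, _ in out)
        ):
            out.append((edge, float(profile[edge])))
    return sorted(out)


def link_tracks(
    puncta_by_frame: list[list[tuple[float, float]]],
    max_step: float = 1.0,
    intensity_gate: float = 0.55,
) -> list[PunctumTrack]:
    """Greedy nearest-neighbour frame-to-frame linking.

    ``puncta_by_frame[f]`` holds ``(position_um, intensity)`` detections
    for frame ``f``. Pairs between consecutive frames are linked in
    order of increasing distance, within ``max_step`` um. A detection
    dimmer than ``intensity_gate`` x the track's median intensity is not
    linked (a genuine punctum keeps its brightness; barely-threshold
    noise does not), unless the gate is set to 0. Tracks spanning fewer
    than two frames are dropped.
    """
    if max_step <= 0:
        raise ParameterError("max_step must be positive")
    active: list[PunctumTrack] = []
    finished: list[PunctumTrack] = []
    for f, detections in enumerate(puncta_by_frame):
        candidates = []
        for ti, tr in enumerate(active):
            if tr.frames[-1] != f - 1:
                continue
            gate = intensity_gate * float(np.median(tr.intensities))
            for di, (pos, inten) in enumerate(detections):
                dist = abs(pos - tr.positions[-1])
                if dist <= max_step and inten >= gate:
                    candidates.append((dist, ti, di))
        candidates.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, ti, di in candidates:
            if ti in used_tracks or di in used_dets:
                continue
            pos, inten = puncta_by_frame[f][di]
            active[ti].frames.append(f)
            active[ti].positions.append(pos)
            active[ti].intensities.append(inten)
            used_tracks.add(ti)
            used_dets.add(di)
        # retire tracks that were not extended
        still_active = []
        for ti, tr in enumerate(active):
            if tr.frames[-1] >= f - 1:
                still_active.append(tr)
            else:
                finished.append(tr)
        active = still_active
        for di, (pos, inten) in enumerate(detections):
            if di not in used_dets:
                active.append(PunctumTrack([f], [pos], [inten]))
    finished.extend(active)
    return [tr for tr in finished if tr.n_frames >= 2]


def stitch_tracks(
    tracks: list[PunctumTrack],
    max_dist: float = 1.0,
    max_gap_frames: int = 2,
) -> list[PunctumTrack]:
    """Stitch broken trajectories back together.

    Detection noise occasionally splits one punctum's trajectory into
    consecutive tracks (e.g. a double local maximum spawns a competing
    fragment). A track ending at frame ``f`` / position ``p`` absorbs a
    track starting within ``max_gap_frames`` frames of ``f`` and within
    ``max_dist`` um of ``p``; overlapping frames keep the earlier
    track's samples.
    """
    tracks = sorted(tracks, key=lambda tr: tr.frames[0])
    merged: list[PunctumTrack] = []
    for tr in tracks:
        best = None
        best_dist = max_dist
        for cand in merged:
            gap = tr.frames[0] - cand.frames[-1]
            if 0 <= gap <= max_gap_frames:
                dist = abs(tr.positions[0] - cand.positions[-1])
                if dist <= best_dist:
                    best, best_dist = cand, dist
        if best is None:
            merged.append(PunctumTrack(list(tr.frames), list(tr.positions),
                                       list(tr.intensities)))
        else:
            for f, p, i in zip(tr.frames, tr.positions, tr.intensities):
                if f > best.frames[-1]:
                    best.frames.append(f)
                    best.positions.append(p)
                    best.intensities.append(i)
    return merged


def call_deposits(
    tracks: list[PunctumTrack],
    kymo: Kymograph,
    tip_zone: float = 1.0,
    dead_band: float = 0.5,
    min_track_frames: int = 5,
) -> list[DepositEvent]:
    """Call deposits from linked tracks.

    A track yields a deposit when (a) it is anterograde — the punctum
    traversed the cytoneme toward the tip, (b) its last position lies
    within ``tip_zone`` um of the tip, (c) it terminates before the end
    of the recording (the punctum is absent in the successive frame),
    and (d) no retrograde step exceeding the dead-band occurred over its
    final three frames. The deposit time is the first frame after tip
    arrival at which the punctum is gone.
    """
    if tip_zone <= 0:
        raise ParameterError("tip_zone must be positive")
    events = []
    tip = kymo.tip_position
    for idx, tr in enumerate(tracks):
        if tr.n_frames < min_track_frames:
            continue
        if tr.direction(tip, dead_band) != "anterograde":
            continue
        # a single dangling retrograde point right before disappearance is
        # detection noise, not retraction (retraction persists as a track);
        # trim at most one such trailing sample
        if (
            tr.n_frames > min_track_frames
            and abs(tip - tr.positions[-2]) < abs(tip - tr.positions[-1]) - dead_band
            and abs(tip - tr.positions[-2]) <= tip_zone
        ):
            tr = PunctumTrack(tr.frames[:-1], tr.positions[:-1],
                              tr.intensities[:-1])
        if abs(tip - tr.positions[-1]) > tip_zone:
            continue
        if tr.frames[-1] >= kymo.n_frames - 1:
            continue  # still present at the end of the recording
        tail = tr.positions[-3:]
        tail_dist = [abs(tip - p) for p in tail]
        if any(
            tail_dist[k + 1] - tail_dist[k] > dead_band
            for k in range(len(tail_dist) - 1)
        ):
            continue  # retrograde movement near the tip
        t_dep = (tr.frames[-1] + 1) * kymo.dt
        events.append(DepositEvent(t_dep, cytoneme_id="", track_index=idx))
    return events


def deposits_from_kymograph(
    kymo: Kymograph,
    factor: float = 1.5,
    max_step_um_per_frame: float | None = None,
    tip_zone: float = 1.0,
    dead_band: float = 0.5,
    cytoneme_id: str = "",
) -> tuple[list[DepositEvent], list[PunctumTrack]]:
    """End-to-end deposit calling on one kymograph.

    Background is estimated per recording (median excluding puncta);
    each frame's line profile is scanned for puncta, detections are
    linked, and deposits called. ``max_step_um_per_frame`` defaults to
    2 um or 4x the pixel pitch, whichever is larger.
    """
    bg = kymo.background
    if bg is None:
        bg = estimate_background(kymo.data.ravel(), factor)
    if max_step_um_per_frame is None:
        max_step_um_per_frame = max(2.0, 4.0 * kymo.dx)
    per_frame = []
    for row in kymo.data:
        dets = detect_puncta(row, bg, factor)
        per_frame.append([(i * kymo.dx, inten) for i, inten in dets])
    tracks = link_tracks(per_frame, max_step_um_per_frame)
    tracks = stitch_tracks(tracks, max_dist=max_step_um_per_frame)
    events = call_deposits(tracks, kymo, tip_zone, dead_band)
    events = [
        DepositEvent(e.t_deposit, cytoneme_id, e.track_index) for e in events
    ]
    return events, tracks
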