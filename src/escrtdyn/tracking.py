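"""Frame-to-frame linking into 3D tracks, validity filters, classification.

Linking solves, per frame, the optimal one-to-one assignment between active
track ends and detections (Hungarian algorithm on squared displacement,
gated at ``max_displacement`` per elapsed frame); unassigned detections
seed new tracks and track ends survive up to ``max_gap`` missing frames.
Situations where several track ends compete for one detection (or one end
for several detections) are flagged as merge/split and excluded from the
valid set, as are tracks touching the series ends or the volume border.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import SpotFit
from .geometry import PointSpreadFunction

__all__ = ["Track", "link_tracks", "filter_valid", "classify_track",
           "classify_tracks"]

REJECTION_REASONS = ("merged", "split", "touches_series_start",
                     "touches_series_end", "near_border", "too_short",
                     "not_significant")


@dataclass
class Track:
    track_id: int
    spots: list[SpotFit] = field(default_factory=list)   # one per occupied frame
    gap_frames: list[int] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    class_label: str = "unclassified"
    rejection_reasons: list[str] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots])

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) positions in nm, (x, y, z)."""
        return np.array([s.position for s in self.spots])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([s.amplitude for s in self.spots])

    @property
    def start(self) -> int:
        return self.spots[0].frame

    @property
    def end(self) -> int:
        return self.spots[-1].frame

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    def mean_step(self) -> float:
        """Mean frame-to-frame displacement, nm (0 for single-spot tracks)."""
        if len(self.spots) < 2:
            return 0.0
        pos, fr = self.positions, self.frames
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1) / np.diff(fr)
        return float(steps.mean())


def link_tracks(frames: list[list[SpotFit]],
                max_displacement: float = 800.0,
                max_gap: int = 2) -> list[Track]:
    """Link per-frame detections into tracks.

    ``frames[t]`` holds the accepted detections of frame ``t`` (may be
    empty). The gate scales with the number of elapsed frames so that a
    track bridging a gap may move proportionally further.
    """
    big = 1e12
    finished: list[Track] = []
    active: list[Track] = []
    next_id = 0

    for t, dets in enumerate(frames):
        # retire tracks whose gap exceeded max_gap
        still = []
        for tr in active:
            if t - tr.end - 1 > max_gap:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        n_tr, n_de = len(active), len(dets)
        if n_tr and n_de:
            tp = np.array([tr.spots[-1].position for tr in active])
            dp = np.array([d.position for d in dets])
            elapsed = np.array([t - tr.end for tr in active], dtype=float)
            d2 = np.sum((tp[:, None, :] - dp[None, :, :]) ** 2, axis=2)
            gate = (max_displacement * elapsed)[:, None]
            allowed = d2 <= gate ** 2

            # competition flags: two ends gated onto one detection or one
            # end onto two detections makes the assignment ambiguous
            per_det = allowed.sum(axis=0)
            per_tr = allowed.sum(axis=1)
            for j in np.where(per_det >= 2)[0]:
                for i in np.where(allowed[:, j])[0]:
                    active[i].flags.add("merged")
            for i in np.where(per_tr >= 2)[0]:
                active[i].flags.add("split")

            cost = np.where(allowed, d2, big)
            size = n_tr + n_de
            mat = np.full((size, size), big)
            mat[:n_tr, :n_de] = cost
            death = (max_displacement * elapsed) ** 2
            mat[np.arange(n_tr), n_de + np.arange(n_tr)] = death
            birth = max_displacement ** 2
            mat[n_tr + np.arange(n_de), np.arange(n_de)] = birth
            mat[n_tr:, n_de:] = 0.0
            rows, cols = linear_sum_assignment(mat)
            assigned_det: dict[int, int] = {}
            unassigned_tr = []
            for r, c in zip(rows, cols):
                if r < n_tr and c < n_de and allowed[r, c]:
                    tr = active[r]
                    for g in range(tr.end + 1, t):
                        tr.gap_frames.append(g)
                    tr.spots.append(dets[c])
                    assigned_det[c] = r
                elif r < n_tr:
                    unassigned_tr.append(r)

            # merge: a losing track end also gated onto an assigned detection
            for r in unassigned_tr:
                for c in np.where(allowed[r])[0]:
                    if c in assigned_det:
                        active[r].flags.add("merged")
                        active[assigned_det[c]].flags.add("merged")
            # split: a detection that seeds a new track while also being
            # within the gate of an already-continued track
            new_tracks = []
            for c in range(n_de):
                if c not in assigned_det:
                    for r in np.where(allowed[:, c])[0]:
                        active[r].flags.add("split")
                    nt = Track(next_id, [dets[c]])
                    if allowed[:, c].any():
                        nt.flags.add("split")
                    new_tracks.append(nt)
                    next_id += 1
            active.extend(new_tracks)
        elif n_de:
            for d in dets:
                active.append(Track(next_id, [d]))
                next_id += 1

    finished.extend(active)
    finished.sort(key=lambda tr: (tr.start, tr.track_id))
    for new_id, tr in enumerate(finished):
        tr.track_id = new_id
    return finished


def filter_valid(tracks: list[Track],
                 bounds_nm: tuple[float, float, float],
                 n_series_frames: int,
                 border_margin: float = 1500.0,
                 min_frames: int = 3,
                 ) -> tuple[list[Track], list[Track], list[Track]]:
    """Partition tracks into (valid, persistent, rejected).

    Valid tracks never merge/split, begin after the first and end before
    the last frame of the series (their lifetimes are fully included),
    keep every position at least ``border_margin`` nm from every volume
    edge, and span at least ``min_frames`` frames. Tracks present in every
    frame are routed to the persistent set (lifetime longer than the
    series); everything else is rejected with machine-readable reasons.

    ``bounds_nm`` is the (z, y, x) extent of the imaged volume in nm.
    """
    zmax, ymax, xmax = bounds_nm
    valid: list[Track] = []
    persistent: list[Track] = []
    rejected: list[Track] = []
    for tr in tracks:
        if tr.start == 0 and tr.end == n_series_frames - 1:
            tr.flags.add("persistent")
            persistent.append(tr)
            continue
        reasons = []
        if "merged" in tr.flags:
            reasons.append("merged")
        if "split" in tr.flags:
            reasons.append("split")
        if tr.start == 0:
            tr.flags.add("touches_series_start")
            reasons.append("touches_series_start")
        if tr.end == n_series_frames - 1:
            tr.flags.add("touches_series_end")
            reasons.append("touches_series_end")
        pos = tr.positions  # (x, y, z)
        lim = np.array([xmax, ymax, zmax])
        if np.any(pos < border_margin) or np.any(pos > lim - border_margin):
            tr.flags.add("near_border")
            reasons.append("near_border")
        if tr.n_frames < min_frames:
            reasons.append("too_short")
        if any(not s.accepted for s in tr.spots):
            reasons.append("not_significant")
        if reasons:
            tr.rejection_reasons = reasons
            rejected.append(tr)
        else:
            valid.append(tr)
    return valid, persistent, rejected


def classify_track(track: Track, psf: PointSpreadFunction,
                   reference_intensity: float,
                   mobility_threshold: float = 100.0,
                   size_tolerance: float = 0.3) -> str:
    """Classify one track as class I, class II or unclassified.

    Diffraction-limited (median fitted lateral sigma within
    ``1 + size_tolerance`` of the PSF) and mobile -> I. Extended, or static
    but at least 3x the class-I reference intensity -> II. A dim static
    diffraction-limited object is ambiguous -> unclassified.
    """
    med_sxy = float(np.median([s.fitted_sigmas[0] for s in track.spots]))
    limited = med_sxy <= (1.0 + size_tolerance) * psf.sigma_xy
    mobile = track.mean_step() >= mobility_threshold
    bright = (reference_intensity > 0 and
              float(np.mean(track.amplitudes)) >= 3.0 * reference_intensity)
    if limited and mobile:
        return "I"
    if (not limited) or ((not mobile) and bright):
        return "II"
    return "unclassified"


def classify_tracks(tracks: list[Track], psf: PointSpreadFunction,
                    mobility_threshold: float = 100.0,
                    size_tolerance: float = 0.3) -> list[Track]:
    """Two-pass classification of a track collection.

    The first pass labels diffraction-limited mobile tracks class I; the
    median mean-amplitude of those then serves as the intensity reference
    for the static/bright class II rule in the second pass.
    """
    means = []
    for tr in tracks:
        med_sxy = float(np.median([s.fitted_sigmas[0] for s in tr.spots]))
        if (med_sxy <= (1.0 + size_tolerance) * psf.sigma_xy
                and tr.mean_step() >= mobility_threshold):
            means.append(float(np.mean(tr.amplitudes)))
    ref = float(np.median(means)) if means else 0.0
    for tr in tracks:
        tr.class_label = classify_track(tr, psf, ref,
                                        mobility_threshold, size_tolerance)
    return tracks
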