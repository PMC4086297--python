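"""Per-channel profile database and the day-by-day tracking loop.

Each channel keeps a set of *profiles*: cross-day histories of putative
single units.  When a new session's spike-sorted units arrive, the tracker

1. reduces each unit to a snapshot (smoothed average waveform + normalised
   ISIH),
2. computes a dissimilarity matrix between the channel's active profiles and
   the incoming units, sending each vector through the trained match
   classifier to obtain a boolean membership matrix plus signed scores,
3. refines the membership matrix into a one-to-one assignment by exhaustive
   back-tracking that first maximises the number of units attached to
   existing profiles and then the total score (classifier confidence),
4. appends matched units to their profiles, opens new profiles for the rest,
   and drops profiles that have not been seen for more than the stability
   window (counted in sessions).

Two instance-selection strategies decide *which* stored instance of a profile
a unit is compared against: FMD (first matching dissimilarity) scans the
most recent in-window instances newest-first and stops at the first match;
MMD (maximum matching dissimilarity) evaluates all in-window instances and
keeps the match with the largest score.  Only active profiles take part in
comparisons; dropped profiles never re-enter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import isih as isih_mod
from . import waveform as wf_mod
from .classifiers import (
    FEATURE_SETS,
    ISIH_FEATURES,
    MATCH,
    DissimilarityVector,
    classify,
)
from .isih import ISIH, IsihBinning
from .waveform import SpikeUnit, Waveform

__all__ = [
    "TrackerConfig",
    "UnitSnapshot",
    "Profile",
    "ProfileDB",
    "MembershipMatrices",
    "Match",
    "TrackReport",
    "snapshot",
    "pair_dissimilarity",
    "select_instance_fmd",
    "select_instance_mmd",
    "build_matrices",
    "assign",
    "update_profiles",
    "track_session",
]

ACTIVE = "active"
DROPPED = "dropped"

FMD_INSTANCE_CAP = 7  # newest-first comparisons per profile under FMD


@dataclass(frozen=True)
class TrackerConfig:
    """Tracking parameters.

    ``stability_window`` is counted in sessions: a profile unseen for more
    than this many sessions is dropped.  ``smoothing_sigma`` is the Gaussian
    kernel width (samples) applied to average waveforms before any feature
    computation.
    """

    stability_window: int = 7
    strategy: str = "MMD"
    feature_set_id: int = 4
    classifier: str = "RVM"
    smoothing_sigma: float = 1.0
    binning: IsihBinning = field(default_factory=IsihBinning)

    def __post_init__(self) -> None:
        if self.stability_window < 1:
            raise ValueError("stability_window must be >= 1 session")
        if self.strategy.upper() not in ("FMD", "MMD"):
            raise ValueError("strategy must be FMD or MMD")
        if self.feature_set_id not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set_id}")
        object.__setattr__(self, "strategy", self.strategy.upper())


@dataclass
class UnitSnapshot:
    """One day's derived record of a unit: features used in all comparisons."""

    day: int
    channel_id: int
    unit_label: int
    waveform: Waveform
    isih: Optional[ISIH]
    spike_count: int


@dataclass
class Profile:
    """Cross-day history of one putative single unit on one channel."""

    profile_id: int
    channel_id: int
    instances: list[UnitSnapshot] = field(default_factory=list)
    status: str = ACTIVE
    last_seen_day: int = -1

    def instance_on(self, day: int) -> Optional[UnitSnapshot]:
        for inst in self.instances:
            if inst.day == day:
                return inst
        return None


class ProfileDB:
    """All-channel profile store with per-channel monotone profile IDs."""

    def __init__(self) -> None:
        self.channels: dict[int, list[Profile]] = {}
        self._next_id: dict[int, int] = {}

    def profiles(self, channel_id: int) -> list[Profile]:
        return self.channels.setdefault(channel_id, [])

    def active_profiles(self, channel_id: int) -> list[Profile]:
        return [p for p in self.profiles(channel_id) if p.status == ACTIVE]

    def next_id(self, channel_id: int) -> int:
        """Next free profile ID on a channel (monotone, never reused)."""
        return self._next_id.get(channel_id, 0)

    def set_next_id(self, channel_id: int, value: int) -> None:
        self._next_id[channel_id] = value

    def all_profiles(self) -> Iterable[Profile]:
        for plist in self.channels.values():
            yield from plist


def snapshot(unit: SpikeUnit, cfg: TrackerConfig) -> UnitSnapshot:
    """Average, smooth, and histogram a unit into its comparison record.

    Units with a single spike get a waveform but no ISIH; such snapshots are
    valid only under waveform-only feature sets.
    """
    avg = wf_mod.average_waveform(unit)
    smoothed = wf_mod.smooth_waveform(avg, cfg.smoothing_sigma)
    h = isih_mod.build_isih(unit.timestamps, cfg.binning) if unit.n_spikes >= 2 else None
    return UnitSnapshot(
        day=unit.day,
        channel_id=unit.channel_id,
        unit_label=unit.unit_label,
        waveform=smoothed,
        isih=h,
        spike_count=unit.n_spikes,
    )


def pair_dissimilarity(
    a: UnitSnapshot, b: UnitSnapshot, feature_set_id: int
) -> DissimilarityVector:
    """Dissimilarity vector between snapshot ``a`` and reference ``b``.

    ``b`` (by convention the stored profile instance) is the normalising
    argument of the asymmetric waveform measures PH and PT.
    """
    if a.channel_id != b.channel_id:
        raise ValueError("snapshots come from different channels")
    names = FEATURE_SETS[feature_set_id]
    needs_isih = any(n in ISIH_FEATURES for n in names)
    if needs_isih and (a.isih is None or b.isih is None):
        raise ValueError(
            f"feature set {feature_set_id} needs ISIH features but a snapshot "
            "has no ISIH (single-spike unit)"
        )
    values = []
    for name in names:
        if name == "PC":
            values.append(wf_mod.pearson_dissimilarity(a.waveform, b.waveform))
        elif name == "PH":
            values.append(wf_mod.peak_height_dissimilarity(a.waveform, b.waveform))
        elif name == "PT":
            values.append(wf_mod.peak_time_dissimilarity(a.waveform, b.waveform))
        elif name == "PM":
            values.append(wf_mod.peak_matching_dissimilarity(a.waveform, b.waveform))
        elif name == "KLD":
            values.append(isih_mod.kl_divergence_sym(a.isih, b.isih))
        elif name == "BD":
            values.append(isih_mod.bhattacharyya(a.isih, b.isih))
        elif name == "KS":
            values.append(isih_mod.ks_statistic(a.isih, b.isih))
        elif name == "EMD":
            values.append(isih_mod.earth_movers(a.isih, b.isih))
    # identical snapshots can leave tiny negative round-off in PC/PM
    return DissimilarityVector(np.maximum(values, 0.0), feature_set_id)


@dataclass
class Match:
    """A classifier-accepted comparison against one stored instance."""

    vector: DissimilarityVector
    score: float
    instance_day: int


def _in_window_instances(p: Profile, day: int, window: int) -> list[UnitSnapshot]:
    """Stored instances within the trailing stability window, newest first."""
    insts = [i for i in p.instances if 0 < day - i.day <= window]
    return sorted(insts, key=lambda i: i.day, reverse=True)


def select_instance_fmd(
    p: Profile, u: UnitSnapshot, model, cfg: TrackerConfig
) -> tuple[Optional[Match], int]:
    """First-matching-dissimilarity: newest-first scan, stop at first match.

    Returns the match (or None) and the number of classifier evaluations.
    """
    calls = 0
    for inst in _in_window_instances(p, u.day, cfg.stability_window)[:FMD_INSTANCE_CAP]:
        vec = pair_dissimilarity(u, inst, cfg.feature_set_id)
        label, score = classify(model, vec)
        calls += 1
        if label == MATCH:
            return Match(vec, score, inst.day), calls
    return None, calls


def select_instance_mmd(
    p: Profile, u: UnitSnapshot, model, cfg: TrackerConfig
) -> tuple[Optional[Match], int]:
    """Maximum-matching-dissimilarity: evaluate all in-window instances and
    keep the match with the largest distance to the decision boundary."""
    best: Optional[Match] = None
    calls = 0
    for inst in _in_window_instances(p, u.day, cfg.stability_window):
        vec = pair_dissimilarity(u, inst, cfg.feature_set_id)
        label, score = classify(model, vec)
        calls += 1
        if label == MATCH and (best is None or score > best.score):
            best = Match(vec, score, inst.day)
    return best, calls


@dataclass
class MembershipMatrices:
    """Profile x unit comparison grids for one channel-session.

    ``mem_mat`` holds raw classifier decisions, ``mem_mat_star`` the
    one-to-one refinement after back-tracking (a subset of ``mem_mat`` with
    row and column sums <= 1).  ``score_mat`` is NaN where no match was
    accepted.
    """

    profile_ids: list[int]
    unit_labels: list[int]
    dis_mat: list[list[Optional[DissimilarityVector]]]
    score_mat: np.ndarray
    mem_mat: np.ndarray
    mem_mat_star: Optional[np.ndarray] = None
    n_classifier_calls: int = 0


def build_matrices(
    profiles: list[Profile], units: list[UnitSnapshot], model, cfg: TrackerConfig
) -> MembershipMatrices:
    """Run the configured instance-selection strategy over every pair."""
    select = select_instance_fmd if cfg.strategy == "FMD" else select_instance_mmd
    m, n = len(profiles), len(units)
    dis: list[list[Optional[DissimilarityVector]]] = [[None] * n for _ in range(m)]
    scores = np.full((m, n), np.nan)
    mem = np.zeros((m, n), dtype=bool)
    calls = 0
    for i, p in enumerate(profiles):
        for j, u in enumerate(units):
            match, c = select(p, u, model, cfg)
            calls += c
            if match is not None:
                dis[i][j] = match.vector
                scores[i, j] = match.score
                mem[i, j] = True
    return MembershipMatrices(
        profile_ids=[p.profile_id for p in profiles],
        unit_labels=[u.unit_label for u in units],
        dis_mat=dis,
        score_mat=scores,
        mem_mat=mem,
        n_classifier_calls=calls,
    )


def assign(mm: MembershipMatrices) -> MembershipMatrices:
    """Back-track to the lexicographically optimal one-to-one assignment.

    Optimality is (1) maximum number of units attached to existing profiles,
    then (2) maximum total score; residual exact ties break toward the
    lexicographically smallest sorted list of (profile_id, unit_label) pairs.
    """
    mem, scores = mm.mem_mat, mm.score_mat
    m, n = mem.shape
    # candidate profiles per unit, best score first (pure search-order heuristic)
    cands = [
        sorted(np.flatnonzero(mem[:, j]), key=lambda i: -scores[i, j]) for j in range(n)
    ]

    best = {"card": -1, "sum": -np.inf, "key": None, "pairs": ()}

    def pairs_key(pairs):
        return tuple(sorted((mm.profile_ids[i], mm.unit_labels[j]) for i, j in pairs))

    def consider(pairs):
        card = len(pairs)
        ssum = sum(scores[i, j] for i, j in pairs)
        if card > best["card"]:
            better = True
        elif card < best["card"]:
            better = False
        elif ssum > best["sum"] + 1e-12:
            better = True
        elif ssum < best["sum"] - 1e-12:
            better = False
        else:
            key = pairs_key(pairs)
            better = best["key"] is None or key < best["key"]
        if better:
            best.update(card=card, sum=ssum, key=pairs_key(pairs), pairs=tuple(pairs))

    def dfs(j, used, pairs):
        if len(pairs) + (n - j) < best["card"]:
            return  # cannot reach the best cardinality any more
        if j == n:
            consider(pairs)
            return
        for i in cands[j]:
            if i not in used:
                dfs(j + 1, used | {i}, pairs + [(i, j)])
        dfs(j + 1, used, pairs)  # leave unit j unassigned

    dfs(0, frozenset(), [])
    star = np.zeros_like(mem)
    for i, j in best["pairs"]:
        star[i, j] = True
    return replace(mm, mem_mat_star=star)


def update_profiles(
    profiles: list[Profile],
    units: list[UnitSnapshot],
    mm: MembershipMatrices,
    day: int,
    cfg: TrackerConfig,
    next_profile_id: Optional[int] = None,
) -> tuple[list[Profile], int, list[dict]]:
    """Apply an assignment: append instances, open new profiles, drop stale.

    ``profiles`` must contain (at least) every profile referenced by the
    assignment.  Returns the updated profile list, the next free profile ID,
    and one assignment record per unit.
    """
    if mm.mem_mat_star is None:
        raise ValueError("assignment missing: call assign() first")
    by_id = {p.profile_id: p for p in profiles}
    if next_profile_id is None:
        next_profile_id = max(by_id, default=-1) + 1
    records = []
    star = mm.mem_mat_star
    for j, u in enumerate(units):
        rows = np.flatnonzero(star[:, j])
        if rows.size:
            i = int(rows[0])
            p = by_id[mm.profile_ids[i]]
            if p.instance_on(day) is not None:
                raise ValueError(
                    f"profile {p.profile_id} already has an instance on day {day}"
                )
            p.instances.append(u)
            p.last_seen_day = day
            records.append(
                dict(day=day, channel=u.channel_id, unit_label=u.unit_label,
                     profile_id=p.profile_id, score=float(mm.score_mat[i, j]),
                     decision="matched")
            )
        else:
            p = Profile(
                profile_id=next_profile_id, channel_id=u.channel_id,
                instances=[u], status=ACTIVE, last_seen_day=day,
            )
            next_profile_id += 1
            profiles.append(p)
            by_id[p.profile_id] = p
            records.append(
                dict(day=day, channel=u.channel_id, unit_label=u.unit_label,
                     profile_id=p.profile_id, score=float("nan"), decision="new")
            )
    for p in profiles:
        if p.status == ACTIVE and day - p.last_seen_day > cfg.stability_window:
            p.status = DROPPED
    return profiles, next_profile_id, records


@dataclass
class TrackReport:
    """Per-session tracking outcome: assignments plus per-channel telemetry."""

    day: int
    frame: pd.DataFrame
    classifier_calls: dict[int, int]
    compared_profiles: dict[int, list[int]]
    errors: dict[int, str]

    @staticmethod
    def columns():
        return ["day", "channel", "unit_label", "profile_id", "score", "decision"]


def track_session(
    db: ProfileDB,
    session: dict[int, list[SpikeUnit]],
    model,
    cfg: TrackerConfig,
    day: Optional[int] = None,
) -> TrackReport:
    """Track one session's units, channel by channel.

    Channels are independent; a failure on one channel is recorded in the
    report and leaves the others untouched.  ``day`` defaults to the (unique)
    day carried by the session's units.
    """
    if getattr(model, "feature_set_id", cfg.feature_set_id) != cfg.feature_set_id:
        raise ValueError("model and tracker configuration use different feature sets")
    records: list[dict] = []
    calls: dict[int, int] = {}
    compared: dict[int, list[int]] = {}
    errors: dict[int, str] = {}
    days = {u.day for units in session.values() for u in units}
    if day is None:
        if len(days) != 1:
            raise ValueError(f"cannot infer session day from unit days {sorted(days)}")
        day = days.pop()
    elif days and days != {day}:
        raise ValueError(f"session units carry days {sorted(days)}, expected {day}")
    for channel_id in sorted(session):
        units = session[channel_id]
        try:
            snaps = [snapshot(u, cfg) for u in units]
            active = db.active_profiles(channel_id)
            mm = build_matrices(active, snaps, model, cfg)
            mm = assign(mm)
            profiles = db.profiles(channel_id)
            _, next_id, recs = update_profiles(
                profiles, snaps, mm, day, cfg, next_profile_id=db.next_id(channel_id)
            )
            db.set_next_id(channel_id, next_id)
            records.extend(recs)
            calls[channel_id] = mm.n_classifier_calls
            compared[channel_id] = list(mm.profile_ids)
        except Exception as exc:  # isolate per-channel failures
            errors[channel_id] = f"{type(exc).__name__}: {exc}"
    frame = pd.DataFrame(records, columns=TrackReport.columns())
    return TrackReport(day=day, frame=frame, classifier_calls=calls,
                       compared_profiles=compared, errors=errors)
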