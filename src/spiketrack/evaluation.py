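"""Scoring tracked output against ground truth, and sliding validation.

Two metrics quantify agreement between the tracker and a reference labelling
(simulator truth here, a human expert in field use):

classification accuracy
    Day-to-day linkage correctness.  For every unit on day x whose true
    identity was also recorded on day x-1 on that channel, the link is
    correct when the unit was assigned to the profile holding that
    identity's day-(x-1) instance.  Units whose identity is genuinely new
    (absent on day x-1) count as correct when they received a new profile.

percentage of correct profiles
    Whole-history correctness.  A reference profile counts as correct only
    when some tracked profile contains exactly the same (day, unit) instance
    set — one missing or extra instance disqualifies it.  Strictly harsher
    than day-to-day accuracy.

The sliding validation protocol respects calendar order: contiguous windows
of sessions are split into a leading training block (classifier fitting) and
a trailing testing block (tracking + metrics), the window sliding one session
at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifiers import train
from .synthetic import make_labeled_vectors
from .tracker import ProfileDB, TrackerConfig, TrackReport, track_session

__all__ = [
    "GroundTruth",
    "ValidationPlan",
    "classification_accuracy",
    "percent_correct_profiles",
    "sliding_validation",
]


@dataclass
class GroundTruth:
    """Reference identity of every (day, channel, unit_label) record."""

    labels: dict[tuple[int, int, int], str]

    def __post_init__(self) -> None:
        if not isinstance(self.labels, dict):
            raise TypeError("labels must be a dict keyed by (day, channel, unit_label)")
        seen: dict[tuple[int, int], set[str]] = {}
        for (day, chan, _), ident in self.labels.items():
            bucket = seen.setdefault((day, chan), set())
            if ident in bucket:
                raise ValueError(
                    f"identity {ident!r} appears twice on day {day} channel {chan}; "
                    "co-recorded units must be distinct"
                )
            bucket.add(ident)

    def identity(self, day: int, channel: int, unit_label: int) -> str:
        return self.labels[(day, channel, unit_label)]

    def identities_on(self, day: int, channel: int) -> dict[str, int]:
        """identity -> unit_label mapping for one channel-day."""
        return {
            ident: lbl
            for (d, c, lbl), ident in self.labels.items()
            if d == day and c == channel
        }

    def days(self) -> list[int]:
        return sorted({d for d, _, _ in self.labels})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(day=d, channel=c, unit_label=l, identity=i)
            for (d, c, l), i in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows, columns=["day", "channel", "unit_label", "identity"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroundTruth":
        return cls(
            {
                (int(r.day), int(r.channel), int(r.unit_label)): str(r.identity)
                for r in frame.itertuples()
            }
        )


def _instance_index(db: ProfileDB) -> dict[tuple[int, int, int], int]:
    """(day, channel, unit_label) -> tracked profile_id over the whole store."""
    index = {}
    for p in db.all_profiles():
        for inst in p.instances:
            index[(inst.day, p.channel_id, inst.unit_label)] = p.profile_id
    return index


def classification_accuracy(
    reports: list[TrackReport] | pd.DataFrame, truth: GroundTruth, db: ProfileDB
) -> float:
    """Percentage of correct day-to-day linkage decisions.

    Requires reports over consecutive sessions; the first tracked session
    only seeds profiles and contributes no decisions.
    """
    frame = (
        reports
        if isinstance(reports, pd.DataFrame)
        else pd.concat([r.frame for r in reports], ignore_index=True)
    )
    if frame.empty:
        raise ValueError("no assignment records to evaluate")
    index = _instance_index(db)
    days = sorted(frame["day"].unique())
    correct = total = 0
    for day in days[1:]:
        prev = day - 1
        for row in frame[frame["day"] == day].itertuples():
            ident = truth.identity(int(row.day), int(row.channel), int(row.unit_label))
            prev_labels = truth.identities_on(prev, int(row.channel))
            total += 1
            if ident in prev_labels:
                expected_pid = index.get((prev, int(row.channel), prev_labels[ident]))
                correct += int(row.profile_id == expected_pid)
            else:
                correct += int(row.decision == "new")
    if total == 0:
        raise ValueError("no evaluable day-to-day decisions (single session?)")
    return 100.0 * correct / total


def percent_correct_profiles(
    db: ProfileDB, truth: GroundTruth, days: list[int] | None = None
) -> float:
    """Percentage of reference profiles tracked exactly, instance for instance."""
    if not truth.labels:
        raise ValueError("empty ground truth")
    if days is None:
        days = sorted({inst.day for p in db.all_profiles() for inst in p.instances})
    dayset = set(days)
    # reference profiles: per channel, identity -> set of (day, unit_label)
    ref: dict[int, dict[str, set[tuple[int, int]]]] = {}
    for (day, chan, lbl), ident in truth.labels.items():
        if day in dayset:
            ref.setdefault(chan, {}).setdefault(ident, set()).add((day, lbl))
    tracked: dict[int, list[set[tuple[int, int]]]] = {}
    for p in db.all_profiles():
        inst_set = {(i.day, i.unit_label) for i in p.instances if i.day in dayset}
        if inst_set:
            tracked.setdefault(p.channel_id, []).append(inst_set)
    n_ref = sum(len(m) for m in ref.values())
    if n_ref == 0:
        raise ValueError("ground truth covers none of the tracked days")
    n_exact = sum(
        1
        for chan, members in ref.items()
        for inst_set in members.values()
        if inst_set in tracked.get(chan, [])
    )
    return 100.0 * n_exact / n_ref


@dataclass(frozen=True)
class ValidationPlan:
    """Calendar-ordered sliding windows over the available sessions.

    Window k (0-based) covers sessions k .. k + train_size + test_size - 1;
    the leading ``train_size`` sessions fit the classifier, the trailing
    ``test_size`` sessions are tracked and scored.
    """

    dataset_count: int = 15
    window_count: int = 6
    train_size: int = 5
    test_size: int = 5

    def __post_init__(self) -> None:
        if min(self.window_count, self.train_size, self.test_size) < 1:
            raise ValueError("plan sizes must be >= 1")
        if self.window_count - 1 + self.span > self.dataset_count:
            raise ValueError(
                f"plan needs {self.window_count - 1 + self.span} sessions, "
                f"only {self.dataset_count} declared"
            )

    @property
    def span(self) -> int:
        return self.train_size + self.test_size

    def windows(self) -> list[range]:
        return [range(k, k + self.span) for k in range(self.window_count)]


def run_tracking(
    sessions: list[dict], model, cfg: TrackerConfig, days: list[int] | None = None
) -> tuple[ProfileDB, list[TrackReport]]:
    """Track an ordered list of sessions into a fresh profile store."""
    db = ProfileDB()
    reports = []
    for k, session in enumerate(sessions):
        day = days[k] if days is not None else None
        reports.append(track_session(db, session, model, cfg, day=day))
    return db, reports


def sliding_validation(
    sessions: list[dict],
    truth: GroundTruth,
    plan: ValidationPlan,
    configs: list[TrackerConfig],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every configuration over every sliding window.

    ``sessions[d]`` maps channel -> list of SpikeUnit for session index d
    (truth is keyed by the same indices).  Returns the per-window table and
    a mean/std summary per configuration.
    """
    if len(sessions) < plan.window_count - 1 + plan.span:
        raise ValueError("not enough sessions for the validation plan")
    rows = []
    for w, window in enumerate(plan.windows()):
        idx = list(window)
        train_idx, test_idx = idx[: plan.train_size], idx[plan.train_size :]
        for cfg in configs:
            ts = make_labeled_vectors(
                [sessions[i] for i in train_idx],
                truth,
                cfg.feature_set_id,
                days=train_idx,
                smoothing_sigma=cfg.smoothing_sigma,
                binning=cfg.binning,
            )
            model = train(ts, cfg.classifier, seed=seed)
            db, reports = run_tracking(
                [sessions[i] for i in test_idx], model, cfg, days=test_idx
            )
            rows.append(
                dict(
                    window=w,
                    classifier=cfg.classifier,
                    feature_set=cfg.feature_set_id,
                    strategy=cfg.strategy,
                    accuracy=classification_accuracy(reports, truth, db),
                    correct_profiles=percent_correct_profiles(db, truth, days=test_idx),
                )
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["classifier", "feature_set", "strategy"])[
            ["accuracy", "correct_profiles"]
        ]
        .agg(["mean", "std"])
        .reset_index()
    )
    return table, summary
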