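"""Episode-based evaluation: hit rate, false-positive rate, mean prediction time.

Window-level predictions become *alarms* by merging maximal runs of
consecutive prefog-predicted windows (optionally bridging short gaps).
Each alarm carries a *trigger*: the end of its first prefog window, the
earliest causal moment the alarm could be raised.  A FOG episode is a
*hit* when some alarm triggers within the horizon before its onset; the
episode's prediction time is the lead from the earliest such trigger to
the onset.  An alarm not confirmed by any onset within the horizon
after its trigger is a *false alarm*.  Alarms triggering inside an
ongoing freeze are ignored — online behaviour during a freeze is out of
scope, since freeze data never reach the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import concat_matrices, extract_matrix
from .model import RFParams, train_and_eval
from .preprocess import (
    LABEL_PREFOG,
    SegmentationParams,
    highpass_detrend,
    replace_outliers,
    segment_and_label,
)
from .synth import EventAnnotation, IMURecording

__all__ = [
    "AlarmEvent",
    "EpisodeScore",
    "form_alarms",
    "episode_metrics",
    "pool_scores",
    "end_to_end_eval",
    "permutation_null_hit_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlarmEvent:
    """A merged run of prefog predictions.

    ``start_sample``/``end_sample`` span the underlying windows.  The
    *trigger* is the moment the alarm could actually be raised — the end
    of the first prefog-predicted window, once its data has been seen.
    For alarms constructed directly (without window provenance) the
    trigger defaults to the span start.
    """

    patient_id: str
    start_sample: int
    end_sample: int  # half-open
    trigger_sample: int | None = None

    @property
    def trigger(self) -> int:
        return (
            self.trigger_sample
            if self.trigger_sample is not None
            else self.start_sample
        )


@dataclass
class EpisodeScore:
    n_episodes: int
    n_hits: int
    n_alarms: int  # alarms considered (outside ongoing freezes)
    n_false_alarms: int
    prediction_times_s: list[float] = field(default_factory=list)
    hit_rate: float | None = None
    false_positive_rate: float | None = None
    mpt_s: float | None = None
    flags: list[str] = field(default_factory=list)

    def finalize(self) -> "EpisodeScore":
        if self.n_episodes > 0:
            self.hit_rate = self.n_hits / self.n_episodes
        else:
            self.hit_rate = None
            self.flags.append("no FOG episodes: hit_rate undefined")
        if self.n_alarms > 0:
            self.false_positive_rate = self.n_false_alarms / self.n_alarms
        else:
            self.false_positive_rate = 0.0
            self.flags.append("no alarms: false_positive_rate reported as 0")
        self.mpt_s = (
            float(np.mean(self.prediction_times_s))
            if self.prediction_times_s
            else None
        )
        return self


def form_alarms(
    window_predictions: list[tuple[int, int, str]],
    patient_id: str = "",
    gap_tolerance_windows: int = 0,
) -> list[AlarmEvent]:
    """Merge runs of prefog-predicted windows into alarms.

    ``window_predictions`` is an ordered list of (start, end, predicted
    label).  Up to ``gap_tolerance_windows`` interleaved non-prefog
    predictions may be bridged; each alarm spans from the first window's
    start to the last window's end of its run.
    """
    starts = [w[0] for w in window_predictions]
    if starts != sorted(starts):
        raise ValueError("window predictions must be ordered by start")
    alarms: list[AlarmEvent] = []
    run_start = run_end = run_trigger = None
    gap = 0
    for start, end, label in window_predictions:
        if label == LABEL_PREFOG:
            if run_start is None:
                run_start, run_end = start, end
                run_trigger = end  # first prefog window fully observed here
            else:
                run_end = end
            gap = 0
        elif run_start is not None:
            gap += 1
            if gap > gap_tolerance_windows:
                alarms.append(
                    AlarmEvent(patient_id, run_start, run_end, run_trigger)
                )
                run_start = run_end = run_trigger = None
                gap = 0
    if run_start is not None:
        alarms.append(AlarmEvent(patient_id, run_start, run_end, run_trigger))
    return alarms


def episode_metrics(
    alarms: list[AlarmEvent],
    ann: EventAnnotation,
    sampling_rate_hz: float,
    horizon_s: float = 6.0,
) -> EpisodeScore:
    """Score alarms against annotated FOG episodes.

    A hit requires an alarm *trigger* in ``[onset - horizon, onset)``;
    prediction time is onset minus the earliest such trigger, in seconds
    (hence always in (0, horizon]).  The false-positive rate is per
    alarm: the fraction of considered alarms with no onset within the
    horizon after their trigger.  For alarms without window provenance
    the trigger equals the span start.
    """
    if horizon_s <= 0:
        raise ValueError("horizon_s must be positive")
    h = int(round(horizon_s * sampling_rate_hz))
    fog = ann.fog_events
    considered = [
        a for a in alarms
        if not any(s <= a.trigger < e for s, e in fog)
    ]
    score = EpisodeScore(
        n_episodes=len(fog),
        n_hits=0,
        n_alarms=len(considered),
        n_false_alarms=0,
    )
    for onset, _ in fog:
        in_horizon = [
            a.trigger for a in considered if onset - h <= a.trigger < onset
        ]
        if in_horizon:
            score.n_hits += 1
            score.prediction_times_s.append(
                (onset - min(in_horizon)) / sampling_rate_hz
            )
    for a in considered:
        confirmed = any(
            onset - h <= a.trigger < onset for onset, _ in fog
        )
        if not confirmed:
            score.n_false_alarms += 1
    return score.finalize()


def pool_scores(scores: list[EpisodeScore]) -> EpisodeScore:
    """Pool per-patient episode scores into cohort-level metrics."""
    pooled = EpisodeScore(
        n_episodes=sum(s.n_episodes for s in scores),
        n_hits=sum(s.n_hits for s in scores),
        n_alarms=sum(s.n_alarms for s in scores),
        n_false_alarms=sum(s.n_false_alarms for s in scores),
        prediction_times_s=[t for s in scores for t in s.prediction_times_s],
    )
    return pooled.finalize()


def predict_windows_lopo(
    data: list[tuple[IMURecording, EventAnnotation]],
    params: SegmentationParams,
    rf: RFParams,
    clean: bool = True,
) -> dict[str, list[tuple[int, int, str]]]:
    """Cleaned, segmented, LOPO-predicted windows per patient."""
    prepared = []
    for rec, ann in data:
        if clean:
            rec = highpass_detrend(replace_outliers(rec))
        prepared.append((rec, ann))
    window_sets = [segment_and_label(rec, ann, params) for rec, ann in prepared]
    mats = [extract_matrix(ws) for ws in window_sets]
    fm = concat_matrices(mats)
    folds = train_and_eval(fm, rf)
    by_patient: dict[str, list[tuple[int, int, str]]] = {}
    offsets = np.cumsum([0] + [len(m.features) for m in mats])
    order = [rec.patient_id for rec, _ in prepared]
    for fold in folds:
        i = order.index(fold.patient_id)
        meta = [(w.start, w.end) for w in window_sets[i].windows]
        local = fold.row_index - offsets[i]
        by_patient[fold.patient_id] = [
            (meta[j][0], meta[j][1], lab) for j, lab in zip(local, fold.predictions)
        ]
    return by_patient


def end_to_end_eval(
    data: list[tuple[IMURecording, EventAnnotation]],
    params: SegmentationParams,
    rf: RFParams,
    horizon_s: float = 6.0,
    gap_tolerance_windows: int = 0,
) -> EpisodeScore:
    """Full pipeline scoring: clean, segment, LOPO-train, alarm, match.

    Episodes and alarms are pooled over all held-out patients; fully
    deterministic given ``rf.seed``.
    """
    predictions = predict_windows_lopo(data, params, rf)
    fs = data[0][0].sampling_rate_hz
    scores = []
    for rec, ann in data:
        preds = predictions.get(rec.patient_id)
        if preds is None:
            continue
        alarms = form_alarms(preds, rec.patient_id, gap_tolerance_windows)
        scores.append(episode_metrics(alarms, ann, fs, horizon_s))
    return pool_scores(scores)


def permutation_null_hit_rate(
    data: list[tuple[IMURecording, EventAnnotation]],
    alarms_by_patient: dict[str, list[AlarmEvent]],
    horizon_s: float,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the pooled hit rate under circular alarm shifts.

    Each permutation shifts every patient's alarm train by an
    independent uniform circular offset, breaking any alignment with
    FOG onsets while preserving alarm count and spacing.
    """
    rng = np.random.default_rng(seed)
    fs = data[0][0].sampling_rate_hz
    nulls = np.empty(n_permutations)
    for k in range(n_permutations):
        scores = []
        for rec, ann in data:
            alarms = alarms_by_patient.get(rec.patient_id, [])
            n = rec.n_samples
            shift = int(rng.integers(0, n))
            shifted = sorted(
                (
                    AlarmEvent(
                        a.patient_id,
                        (a.start_sample + shift) % n,
                        (a.start_sample + shift) % n
                        + (a.end_sample - a.start_sample),
                        trigger_sample=(a.trigger + shift) % n,
                    )
                    for a in alarms
                ),
                key=lambda a: a.start_sample,
            )
            scores.append(episode_metrics(shifted, ann, fs, horizon_s))
        pooled = pool_scores(scores)
        nulls[k] = pooled.hit_rate if pooled.hit_rate is not None else 0.0
    return nulls
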