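"""Pairing of recorded arrows with calculated trend categories and all
concordance statistics.

For every diary record the sensor's own trace (or, in the BG-reference
variant, the participant's blood-glucose trace) is interpolated at the
recording time and 30 min later; the resulting rate is classified with the
device's own taxonomy and compared with the displayed arrow.  Records whose
forward rate is not computable (time outside the trace span, or a data gap
wider than ``max_gap``) are excluded and logged — missing data are never
replaced.

Percentages are reported to one decimal with round-half-up, matching the
display precision used in CGM evaluation tables.  Per-participant spread is
the sample standard deviation (n-1) of participant-level match percentages;
participants contributing no records are omitted.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ProfileMismatchError, TraceGapError, TraceRangeError
from .events import DEFAULT_POST_MIN, DEFAULT_PRE_MIN, TherapyEvent, event_window_flags
from .profiles import DeviceProfile, TrendCategory, category_difference, classify_rate
from .traces import GlucoseTrace, default_max_gap, forward_rate

__all__ = [
    "DiaryRecord",
    "ConcordanceRecord",
    "ConcordanceSummary",
    "AgreementSummary",
    "Exclusion",
    "VISIT_SPANS",
    "visit_label",
    "build_concordance",
    "contingency",
    "summarize",
    "stratify_by_visit",
    "parallel_sensor_agreement",
]

logger = logging.getLogger(__name__)

#: Visit spans in minutes since study start: visit 1 = days 0-2,
#: visit 2 = days 5-7, visit 3 = days 12-14 (a "day d" record written as
#: 2400 lands on minute (d+1)*1440 and still belongs to that visit).
VISIT_SPANS: dict[int, tuple[float, float]] = {
    1: (0.0, 3 * 1440.0),
    2: (5 * 1440.0, 8 * 1440.0),
    3: (12 * 1440.0, 15 * 1440.0),
}

#: BG reference readings are quarter-hourly to hourly; 75 min tolerates one
#: missed hourly measurement without bridging overnight gaps.
BG_MAX_GAP_MIN = 75.0


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (display convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def visit_label(t: float, spans: Mapping[int, tuple[float, float]] = VISIT_SPANS) -> int | None:
    """Visit number whose closed span contains ``t``, or None ("home")."""
    for visit, (lo, hi) in spans.items():
        if lo <= t <= hi:
            return visit
    return None


@dataclass(frozen=True)
class DiaryRecord:
    """One displayed-arrow observation from the participant diary."""

    participant_id: str
    system: str
    sensor_id: str
    time: float
    recorded: TrendCategory
    visit: int | None

    def __post_init__(self) -> None:
        if self.recorded.profile_name != self.system:
            raise ProfileMismatchError(
                f"diary record for system {self.system} carries a "
                f"{self.recorded.profile_name} category"
            )


@dataclass(frozen=True)
class ConcordanceRecord:
    """One recorded-vs-calculated pairing."""

    diary: DiaryRecord
    calculated: TrendCategory
    diff: int
    in_window: bool
    reference: str  # "TG" or "BG"


@dataclass(frozen=True)
class Exclusion:
    """A diary record dropped from the analysis, with the reason code."""

    diary: DiaryRecord
    reason: str  # "out-of-range" | "gap"


@dataclass(frozen=True)
class ConcordanceSummary:
    """Pooled and participant-level concordance statistics.

    ``pct_*`` fields are percentages of the pooled record set rounded to one
    decimal; they are ``None`` when ``n == 0``.  ``participant_mean_match``
    and ``participant_sd_match`` aggregate per-participant match
    percentages (unrounded); the SD is the sample SD and is ``None`` with
    fewer than two contributing participants.
    """

    n: int
    n_match: int
    n_off1: int
    n_off2plus: int
    pct_match: float | None
    pct_off1: float | None
    pct_off2plus: float | None
    participant_mean_match: float | None
    participant_sd_match: float | None


@dataclass(frozen=True)
class AgreementSummary:
    """Agreement between the two parallel sensors of one system."""

    system: str
    n_pairs: int
    n_unpaired: int
    pct_identical: float | None
    pct_off1: float | None
    pct_off2plus: float | None


def build_concordance(
    diary: Sequence[DiaryRecord],
    traces: Mapping[str, GlucoseTrace],
    events: Sequence[TherapyEvent],
    profile: DeviceProfile,
    reference: str = "TG",
    horizon: float = 30.0,
    max_gap: float | None = None,
    window_pre: float = DEFAULT_PRE_MIN,
    window_post: float = DEFAULT_POST_MIN,
) -> tuple[list[ConcordanceRecord], list[Exclusion]]:
    """Pair each diary record with the trend category of its realized rate.

    Parameters
    ----------
    diary:
        Diary records of one system (matching ``profile``).
    traces:
        In TG mode, a mapping sensor_id -> trace; in BG mode, a mapping
        participant_id -> shared blood-glucose trace.
    events:
        Therapy events for all participants; only each record's own
        participant's events open windows.
    reference:
        "TG" evaluates each arrow against its own sensor's trace, "BG"
        against the participant's reference blood-glucose trace.
    max_gap:
        Interpolation gap cap in minutes; defaults to 2.5x the device
        storage cadence in TG mode and to 75 min in BG mode.

    Returns
    -------
    (records, exclusions)
        One :class:`ConcordanceRecord` per computable diary record, and one
        :class:`Exclusion` with a reason code per dropped record.
    """
    if reference not in ("TG", "BG"):
        raise ValueError(f"reference must be 'TG' or 'BG', got {reference!r}")
    if max_gap is None:
        max_gap = default_max_gap(profile.storage_interval) if reference == "TG" else BG_MAX_GAP_MIN

    events_by_pid: dict[str, list[TherapyEvent]] = defaultdict(list)
    for ev in events:
        events_by_pid[ev.participant_id].append(ev)

    # Window flags computed per participant in one vectorized pass.
    flags: dict[int, bool] = {}
    by_pid: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(diary):
        by_pid[rec.participant_id].append(i)
    for pid, idx in by_pid.items():
        f = event_window_flags(
            [diary[i].time for i in idx], events_by_pid.get(pid, []), window_pre, window_post
        )
        flags.update(zip(idx, f.tolist()))

    records: list[ConcordanceRecord] = []
    exclusions: list[Exclusion] = []
    for i, rec in enumerate(diary):
        key = rec.sensor_id if reference == "TG" else rec.participant_id
        try:
            trace = traces[key]
        except KeyError:
            raise ConfigurationError(
                f"no {reference} trace for {'sensor' if reference == 'TG' else 'participant'} {key!r}"
            ) from None
        try:
            rate = forward_rate(trace, rec.time, horizon=horizon, max_gap=max_gap)
        except TraceRangeError:
            exclusions.append(Exclusion(rec, "out-of-range"))
            logger.info(
                "excluded %s %s t=%g: out-of-range", rec.participant_id, rec.sensor_id, rec.time
            )
            continue
        except TraceGapError:
            exclusions.append(Exclusion(rec, "gap"))
            logger.info("excluded %s %s t=%g: gap", rec.participant_id, rec.sensor_id, rec.time)
            continue
        calculated = classify_rate(rate, profile)
        records.append(
            ConcordanceRecord(
                diary=rec,
                calculated=calculated,
                diff=category_difference(rec.recorded, calculated),
                in_window=flags[i],
                reference=reference,
            )
        )
    return records, exclusions


def contingency(
    records: Iterable[ConcordanceRecord], profile: DeviceProfile
) -> pd.DataFrame:
    """Recorded x calculated count matrix over the profile's codes.

    Rows are recorded codes, columns calculated codes, both ordered from the
    steepest fall to the steepest rise; marginal sums equal the number of
    records.
    """
    codes = [c.code for c in profile.categories]
    mat = pd.DataFrame(0, index=pd.Index(codes, name="recorded"),
                       columns=pd.Index(codes, name="calculated"))
    for r in records:
        if (
            r.diary.recorded.profile_name != profile.name
            or r.calculated.profile_name != profile.name
        ):
            raise ProfileMismatchError(
                f"record with profiles ({r.diary.recorded.profile_name}, "
                f"{r.calculated.profile_name}) in a {profile.name} contingency table"
            )
        mat.loc[r.diary.recorded.code, r.calculated.code] += 1
    return mat


def _summary_from_diffs(
    diffs: Sequence[int], participants: Sequence[str]
) -> ConcordanceSummary:
    n = len(diffs)
    d = np.asarray(diffs, dtype=int)
    n_match = int(np.sum(d == 0))
    n_off1 = int(np.sum(d == 1))
    n_off2 = int(np.sum(d >= 2))
    if n == 0:
        return ConcordanceSummary(0, 0, 0, 0, None, None, None, None, None)
    per_part: dict[str, list[int]] = defaultdict(list)
    for pid, diff in zip(participants, diffs):
        per_part[pid].append(diff)
    pcts = [
        100.0 * sum(1 for x in v if x == 0) / len(v) for v in per_part.values()
    ]
    mean = float(np.mean(pcts))
    sd = float(np.std(pcts, ddof=1)) if len(pcts) >= 2 else None
    return ConcordanceSummary(
        n=n,
        n_match=n_match,
        n_off1=n_off1,
        n_off2plus=n_off2,
        pct_match=_round1(100.0 * n_match / n),
        pct_off1=_round1(100.0 * n_off1 / n),
        pct_off2plus=_round1(100.0 * n_off2 / n),
        participant_mean_match=mean,
        participant_sd_match=sd,
    )


def summarize(records: Sequence[ConcordanceRecord]) -> ConcordanceSummary:
    """Pooled match / off-by-one / off-by-two-plus percentages plus the
    participant-level mean and SD of the match percentage."""
    return _summary_from_diffs(
        [r.diff for r in records], [r.diary.participant_id for r in records]
    )


def summary_from_counts(n_match: int, n_off1: int, n_off2plus: int) -> ConcordanceSummary:
    """Summary from pre-tabulated counts (single pooled participant).

    Useful for re-deriving published percentages from published counts; the
    participant-level statistics are not meaningful here and are set to the
    pooled value / None.
    """
    diffs = [0] * n_match + [1] * n_off1 + [2] * n_off2plus
    return _summary_from_diffs(diffs, ["pooled"] * len(diffs))


def stratify_by_visit(
    records: Sequence[ConcordanceRecord],
) -> dict[int, ConcordanceSummary]:
    """One summary per study-site visit 1/2/3.

    Records whose diary time falls outside every visit span carry
    ``visit=None`` ("home") and are excluded from visit stratification.
    """
    out: dict[int, ConcordanceSummary] = {}
    for visit in sorted(VISIT_SPANS):
        out[visit] = summarize([r for r in records if r.diary.visit == visit])
    return out


def parallel_sensor_agreement(
    diary: Sequence[DiaryRecord], system: str
) -> AgreementSummary:
    """Agreement of arrows displayed by the two sensors of one system.

    Records are paired by (participant, time); a time at which only one
    sensor produced an arrow is dropped and counted as unpaired.
    """
    recs = [r for r in diary if r.system == system]
    sensors_by_pid: dict[str, set[str]] = defaultdict(set)
    for r in recs:
        sensors_by_pid[r.participant_id].add(r.sensor_id)
    for pid, sensors in sensors_by_pid.items():
        if len(sensors) > 2:
            raise ConfigurationError(
                f"participant {pid} has {len(sensors)} {system} sensors; expected at most 2"
            )
    groups: dict[tuple[str, float], list[DiaryRecord]] = defaultdict(list)
    for r in recs:
        groups[(r.participant_id, r.time)].append(r)
    diffs: list[int] = []
    n_unpaired = 0
    for pair in groups.values():
        if len(pair) == 2:
            diffs.append(category_difference(pair[0].recorded, pair[1].recorded))
        else:
            n_unpaired += len(pair)
    n = len(diffs)
    counts = Counter(min(d, 2) for d in diffs)
    return AgreementSummary(
        system=system,
        n_pairs=n,
        n_unpaired=n_unpaired,
        pct_identical=_round1(100.0 * counts[0] / n) if n else None,
        pct_off1=_round1(100.0 * counts[1] / n) if n else None,
        pct_off2plus=_round1(100.0 * counts[2] / n) if n else None,
    )
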