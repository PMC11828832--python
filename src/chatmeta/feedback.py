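"""Donor-facing feedback summaries on minimized donations.

Everything here is a pure function of the minimized donation; contact
information is always aggregated, and any time bin in which fewer than
two distinct contacts were active has its received side suppressed so no
single partner's behavior is exposed.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .minimizer import Donation

DEFAULT_RESPONSE_CAP = dt.timedelta(days=7)
MIN_CONTACTS_PER_BIN = 2


@dataclass
class TimeBinSeries:
    bin_kind: str
    bins: list[dt.date]  # bin start dates
    words_sent: list[int]
    words_received: list[Optional[int]]  # None where suppressed
    received_suppressed: list[bool]


@dataclass
class HourHistogram:
    counts: list[int] = field(default_factory=lambda: [0] * 24)


@dataclass
class ResponseTimeSummary:
    latencies: list[float]  # seconds, ascending
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]


def _bin_start(day: dt.date, kind: str) -> dt.date:
    if kind == "month":
        return day.replace(day=1)
    if kind == "week":
        return day - dt.timedelta(days=day.weekday())
    raise ValueError(f"unknown bin kind {kind!r}")


def _next_bin(start: dt.date, kind: str) -> dt.date:
    if kind == "month":
        return (start.replace(day=28) + dt.timedelta(days=4)).replace(day=1)
    return start + dt.timedelta(days=7)


def intensity_series(
    d: Donation,
    bin: Literal["month", "week"] = "month",
    min_contacts: int = MIN_CONTACTS_PER_BIN,
) -> TimeBinSeries:
    """Words sent and (aggregated, possibly suppressed) words received per bin."""
    stamps = [m.timestamp for c in d.conversations for m in c.messages]
    if not stamps:
        raise ValueError("donation has no messages")
    first = _bin_start(min(stamps).date(), bin)
    last = _bin_start(max(stamps).date(), bin)

    bins: list[dt.date] = []
    cur = first
    while cur <= last:
        bins.append(cur)
        cur = _next_bin(cur, bin)
    index = {b: i for i, b in enumerate(bins)}

    sent = [0] * len(bins)
    received = [0] * len(bins)
    active_contacts: list[set[str]] = [set() for _ in bins]
    for conv in d.conversations:
        for m in conv.messages:
            i = index[_bin_start(m.timestamp.date(), bin)]
            if m.sender_id == d.donor_id:
                sent[i] += m.word_count
            else:
                received[i] += m.word_count
                active_contacts[i].add(m.sender_id)

    suppressed = [len(cs) < min_contacts for cs in active_contacts]
    return TimeBinSeries(
        bin_kind=bin,
        bins=bins,
        words_sent=sent,
        words_received=[None if s else r for r, s in zip(received, suppressed)],
        received_suppressed=suppressed,
    )


def active_hours(d: Donation) -> HourHistogram:
    """Histogram of donor-sent messages by hour of day."""
    hist = HourHistogram()
    for conv in d.conversations:
        for m in conv.messages:
            if m.sender_id == d.donor_id:
                hist.counts[m.timestamp.hour] += 1
    return hist


def response_times(
    d: Donation,
    cap: dt.timedelta = DEFAULT_RESPONSE_CAP,
) -> ResponseTimeSummary:
    """Donor reply latencies to the most recent preceding contact message.

    Within each chat, each donor message directly following one or more
    contact messages contributes one latency; latencies above ``cap``
    are treated as conversation restarts and discarded.
    """
    latencies: list[float] = []
    for conv in d.conversations:
        last_contact: Optional[dt.datetime] = None
        for m in conv.messages:
            if m.sender_id == d.donor_id:
                if last_contact is not None:
                    delta = m.timestamp - last_contact
                    if dt.timedelta(0) < delta <= cap:
                        latencies.append(delta.total_seconds())
                    last_contact = None
            else:
                last_contact = m.timestamp
    latencies.sort()
    if latencies:
        q1, med, q3 = (float(q) for q in np.percentile(latencies, [25, 50, 75]))
    else:
        q1 = med = q3 = None
    return ResponseTimeSummary(latencies=latencies, median=med, q1=q1, q3=q3)


def feedback_bundle(d: Donation, bin: Literal["month", "week"] = "month",
                    cap: dt.timedelta = DEFAULT_RESPONSE_CAP) -> dict:
    """Plot-ready JSON document with all three feedback panels."""
    series = intensity_series(d, bin)
    hours = active_hours(d)
    resp = response_times(d, cap)
    return {
        "intensity": {
            "bin": series.bin_kind,
            "bins": [b.isoformat() for b in series.bins],
            "words_sent": series.words_sent,
            "words_received": series.words_received,
            "received_suppressed": series.received_suppressed,
        },
        "active_hours": {"counts": hours.counts},
        "response_times": {
            "n": len(resp.latencies),
            "median_s": resp.median,
            "q1_s": resp.q1,
            "q3_s": resp.q3,
        },
    }
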