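"""Objective social-interaction features on minimized donations.

Implements the interactivity filter (no partner above 90% of words),
directed interaction bias, Gini heterogeneity of donor-sent words,
day-level inter-event burstiness, per-donation summary statistics and
the contact-resampling analysis.

All word-based measures operate on word counts only, so media and voice
messages (word count 0) drop out automatically; timing-based measures
see every minimized message.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTally,
    EmptyChat,
    IneligibleChat,
    InvalidSample,
    ZeroTotal,
)
from .minimizer import Donation, MinimizedConversation

INTERACTIVITY_THRESHOLD = 0.9
MIN_INTERACTION_DAYS = 10


# ---------------------------------------------------------------------------
# interactivity filter

def word_shares(conv: MinimizedConversation) -> dict[str, float]:
    """Per-participant share of the chat's total word count."""
    totals: dict[str, int] = {}
    for m in conv.messages:
        totals[m.sender_id] = totals.get(m.sender_id, 0) + m.word_count
    grand = sum(totals.values())
    if grand == 0:
        raise EmptyChat(f"chat {conv.conversation_id} has no words")
    return {s: w / grand for s, w in totals.items()}


@dataclass(frozen=True)
class ChatFilterDecision:
    interactive: bool
    max_share: float


def is_interactive(
    conv: MinimizedConversation,
    threshold: float = INTERACTIVITY_THRESHOLD,
) -> ChatFilterDecision:
    """A chat is interactive iff no partner contributed more than ``threshold``.

    The comparison is strict: a partner at exactly the threshold share
    keeps the chat interactive.
    """
    max_share = max(word_shares(conv).values())
    return ChatFilterDecision(interactive=max_share <= threshold, max_share=max_share)


# ---------------------------------------------------------------------------
# interaction bias

@dataclass(frozen=True)
class ContactTally:
    """Directed word totals for one donor-contact dyad."""

    w_ij: int  # words donor -> contact
    w_ji: int  # words contact -> donor


def interaction_bias(t: ContactTally) -> float:
    """0.5 − w_ij/(w_ij + w_ji): 0 balanced, −0.5 donor-only, +0.5 contact-only."""
    total = t.w_ij + t.w_ji
    if total == 0:
        raise DegenerateTally("no words in either direction")
    return 0.5 - t.w_ij / total


def contact_tally(conv: MinimizedConversation, donor_id: str) -> ContactTally:
    sent = sum(m.word_count for m in conv.messages if m.sender_id == donor_id)
    received = sum(m.word_count for m in conv.messages if m.sender_id != donor_id)
    return ContactTally(w_ij=sent, w_ji=received)


# ---------------------------------------------------------------------------
# Gini heterogeneity

def gini(weights: Sequence[float] | np.ndarray) -> float:
    """Gini index of a contact-weight vector.

    Computed on the ascending-sorted vector V with ranks j = 1..k as
    2·Σ j·V_j / (k·Σ V_j) − (k+1)/k, which equals the standard
    mean-absolute-pairwise-difference Gini. Range [0, (k−1)/k].
    """
    v = np.sort(np.asarray(weights, dtype=float))
    if v.size == 0 or np.any(v < 0):
        raise ValueError("weights must be a non-empty non-negative vector")
    total = v.sum()
    if total == 0:
        raise ZeroTotal("all-zero weight vector")
    k = v.size
    j = np.arange(1, k + 1)
    return float(2.0 * np.dot(j, v) / (k * total) - (k + 1) / k)


def donor_weight_vector(
    donation: Donation,
    interactive_only: bool = True,
    threshold: float = INTERACTIVITY_THRESHOLD,
) -> np.ndarray:
    """Words sent by the donor to each contact (one entry per chat).

    Chat partners are not linkable across chats in minimized data, so a
    contact is identified with a conversation.
    """
    out = []
    for conv in donation.conversations:
        try:
            if interactive_only and not is_interactive(conv, threshold).interactive:
                continue
        except EmptyChat:
            continue
        out.append(sum(m.word_count for m in conv.messages
                       if m.sender_id == donation.donor_id))
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# burstiness

@dataclass(frozen=True)
class InterEventSeries:
    """Sorted unique interaction days of a chat and their day gaps."""

    interaction_days: tuple[dt.date, ...]
    inter_event_times: tuple[int, ...]

    @property
    def n_days(self) -> int:
        return len(self.interaction_days)

    @property
    def eligible(self) -> bool:
        return self.n_days >= MIN_INTERACTION_DAYS


@dataclass(frozen=True)
class BurstinessResult:
    mu: float
    sigma: float
    r: float
    b1: float


def interevent_series(conv: MinimizedConversation) -> InterEventSeries:
    """Day-level inter-event times: gaps between consecutive interaction days.

    An interaction day is a calendar day with at least one message from
    either partner, media included.
    """
    days = sorted({m.timestamp.date() for m in conv.messages})
    gaps = tuple((b - a).days for a, b in zip(days, days[1:]))
    return InterEventSeries(interaction_days=tuple(days), inter_event_times=gaps)


def burstiness_from_gaps(gaps: Sequence[float] | np.ndarray) -> BurstinessResult:
    """μ, population σ, r = σ/μ and B1 = (r−1)/(r+1) for an inter-event series."""
    g = np.asarray(gaps, dtype=float)
    if g.size == 0 or np.any(g <= 0):
        raise ValueError("need a non-empty positive inter-event series")
    mu = float(g.mean())
    sigma = float(g.std(ddof=0))
    r = sigma / mu
    return BurstinessResult(mu=mu, sigma=sigma, r=r, b1=(r - 1.0) / (r + 1.0))


def burstiness(
    s: InterEventSeries,
    min_days: int = MIN_INTERACTION_DAYS,
) -> BurstinessResult:
    if s.n_days < min_days:
        raise IneligibleChat(f"{s.n_days} interaction days < {min_days}")
    return burstiness_from_gaps(s.inter_event_times)


# ---------------------------------------------------------------------------
# resampling

def resample_gini(
    full_network: Sequence[float] | np.ndarray,
    n: int,
    mode: Literal["random", "top"],
    reps: int = 200,
    seed: int = 0,
) -> list[float]:
    """Gini of n-contact sub-networks, sampled randomly or as the top n.

    Top-n selection is deterministic, so reps is forced to 1 for it.
    """
    weights = np.asarray(full_network, dtype=float)
    k = weights.size
    if not 1 <= n <= k:
        raise InvalidSample(f"cannot sample {n} of {k} contacts")
    if mode == "top":
        top = np.sort(weights)[-n:]
        return [gini(top)]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(max(1, reps)):
        sub = rng.choice(weights, size=n, replace=False)
        out.append(gini(sub))
    return out


DEFAULT_RESAMPLE_GRID = (3, 5, 7, 10, 15, 20)


# ---------------------------------------------------------------------------
# per-chat / per-participant / per-platform tables

def per_chat_metrics(
    donation: Donation,
    threshold: float = INTERACTIVITY_THRESHOLD,
    min_days: int = MIN_INTERACTION_DAYS,
) -> pd.DataFrame:
    """One row per chat: filter decision, bias (dyadic), burstiness."""
    rows = []
    for conv in donation.conversations:
        row: dict = {
            "donor_id": donation.donor_id,
            "conversation_id": conv.conversation_id,
            "platform": conv.platform.value,
            "is_group": conv.is_group,
            "n_messages": len(conv.messages),
            "total_words": sum(m.word_count for m in conv.messages),
            "max_share": np.nan,
            "interactive": False,
            "bias": np.nan,
            "n_days": interevent_series(conv).n_days,
            "b1": np.nan,
        }
        try:
            decision = is_interactive(conv, threshold)
            row["max_share"] = decision.max_share
            row["interactive"] = decision.interactive
        except EmptyChat:
            rows.append(row)
            continue
        if decision.interactive and not conv.is_group:
            tally = contact_tally(conv, donation.donor_id)
            if tally.w_ij + tally.w_ji > 0:
                row["bias"] = interaction_bias(tally)
        if decision.interactive:
            series = interevent_series(conv)
            if series.n_days >= min_days:
                row["b1"] = burstiness(series, min_days).b1
        rows.append(row)
    return pd.DataFrame(rows)


def per_participant_metrics(
    donations: Iterable[Donation],
    threshold: float = INTERACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """One row per donation: median bias over interactive dyadic chats and
    Gini of donor-sent words over interactive chats."""
    rows = []
    for d in donations:
        chats = per_chat_metrics(d, threshold)
        biases = chats.loc[chats["interactive"] & ~chats["is_group"], "bias"].dropna()
        weights = donor_weight_vector(d, interactive_only=True, threshold=threshold)
        try:
            g = gini(weights) if weights.size else np.nan
        except ZeroTotal:
            g = np.nan
        rows.append({
            "donor_id": d.donor_id,
            "platform": d.platform.value,
            "n_chats": len(d.conversations),
            "n_interactive": int(chats["interactive"].sum()),
            "median_bias": float(biases.median()) if len(biases) else np.nan,
            "gini": g,
        })
    return pd.DataFrame(rows)


def _spread(x: pd.Series) -> dict:
    x = x.dropna()
    return {
        "median": float(x.median()),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        "min": float(x.min()),
        "max": float(x.max()),
    }


def summarize_donations(
    donations: Sequence[Donation],
    threshold: float = INTERACTIVITY_THRESHOLD,
    min_days: int = MIN_INTERACTION_DAYS,
) -> dict:
    """Descriptive statistics per platform plus pooled metric medians."""
    if not donations:
        raise ValueError("need at least one donation")
    chat_tables = [per_chat_metrics(d, threshold, min_days) for d in donations]
    chats = pd.concat(chat_tables, ignore_index=True)
    participants = per_participant_metrics(donations, threshold)

    summary: dict = {"platforms": {}, "pooled": {}}
    for platform in sorted({d.platform.value for d in donations}):
        plat_donations = [d for d in donations if d.platform.value == platform]
        pchats = chats[chats["platform"] == platform]
        ppart = participants[participants["platform"] == platform]
        inter = pchats[pchats["interactive"]]
        per_person_chats = pd.Series([len(d.conversations) for d in plat_donations])
        per_person_groups = pd.Series([
            sum(c.is_group for c in d.conversations) for d in plat_donations
        ])
        timespans, msg_counts = [], []
        for d in plat_donations:
            stamps = [m.timestamp for c in d.conversations for m in c.messages]
            timespans.append((max(stamps) - min(stamps)).days if stamps else 0)
            msg_counts.append(sum(len(c.messages) for c in d.conversations))
        eligible = inter["b1"].dropna()
        summary["platforms"][platform] = {
            "n_donations": len(plat_donations),
            "n_chats": int(len(pchats)),
            "pct_group_chats": 100.0 * pchats["is_group"].mean() if len(pchats) else 0.0,
            "n_interactive_chats": int(len(inter)),
            "pct_group_interactive": 100.0 * inter["is_group"].mean() if len(inter) else 0.0,
            "chats_per_person": _spread(per_person_chats),
            "group_chats_per_person": _spread(per_person_groups),
            "timespan_days": _spread(pd.Series(timespans)),
            "message_count": _spread(pd.Series(msg_counts)),
            "median_interactive_share": float(np.median([
                len(t[t["interactive"]]) / len(t)
                for d, t in zip(donations, chat_tables)
                if d.platform.value == platform and len(t)
            ])),
            "median_bias": float(ppart["median_bias"].median()),
            "median_gini": float(ppart["gini"].median()),
            "n_eligible_chats": int(len(eligible)),
            "pct_b1_positive": 100.0 * float((eligible > 0).mean()) if len(eligible) else np.nan,
            "median_b1": float(eligible.median()) if len(eligible) else np.nan,
        }
    pooled_b1 = chats.loc[chats["interactive"], "b1"].dropna()
    summary["pooled"] = {
        "n_eligible_chats": int(len(pooled_b1)),
        "median_b1": float(pooled_b1.median()) if len(pooled_b1) else np.nan,
        "median_bias": float(participants["median_bias"].median()),
        "median_gini": float(participants["gini"].median()),
    }
    return summary


# ---------------------------------------------------------------------------
# loading external minimized datasets

def load_donations_csv(
    conversations_csv: str,
    messages_csv: str,
    column_map: Optional[dict[str, str]] = None,
) -> list[Donation]:
    """Rebuild donations from the relational CSV schema.

    ``column_map`` renames external columns onto the native schema
    (donor_id, external_donor_id, conversation_id, sender_id, datetime,
    word_count, voice_duration_s, is_group, platform), so a deposited
    dataset can be ingested after a documented mapping step.
    """
    from .minimizer import MinimizedConversation, MinimizedMessage  # local import

    convs = pd.read_csv(conversations_csv)
    msgs = pd.read_csv(messages_csv)
    if column_map:
        convs = convs.rename(columns=column_map)
        msgs = msgs.rename(columns=column_map)
    for col in ("conversation_id", "donor_id", "platform"):
        if col not in convs.columns:
            raise KeyError(f"conversations table missing column '{col}'")
    for col in ("conversation_id", "sender_id", "datetime", "word_count"):
        if col not in msgs.columns:
            raise KeyError(f"messages table missing column '{col}'")

    msgs_by_conv = dict(tuple(msgs.groupby("conversation_id", sort=False)))
    donations: list[Donation] = []
    for (donor_id, platform), group in convs.groupby(["donor_id", "platform"], sort=True):
        conversations = []
        for _, crow in group.iterrows():
            block = msgs_by_conv.get(crow["conversation_id"])
            messages = []
            if block is not None:
                for _, mrow in block.iterrows():
                    dur = mrow.get("voice_duration_s")
                    messages.append(MinimizedMessage(
                        sender_id=str(mrow["sender_id"]),
                        timestamp=pd.Timestamp(mrow["datetime"]).to_pydatetime(),
                        word_count=int(mrow["word_count"]),
                        voice_duration_s=None if pd.isna(dur) else float(dur),
                        is_media=bool(mrow.get("is_media", False)),
                    ))
                messages.sort(key=lambda m: m.timestamp)
            conversations.append(MinimizedConversation(
                conversation_id=str(crow["conversation_id"]),
                platform=_platform_of(str(platform)),
                is_group=bool(crow.get("is_group", False)),
                participant_ids={m.sender_id for m in messages} | {str(donor_id)},
                messages=messages,
            ))
        donations.append(Donation(
            donor_id=str(donor_id),
            platform=_platform_of(str(platform)),
            conversations=conversations,
            donation_timestamp=dt.datetime(1970, 1, 1),
            external_donor_id=None,
        ))
    return donations


def _platform_of(name: str):
    from .types import Platform

    return Platform(name.lower())
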