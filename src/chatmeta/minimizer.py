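"""De-identification of raw conversations into metadata-only donations.

This is the privacy boundary of the pipeline: everything downstream of
:func:`minimize` sees only pseudonymous IDs, timestamps, word counts and
voice durations. No text field other than opaque IDs survives, and the
donor is the only party whose ID is shared across conversations.
"""
from __future__ import annotations

import datetime as dt
import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .chat_formats.encoding import repair_text_encoding
from .errors import InvalidRange, UnmappedSender
from .types import DonorProfile, MessageKind, Platform, RawConversation

_TOKEN_RE = re.compile(r"\S+")
_ID_BITS = 64

SCHEMA_VERSION = "chatmeta-donation/1"


def count_words(content: str) -> int:
    """Number of maximal whitespace-delimited tokens after encoding repair."""
    if not content:
        return 0
    return len(_TOKEN_RE.findall(repair_text_encoding(content)))


@dataclass
class PseudonymMap:
    """Injective display-name → opaque-ID mapping for one donation."""

    name_to_id: dict[str, str]
    donor_pseudonym: str

    def lookup(self, name: str) -> str:
        try:
            return self.name_to_id[name]
        except KeyError:
            raise UnmappedSender(f"sender has no pseudonym") from None


@dataclass
class MinimizedMessage:
    sender_id: str
    timestamp: dt.datetime
    word_count: int
    voice_duration_s: Optional[float] = None
    is_media: bool = False


@dataclass
class MinimizedConversation:
    conversation_id: str
    platform: Platform
    is_group: bool
    participant_ids: set[str]
    messages: list[MinimizedMessage] = field(default_factory=list)


@dataclass
class Donation:
    donor_id: str
    platform: Platform
    conversations: list[MinimizedConversation]
    donation_timestamp: dt.datetime
    external_donor_id: Optional[str] = None


def _draw_id(rng: random.Random, forbidden: Iterable[str]) -> str:
    lowered = [f.lower() for f in forbidden if f]
    for _ in range(1000):
        token = f"{rng.getrandbits(_ID_BITS):016x}"
        if not any(name in token for name in lowered):
            return token
    raise RuntimeError("could not draw a clean pseudonym")  # pragma: no cover


def build_pseudonym_map(
    donor: DonorProfile,
    convs: list[RawConversation],
    rng_seed: int,
) -> PseudonymMap:
    """Assign opaque IDs to every participant name across all conversations.

    All donor aliases share one ID; other names get independent IDs.
    Deterministic under ``rng_seed``; IDs never contain a source name.
    """
    rng = random.Random(rng_seed)
    names = sorted({n for c in convs for n in c.participant_names} | donor.display_names)
    mapping: dict[str, str] = {}
    used: set[str] = set()
    donor_id = _draw_id(rng, names)
    used.add(donor_id)
    for name in names:
        if name in donor.display_names:
            mapping[name] = donor_id
            continue
        token = _draw_id(rng, names)
        while token in used:
            token = _draw_id(rng, names)  # pragma: no cover
        used.add(token)
        mapping[name] = token
    return PseudonymMap(name_to_id=mapping, donor_pseudonym=donor_id)


def minimize(
    conv: RawConversation,
    pmap: PseudonymMap,
    conversation_id: str,
) -> MinimizedConversation:
    """Reduce a raw conversation to de-identified metadata.

    System messages are dropped (they are not interactions); media and
    voice messages are kept with word count 0 so timing analyses see
    them; voice durations are preserved.
    """
    out: list[MinimizedMessage] = []
    for msg in conv.messages:
        if msg.kind == MessageKind.SYSTEM:
            continue
        sender_id = pmap.lookup(msg.sender_name)
        if msg.kind == MessageKind.VOICE:
            out.append(MinimizedMessage(sender_id, msg.timestamp, 0,
                                        voice_duration_s=msg.voice_duration_s))
        elif msg.kind == MessageKind.MEDIA:
            out.append(MinimizedMessage(sender_id, msg.timestamp, 0, is_media=True))
        else:
            out.append(MinimizedMessage(sender_id, msg.timestamp, count_words(msg.content)))
    return MinimizedConversation(
        conversation_id=conversation_id,
        platform=conv.platform,
        is_group=conv.is_group,
        participant_ids={pmap.lookup(n) for n in conv.participant_names},
        messages=out,
    )


def minimize_donation(
    donor: DonorProfile,
    convs: list[RawConversation],
    rng_seed: int,
    external_donor_id: Optional[str] = None,
    donation_timestamp: Optional[dt.datetime] = None,
) -> Donation:
    """Pseudonymize and minimize a full set of conversations in one step."""
    pmap = build_pseudonym_map(donor, convs, rng_seed)
    rng = random.Random(rng_seed + 1)
    platform = convs[0].platform if convs else Platform.WHATSAPP
    minimized = [
        minimize(c, pmap, conversation_id=f"c{rng.getrandbits(_ID_BITS):016x}")
        for c in convs
    ]
    return Donation(
        donor_id=pmap.donor_pseudonym,
        platform=platform,
        conversations=minimized,
        donation_timestamp=donation_timestamp or dt.datetime.now().replace(microsecond=0),
        external_donor_id=external_donor_id,
    )


def restrict_period(d: Donation, start: dt.date, end: dt.date) -> Donation:
    """Keep only messages whose date lies in [start, end]; drop emptied chats."""
    if start > end:
        raise InvalidRange(f"start {start} after end {end}")
    convs = []
    for conv in d.conversations:
        kept = [m for m in conv.messages if start <= m.timestamp.date() <= end]
        if kept:
            convs.append(MinimizedConversation(
                conv.conversation_id, conv.platform, conv.is_group,
                set(conv.participant_ids), kept,
            ))
    return Donation(d.donor_id, d.platform, convs, d.donation_timestamp, d.external_donor_id)


# ---------------------------------------------------------------------------
# serialization

def donation_to_dict(d: Donation) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "donor_id": d.donor_id,
        "external_donor_id": d.external_donor_id,
        "platform": d.platform.value,
        "donation_timestamp": d.donation_timestamp.isoformat(),
        "conversations": [
            {
                "conversation_id": c.conversation_id,
                "platform": c.platform.value,
                "is_group": c.is_group,
                "participant_ids": sorted(c.participant_ids),
                "messages": [
                    {
                        "sender_id": m.sender_id,
                        "datetime": m.timestamp.isoformat(),
                        "word_count": m.word_count,
                        **({"voice_duration_s": m.voice_duration_s}
                           if m.voice_duration_s is not None else {}),
                        **({"is_media": True} if m.is_media else {}),
                    }
                    for m in c.messages
                ],
            }
            for c in d.conversations
        ],
    }


def donation_from_dict(doc: dict) -> Donation:
    convs = []
    for c in doc["conversations"]:
        msgs = [
            MinimizedMessage(
                sender_id=m["sender_id"],
                timestamp=dt.datetime.fromisoformat(m["datetime"]),
                word_count=int(m["word_count"]),
                voice_duration_s=m.get("voice_duration_s"),
                is_media=bool(m.get("is_media", False)),
            )
            for m in c["messages"]
        ]
        convs.append(MinimizedConversation(
            conversation_id=c["conversation_id"],
            platform=Platform(c["platform"]),
            is_group=bool(c["is_group"]),
            participant_ids=set(c["participant_ids"]),
            messages=msgs,
        ))
    return Donation(
        donor_id=doc["donor_id"],
        platform=Platform(doc["platform"]),
        conversations=convs,
        donation_timestamp=dt.datetime.fromisoformat(doc["donation_timestamp"]),
        external_donor_id=doc.get("external_donor_id"),
    )


def write_donation_json(d: Donation, path: str | Path) -> None:
    Path(path).write_text(json.dumps(donation_to_dict(d), indent=1), encoding="utf-8")


def read_donation_json(path: str | Path) -> Donation:
    return donation_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def donation_to_frames(d: Donation) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relational form: one conversations table, one messages table."""
    conv_rows = [
        {
            "conversation_id": c.conversation_id,
            "donor_id": d.donor_id,
            "external_donor_id": d.external_donor_id,
            "platform": c.platform.value,
            "is_group": c.is_group,
        }
        for c in d.conversations
    ]
    msg_rows = [
        {
            "conversation_id": c.conversation_id,
            "sender_id": m.sender_id,
            "datetime": m.timestamp.isoformat(),
            "word_count": m.word_count,
            "voice_duration_s": m.voice_duration_s,
            "is_media": m.is_media,
        }
        for c in d.conversations
        for m in c.messages
    ]
    return pd.DataFrame(conv_rows), pd.DataFrame(msg_rows)


def write_donation_csv(d: Donation, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    convs, msgs = donation_to_frames(d)
    conv_path, msg_path = out / "conversations.csv", out / "messages.csv"
    convs.to_csv(conv_path, index=False)
    msgs.to_csv(msg_path, index=False)
    return conv_path, msg_path


# ---------------------------------------------------------------------------
# leakage audit

def audit_no_leakage(d: Donation, sentinel_vocabulary: set[str]) -> list[dict]:
    """Scan every serialized field of a donation for planted sentinel strings.

    Returns one finding per (field path, sentinel) hit; an empty list
    means the minimization contract holds for this fixture.
    """
    sentinels = [s.lower() for s in sentinel_vocabulary if s]
    findings: list[dict] = []

    def scan(path: str, value) -> None:
        if isinstance(value, dict):
            for k, v in value.items():
                scan(f"{path}.{k}" if path else k, v)
        elif isinstance(value, list):
            for i, v in enumerate(value):
                scan(f"{path}[{i}]", v)
        elif isinstance(value, str):
            low = value.lower()
            for s in sentinels:
                if s in low:
                    findings.append({"field": path, "sentinel": s})

    scan("", donation_to_dict(d))
    return findings
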