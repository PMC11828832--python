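"""Raw (pre-minimization) conversation model shared by all parsers.

Raw objects hold message content and display names. They exist only in
memory between parsing and minimization and are never serialized by the
pipeline.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

EARLIEST_TIMESTAMP = dt.datetime(1990, 1, 1)


class MessageKind(str, Enum):
    TEXT = "text"
    MEDIA = "media"
    VOICE = "voice"
    SYSTEM = "system"


class Platform(str, Enum):
    WHATSAPP = "whatsapp"
    FACEBOOK = "facebook"
    INSTAGRAM = "instagram"


@dataclass
class RawMessage:
    """A single message as exported by a platform.

    ``sender_name`` is empty for system messages.  ``voice_duration_s``
    is present exactly when ``kind`` is voice.
    """

    timestamp: dt.datetime
    sender_name: str
    content: str
    kind: MessageKind = MessageKind.TEXT
    voice_duration_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == MessageKind.SYSTEM and self.sender_name:
            raise ValueError("system messages carry no sender name")
        if self.kind == MessageKind.VOICE:
            if self.voice_duration_s is None or self.voice_duration_s < 0:
                raise ValueError("voice messages need a non-negative duration")
        elif self.voice_duration_s is not None:
            raise ValueError("voice_duration_s only valid for voice messages")
        horizon = dt.datetime.now() + dt.timedelta(days=1)
        if not (EARLIEST_TIMESTAMP <= self.timestamp <= horizon):
            raise ValueError(f"timestamp out of plausible range: {self.timestamp}")


@dataclass
class RawConversation:
    """One chat thread: participants plus its time-ordered messages."""

    platform: Platform
    thread_name: str
    participant_names: set[str] = field(default_factory=set)
    is_group: bool = False
    messages: list[RawMessage] = field(default_factory=list)

    def sort(self) -> None:
        self.messages.sort(key=lambda m: m.timestamp)

    def validate(self) -> None:
        for a, b in zip(self.messages, self.messages[1:]):
            if b.timestamp < a.timestamp:
                raise ValueError("messages not time-ordered")
        for m in self.messages:
            if m.kind != MessageKind.SYSTEM and m.sender_name not in self.participant_names:
                raise ValueError(f"sender not in participant set")


@dataclass
class DonorProfile:
    """Display names under which the donor appears in the export."""

    display_names: set[str]

    def __post_init__(self) -> None:
        if not any(n for n in self.display_names):
            raise ValueError("donor profile needs at least one non-empty name")
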