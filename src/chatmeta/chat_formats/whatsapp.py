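"""WhatsApp plain-text export parsing.

WhatsApp writes one export file per chat, with a header line per message
whose layout depends on the device locale: bracketed vs plain-dash
framing, day-month-year vs month-day-year dates, 12h vs 24h clocks, with
or without seconds. The dialect is auto-detected as the candidate grammar
that parses the most header lines.
"""
from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Optional, Sequence

from ..errors import NoDialectMatch
from ..types import MessageKind, Platform, RawConversation, RawMessage
from .languages import MEDIA_MARKERS, SYSTEM_PATTERNS, all_media_markers, all_system_patterns

log = logging.getLogger(__name__)

_DATE_RE = r"(?P<d1>\d{1,2})(?P<sep>[./])(?P<d2>\d{1,2})(?P=sep)(?P<y>\d{2,4})"
_TIME24 = r"(?P<h>\d{1,2}):(?P<mi>\d{2})"
_TIME12_SUFFIX = r" (?P<ampm>[AaPp])\.?[Mm]\.?"
_SECONDS = r":(?P<s>\d{2})"


@dataclass(frozen=True)
class WhatsAppDialect:
    """One concrete header grammar for a WhatsApp export."""

    bracket_style: str  # "bracketed" | "plain-dash"
    date_order: str  # "DMY" | "MDY"
    hour24: bool
    seconds: bool
    year_digits: int = 2
    date_sep: str = "."
    language: str = "en"

    def header_regex(self) -> re.Pattern[str]:
        time = _TIME24
        if self.seconds:
            time += _SECONDS
        if not self.hour24:
            time += _TIME12_SUFFIX
        if self.bracket_style == "bracketed":
            pattern = rf"^\[{_DATE_RE}, {time}\] (?P<rest>.*)$"
        else:
            pattern = rf"^{_DATE_RE}, {time} - (?P<rest>.*)$"
        return re.compile(pattern)

    def parse_timestamp(self, m: re.Match[str]) -> dt.datetime:
        d1, d2, y = int(m["d1"]), int(m["d2"]), int(m["y"])
        if y < 100:  # two-digit years: pivot at 70
            y = 2000 + y if y < 70 else 1900 + y
        day, month = (d1, d2) if self.date_order == "DMY" else (d2, d1)
        hour, minute = int(m["h"]), int(m["mi"])
        second = int(m["s"]) if self.seconds and m["s"] else 0
        if not self.hour24:
            if hour < 1 or hour > 12:
                raise ValueError(f"bad 12h hour {hour}")
            hour %= 12
            if m["ampm"].lower() == "p":
                hour += 12
        return dt.datetime(y, month, day, hour, minute, second)

    def format_timestamp(self, ts: dt.datetime) -> str:
        day, month = ts.day, ts.month
        a, b = (day, month) if self.date_order == "DMY" else (month, day)
        year = ts.year % 100 if self.year_digits == 2 else ts.year
        ystr = f"{year:02d}" if self.year_digits == 2 else f"{year:04d}"
        date = f"{a:02d}{self.date_sep}{b:02d}{self.date_sep}{ystr}"
        hour = ts.hour
        suffix = ""
        if not self.hour24:
            suffix = " AM" if hour < 12 else " PM"
            hour = hour % 12 or 12
        time = f"{hour:02d}:{ts.minute:02d}" if self.hour24 else f"{hour}:{ts.minute:02d}"
        if self.seconds:
            time += f":{ts.second:02d}"
        return f"{date}, {time}{suffix}"

    def format_header(self, ts: dt.datetime, sender: str, body: str) -> str:
        stamp = self.format_timestamp(ts)
        rest = f"{sender}: {body}" if sender else body
        if self.bracket_style == "bracketed":
            return f"[{stamp}] {rest}"
        return f"{stamp} - {rest}"


def candidate_dialects() -> list[WhatsAppDialect]:
    """All grammars tried during detection, in tie-break preference order."""
    out = []
    for order, hour24, bracket, seconds in product(
        ("DMY", "MDY"), (True, False), ("plain-dash", "bracketed"), (False, True)
    ):
        out.append(WhatsAppDialect(bracket, order, hour24, seconds))
    return out


def _normalize_line(line: str) -> str:
    # iOS inserts LTR marks and narrow no-break spaces around timestamps
    return line.replace("‎", "").replace(" ", " ").replace("\xa0", " ").rstrip("\r\n")


def _count_matches(dialect: WhatsAppDialect, lines: Sequence[str]) -> int:
    rx = dialect.header_regex()
    n = 0
    for line in lines:
        m = rx.match(line)
        if m is None:
            continue
        try:
            dialect.parse_timestamp(m)
        except ValueError:
            continue
        n += 1
    return n


def detect_whatsapp_dialect(lines: Iterable[str]) -> WhatsAppDialect:
    """Pick the dialect whose grammar parses the most header lines.

    Ties are broken by preferring day-month-year dates and 24h clocks,
    the most common layouts in the supported locales. Raises
    :class:`NoDialectMatch` when no candidate parses a single line.
    """
    norm = [_normalize_line(l) for l in lines]
    best: Optional[WhatsAppDialect] = None
    best_count = 0
    for cand in candidate_dialects():  # ordered by preference
        c = _count_matches(cand, norm)
        if c > best_count:
            best, best_count = cand, c
    if best is None:
        raise NoDialectMatch("no WhatsApp header grammar matches any line")
    # pin concrete separator / year width from the first matching line
    rx = best.header_regex()
    for line in norm:
        m = rx.match(line)
        if m:
            return replace(best, date_sep=m["sep"], year_digits=2 if len(m["y"]) < 4 else 4)
    return best


_SENDER_RE = re.compile(r"^(?P<sender>[^:]+?): (?P<content>.*)$", re.DOTALL)


def _classify_media(content: str) -> bool:
    stripped = content.strip()
    return stripped in all_media_markers()


def _is_system_body(body: str) -> bool:
    low = body.lower()
    return any(pat.lower() in low for pat in all_system_patterns())


def parse_whatsapp(
    text: str,
    dialect: Optional[WhatsAppDialect] = None,
    thread_name: str = "",
) -> RawConversation:
    """Parse one WhatsApp export file into a :class:`RawConversation`.

    Header lines become messages; other lines continue the previous
    message. Lines before the first header (export preambles) are
    discarded with a warning. Headers without a ``sender: `` part, and
    bodies matching the per-language system tables, become system
    messages; bodies equal to a media marker become media messages.
    """
    if text.startswith("﻿"):
        text = text[1:]
    lines = [_normalize_line(l) for l in text.split("\n")]
    if dialect is None:
        dialect = detect_whatsapp_dialect(lines)
    rx = dialect.header_regex()

    messages: list[RawMessage] = []
    participants: set[str] = set()
    preamble = 0
    skipped = 0
    for line in lines:
        if not line:
            if messages and messages[-1].kind == MessageKind.TEXT:
                messages[-1].content += "\n"
            continue
        m = rx.match(line)
        if m is None:
            if messages:
                prev = messages[-1]
                if prev.kind == MessageKind.TEXT:
                    prev.content = prev.content + "\n" + line if prev.content else line
            else:
                preamble += 1
            continue
        try:
            ts = dialect.parse_timestamp(m)
        except ValueError:
            skipped += 1
            continue
        rest = m["rest"]
        sm = _SENDER_RE.match(rest)
        if sm is None or _is_system_body(rest):
            messages.append(RawMessage(ts, "", rest if sm is None else rest, MessageKind.SYSTEM))
            continue
        sender, content = sm["sender"], sm["content"]
        participants.add(sender)
        if _classify_media(content):
            messages.append(RawMessage(ts, sender, "", MessageKind.MEDIA))
        else:
            messages.append(RawMessage(ts, sender, content, MessageKind.TEXT))
    if preamble:
        log.warning("%s: discarded %d pre-header lines", thread_name or "<whatsapp>", preamble)
    if skipped:
        log.warning("%s: skipped %d headers with malformed timestamps", thread_name or "<whatsapp>", skipped)

    for msg in messages:  # trailing blank continuations are noise
        if msg.kind == MessageKind.TEXT:
            msg.content = msg.content.rstrip("\n")
    conv = RawConversation(
        platform=Platform.WHATSAPP,
        thread_name=thread_name,
        participant_names=participants,
        is_group=len(participants) > 2,
        messages=messages,
    )
    conv.sort()
    return conv
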