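"""Facebook / Instagram "Download Your Information" archive parsing.

The archive (zip or unpacked directory) holds one directory per thread
under an ``inbox`` tree, each with numbered ``message_<n>.json`` parts.
Everything outside the message tree and the profile-information file is
ignored. String fields use Meta's Latin-1-escaped UTF-8 convention and
are repaired on read.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
import re
import zipfile
from collections import Counter, defaultdict
from pathlib import Path, PurePosixPath
from typing import Iterator, Optional

from ..errors import EmptyArchive, MalformedThread
from ..types import DonorProfile, MessageKind, Platform, RawConversation, RawMessage
from .encoding import repair_text_encoding

log = logging.getLogger(__name__)

_MESSAGE_FILE_RE = re.compile(r"message_\d+\.json$")
_EPOCH = dt.datetime(1970, 1, 1)


def _iter_files(root: Path) -> Iterator[tuple[str, bytes]]:
    if root.is_file() and root.suffix == ".zip":
        with zipfile.ZipFile(root) as zf:
            for name in zf.namelist():
                if not name.endswith("/"):
                    yield name, zf.read(name)
    else:
        for p in sorted(root.rglob("*")):
            if p.is_file():
                yield str(p.relative_to(root)), p.read_bytes()


def _from_epoch_ms(ms: int) -> dt.datetime:
    # naive epoch-UTC datetimes; no timezone shifting is applied
    return _EPOCH + dt.timedelta(milliseconds=ms)


def _voice_duration(entry: dict) -> float:
    for key in ("duration_seconds", "length_seconds", "duration_s"):
        if key in entry:
            return float(entry[key])
    return 0.0


def _parse_message(raw: dict) -> RawMessage:
    ts = _from_epoch_ms(int(raw["timestamp_ms"]))
    sender = repair_text_encoding(raw.get("sender_name", ""))
    audio = raw.get("audio_files")
    if audio:
        return RawMessage(ts, sender, "", MessageKind.VOICE,
                          voice_duration_s=_voice_duration(audio[0]))
    if raw.get("photos") or raw.get("videos") or raw.get("gifs") or raw.get("sticker"):
        return RawMessage(ts, sender, "", MessageKind.MEDIA)
    content = raw.get("content")
    if content is None:
        return RawMessage(ts, sender, "", MessageKind.MEDIA)
    return RawMessage(ts, sender, repair_text_encoding(content), MessageKind.TEXT)


def _infer_platform(paths: list[str]) -> Platform:
    joined = " ".join(paths).lower()
    if "instagram" in joined:
        return Platform.INSTAGRAM
    return Platform.FACEBOOK


def _read_profile(blob: bytes) -> Optional[DonorProfile]:
    try:
        doc = json.loads(blob)
    except json.JSONDecodeError:
        return None
    names: set[str] = set()

    def walk(node):
        if isinstance(node, dict):
            for key, val in node.items():
                if key in ("full_name", "name", "username") and isinstance(val, str):
                    names.add(repair_text_encoding(val))
                elif isinstance(val, (dict, list)):
                    walk(val)
        elif isinstance(node, list):
            for item in node:
                walk(item)

    walk(doc)
    names.discard("")
    return DonorProfile(display_names=names) if names else None


def parse_meta_archive(
    root: str | Path,
    platform: Optional[Platform] = None,
) -> tuple[DonorProfile, list[RawConversation]]:
    """Parse a Meta export into a donor profile plus one conversation per thread.

    Message parts of a thread are merged and time-sorted. The donor is
    read from the profile-information file when present; otherwise the
    participant present in the largest number of threads is taken (the
    donor is in every thread). Raises :class:`EmptyArchive` when the tree
    holds no message files; malformed threads are skipped with a warning.
    """
    root = Path(root)
    threads: dict[str, list[bytes]] = defaultdict(list)
    profile: Optional[DonorProfile] = None
    seen_paths: list[str] = [str(root)]
    for name, blob in _iter_files(root):
        seen_paths.append(name)
        posix = PurePosixPath(name.replace("\\", "/"))
        if "profile_information" in name and posix.suffix == ".json" and profile is None:
            profile = _read_profile(blob)
        if "inbox" in posix.parts and _MESSAGE_FILE_RE.search(posix.name):
            threads[str(posix.parent)].append(blob)
    if not threads:
        raise EmptyArchive(f"no message files under an inbox tree in {root}")
    if platform is None:
        platform = _infer_platform(seen_paths)

    conversations: list[RawConversation] = []
    for thread_dir in sorted(threads):
        try:
            conv = _parse_thread(thread_dir, threads[thread_dir], platform)
        except MalformedThread as exc:
            log.warning("skipping thread %s: %s", thread_dir, exc)
            continue
        conversations.append(conv)
    if not conversations:
        raise EmptyArchive(f"no parseable threads in {root}")

    if profile is None:
        profile = _infer_donor(conversations)
    return profile, conversations


def _parse_thread(thread_dir: str, parts: list[bytes], platform: Platform) -> RawConversation:
    participants: set[str] = set()
    title = ""
    messages: list[RawMessage] = []
    for blob in parts:
        try:
            doc = json.loads(blob)
        except json.JSONDecodeError as exc:
            raise MalformedThread(f"invalid JSON: {exc}") from exc
        if "participants" not in doc or "messages" not in doc:
            raise MalformedThread("missing participants or messages field")
        for p in doc["participants"]:
            if "name" in p:
                participants.add(repair_text_encoding(p["name"]))
        title = title or repair_text_encoding(doc.get("title", ""))
        for raw in doc["messages"]:
            if "timestamp_ms" not in raw:
                raise MalformedThread("message without timestamp_ms")
            messages.append(_parse_message(raw))
    conv = RawConversation(
        platform=platform,
        thread_name=title or thread_dir,
        participant_names=participants | {m.sender_name for m in messages if m.sender_name},
        is_group=len(participants) > 2,
        messages=messages,
    )
    conv.sort()
    return conv


def _infer_donor(conversations: list[RawConversation]) -> DonorProfile:
    membership: Counter[str] = Counter()
    sending: Counter[str] = Counter()
    for conv in conversations:
        for name in conv.participant_names:
            membership[name] += 1
        for name in {m.sender_name for m in conv.messages if m.sender_name}:
            sending[name] += 1
    best = max(membership, key=lambda n: (membership[n], sending[n], n))
    return DonorProfile(display_names={best})
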