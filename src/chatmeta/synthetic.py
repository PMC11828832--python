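"""Synthetic conversation generator and export renderers.

Produces raw conversations with controllable sender balance, contact
heterogeneity and day-gap burstiness, and renders them in the real
export formats (WhatsApp text dialects, Meta JSON trees) for end-to-end
round-trip and privacy testing.

All generated names and content tokens come from a closed sentinel
vocabulary, so a leakage audit of a minimized output can search for
every string the generator could possibly have planted.
"""
from __future__ import annotations

import datetime as dt
import json
import random
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from .chat_formats.languages import MEDIA_MARKERS
from .chat_formats.whatsapp import WhatsAppDialect
from .errors import InvalidParams
from .types import DonorProfile, MessageKind, Platform, RawConversation, RawMessage

SENTINEL_TOKENS: tuple[str, ...] = (
    "zorply", "quixat", "mirvon", "tulgrev", "wospren", "klyvet",
    "drossim", "pangrev", "yultrix", "sqanth", "grünkohl", "вітаю",
)
SENTINEL_NAMES: tuple[str, ...] = (
    "Vexalor Quint", "Morwint Süß", "Quissanda Grüße", "Truvelle Oz",
    "Ozmande Klyr", "Jörgenska Vil", "Plumetta Wyx", "Gravenna Tusk",
    "Ulfharan Mox", "Zembrosia Kelt",
)

_EPOCH = dt.datetime(1970, 1, 1)


@dataclass
class ChatSimParams:
    """Generative settings for one synthetic chat."""

    n_interaction_days: int = 10
    day_gap: tuple = ("fixed", 1)  # ("fixed", g) | ("geometric", p) | ("pareto", alpha, scale)
    messages_per_day: tuple = ("poisson", 3.0)  # ("fixed", m) | ("poisson", lam); min 1
    balance: float = 0.5  # target donor share of words
    words_per_message: tuple = ("lognormal", 1.5, 0.6)  # or ("fixed", w); min 1
    media_rate: float = 0.0
    voice_rate: float = 0.0  # only representable in Meta renders
    language: str = "en"
    start: dt.date = dt.date(2021, 1, 4)
    donor_name: str = SENTINEL_NAMES[0]
    contact_names: tuple[str, ...] = (SENTINEL_NAMES[1],)
    exact_donor_words: Optional[int] = None  # force the donor word total exactly

    def validate(self) -> None:
        if self.n_interaction_days < 1:
            raise InvalidParams("need at least one interaction day")
        for rate in (self.balance, self.media_rate, self.voice_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidParams("rates must lie in [0, 1]")
        if not self.contact_names:
            raise InvalidParams("need at least one contact")


@dataclass
class NetworkSimParams:
    """Settings for a donor's whole synthetic ego network."""

    k: int = 5
    contact_weights: tuple = ("equal", 200)  # ("equal", w) | ("lognormal", mu, sigma) | ("single_dominant", w)
    chat_params: ChatSimParams = field(default_factory=ChatSimParams)
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise InvalidParams("need at least one contact")
        self.chat_params.validate()


def _draw_gap(rng: random.Random, law: tuple) -> int:
    kind = law[0]
    if kind == "fixed":
        return int(law[1])
    if kind == "geometric":
        p = law[1]
        g = 1
        while rng.random() >= p:
            g += 1
        return g
    if kind == "pareto":
        alpha, scale = law[1], law[2]
        draw = scale / (rng.random() ** (1.0 / alpha))
        return max(1, round(draw))
    raise InvalidParams(f"unknown day-gap law {kind!r}")


def _draw_count(rng: random.Random, law: tuple) -> int:
    kind = law[0]
    if kind == "fixed":
        return max(1, int(law[1]))
    if kind == "poisson":
        # inverse-transform Poisson; lambdas here are small
        lam, total, k, p = law[1], 0.0, 0, 1.0
        import math

        l = math.exp(-lam)
        p = 1.0
        while True:
            p *= rng.random()
            if p <= l:
                break
            k += 1
        return max(1, k)
    raise InvalidParams(f"unknown count law {kind!r}")


def _draw_words(rng: random.Random, law: tuple) -> int:
    kind = law[0]
    if kind == "fixed":
        return max(1, int(law[1]))
    if kind == "lognormal":
        return max(1, round(rng.lognormvariate(law[1], law[2])))
    raise InvalidParams(f"unknown word law {kind!r}")


def _content(rng: random.Random, n_words: int) -> str:
    return " ".join(rng.choice(SENTINEL_TOKENS) for _ in range(n_words))


def _partition(rng: random.Random, total: int, parts: int) -> list[int]:
    """Random composition of ``total`` into ``parts`` positive integers."""
    if parts == 1:
        return [total]
    cuts = sorted(rng.sample(range(1, total), parts - 1))
    bounds = [0, *cuts, total]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def simulate_conversation(p: ChatSimParams, rng: random.Random) -> RawConversation:
    """Generate one raw conversation on exactly ``n_interaction_days`` days."""
    p.validate()
    days = [p.start]
    for _ in range(p.n_interaction_days - 1):
        days.append(days[-1] + dt.timedelta(days=_draw_gap(rng, p.day_gap)))
    yesterday = dt.date.today() - dt.timedelta(days=1)
    if days[-1] > yesterday:  # keep long series inside the plausible-time window
        shift = (days[-1] - yesterday).days
        days = [d - dt.timedelta(days=shift) for d in days]
        if days[0] < dt.date(1990, 1, 2):
            raise InvalidParams("series too long to fit the plausible time range")

    messages: list[RawMessage] = []
    participants = (p.donor_name, *p.contact_names)
    for day in days:
        n_msgs = _draw_count(rng, p.messages_per_day)
        minutes = sorted(rng.sample(range(24 * 60), min(n_msgs, 24 * 60)))
        for minute in minutes:
            ts = dt.datetime.combine(day, dt.time(minute // 60, minute % 60))
            donor_turn = rng.random() < p.balance
            sender = p.donor_name if donor_turn else rng.choice(p.contact_names)
            u = rng.random()
            if u < p.voice_rate:
                messages.append(RawMessage(ts, sender, "", MessageKind.VOICE,
                                           voice_duration_s=float(rng.randint(1, 120))))
            elif u < p.voice_rate + p.media_rate:
                messages.append(RawMessage(ts, sender, "", MessageKind.MEDIA))
            else:
                messages.append(RawMessage(ts, sender, _content(rng, _draw_words(rng, p.words_per_message))))

    if p.exact_donor_words is not None:
        _force_donor_words(messages, p, rng)

    conv = RawConversation(
        platform=Platform.WHATSAPP,
        thread_name=p.contact_names[0],
        participant_names=set(participants),
        is_group=len(participants) > 2,
        messages=messages,
    )
    conv.sort()
    return conv


def _force_donor_words(messages: list[RawMessage], p: ChatSimParams, rng: random.Random) -> None:
    """Rewrite donor text messages so their word counts sum exactly."""
    target = p.exact_donor_words or 0
    donor_texts = [m for m in messages
                   if m.sender_name == p.donor_name and m.kind == MessageKind.TEXT]
    if target == 0:
        for m in donor_texts:
            m.sender_name = rng.choice(p.contact_names)
        return
    if not donor_texts:  # promote the first text message to the donor
        texts = [m for m in messages if m.kind == MessageKind.TEXT]
        if not texts:
            raise InvalidParams("cannot force donor words in a chat without text")
        texts[0].sender_name = p.donor_name
        donor_texts = [texts[0]]
    if target < len(donor_texts):  # too many messages for the budget
        for m in donor_texts[target:]:
            m.sender_name = rng.choice(p.contact_names)
        donor_texts = donor_texts[:target]
    for m, words in zip(donor_texts, _partition(rng, target, len(donor_texts))):
        m.content = _content(rng, words)


def simulate_donation(
    p: NetworkSimParams,
    rng: Optional[random.Random] = None,
) -> tuple[DonorProfile, list[RawConversation]]:
    """Generate a donor's ego network of k dyadic chats."""
    p.validate()
    rng = rng or random.Random(p.seed)
    weights = _contact_weight_targets(p, rng)
    convs: list[RawConversation] = []
    for i in range(p.k):
        contact = f"{SENTINEL_NAMES[1 + i % (len(SENTINEL_NAMES) - 1)]} {i + 1:03d}"
        chat = replace(
            p.chat_params,
            contact_names=(contact,),
            exact_donor_words=weights[i] if weights is not None else p.chat_params.exact_donor_words,
        )
        convs.append(simulate_conversation(chat, rng))
    return DonorProfile(display_names={p.chat_params.donor_name}), convs


def _contact_weight_targets(p: NetworkSimParams, rng: random.Random) -> Optional[list[int]]:
    kind = p.contact_weights[0]
    if kind == "equal":
        return [int(p.contact_weights[1])] * p.k
    if kind == "single_dominant":
        return [int(p.contact_weights[1])] + [0] * (p.k - 1)
    if kind == "lognormal":
        mu, sigma = p.contact_weights[1], p.contact_weights[2]
        return [max(1, round(rng.lognormvariate(mu, sigma))) for _ in range(p.k)]
    if kind == "free":
        return None
    raise InvalidParams(f"unknown contact-weight law {p.contact_weights[0]!r}")


def sentinel_vocabulary(profile: DonorProfile, convs: Sequence[RawConversation]) -> set[str]:
    """Everything the generator may have planted: tokens plus all names."""
    vocab = set(SENTINEL_TOKENS)
    vocab |= profile.display_names
    for c in convs:
        vocab |= c.participant_names
    return vocab


# ---------------------------------------------------------------------------
# renderers

def render_whatsapp(conv: RawConversation, dialect: WhatsAppDialect) -> str:
    """Render a conversation as a WhatsApp export file in the given dialect.

    Voice messages are not representable in WhatsApp text exports and
    render as media markers.
    """
    marker = MEDIA_MARKERS[dialect.language][0]
    lines = []
    for m in conv.messages:
        if m.kind == MessageKind.SYSTEM:
            lines.append(dialect.format_header(m.timestamp, "", m.content))
        elif m.kind in (MessageKind.MEDIA, MessageKind.VOICE):
            lines.append(dialect.format_header(m.timestamp, m.sender_name, marker))
        else:
            lines.append(dialect.format_header(m.timestamp, m.sender_name, m.content))
    return "\n".join(lines) + "\n"


def _mojibake(s: str) -> str:
    # Meta's convention: UTF-8 bytes appear as individual Latin-1 code points
    return s.encode("utf-8").decode("latin-1")


def _to_epoch_ms(ts: dt.datetime) -> int:
    return round((ts - _EPOCH).total_seconds() * 1000)


def render_meta_json(
    profile: DonorProfile,
    convs: Sequence[RawConversation],
    out_dir: str | Path,
    parts_per_thread: int = 1,
    platform: Platform = Platform.FACEBOOK,
) -> Path:
    """Write an inbox-style Meta export tree; returns its root directory."""
    if parts_per_thread < 1:
        raise InvalidParams("parts_per_thread must be >= 1")
    root = Path(out_dir)
    donor_name = sorted(profile.display_names)[0]
    prof_dir = root / "profile_information"
    prof_dir.mkdir(parents=True, exist_ok=True)
    (prof_dir / "profile_information.json").write_text(json.dumps(
        {"profile_v2": {"name": {"full_name": _mojibake(donor_name)}}},
        ensure_ascii=True,
    ), encoding="utf-8")

    for i, conv in enumerate(convs):
        thread_dir = root / "messages" / "inbox" / f"thread_{i + 1}"
        thread_dir.mkdir(parents=True, exist_ok=True)
        msgs = [_meta_message(m) for m in reversed(conv.messages)]  # newest first
        chunks = _chunk(msgs, parts_per_thread)
        for part, chunk in enumerate(chunks, start=1):
            doc = {
                "participants": [{"name": _mojibake(n)} for n in sorted(conv.participant_names)],
                "messages": chunk,
                "title": _mojibake(conv.thread_name),
                "is_still_participant": True,
                "thread_path": f"inbox/thread_{i + 1}",
            }
            (thread_dir / f"message_{part}.json").write_text(
                json.dumps(doc, ensure_ascii=True), encoding="utf-8")
    return root


def _meta_message(m: RawMessage) -> dict:
    doc: dict = {
        "sender_name": _mojibake(m.sender_name),
        "timestamp_ms": _to_epoch_ms(m.timestamp),
    }
    if m.kind == MessageKind.VOICE:
        doc["audio_files"] = [{
            "uri": "messages/audio/clip.aac",
            "duration_seconds": m.voice_duration_s,
        }]
    elif m.kind == MessageKind.MEDIA:
        doc["photos"] = [{"uri": "messages/photos/img.jpg"}]
    else:
        doc["content"] = _mojibake(m.content)
    return doc


def _chunk(items: list, n_chunks: int) -> list[list]:
    n_chunks = min(n_chunks, max(1, len(items)))
    size = -(-len(items) // n_chunks) if items else 1
    chunks = [items[i:i + size] for i in range(0, len(items), size)]
    return chunks or [[]]


def zip_tree(root: str | Path, zip_path: str | Path) -> Path:
    """Pack a rendered export tree into a zip (as platforms deliver them)."""
    root, zip_path = Path(root), Path(zip_path)
    with zipfile.ZipFile(zip_path, "w") as zf:
        for p in sorted(root.rglob("*")):
            if p.is_file():
                zf.write(p, p.relative_to(root))
    return zip_path
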