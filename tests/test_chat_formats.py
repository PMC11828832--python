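import datetime as dt
import json
import random

import pytest
from hypothesis import given, strategies as st

from chatmeta import chat_formats as cf
from chatmeta import synthetic as sy
from chatmeta.chat_formats.whatsapp import WhatsAppDialect, candidate_dialects
from chatmeta.errors import EmptyArchive, NoDialectMatch
from chatmeta.types import MessageKind, Platform


class TestDialectDetection:
    def test_plain_dash_dmy_24h(self):
        d = cf.detect_whatsapp_dialect(["15.03.22, 14:32 - Alice: hi"])
        assert d.bracket_style == "plain-dash"
        assert d.date_order == "DMY"
        assert d.hour24 and not d.seconds
        assert d.year_digits == 2

    def test_bracketed_mdy_12h_seconds(self):
        d = cf.detect_whatsapp_dialect(["[3/15/22, 2:32:10 PM] Alice: hi"])
        assert d.bracket_style == "bracketed"
        assert d.date_order == "MDY"
        assert not d.hour24 and d.seconds
        assert d.date_sep == "/"

    def test_no_header_lines(self):
        with pytest.raises(NoDialectMatch):
            cf.detect_whatsapp_dialect(["random prose", "no headers"])

    def test_ambiguous_date_prefers_dmy(self):
        # 03.04 parses under both orders; DMY wins the tie
        d = cf.detect_whatsapp_dialect(["03.04.22, 10:11 - A: x"])
        assert d.date_order == "DMY"

    def test_unambiguous_mdy(self):
        # day 13 in the second slot rules out DMY on one of the lines
        lines = ["04/13/22, 10:11 - A: x", "04/02/22, 11:12 - B: y"]
        d = cf.detect_whatsapp_dialect(lines)
        assert d.date_order == "MDY"

    def test_majority_vote(self):
        lines = (["15.03.22, 14:32 - A: x"] * 3) + ["[3/15/22, 2:32 PM] A: y"]
        d = cf.detect_whatsapp_dialect(lines)
        assert d.bracket_style == "plain-dash"

    def test_detection_stable_under_continuation_shuffle(self, rng):
        headers = ["15.03.22, 14:32 - Alice: hello", "16.03.22, 09:01 - Bob: hey"]
        continuations = ["just prose", "another line", "more words here"]
        base = cf.detect_whatsapp_dialect(headers + continuations)
        for _ in range(5):
            rng.shuffle(continuations)
            assert cf.detect_whatsapp_dialect(headers + continuations) == base


class TestParseWhatsApp:
    def test_two_messages(self):
        conv = cf.parse_whatsapp("15.03.22, 14:32 - Alice: hello world\n"
                                 "15.03.22, 14:33 - Bob: hey")
        assert len(conv.messages) == 2
        assert conv.participant_names == {"Alice", "Bob"}
        assert conv.platform == Platform.WHATSAPP
        assert not conv.is_group

    def test_multiline_continuation(self):
        conv = cf.parse_whatsapp("15.03.22, 14:32 - Alice: line one\ncontinued line")
        assert len(conv.messages) == 1
        assert conv.messages[0].content == "line one\ncontinued line"

    def test_media_marker(self):
        conv = cf.parse_whatsapp("15.03.22, 14:32 - Alice: <Media omitted>")
        assert conv.messages[0].kind == MessageKind.MEDIA
        assert conv.messages[0].content == ""

    def test_system_line_without_sender(self):
        text = ("15.03.22, 14:31 - Messages and calls are end-to-end encrypted. "
                "No one outside of this chat can read them.\n"
                "15.03.22, 14:32 - Alice: hi")
        conv = cf.parse_whatsapp(text)
        assert [m.kind for m in conv.messages] == [MessageKind.SYSTEM, MessageKind.TEXT]
        assert conv.messages[0].sender_name == ""
        assert conv.participant_names == {"Alice"}

    def test_preamble_discarded(self):
        conv = cf.parse_whatsapp("some export preamble\n15.03.22, 14:32 - Alice: hi")
        assert len(conv.messages) == 1

    def test_malformed_timestamp_skipped(self):
        text = "31.02.22, 14:32 - Alice: bad date\n15.03.22, 14:33 - Bob: ok"
        dialect = WhatsAppDialect("plain-dash", "DMY", True, False)
        conv = cf.parse_whatsapp(text, dialect=dialect)
        assert len(conv.messages) == 1
        assert conv.messages[0].sender_name == "Bob"

    def test_two_digit_year_pivot(self):
        old = cf.parse_whatsapp("15.03.99, 14:32 - Alice: then",
                                dialect=WhatsAppDialect("plain-dash", "DMY", True, False))
        new = cf.parse_whatsapp("15.03.22, 14:32 - Alice: now",
                                dialect=WhatsAppDialect("plain-dash", "DMY", True, False))
        assert old.messages[0].timestamp.year == 1999
        assert new.messages[0].timestamp.year == 2022

    def test_group_flag(self):
        text = "\n".join(f"15.03.22, 14:{30 + i:02d} - P{i}: hi" for i in range(3))
        assert cf.parse_whatsapp(text).is_group

    def test_bom_tolerated(self):
        conv = cf.parse_whatsapp("﻿15.03.22, 14:32 - Alice: hi")
        assert len(conv.messages) == 1


class TestRepairEncoding:
    @pytest.mark.parametrize("clean", ["Grüße", "Привіт", "Բարեւ", "naïve café", "Süß"])
    def test_repairs_mojibake(self, clean):
        # oracle: mojibake is what a Latin-1 mis-decode of UTF-8 bytes produces
        mangled = clean.encode("utf-8").decode("latin-1")
        assert cf.repair_text_encoding(mangled) == clean

    def test_ascii_identity(self):
        assert cf.repair_text_encoding("hello") == "hello"

    def test_clean_unicode_untouched(self):
        assert cf.repair_text_encoding("Grüße") == "Grüße"

    def test_double_mangling_recovered(self):
        clean = "Grüße"
        double = clean.encode("utf-8").decode("latin-1").encode("utf-8").decode("latin-1")
        assert cf.repair_text_encoding(double) == clean

    @given(st.text(max_size=40))
    def test_idempotent(self, s):
        once = cf.repair_text_encoding(s)
        assert cf.repair_text_encoding(once) == once


class TestParseMetaArchive:
    def _archive(self, tmp_path, convs=None, parts=1, voice=False):
        rng = random.Random(7)
        if convs is None:
            p = sy.ChatSimParams(n_interaction_days=3, voice_rate=0.3 if voice else 0.0,
                                 messages_per_day=("fixed", 2))
            convs = [sy.simulate_conversation(p, rng)]
        profile = sy.DonorProfile(display_names={sy.SENTINEL_NAMES[0]})
        return sy.render_meta_json(profile, convs, tmp_path / "archive", parts_per_thread=parts)

    def test_basic_thread(self, tmp_path):
        root = self._archive(tmp_path)
        profile, convs = cf.parse_meta_archive(root)
        assert len(convs) == 1
        assert convs[0].platform == Platform.FACEBOOK
        assert sy.SENTINEL_NAMES[0] in profile.display_names

    def test_parts_merged_and_sorted(self, tmp_path):
        rng = random.Random(11)
        conv = sy.simulate_conversation(
            sy.ChatSimParams(n_interaction_days=5, messages_per_day=("fixed", 3)), rng)
        root = self._archive(tmp_path, convs=[conv], parts=2)
        assert len(list((root / "messages" / "inbox").rglob("message_*.json"))) == 2
        _, parsed = cf.parse_meta_archive(root)
        stamps = [m.timestamp for m in parsed[0].messages]
        assert stamps == sorted(stamps)
        assert len(parsed[0].messages) == len(conv.messages)

    def test_voice_duration_recovered(self, tmp_path):
        root = self._archive(tmp_path, voice=True)
        _, convs = cf.parse_meta_archive(root)
        voices = [m for m in convs[0].messages if m.kind == MessageKind.VOICE]
        assert voices and all(m.voice_duration_s > 0 for m in voices)

    def test_empty_archive(self, tmp_path):
        (tmp_path / "posts").mkdir()
        (tmp_path / "comments").mkdir()
        (tmp_path / "posts" / "your_posts.json").write_text("{}")
        with pytest.raises(EmptyArchive):
            cf.parse_meta_archive(tmp_path)

    def test_malformed_thread_skipped(self, tmp_path):
        root = self._archive(tmp_path)
        bad = root / "messages" / "inbox" / "thread_bad"
        bad.mkdir()
        (bad / "message_1.json").write_text(json.dumps({"no": "fields"}))
        _, convs = cf.parse_meta_archive(root)
        assert len(convs) == 1

    def test_zip_input(self, tmp_path):
        root = self._archive(tmp_path)
        zip_path = sy.zip_tree(root, tmp_path / "export.zip")
        _, convs = cf.parse_meta_archive(zip_path)
        assert len(convs) == 1

    def test_donor_inferred_without_profile(self, tmp_path):
        root = self._archive(tmp_path)
        (root / "profile_information" / "profile_information.json").unlink()
        rng = random.Random(5)
        convs = [sy.simulate_conversation(
            sy.ChatSimParams(n_interaction_days=2,
                             contact_names=(sy.SENTINEL_NAMES[i],)), rng)
            for i in range(2, 5)]
        root = sy.render_meta_json(sy.DonorProfile(display_names={sy.SENTINEL_NAMES[0]}),
                                   convs, tmp_path / "noprof")
        (root / "profile_information" / "profile_information.json").unlink()
        profile, _ = cf.parse_meta_archive(root)
        assert profile.display_names == {sy.SENTINEL_NAMES[0]}

    def test_instagram_platform_inferred(self, tmp_path):
        root = self._archive(tmp_path / "instagram_export")
        _, convs = cf.parse_meta_archive(root)
        assert convs[0].platform == Platform.INSTAGRAM


def _token_counts(conv):
    return [len(m.content.split()) if m.kind == MessageKind.TEXT else 0
            for m in conv.messages]


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", candidate_dialects(),
                             ids=lambda d: f"{d.bracket_style}-{d.date_order}-"
                                           f"{'24h' if d.hour24 else '12h'}-"
                                           f"{'s' if d.seconds else 'nos'}")
    def test_whatsapp_all_dialects(self, dialect, rng):
        p = sy.ChatSimParams(n_interaction_days=6, media_rate=0.15)
        conv = sy.simulate_conversation(p, rng)
        # the dialect is passed explicitly: ambiguous dates (day <= 12)
        # cannot distinguish DMY from MDY, by construction of the format
        parsed = cf.parse_whatsapp(sy.render_whatsapp(conv, dialect), dialect=dialect)
        assert parsed.participant_names == conv.participant_names
        assert [m.sender_name for m in parsed.messages] == [m.sender_name for m in conv.messages]
        assert [m.timestamp.replace(second=0) for m in parsed.messages] == \
               [m.timestamp.replace(second=0) for m in conv.messages]
        assert [m.kind for m in parsed.messages] == [m.kind for m in conv.messages]
        assert _token_counts(parsed) == _token_counts(conv)

    @pytest.mark.parametrize("language", cf.LANGUAGES)
    def test_all_language_markers(self, language, rng):
        p = sy.ChatSimParams(n_interaction_days=4, media_rate=0.3, language=language)
        conv = sy.simulate_conversation(p, rng)
        dialect = WhatsAppDialect("plain-dash", "DMY", True, False, language=language)
        parsed = cf.parse_whatsapp(sy.render_whatsapp(conv, dialect))
        assert [m.kind for m in parsed.messages] == [m.kind for m in conv.messages]

    def test_meta_round_trip_exact(self, tmp_path, rng):
        p = sy.ChatSimParams(n_interaction_days=5, media_rate=0.1, voice_rate=0.1)
        convs = [sy.simulate_conversation(p, rng)]
        profile = sy.DonorProfile(display_names={p.donor_name})
        root = sy.render_meta_json(profile, convs, tmp_path, parts_per_thread=2)
        _, parsed = cf.parse_meta_archive(root)
        orig, back = convs[0], parsed[0]
        assert back.participant_names == orig.participant_names
        assert [m.timestamp for m in back.messages] == [m.timestamp for m in orig.messages]
        assert [m.kind for m in back.messages] == [m.kind for m in orig.messages]
        assert _token_counts(back) == _token_counts(orig)

    def test_mojibake_name_recovered(self, tmp_path, rng):
        name = "Quissanda Grüße"
        p = sy.ChatSimParams(n_interaction_days=2, contact_names=(name,))
        convs = [sy.simulate_conversation(p, rng)]
        root = sy.render_meta_json(sy.DonorProfile(display_names={p.donor_name}),
                                   convs, tmp_path)
        raw = (root / "messages" / "inbox" / "thread_1" / "message_1.json").read_text()
        assert name not in raw  # stored mojibake-escaped
        _, parsed = cf.parse_meta_archive(root)
        assert name in parsed[0].participant_names
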