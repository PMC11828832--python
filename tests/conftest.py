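import datetime as dt
import random

import pytest

from chatmeta.minimizer import Donation, MinimizedConversation, MinimizedMessage
from chatmeta.types import Platform


def make_conv(donor_id, entries, cid="c1", platform=Platform.WHATSAPP,
              is_group=False, start=dt.datetime(2022, 1, 1, 12, 0)):
    """Build a MinimizedConversation from (sender, words[, timestamp]) tuples.

    Without explicit timestamps, messages are spaced one minute apart.
    """
    messages = []
    for i, entry in enumerate(entries):
        if len(entry) == 3:
            sender, words, ts = entry
        else:
            sender, words = entry
            ts = start + dt.timedelta(minutes=i)
        messages.append(MinimizedMessage(sender_id=sender, timestamp=ts, word_count=words))
    participants = {m.sender_id for m in messages} | {donor_id}
    return MinimizedConversation(
        conversation_id=cid, platform=platform, is_group=is_group,
        participant_ids=participants, messages=sorted(messages, key=lambda m: m.timestamp))


def make_donation(donor_id, convs, platform=Platform.WHATSAPP):
    return Donation(donor_id=donor_id, platform=platform, conversations=convs,
                    donation_timestamp=dt.datetime(2023, 6, 1, 9, 0))


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def balanced_donation():
    """Five dyadic chats, donor and contact each sending 50 words."""
    convs = [
        make_conv("donor", [("donor", 25), (f"p{i}", 25), ("donor", 25), (f"p{i}", 25)],
                  cid=f"c{i}")
        for i in range(5)
    ]
    return make_donation("donor", convs)
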