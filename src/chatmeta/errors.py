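"""Exception hierarchy for the chatmeta pipeline."""


class ChatMetaError(Exception):
    """Base class for all chatmeta errors."""


class NoDialectMatch(ChatMetaError):
    """No candidate WhatsApp dialect parses a single header line."""


class MalformedTimestamp(ChatMetaError):
    """A header line's datetime failed to parse under the chosen dialect."""


class EmptyArchive(ChatMetaError):
    """A Meta archive contains no message files."""


class MalformedThread(ChatMetaError):
    """A Meta thread JSON lacks required fields."""


class UnmappedSender(ChatMetaError):
    """A message sender has no pseudonym in the map."""


class InvalidRange(ChatMetaError):
    """Period restriction with start > end."""


class EmptyChat(ChatMetaError):
    """Word-based metric requested on a chat with zero words."""


class DegenerateTally(ChatMetaError):
    """Bias requested on a tally with no words in either direction."""


class ZeroTotal(ChatMetaError):
    """Gini requested on an all-zero weight vector."""


class IneligibleChat(ChatMetaError):
    """Burstiness requested on a chat with too few interaction days."""


class InvalidSample(ChatMetaError):
    """Resampling with more contacts than the network contains."""


class InvalidParams(ChatMetaError):
    """Simulation parameters outside their valid domain."""
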