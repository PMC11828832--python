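"""Repair of Latin-1-mis-decoded UTF-8 text (mojibake).

Meta archives escape UTF-8 bytes as individual Latin-1 code points, so a
JSON load yields strings like ``"GrÃ¼Ãe"`` for ``"Grüße"``.
"""
from __future__ import annotations

_MAX_PASSES = 5


def repair_text_encoding(s: str) -> str:
    """Re-decode Latin-1-mis-decoded UTF-8 sequences; idempotent.

    Applies the latin-1-encode / utf-8-decode round trip until the string
    stops changing, so already-clean text (which fails the round trip) and
    doubly-mangled text both converge to the same fixed point.
    """
    for _ in range(_MAX_PASSES):
        try:
            fixed = s.encode("latin-1").decode("utf-8")
        except (UnicodeEncodeError, UnicodeDecodeError):
            return s
        if fixed == s:
            return s
        s = fixed
    return s
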