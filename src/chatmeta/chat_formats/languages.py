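"""Per-language literal tables for WhatsApp exports.

Media-omitted markers and system-line patterns are table-driven so a new
locale is a configuration change rather than a code change. The tables
cover the five supported export languages; strings can be extended at
runtime via :func:`register_language`.
"""
from __future__ import annotations

# language code -> literal "media omitted" strings (without surrounding < >)
MEDIA_MARKERS: dict[str, tuple[str, ...]] = {
    "en": ("<Media omitted>", "image omitted", "video omitted", "audio omitted"),
    "de": ("<Medien ausgeschlossen>", "Bild weggelassen", "Video weggelassen"),
    "uk": ("<Без медіафайлів>", "зображення не додано"),
    "hy": ("<Մեդիան բացակայում է>",),
    "ru": ("<Без медиафайлов>", "изображение отсутствует"),
}

# substrings marking WhatsApp system lines (encryption notices, subject
# changes, group events); matched case-insensitively against the line body
SYSTEM_PATTERNS: dict[str, tuple[str, ...]] = {
    "en": (
        "Messages and calls are end-to-end encrypted",
        "created group",
        "changed the subject",
        "added you",
        "changed this group's icon",
        "You joined using this group's invite link",
    ),
    "de": (
        "Nachrichten und Anrufe sind Ende-zu-Ende-verschlüsselt",
        "hat die Gruppe erstellt",
        "hat den Betreff geändert",
    ),
    "uk": (
        "Повідомлення та дзвінки захищено наскрізним шифруванням",
        "створив(-ла) групу",
    ),
    "hy": (
        "Հաղորդագրություններն ու զանգերը ծայրից ծայր գաղտնագրված են",
        "ստեղծել է խումբը",
    ),
    "ru": (
        "Сообщения и звонки защищены сквозным шифрованием",
        "создал(-а) группу",
    ),
}

LANGUAGES = tuple(MEDIA_MARKERS)


def register_language(code: str, media_markers: tuple[str, ...],
                      system_patterns: tuple[str, ...]) -> None:
    """Add or extend the literal tables for a locale."""
    MEDIA_MARKERS[code] = tuple(media_markers)
    SYSTEM_PATTERNS[code] = tuple(system_patterns)


def all_media_markers() -> frozenset[str]:
    return frozenset(m for ms in MEDIA_MARKERS.values() for m in ms)


def all_system_patterns() -> frozenset[str]:
    return frozenset(p for ps in SYSTEM_PATTERNS.values() for p in ps)
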