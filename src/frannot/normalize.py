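"""Text normalization shared by the dictionary builder, the recognizer and
the context detector.

All matching in this package happens on a *normalized* view of the text:
Unicode casefold, optional diacritic folding (NFKD decomposition with
combining marks removed), punctuation replaced by single spaces, whitespace
collapsed. A per-character offset map links every normalized character back
to the original string, so that reported annotation spans always index the
raw input (gold standards such as BRAT index raw text).

Normalization is idempotent: applying it to an already-normalized string is
a no-op.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field


def _fold_char(ch: str, fold_diacritics: bool) -> str:
    if not fold_diacritics:
        return ch
    # NFKD can surface cased characters (e.g. '𝕊' -> 'S'); casefold again
    # until stable so normalization stays idempotent
    for _ in range(3):
        decomposed = unicodedata.normalize("NFKD", ch)
        stripped = "".join(
            c for c in decomposed if not unicodedata.combining(c))
        folded = stripped.casefold()
        if folded == ch:
            break
        ch = folded
    return ch


@dataclass(frozen=True)
class NormalizedText:
    """A normalized string plus the offset map back to the original text.

    ``starts[i]``/``ends[i]`` give the half-open span of the original text
    that produced normalized character ``i``.
    """

    text: str
    starts: tuple[int, ...]
    ends: tuple[int, ...]
    original: str = field(repr=False, default="")

    def to_original(self, begin: int, end: int) -> tuple[int, int]:
        """Map a half-open span of the normalized text to original offsets."""
        if not (0 <= begin < end <= len(self.text)):
            raise ValueError(f"invalid normalized span ({begin}, {end})")
        return self.starts[begin], self.ends[end - 1]

    def is_token_start(self, i: int) -> bool:
        return i == 0 or self.text[i - 1] == " "

    def is_token_end(self, i: int) -> bool:
        """True if position i (exclusive end) falls on a token boundary."""
        return i == len(self.text) or self.text[i] == " "


def normalize_text(text: str, fold_diacritics: bool = True) -> NormalizedText:
    """Normalize ``text`` keeping a character-level offset map.

    Token boundary rule: a token is a maximal run of alphanumeric characters
    (accented letters included before folding); everything else — including
    apostrophes and hyphens — separates tokens, so ``l'urètre`` exposes the
    token ``uretre``.
    """
    chars: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for i, raw in enumerate(text):
        for folded in raw.casefold():
            for ch in _fold_char(folded, fold_diacritics):
                chars.append(ch if ch.isalnum() else " ")
                starts.append(i)
                ends.append(i + 1)
    # collapse space runs and strip the edges
    out_c: list[str] = []
    out_s: list[int] = []
    out_e: list[int] = []
    pending_space = False
    for ch, s, e in zip(chars, starts, ends):
        if ch == " ":
            pending_space = bool(out_c)
            continue
        if pending_space:
            out_c.append(" ")
            out_s.append(s)
            out_e.append(e)
            pending_space = False
        out_c.append(ch)
        out_s.append(s)
        out_e.append(e)
    return NormalizedText("".join(out_c), tuple(out_s), tuple(out_e), text)


def normalize(text: str, fold_diacritics: bool = True) -> str:
    """Normalized string without the offset map (for labels and triggers)."""
    return normalize_text(text, fold_diacritics=fold_diacritics).text


def tokenize(normalized: str) -> list[str]:
    return normalized.split(" ") if normalized else []
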