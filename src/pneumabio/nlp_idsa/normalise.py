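"""Spanish clinical-text normalisation with an offset map back to the raw note."""

from __future__ import annotations

import unicodedata

__all__ = ["normalise_text"]

# punctuation that is semantically inert in criterion matching; runs become
# a single space.  '/', '<', '>', '=' and '%' carry clinical meaning
# (e.g. "pao2/fio2 < 250") and are kept.
_STRIP_PUNCT = set(".,;:!?¡¿()[]{}\"'`«»*#|\\_-")


def normalise_text(raw: str) -> tuple[str, list[int]]:
    """Lowercase, fold diacritics (ñ preserved), collapse punctuation runs.

    Returns ``(normalised, offset_map)`` where ``offset_map[i]`` is the index
    in ``raw`` of the character that produced normalised character ``i``,
    allowing matched spans to be reported against the original note.
    """
    out: list[str] = []
    offsets: list[int] = []
    pending_space_from: int | None = None

    def emit(ch: str, orig_idx: int) -> None:
        nonlocal pending_space_from
        if pending_space_from is not None and out:
            out.append(" ")
            offsets.append(pending_space_from)
        pending_space_from = None
        out.append(ch)
        offsets.append(orig_idx)

    for idx, raw_ch in enumerate(raw):
        # compatibility-fold first (subscripts, ligatures), then lowercase
        for ch in unicodedata.normalize("NFKC", raw_ch).lower():
            if ch == "ñ":
                emit("ñ", idx)
                continue
            decomposed = unicodedata.normalize("NFD", ch)
            base = "".join(c for c in decomposed if not unicodedata.combining(c))
            for c in base:
                if c.isspace() or c in _STRIP_PUNCT:
                    if pending_space_from is None:
                        pending_space_from = idx
                else:
                    emit(c, idx)
    return "".join(out), offsets
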