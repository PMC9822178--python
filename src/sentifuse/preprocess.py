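"""Tweet text cleaning.

Raw tweets carry noise that sentiment classifiers should not see: URLs,
@-mentions, retweet markers, hashtag sigils, emoji and stray symbols.
:func:`clean_text` applies a fixed, ordered rule set; the order matters —
URLs are stripped before punctuation so URL fragments cannot survive.

The cleaning is idempotent and never lengthens a string, which makes it safe
to apply defensively at any pipeline stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["CleaningOptions", "clean_text", "word_count"]


@dataclass(frozen=True)
class CleaningOptions:
    """Cleaning flags.

    keep_hashtag_words: strip only the ``#`` sigil, keeping sentiment-bearing
    tokens like ``#exhausted``; set False to drop the whole hashtag token.
    """

    keep_hashtag_words: bool = True


_URL = re.compile(r"(?:https?://\S+|\bt\.co/\S+|\bwww\.\S+)", re.IGNORECASE)
_MENTION = re.compile(r"@\w+")
_RT = re.compile(r"^\s*RT\b\s*:?\s*")
_HASHTAG_TOKEN = re.compile(r"#\w+")

# textual emoticons removed as whole tokens; small fixed list
_EMOTICONS = re.compile(
    r"(?:(?<=\s)|^)(?::-?[)(DPpO/\\|]|;-?[)(]|:'\(|<3|xD|XD|:3)(?=\s|$)"
)

# unicode emoji/pictograph blocks
_EMOJI = re.compile(
    "["
    "\U0001f300-\U0001f5ff"  # symbols & pictographs
    "\U0001f600-\U0001f64f"  # emoticons
    "\U0001f680-\U0001f6ff"  # transport & map
    "\U0001f1e6-\U0001f1ff"  # regional indicators (flags)
    "\U0001f900-\U0001f9ff"  # supplemental symbols
    "\U0001fa70-\U0001faff"
    "☀-➿"  # misc symbols & dingbats
    "←-⇿"  # arrows
    "︎️‍"  # variation selectors, ZWJ
    "]+"
)

# keep word characters plus sentence punctuation . , ! ? ' -
_DISALLOWED = re.compile(r"[^\w\s.,!?'\-]|_")


def clean_text(raw: str, options: CleaningOptions = CleaningOptions()) -> str:
    """Clean one tweet.

    Rules applied in order: (1) strip URLs; (2) strip @mentions; (3) strip a
    leading ``RT`` retweet marker; (4) drop ``#`` sigils (or whole hashtag
    tokens in strict mode); (5) remove emoji and textual emoticons;
    (6) remove remaining characters outside letters/digits and the sentence
    punctuation ``. , ! ? ' -``; (7) collapse whitespace.
    """
    text = _URL.sub(" ", raw)
    text = _MENTION.sub(" ", text)
    text = _RT.sub("", text)
    if options.keep_hashtag_words:
        text = text.replace("#", " ")
    else:
        text = _HASHTAG_TOKEN.sub(" ", text)
    text = _EMOTICONS.sub(" ", text)
    text = _EMOJI.sub(" ", text)
    text = _DISALLOWED.sub(" ", text)
    return " ".join(text.split())


def word_count(text: str, options: CleaningOptions = CleaningOptions()) -> int:
    """Number of whitespace-delimited tokens after cleaning."""
    return len(clean_text(text, options).split())
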