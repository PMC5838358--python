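"""Normalization and tweet-aware tokenization.

Raw social-media posts are noisy: user handles and URLs carry no
distributional information about the vocabulary we care about, while
hashtags, emoticons and emoji frequently *are* the vocabulary (a pair of
leaf emoji is an attested slang term for marijuana). Normalization
therefore strips handles and URLs, lowercases everything, and leaves the
rest untouched; tokenization splits on whitespace while keeping hashtags,
emoticons and individual emoji as single tokens.

The corpus serialization format is JSONL, one record per document with a
``"tokens"`` array; the round trip is lossless.
"""

from __future__ import annotations

import json
import re
from typing import Iterable, Iterator, List, Sequence, TextIO, Union

__all__ = [
    "normalize",
    "tokenize",
    "preprocess_corpus",
    "read_raw",
    "read_corpus",
    "write_corpus",
    "HANDLE_RE",
    "URL_RE",
]

TokenizedDocument = List[str]
TokenizedCorpus = List[TokenizedDocument]

# A handle is "@" followed by at least one word character; a URL is a
# scheme-prefixed or "www."-prefixed maximal non-space run.
HANDLE_RE = re.compile(r"@\w+")
URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)

# Emoji: the standard pictographic blocks plus common symbol/dingbat
# ranges and regional indicators. Variation selectors and zero-width
# joiners are glued to the preceding emoji so a ZWJ family sequence stays
# one token.
_EMOJI_CORE = (
    "\U0001F300-\U0001F5FF"  # misc symbols & pictographs
    "\U0001F600-\U0001F64F"  # emoticons
    "\U0001F680-\U0001F6FF"  # transport & map
    "\U0001F700-\U0001F77F"
    "\U0001F900-\U0001F9FF"  # supplemental symbols
    "\U0001FA00-\U0001FAFF"
    "\U00002600-\U000027BF"  # misc symbols, dingbats
    "\U0001F1E6-\U0001F1FF"  # regional indicators
    "⬀-⯿"
    "←-⇿"
)
_EMOJI = rf"[{_EMOJI_CORE}](?:[︎️‍]|[{_EMOJI_CORE}](?<=‍.))*"

# Western emoticons, e.g. :) :-( ;P =D <3
_EMOTICON = r"(?:[<>]?[:;=8][\-o\*']?[\)\]\(\[dDpP/\:\}\{@\|\\]|<3)"

_HASHTAG = r"#\w+"
_WORD = r"[\w']+(?:-[\w']+)*"  # words incl. apostrophes and hyphens
_TOKEN_RE = re.compile(
    rf"(?:{_EMOJI})|(?:{_HASHTAG})|(?:{_EMOTICON})|(?:{_WORD})|[^\w\s]",
    re.UNICODE,
)


def normalize(text: str) -> str:
    """Strip user handles and URLs, lowercase, and collapse whitespace.

    Hashtags, emoticons and emoji are retained verbatim (modulo
    case-folding, which does not affect them). Empty input maps to empty
    output.
    """
    text = URL_RE.sub(" ", text)
    text = HANDLE_RE.sub(" ", text)
    return " ".join(text.split()).lower()


def tokenize(text: str) -> TokenizedDocument:
    """Split normalized text into tokens, tweet-style.

    Hashtags are single tokens; each emoji is its own token (so a
    two-emoji run becomes two adjacent tokens, eligible for phrase
    merging); emoticons like ``:)`` are kept whole. No token contains
    whitespace.
    """
    return _TOKEN_RE.findall(text)


def preprocess_corpus(raw_docs: Iterable[str]) -> TokenizedCorpus:
    """normalize + tokenize every document; empty documents yield []."""
    return [tokenize(normalize(doc)) for doc in raw_docs]


def read_raw(source: Union[str, TextIO]) -> Iterator[str]:
    """Yield raw documents from a plain-text file, one per line, UTF-8."""
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            yield from (line.rstrip("\n") for line in fh)
    else:
        yield from (line.rstrip("\n") for line in source)


def write_corpus(corpus: Iterable[Sequence[str]], path: str) -> None:
    """Write a tokenized corpus as JSONL, one {"tokens": [...]} per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps({"tokens": list(doc)}, ensure_ascii=False))
            fh.write("\n")


def read_corpus(path: str) -> TokenizedCorpus:
    """Read a JSONL tokenized corpus written by :func:`write_corpus`."""
    corpus: TokenizedCorpus = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                tokens = rec["tokens"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed corpus record") from exc
            corpus.append([str(t) for t in tokens])
    return corpus
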