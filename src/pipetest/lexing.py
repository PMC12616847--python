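"""Lightweight lexer for DSL2-style workflow source and compat suites.

Only enough of the host language is understood to make discovery-level
parsing robust: line (``//``) and block (``/* */``) comments, single-,
double-, and triple-quoted strings, braces, parens, and bare words.
Everything else is opaque.  No code from the scanned file is ever
evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

from pipetest.model import SpecError


@dataclass(frozen=True)
class GToken:
    kind: str  # word | string | lbrace | rbrace | lparen | rparen | other
    value: str
    line: int  # 1-based
    pos: int = 0  # character offset of the token start


_WORD_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_")


def groovy_tokens(text: str, path: str = "<text>") -> list[GToken]:
    """Tokenize, skipping comments and keeping string literals as values."""
    tokens: list[GToken] = []
    i, n, line = 0, len(text), 1
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            i += 1
            continue
        if ch in " \t\r":
            i += 1
            continue
        if text.startswith("//", i) or text.startswith("#!", i):
            j = text.find("\n", i)
            i = n if j < 0 else j
            continue
        if text.startswith("/*", i):
            j = text.find("*/", i + 2)
            if j < 0:
                # unterminated comment: treat rest of file as comment
                line += text.count("\n", i)
                i = n
            else:
                line += text.count("\n", i, j + 2)
                i = j + 2
            continue
        if ch in "'\"":
            start = i
            value, i, nl = _scan_string(text, i, path, line)
            tokens.append(GToken("string", value, line, start))
            line += nl
            continue
        if ch == "{":
            tokens.append(GToken("lbrace", ch, line, i))
            i += 1
            continue
        if ch == "}":
            tokens.append(GToken("rbrace", ch, line, i))
            i += 1
            continue
        if ch == "(":
            tokens.append(GToken("lparen", ch, line, i))
            i += 1
            continue
        if ch == ")":
            tokens.append(GToken("rparen", ch, line, i))
            i += 1
            continue
        if ch in _WORD_CHARS:
            j = i
            while j < n and text[j] in _WORD_CHARS:
                j += 1
            tokens.append(GToken("word", text[i:j], line, i))
            i = j
            continue
        tokens.append(GToken("other", ch, line, i))
        i += 1
    return tokens


def _scan_string(text: str, i: int, path: str, line: int):
    """Scan a quoted string starting at i; returns (value, next_i, newlines)."""
    quote = text[i]
    triple = text.startswith(quote * 3, i)
    delim = quote * 3 if triple else quote
    j = i + len(delim)
    out: list[str] = []
    while j < len(text):
        if text.startswith(delim, j):
            raw = "".join(out)
            return raw, j + len(delim), raw.count("\n")
        if text[j] == "\\" and j + 1 < len(text):
            out.append(text[j + 1])
            j += 2
            continue
        if text[j] == "\n" and not triple:
            raise SpecError("unterminated string literal", path, line)
        out.append(text[j])
        j += 1
    raise SpecError("unterminated string literal", path, line)
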