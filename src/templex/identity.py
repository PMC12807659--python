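"""Deterministic three-layer template identifiers and sequence-support score.

Identifier layout: ``RR:AAAAAA-BBBBBB-CCCCCC``.  The A segment hashes the
substrate pattern's heavy-atom connectivity (element + bond topology only;
hydrogen counts, charges and atom maps excluded), B does the same for the
product pattern(s), and C hashes the full canonical SMARTS string.  Each
segment is the SHA-256 digest of the canonical serialization truncated to 30
bits and rendered as 6 characters of RFC 4648 base32 (alphabet A-Z2-7), so
templates sharing a substrate motif share their A segment and byte-identical
SMARTS share the full identifier.  The hash construction is versioned in
output metadata (``HASH_SCHEME``).

The sequence-support score summarizes enzyme-sequence evidence:
``s = n**(-1/r)`` with ``n`` the number of supporting sequence clusters and
``r > 0`` a regularization parameter (default 2).  ``s`` lies in (0, 1];
``s = 1`` means unambiguous support.  Templates from spontaneous reactions
are never penalized for missing evidence: they score exactly 1.  Templates
with neither sequence annotation nor a spontaneous flag carry a null score.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass

from .canonical import topology_string
from .errors import ConfigurationError, InvalidAnnotationError
from .pattern import parse_template

HASH_SCHEME = "sha256/30bit/base32"
DEFAULT_R = 2.0

_BASE32 = "ABCDEFGHIJKLMNOPQRSTUVWXYZ234567"

IDENTIFIER_PATTERN = re.compile(r"^RR:[A-Z2-7]{6}-[A-Z2-7]{6}-[A-Z2-7]{6}$")


@dataclass(frozen=True)
class TemplateIdentifier:
    a_segment: str
    b_segment: str
    c_segment: str

    def render(self) -> str:
        return f"RR:{self.a_segment}-{self.b_segment}-{self.c_segment}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _segment(payload: str) -> str:
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    bits = int.from_bytes(digest[:4], "big") >> 2  # first 30 bits
    chars = []
    for shift in range(25, -1, -5):
        chars.append(_BASE32[(bits >> shift) & 0x1F])
    return "".join(chars)


def make_identifier(smarts: str) -> TemplateIdentifier:
    """Mint the three-layer identifier of a canonical template SMARTS."""
    sub, prod = parse_template(smarts)
    return TemplateIdentifier(
        a_segment=_segment(topology_string(sub)),
        b_segment=_segment(topology_string(prod)),
        c_segment=_segment(smarts),
    )


def parse_identifier(text: str) -> TemplateIdentifier:
    if not IDENTIFIER_PATTERN.match(text):
        raise ValueError(f"not a template identifier: {text!r}")
    body = text[3:]
    a, b, c = body.split("-")
    return TemplateIdentifier(a, b, c)


@dataclass(frozen=True)
class SequenceScore:
    s: float
    n: int | None
    r: float


def sequence_score(
    n: int | None, r: float = DEFAULT_R, spontaneous: bool = False
) -> SequenceScore | None:
    """Normalized sequence-support score ``s = n**(-1/r)``.

    Spontaneous reactions score exactly 1 regardless of ``n``.  ``None`` is
    returned (a null score, exported as an empty field) when a
    non-spontaneous template carries no sequence annotation.
    """
    if r <= 0:
        raise ConfigurationError(f"regularization parameter r must be > 0, got {r}")
    if spontaneous:
        return SequenceScore(s=1.0, n=n, r=r)
    if n is None:
        return None
    if n < 1:
        raise InvalidAnnotationError(
            f"sequence cluster count must be >= 1, got {n}"
        )
    return SequenceScore(s=float(n) ** (-1.0 / r), n=n, r=r)


def format_score(score: SequenceScore | None) -> str:
    """Serialize with 6 significant digits; null scores as empty field."""
    if score is None:
        return ""
    return f"{score.s:.6g}"
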