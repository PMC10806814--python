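"""Atom-type renaming for CHARMM-format compatibility.

NAMD reads CHARMM-format atom types as capitalised, ignores symbols and
spaces, and rejects leading digits — all of which AMBER type names use.
The prefix scheme encodes the lost information: one capital letter per
character of the raw name describing its nature (Uppercase, Lowercase,
Space, Number, Asterisk, Plus, Minus), followed by the uppercased
alphanumeric body with trailing symbols dropped.  ``CG → UUCG``,
``cg → LLCG``, ``Na+ → ULPNA``.

Two postfix schemes create *duplicate* types that inherit every parameter
of their base: a decimal index for per-grid CMAP Cα variants and an ``X``
for atoms needing a second 1-4 van-der-Waals scaling factor.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

# U+2212 (minus sign) and ASCII hyphen both denote the minus prefix.
_MINUS_CHARS = {"-", "−"}
_SYMBOL_PREFIX = {"*": "A", "+": "P"}

_ENCODED_RE = re.compile(r"[A-Z][A-Z0-9]*$")


class EncodingError(ValueError):
    pass


def _classify(ch: str) -> str:
    if ch in string.ascii_uppercase:
        return "U"
    if ch in string.ascii_lowercase:
        return "L"
    if ch == " ":
        return "S"
    if ch in string.digits:
        return "N"
    if ch in _SYMBOL_PREFIX:
        return _SYMBOL_PREFIX[ch]
    if ch in _MINUS_CHARS:
        return "M"
    raise EncodingError(f"character {ch!r} is not a legal atom-type character")


def encode_atom_type(raw: str) -> str:
    """Encode a raw AMBER atom-type name into its prefixed CHARMM-safe form.

    The prefix has exactly one letter per raw character; the body is the
    uppercased alphanumeric content with trailing symbols dropped.
    """
    if not raw:
        raise EncodingError("empty atom-type name")
    if _classify(raw[0]) not in ("U", "L", "N"):
        raise EncodingError(
            f"atom type {raw!r} starts with a symbol; no shipped AMBER "
            "force field does this and no encoding is defined for it")
    prefix = "".join(_classify(ch) for ch in raw)
    body_chars = []
    interior_symbol = False
    alnum_seen_after = False
    for ch in reversed(raw):
        if ch.isalnum():
            alnum_seen_after = True
        elif ch != " " and alnum_seen_after:
            interior_symbol = True
    for ch in raw:
        if ch.isalnum():
            body_chars.append(ch.upper())
    if interior_symbol:
        logger.warning("atom type %r has interior symbols; they are dropped "
                       "from the encoded body", raw)
    return prefix + "".join(body_chars)


@dataclass
class TypeEncodingMap:
    """Bidirectional raw↔encoded registry with a collision audit."""
    forward: dict = field(default_factory=dict)
    reverse: dict = field(default_factory=dict)
    collisions: list = field(default_factory=list)   # (raw1, raw2, encoded)

    @property
    def ok(self) -> bool:
        return not self.collisions

    def encode(self, raw: str) -> str:
        if raw not in self.forward:
            raise KeyError(f"raw type {raw!r} not registered")
        return self.forward[raw]

    def decode(self, encoded: str) -> str:
        return self.reverse[encoded]

    def register(self, raw: str) -> str:
        enc = encode_atom_type(raw)
        if raw in self.forward:
            return self.forward[raw]
        if enc in self.reverse and self.reverse[enc] != raw:
            self.collisions.append((self.reverse[enc], raw, enc))
        self.forward[raw] = enc
        self.reverse.setdefault(enc, raw)
        return enc

    def register_variant(self, encoded: str, raw_note: str) -> None:
        """Record a postfixed duplicate type in the reverse map."""
        self.reverse.setdefault(encoded, raw_note)


def audit_injectivity(raw_types) -> TypeEncodingMap:
    """Encode every raw type; collisions are reported as data, not raised."""
    m = TypeEncodingMap()
    for raw in sorted(raw_types):
        m.register(raw)
    return m


def make_cmap_variant(encoded_ca_type: str, cmap_index: int, *,
                      max_index: int = 15) -> str:
    """Numeric-postfix duplicate used to key a CMAP by dihedral type.

    The base type stays in use in every other parameter declaration; only
    the Cα atoms of residues owning the grid are retyped.
    """
    if cmap_index < 0:
        raise EncodingError("CMAP variant index must be non-negative")
    if cmap_index > max_index:
        raise EncodingError(
            f"CMAP variant index {cmap_index} exceeds the configured bound "
            f"{max_index}")
    _check_encoded(encoded_ca_type)
    return f"{encoded_ca_type}{cmap_index}"


def make_scnb_variant(encoded_type: str, existing_types=()) -> str:
    """X-postfix duplicate for atoms whose 1-4 LJ scaling depends on the
    interaction partner (mixed-SCNB force fields)."""
    _check_encoded(encoded_type)
    if encoded_type.endswith("X"):
        logger.warning("X-postfixing %r, which already ends in X; "
                       "double variants are suspicious", encoded_type)
    variant = encoded_type + "X"
    if variant in set(existing_types):
        raise EncodingError(
            f"SCNB variant {variant!r} collides with an existing type")
    return variant


def _check_encoded(name: str) -> None:
    if not _ENCODED_RE.match(name):
        raise EncodingError(f"{name!r} is not a valid encoded type name")
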