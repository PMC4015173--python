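"""Hashed reaction keys: the four RInChIKey variants.

Two families of keys digest a reaction identifier:

* **Long keys** concatenate the 27-character molecule keys (InChIKeys)
  of every participant, in identifier order, with ``-`` between
  molecules and ``--`` at group boundaries.  Their length grows with
  the number of molecules.
* **Short keys** are fixed-length digests computed directly from the
  identifier's group strings, without per-molecule keys.

Each family comes in version A (the direction layer is folded into one
hash of all additional layers) and version B (block 2 starts with an
explicit direction letter — F, B, E or U for forward, backward,
equilibrium, unspecified — so keyed collections can still be searched
by role).  Version B of the short key additionally splits every InChI
into major layers (formula, connectivity, hydrogen, charge) and minor
layers (the rest), hashed separately per group, so that two reactions
differing only in stereochemistry share their major blocks.

This module also carries a from-scratch implementation of the official
molecule-key (InChIKey) algorithm: SHA-256 digests of the major and
minor parts of the InChI, encoded in a base-26 alphabet, plus flag and
protonation characters.  Its output is byte-identical to the reference
engine's.  The same digest-to-letters encoding drives the reaction-key
hash blocks.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

from .errors import LayerParseError, RInChIError
from .inchi_adapter import INCHI_PREFIX, split_major_minor, strip_inchi_prefix
from .rinchi_core import MOL_SEP, RDirection, RInChI

_AZ = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# ---------------------------------------------------------------------------
# base-26 encoding of SHA-256 digests (the official molecule-key encoding)
# ---------------------------------------------------------------------------

def _triplet_letters(value: int) -> str:
    """Map a 14-bit value to three uppercase letters.

    The official table enumerates three-letter combinations in
    alphabetical order but skips the 676 triplets beginning with ``E``
    and the 516-triplet run ``TAA``–``TTV``, leaving exactly 2**14
    usable entries.
    """
    r = value
    if r >= 2704:       # skip the E** block
        r += 676
    if r >= 12844:      # skip TAA..TTV
        r += 516
    return _AZ[r // 676] + _AZ[(r // 26) % 26] + _AZ[r % 26]


def _doublet_letters(value: int) -> str:
    """Map a 9-bit value to two letters (plain base 26)."""
    return _AZ[value // 26] + _AZ[value % 26]


def _bit_slices(d: bytes) -> tuple[int, int, int, int, int, int]:
    """The official bit extraction over the first nine digest bytes:
    four 14-bit triplet values, plus 9-bit doublet values taken at bit
    offsets 28 and 56."""
    t1 = d[0] | ((d[1] & 0x3F) << 8)
    t2 = ((d[1] & 0xC0) >> 6) | (d[2] << 2) | ((d[3] & 0x0F) << 10)
    t3 = ((d[3] & 0xF0) >> 4) | (d[4] << 4) | ((d[5] & 0x03) << 12)
    t4 = ((d[5] & 0xFC) >> 2) | (d[6] << 6)
    d28 = ((d[3] & 0xF0) >> 4) | ((d[4] & 0x1F) << 4)
    d56 = d[7] | ((d[8] & 0x01) << 8)
    return t1, t2, t3, t4, d28, d56


def _major_block(text: str) -> str:
    """14-letter digest block (4 triplets + 1 doublet, 65 bits)."""
    t1, t2, t3, t4, _, d56 = _bit_slices(hashlib.sha256(text.encode()).digest())
    return (_triplet_letters(t1) + _triplet_letters(t2)
            + _triplet_letters(t3) + _triplet_letters(t4) + _doublet_letters(d56))


def _minor_block(text: str) -> str:
    """8-letter digest block (2 triplets + 1 doublet, 37 bits)."""
    t1, t2, _, _, d28, _ = _bit_slices(hashlib.sha256(text.encode()).digest())
    return _triplet_letters(t1) + _triplet_letters(t2) + _doublet_letters(d28)


def hash_block(text: str, length: int) -> str:
    """A deterministic uppercase-letter digest of ``text``.

    SHA-256 of the UTF-8 text, mapped to letters through the same
    base-26 triplet encoding as the molecule key, truncated to
    ``length``.  Truncation is a prefix operation:
    ``hash_block(s, n)`` is a prefix of ``hash_block(s, n + 1)``.
    The empty string hashes like any other input.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    letters: list[str] = []
    # each 7-byte window yields four 14-bit triplets = 12 letters
    for off in range(0, len(digest) - 6, 7):
        t1, t2, t3, t4, _, _ = _bit_slices(digest[off:off + 9].ljust(9, b"\0"))
        letters.append(_triplet_letters(t1) + _triplet_letters(t2)
                       + _triplet_letters(t3) + _triplet_letters(t4))
        if sum(len(x) for x in letters) >= length:
            break
    return "".join(letters)[:length]


def _protonation_char(p: int) -> str:
    """Official protonation flag: ``N`` + p, ``A`` when out of range."""
    if -12 <= p <= 12:
        return chr(ord("N") + p)
    return "A"


def _group_protonation_char(p: int) -> str:
    """Group-level protonation flag for short version-B keys.

    Same ``N``-centred letter scale, but clamped to the alphabet's ends
    for extreme totals (with a warning) so the block stays well formed.
    """
    if p > 12:
        warnings.warn(f"group protonation {p:+d} clamps to 'Z'", stacklevel=3)
        return "Z"
    if p < -13:
        warnings.warn(f"group protonation {p:+d} clamps to 'A'", stacklevel=3)
        return "A"
    return chr(ord("N") + p)


def inchikey(inchi: str) -> str:
    """The 27-character hashed molecule key of a standard InChI.

    Byte-identical to the official engine's InChIKey: a 14-letter hash
    of the major part, a hyphen, an 8-letter hash of the minor part
    (doubled before hashing when shorter than 255 characters), the
    standard/version flags ``SA``, a hyphen and the protonation
    character.
    """
    if not inchi.startswith(INCHI_PREFIX):
        raise RInChIError(f"not a standard (1S) InChI: {inchi[:20]!r}")
    body = strip_inchi_prefix(inchi)
    if not body or body.startswith("/"):
        raise RInChIError("InChI has an empty formula layer")
    major, minor, p = split_major_minor(body)
    if 0 < len(minor) < 255:
        minor = minor + minor
    return _major_block(major) + "-" + _minor_block(minor) + "SA-" + _protonation_char(p)


# ---------------------------------------------------------------------------
# reaction keys
# ---------------------------------------------------------------------------

_DIRECTION_LETTER = {
    RDirection.PLUS: "F",
    RDirection.MINUS: "B",
    RDirection.EQUILIBRIUM: "E",
    RDirection.OMITTED: "U",
}

#: Block-1 of every reaction key: lowercase version letter ('a' or 'b')
#: followed by "SA" = standard InChIs, standard key flavour.
_BLOCK1 = {"A": "aSA", "B": "bSA"}

_LEN_BLOCK2_A = 5      # hash of all additional layers, direction included
_LEN_BLOCK2_B = 4      # hash of additional layers after the direction letter
_LEN_SHORT_A_GROUP = 15
_LEN_SHORT_B_MAJOR = 10
_LEN_SHORT_B_MINOR = 4


def _extra_layers(r: RInChI, include_direction: bool) -> str:
    parts = []
    if include_direction:
        parts.append(r.direction.token)
    parts.extend(r.extras)
    return "".join(parts)


def _block2(r: RInChI, version: str) -> str:
    if version == "A":
        return hash_block(_extra_layers(r, include_direction=True), _LEN_BLOCK2_A)
    return _DIRECTION_LETTER[r.direction] + hash_block(
        _extra_layers(r, include_direction=False), _LEN_BLOCK2_B
    )


def _check_version(version: str) -> str:
    v = version.upper()
    if v not in ("A", "B"):
        raise ValueError(f"key version must be 'A' or 'B', not {version!r}")
    return v


def long_key(r: RInChI, version: str = "B") -> str:
    """The variable-length key: one molecule key per participant.

    Blocks: version/flavour block, the additional-layers block, then the
    27-character molecule keys in exactly the identifier's order, with
    ``--`` marking each group boundary (the ``///`` of the identifier).
    Trailing empty groups are omitted, mirroring the identifier string.
    """
    v = _check_version(version)
    groups = [list(r.group1), list(r.group2), list(r.group3)]
    while groups and not groups[-1]:
        groups.pop()
    parts = [_BLOCK1[v], _block2(r, v)]
    body = "--".join(
        "-".join(inchikey(INCHI_PREFIX + b) for b in g) for g in groups
    )
    if body:
        parts.append(body)
    return "-".join(parts)


def short_key(r: RInChI, version: str = "B") -> str:
    """The fixed-length key, hashed directly from the identifier groups.

    Version A: the two header blocks followed by exactly three 15-letter
    blocks, one per group (present even when the group is empty), each a
    hash of the group's concatenated InChI bodies.

    Version B: header blocks, then three 10-letter hashes of the groups'
    concatenated major parts, then three 5-letter minor blocks — one
    letter flagging the group's net protonation plus a 4-letter hash of
    the concatenated minor parts.  Enantiomeric reactions therefore
    share every block except the minor blocks of the changed groups.
    """
    v = _check_version(version)
    groups = (r.group1, r.group2, r.group3)
    parts = [_BLOCK1[v], _block2(r, v)]
    if v == "A":
        for g in groups:
            parts.append(hash_block(MOL_SEP.join(g), _LEN_SHORT_A_GROUP))
        return "-".join(parts)
    majors, minors, protons = [], [], []
    for g in groups:
        try:
            split = [split_major_minor(b) for b in g]
        except LayerParseError as exc:
            raise RInChIError(f"cannot split group body: {exc}") from exc
        majors.append(MOL_SEP.join(s[0] for s in split))
        minors.append(MOL_SEP.join(s[1] for s in split))
        protons.append(sum(s[2] for s in split))
    for m in majors:
        parts.append(hash_block(m, _LEN_SHORT_B_MAJOR))
    for m, p in zip(minors, protons):
        parts.append(_group_protonation_char(p) + hash_block(m, _LEN_SHORT_B_MINOR))
    return "-".join(parts)


@dataclass(frozen=True)
class KeyBundle:
    """All four hashed keys of one reaction identifier."""

    long_a: str
    long_b: str
    short_a: str
    short_b: str


def make_keys(r: RInChI) -> KeyBundle:
    return KeyBundle(
        long_a=long_key(r, "A"),
        long_b=long_key(r, "B"),
        short_a=short_key(r, "A"),
        short_b=short_key(r, "B"),
    )
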