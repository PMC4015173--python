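"""Assembly, serialization and parsing of the canonical reaction identifier.

A reaction identifier (RInChI, format version 0.02) consists of a label,
three groups of molecule InChI bodies — the two sides of the arrow plus
the agents (solvents, catalysts: species present on both sides) — and an
optional direction layer.  Canonicality comes from sorting: InChIs are
byte-wise sorted within each group, and the two reaction-side groups are
themselves ordered byte-wise, so the identifier cannot depend on the
order in which molecules appeared in the source file.  Which group holds
the starting materials is recorded separately in the direction layer:
``/d+`` (group1 are the reactants), ``/d-`` (group2 are), ``/d=``
(equilibrium), or no layer at all when the direction is unknown — an
identifier without a direction layer is still valid.

Serialized form::

    RInChI=0.02.1S/<g1 InChIs joined by //>///<g2>///<g3>/d+

The per-molecule ``InChI=1S`` prefix is stripped before embedding: the
InChI version is already declared once in the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import RInChIValidationError
from .inchi_adapter import (
    AUXINFO_PREFIX,
    INCHI_PREFIX,
    MolRecord,
    inchi_to_molfile,
    split_major_minor,
    strip_inchi_prefix,
)
from .rxn_io import Direction, ReactionRecord

RINCHI_VERSION = "0.02"
INCHI_VERSION = "1S"
HEADER = f"RInChI={RINCHI_VERSION}.{INCHI_VERSION}/"
#: Also accepted on parse: the label punctuation variant with a period
#: between the InChI version digit and its letter.
_ALT_HEADER = f"RInChI={RINCHI_VERSION}.1.S/"
RAUXINFO_HEADER = f"RAuxInfo={RINCHI_VERSION}.1/"

GROUP_SEP = "///"
MOL_SEP = "//"


class RDirection(Enum):
    """Direction layer of a reaction identifier."""

    PLUS = "+"
    MINUS = "-"
    EQUILIBRIUM = "="
    OMITTED = None

    @property
    def token(self) -> str:
        return "" if self.value is None else f"/d{self.value}"

    def flipped(self) -> "RDirection":
        if self is RDirection.PLUS:
            return RDirection.MINUS
        if self is RDirection.MINUS:
            return RDirection.PLUS
        return self


def sort_group(inchis: Sequence[str], mode: str = "bytewise") -> list[str]:
    """Sort InChI bodies within a group.

    ``bytewise`` reproduces ``LC_ALL=C sort`` semantics (the format-0.02
    behaviour).  ``major_then_minor`` sorts on the major-layer substring
    first with the remaining layers as tiebreak — an opt-in mode that
    keeps small minor-layer edits from reshuffling a group.  Duplicate
    entries are preserved, never collapsed: they are the only
    stoichiometry-like signal the identifier retains.
    """
    if mode == "bytewise":
        return sorted(inchis, key=lambda s: s.encode("utf-8"))
    if mode == "major_then_minor":
        def key(body: str):
            major, minor, p = split_major_minor(body)
            return (major.encode("utf-8"), body.encode("utf-8"))
        return sorted(inchis, key=key)
    raise ValueError(f"unknown sort mode {mode!r}")


def _group_sort_key(group: Sequence[str]) -> tuple[int, bytes]:
    """Ordering key for the two reaction-side groups.

    Groups are compared by the byte-wise order of their concatenated
    InChIs; an empty group sorts last so that a half-known reaction
    shows its known side as the first group and the empty group can be
    dropped from the tail of the string.
    """
    if not group:
        return (1, b"")
    return (0, MOL_SEP.join(group).encode("utf-8"))


@dataclass(frozen=True)
class RInChI:
    """The reaction identifier as a value object.

    Equality is structural, and serialization is injective: two values
    are equal exactly when their strings are equal.
    """

    group1: tuple[str, ...] = ()
    group2: tuple[str, ...] = ()
    group3: tuple[str, ...] = ()
    direction: RDirection = RDirection.OMITTED
    rinchi_version: str = RINCHI_VERSION
    inchi_version: str = INCHI_VERSION
    extras: tuple[str, ...] = ()

    def serialized(self) -> str:
        return serialize(self)

    @property
    def all_bodies(self) -> tuple[str, ...]:
        return self.group1 + self.group2 + self.group3

    def reactant_bodies(self) -> tuple[str, ...]:
        """Group holding the starting materials (group1 unless ``/d-``)."""
        return self.group2 if self.direction is RDirection.MINUS else self.group1

    def product_bodies(self) -> tuple[str, ...]:
        return self.group1 if self.direction is RDirection.MINUS else self.group2

    def flipped(self) -> "RInChI":
        """The same reaction with reactant/product roles exchanged."""
        return replace(self, direction=self.direction.flipped())


@dataclass(frozen=True)
class RAuxInfo:
    """Auxiliary information mirroring an identifier group-by-group.

    Each group's list is aligned index-by-index with the companion
    :class:`RInChI`; an entry is the AuxInfo body (prefix stripped) or
    ``""`` when no auxiliary data is available for that molecule.
    """

    group1: tuple[str, ...] = ()
    group2: tuple[str, ...] = ()
    group3: tuple[str, ...] = ()

    def serialized(self) -> str:
        groups = [self.group1, self.group2, self.group3]
        while groups and not groups[-1]:
            groups.pop()
        return RAUXINFO_HEADER + GROUP_SEP.join(MOL_SEP.join(g) for g in groups)

    def validate_against(self, rinchi: RInChI) -> None:
        for name, mine, theirs in (
            ("group1", self.group1, rinchi.group1),
            ("group2", self.group2, rinchi.group2),
            ("group3", self.group3, rinchi.group3),
        ):
            if len(mine) != len(theirs):
                raise RInChIValidationError(
                    f"RAuxInfo {name} has {len(mine)} entries, identifier has "
                    f"{len(theirs)}", rule="auxinfo-alignment",
                )


def _strip_prefix(inchi: str) -> str:
    return strip_inchi_prefix(inchi)


def _aux_body(aux: Optional[str]) -> str:
    if not aux:
        return ""
    if aux.startswith(AUXINFO_PREFIX):
        return aux[len(AUXINFO_PREFIX):]
    return aux


def build_rinchi(
    rxn: ReactionRecord, sort_mode: str = "bytewise"
) -> tuple[RInChI, RAuxInfo]:
    """Build the canonical identifier (and its RAuxInfo) for a reaction.

    Reactant and product InChIs are sorted within their groups, the two
    sorted groups are compared byte-wise and the smaller becomes group1.
    The direction layer records where the reactants landed: ``/d+`` for
    group1, ``/d-`` for group2; an equilibrium reaction keeps the
    canonical group order under ``/d=``; an unspecified direction omits
    the layer.  When both sides are identical the direction is forced to
    omitted — "forward" and "backward" would be meaningless.  AuxInfo
    entries are permuted exactly as their InChIs.
    """
    if rxn.direction is Direction.BACKWARD:
        reactants, products = rxn.products, rxn.reactants
    else:
        reactants, products = rxn.reactants, rxn.products

    def sorted_with_aux(mols: Sequence[MolRecord]) -> tuple[list[str], list[str]]:
        pairs = [( _strip_prefix(m.inchi), _aux_body(m.auxinfo)) for m in mols]
        pairs.sort(key=lambda pr: pr[0].encode("utf-8"))
        if sort_mode != "bytewise":
            bodies = sort_group([p[0] for p in pairs], mode=sort_mode)
            order = _stable_order([p[0] for p in pairs], bodies)
            pairs = [pairs[i] for i in order]
        return [p[0] for p in pairs], [p[1] for p in pairs]

    r_bodies, r_aux = sorted_with_aux(reactants)
    p_bodies, p_aux = sorted_with_aux(products)
    a_bodies, a_aux = sorted_with_aux(rxn.agents)

    if _group_sort_key(r_bodies) <= _group_sort_key(p_bodies):
        g1, g2 = (r_bodies, r_aux), (p_bodies, p_aux)
        reactants_in_g1 = True
    else:
        g1, g2 = (p_bodies, p_aux), (r_bodies, r_aux)
        reactants_in_g1 = False

    if rxn.direction is Direction.EQUILIBRIUM:
        direction = RDirection.EQUILIBRIUM
    elif rxn.direction is Direction.UNSPECIFIED:
        direction = RDirection.OMITTED
    elif g1[0] == g2[0]:
        direction = RDirection.OMITTED
    else:
        direction = RDirection.PLUS if reactants_in_g1 else RDirection.MINUS

    rinchi = RInChI(
        group1=tuple(g1[0]),
        group2=tuple(g2[0]),
        group3=tuple(a_bodies),
        direction=direction,
    )
    raux = RAuxInfo(group1=tuple(g1[1]), group2=tuple(g2[1]), group3=tuple(a_aux))
    return rinchi, raux


def _stable_order(original: list[str], target: list[str]) -> list[int]:
    remaining = list(range(len(original)))
    order = []
    for t in target:
        for j in remaining:
            if original[j] == t:
                order.append(j)
                remaining.remove(j)
                break
    return order


def serialize(r: RInChI) -> str:
    """Render the canonical string form of an identifier.

    Trailing empty groups are omitted together with their ``///``
    separators; no trailing slash is emitted.
    """
    groups = [list(r.group1), list(r.group2), list(r.group3)]
    while groups and not groups[-1]:
        groups.pop()
    body = GROUP_SEP.join(MOL_SEP.join(g) for g in groups)
    return HEADER + body + r.direction.token + "".join(r.extras)


_DIRECTION_TOKENS = {
    "/d+": RDirection.PLUS,
    "/d-": RDirection.MINUS,
    "/d=": RDirection.EQUILIBRIUM,
}


def parse(text: str, validate_order: bool = True) -> RInChI:
    """Parse a serialized identifier back into an :class:`RInChI`.

    The exact inverse of :func:`serialize`.  Both header punctuation
    variants (``0.02.1S`` and ``0.02.1.S``) and an optional trailing
    slash are accepted.  Unknown layers following the direction layer
    are preserved verbatim in ``extras`` and echoed on re-serialization.
    Out-of-order groups raise a validation error naming the violated
    rule; pass ``validate_order=False`` to inspect malformed strings.
    """
    if text.startswith(HEADER):
        rest = text[len(HEADER):]
    elif text.startswith(_ALT_HEADER):
        rest = text[len(_ALT_HEADER):]
    elif not text.startswith("RInChI="):
        raise RInChIValidationError(
            "identifier must start with 'RInChI='", rule="header"
        )
    else:
        raise RInChIValidationError(
            f"unsupported version label in {text.split('/', 1)[0]!r}", rule="header"
        )

    if rest.endswith("/") and not rest.endswith(MOL_SEP):
        rest = rest[:-1]
    direction = RDirection.OMITTED
    extras: tuple[str, ...] = ()
    for tok, d in _DIRECTION_TOKENS.items():
        i = rest.find(tok)
        if i != -1 and (i + len(tok) == len(rest) or rest[i + len(tok)] == "/"):
            direction = d
            tail = rest[i + len(tok):]
            if tail:
                extras = (tail,)
            rest = rest[:i]
            break
    else:
        if rest.endswith("/d"):
            raise RInChIValidationError(
                "bad direction token: expected /d+, /d- or /d=", rule="direction"
            )

    parts = rest.split(GROUP_SEP) if rest else [""]
    if len(parts) > 3:
        raise RInChIValidationError(
            f"identifier has {len(parts)} groups; at most 3 allowed", rule="groups"
        )
    groups: list[tuple[str, ...]] = []
    for part in parts:
        groups.append(tuple(b for b in part.split(MOL_SEP) if b) if part else ())
    while len(groups) < 3:
        groups.append(())

    r = RInChI(
        group1=groups[0], group2=groups[1], group3=groups[2],
        direction=direction, extras=extras,
    )
    if validate_order:
        _validate(r)
    return r


def _validate(r: RInChI) -> None:
    for name, g in (("group1", r.group1), ("group2", r.group2), ("group3", r.group3)):
        if list(g) != sort_group(g):
            raise RInChIValidationError(
                f"{name} is not in byte-wise sorted order", rule="group-sort"
            )
    if _group_sort_key(r.group1) > _group_sort_key(r.group2):
        raise RInChIValidationError(
            "group1 must not sort after group2", rule="group-order"
        )


def parse_rauxinfo(text: str) -> RAuxInfo:
    if not text.startswith(RAUXINFO_HEADER):
        raise RInChIValidationError(
            f"RAuxInfo must start with {RAUXINFO_HEADER!r}", rule="auxinfo-header"
        )
    parts = text[len(RAUXINFO_HEADER):].split(GROUP_SEP)
    if len(parts) > 3:
        raise RInChIValidationError("RAuxInfo has more than 3 groups", rule="groups")
    groups = [tuple(b for b in part.split(MOL_SEP) if b) if part else () for part in parts]
    while len(groups) < 3:
        groups.append(())
    return RAuxInfo(group1=groups[0], group2=groups[1], group3=groups[2])


def to_reaction(
    r: RInChI, raux: Optional[RAuxInfo] = None, layout: str = "auto"
) -> ReactionRecord:
    """Reconstruct a :class:`ReactionRecord` from an identifier.

    Molfiles are regenerated through the InChI engine; 2D coordinates
    come from the RAuxInfo when provided (see
    :func:`~rinchilib.inchi_adapter.inchi_to_molfile` for the fallback).
    The record's reactants are the group the direction layer designates
    (group1 when the layer is absent).
    """
    if raux is not None:
        raux.validate_against(r)

    def mols(bodies: Sequence[str], auxes: Sequence[str]) -> tuple[MolRecord, ...]:
        out = []
        for i, body in enumerate(bodies):
            inchi = INCHI_PREFIX + body
            aux = (AUXINFO_PREFIX + auxes[i]) if i < len(auxes) and auxes[i] else None
            out.append(
                MolRecord(
                    molfile_text=inchi_to_molfile(inchi, aux, layout=layout),
                    inchi=inchi,
                    auxinfo=aux,
                )
            )
        return tuple(out)

    aux = raux or RAuxInfo()
    g1 = mols(r.group1, aux.group1)
    g2 = mols(r.group2, aux.group2)
    g3 = mols(r.group3, aux.group3)
    if r.direction is RDirection.MINUS:
        reactants, products = g2, g1
    else:
        reactants, products = g1, g2
    direction = {
        RDirection.PLUS: Direction.FORWARD,
        RDirection.MINUS: Direction.FORWARD,
        RDirection.EQUILIBRIUM: Direction.EQUILIBRIUM,
        RDirection.OMITTED: Direction.UNSPECIFIED,
    }[r.direction]
    return ReactionRecord(
        reactants=reactants, products=products, agents=g3, direction=direction
    )


def from_groups(
    reactants: Iterable[str],
    products: Iterable[str],
    agents: Iterable[str] = (),
    direction: Direction = Direction.FORWARD,
) -> RInChI:
    """Build an identifier directly from InChI bodies (no structures).

    Applies the same sorting, group-ordering and direction rules as
    :func:`build_rinchi`; used by the multistep combiner, which works on
    identifier strings rather than structure files.
    """
    if direction is Direction.BACKWARD:
        reactants, products = products, reactants
        direction = Direction.FORWARD
    r_bodies = sort_group([b for b in reactants])
    p_bodies = sort_group([b for b in products])
    a_bodies = sort_group([b for b in agents])
    if _group_sort_key(r_bodies) <= _group_sort_key(p_bodies):
        g1, g2, in_g1 = r_bodies, p_bodies, True
    else:
        g1, g2, in_g1 = p_bodies, r_bodies, False
    if direction is Direction.EQUILIBRIUM:
        d = RDirection.EQUILIBRIUM
    elif direction is Direction.UNSPECIFIED or g1 == g2:
        d = RDirection.OMITTED
    else:
        d = RDirection.PLUS if in_g1 else RDirection.MINUS
    return RInChI(group1=tuple(g1), group2=tuple(g2), group3=tuple(a_bodies), direction=d)
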