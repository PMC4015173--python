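"""Database-scale operations on reaction-identifier collections.

Everything here works on the identifier strings alone — no structure
files, no InChI engine.  Deduplication is exact string grouping (the
identifier is canonical, so equal reactions have equal strings);
reaction-partner search resolves roles through the direction layer; the
ring and stereocentre tools read the connectivity and stereo layers of
the constituent InChIs.  Ring counts use the cyclomatic number
``edges - atoms + components`` computed from the decoded ``/c`` layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional, Sequence

from .errors import RInChIError
from .inchi_adapter import INCHI_PREFIX, ParsedInChI, parse_inchi_layers, strip_inchi_prefix
from .rinchi_core import RDirection, RInChI, parse


@dataclass(frozen=True)
class CorpusEntry:
    rinchi: str
    source_id: str = ""


class RInChICorpus:
    """A list of identifier strings with a role-resolved molecule index.

    The index maps each InChI body to the entries containing it together
    with the role the body plays there: ``reactant``, ``product``,
    ``agent``, or ``equilibrium-participant`` for either side of an
    equilibrium or direction-less entry (such species cannot be pinned
    to one side).  Every occurrence is indexed exactly once.
    """

    def __init__(self, entries: Iterable[CorpusEntry | tuple[str, str] | str]):
        self.entries: list[CorpusEntry] = []
        for e in entries:
            if isinstance(e, CorpusEntry):
                self.entries.append(e)
            elif isinstance(e, str):
                self.entries.append(CorpusEntry(e))
            else:
                self.entries.append(CorpusEntry(*e))
        self._parsed: list[RInChI] = [parse(e.rinchi) for e in self.entries]
        self.index: dict[str, list[tuple[int, str]]] = {}
        for i, r in enumerate(self._parsed):
            undirected = r.direction in (RDirection.EQUILIBRIUM, RDirection.OMITTED)
            for body in r.reactant_bodies():
                role = "equilibrium-participant" if undirected else "reactant"
                self.index.setdefault(body, []).append((i, role))
            for body in r.product_bodies():
                role = "equilibrium-participant" if undirected else "product"
                self.index.setdefault(body, []).append((i, role))
            for body in r.group3:
                self.index.setdefault(body, []).append((i, "agent"))

    @classmethod
    def from_lines(cls, text: str, source_id: str = "") -> "RInChICorpus":
        """Build a corpus from one-identifier-per-line text (UTF-8, LF)."""
        entries = [
            CorpusEntry(ln.strip(), f"{source_id}:{i}" if source_id else str(i))
            for i, ln in enumerate(text.splitlines())
            if ln.strip()
        ]
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def parsed(self, i: int) -> RInChI:
        return self._parsed[i]

    def to_lines(self) -> str:
        return "\n".join(e.rinchi for e in self.entries) + ("\n" if self.entries else "")


@dataclass(frozen=True)
class DuplicateReport:
    """Groups of entries sharing one identifier string."""

    groups: tuple[tuple[int, ...], ...]   # entry indices, only groups of >= 2
    unique_count: int
    duplicate_count: int                  # entries beyond the first of each group


def _dedup_key(r: RInChI, mode: str) -> str:
    if mode == "full":
        return r.serialized()
    if mode == "core":
        # ignore agents and direction: identity of the two sides only
        from .rinchi_core import GROUP_SEP, MOL_SEP
        return GROUP_SEP.join((MOL_SEP.join(r.group1), MOL_SEP.join(r.group2)))
    raise ValueError(f"unknown dedup mode {mode!r}")


def find_duplicates(corpus: RInChICorpus, mode: str = "full") -> DuplicateReport:
    """Group identical reactions.

    ``full`` mode (default) compares complete identifier strings,
    direction layer and agents included — equivalent to sorting the
    corpus file and counting repeats.  ``core`` mode ignores group3 and
    the direction layer.
    """
    seen: dict[str, list[int]] = {}
    for i in range(len(corpus)):
        seen.setdefault(_dedup_key(corpus.parsed(i), mode), []).append(i)
    groups = tuple(tuple(v) for v in seen.values() if len(v) > 1)
    return DuplicateReport(
        groups=groups,
        unique_count=len(seen),
        duplicate_count=len(corpus) - len(seen),
    )


def search_partner(
    corpus: RInChICorpus, query_inchi: str, role: str = "any"
) -> list[int]:
    """Entries in which a molecule takes part in a given role.

    ``role`` is ``reactant``, ``product``, ``agent``,
    ``equilibrium-participant`` or ``any``.  Role resolution honours the
    direction layer (under ``/d-`` group1 holds the products), and
    species of equilibrium or direction-less entries match both the
    reactant and the product role.
    """
    if role not in ("reactant", "product", "agent", "equilibrium-participant", "any"):
        raise ValueError(f"unknown role {role!r}")
    body = strip_inchi_prefix(query_inchi) if query_inchi.startswith("InChI=") else None
    if body is None:
        raise RInChIError(f"query is not a standard InChI: {query_inchi[:20]!r}")
    hits = corpus.index.get(body, [])
    out: list[int] = []
    for i, r in hits:
        if (
            role == "any"
            or r == role
            or (r == "equilibrium-participant" and role in ("reactant", "product"))
        ):
            if i not in out:
                out.append(i)
    return out


@dataclass(frozen=True)
class ChangeReport:
    """Structural change of one entry, products minus reactants.

    Per-molecule ratios are exact rationals; a ratio whose denominator
    would be empty (no molecules, or no cyclic molecules on a side) is
    reported as 0 with the corresponding flag raised so corpus scans
    stay total.  For entries without a direction layer the deltas are
    absolute values and ``direction_unknown`` is set.
    """

    ring_count_delta: int = 0
    rings_per_molecule_delta: Fraction = Fraction(0)
    rings_per_cyclic_molecule_delta: Fraction = Fraction(0)
    stereocentre_delta_per_molecule: Fraction = Fraction(0)
    direction_unknown: bool = False
    empty_denominator: bool = False


def _parse_entry(entry: str | RInChI) -> RInChI:
    return entry if isinstance(entry, RInChI) else parse(entry)


def _side_layers(bodies: Sequence[str]) -> list[ParsedInChI]:
    return [parse_inchi_layers(INCHI_PREFIX + b) for b in bodies]


def _ring_stats(parsed: list[ParsedInChI]) -> tuple[int, int, int]:
    """(total rings, molecule count, cyclic molecule count) of one side.

    Each covalently connected component counts as one molecule, so a
    multi-component InChI contributes several molecules.
    """
    rings = 0
    molecules = 0
    cyclic = 0
    for p in parsed:
        for comp in p.components:
            molecules += 1
            r = comp.ring_count
            rings += r
            if r >= 1:
                cyclic += 1
    return rings, molecules, cyclic


def ring_change(entry: str | RInChI) -> ChangeReport:
    """Ring statistics of one entry from its connectivity layers.

    Per molecule, the ring count is the cyclomatic number of the decoded
    ``/c`` layer graph.  Deltas are products minus reactants, with the
    sides assigned by the direction layer.
    """
    r = _parse_entry(entry)
    unknown = r.direction is RDirection.OMITTED
    react = _ring_stats(_side_layers(r.reactant_bodies()))
    prod = _ring_stats(_side_layers(r.product_bodies()))

    def ratio(rings: int, denom: int) -> tuple[Fraction, bool]:
        if denom == 0:
            return Fraction(0), True
        return Fraction(rings, denom), False

    rpm_p, f1 = ratio(prod[0], prod[1])
    rpm_r, f2 = ratio(react[0], react[1])
    rpc_p, f3 = ratio(prod[0], prod[2])
    rpc_r, f4 = ratio(react[0], react[2])

    delta = prod[0] - react[0]
    rpm = rpm_p - rpm_r
    rpc = rpc_p - rpc_r
    if unknown:
        delta, rpm, rpc = abs(delta), abs(rpm), abs(rpc)
    return ChangeReport(
        ring_count_delta=delta,
        rings_per_molecule_delta=rpm,
        rings_per_cyclic_molecule_delta=rpc,
        direction_unknown=unknown,
        empty_denominator=f1 or f2 or f3 or f4,
    )


def _stereo_stats(parsed: list[ParsedInChI], mode: str) -> tuple[int, int]:
    total = 0
    molecules = 0
    for p in parsed:
        molecules += p.component_count
        total += len(p.stereo_t)
        if mode == "t_and_b":
            total += len(p.stereo_b)
    return total, molecules


def stereo_change(entry: str | RInChI, mode: str = "t_and_b") -> ChangeReport:
    """Stereocentre statistics of one entry from its stereo layers.

    A stereocentre is a tetrahedral (``/t``) designation plus, by
    default, a double-bond (``/b``) designation; ``mode="t_only"``
    restricts the count to tetrahedral centres.  The reported value is
    the difference of the per-molecule means of the two sides.
    """
    if mode not in ("t_and_b", "t_only"):
        raise ValueError(f"unknown stereo mode {mode!r}")
    r = _parse_entry(entry)
    unknown = r.direction is RDirection.OMITTED
    st_r, n_r = _stereo_stats(_side_layers(r.reactant_bodies()), mode)
    st_p, n_p = _stereo_stats(_side_layers(r.product_bodies()), mode)
    empty = n_r == 0 or n_p == 0
    mean_r = Fraction(st_r, n_r) if n_r else Fraction(0)
    mean_p = Fraction(st_p, n_p) if n_p else Fraction(0)
    delta = mean_p - mean_r
    if unknown:
        delta = abs(delta)
    return ChangeReport(
        stereocentre_delta_per_molecule=delta,
        direction_unknown=unknown,
        empty_denominator=empty,
    )


@dataclass(frozen=True)
class CorpusStats:
    entry_count: int
    unique_reactions: int
    total_molecule_occurrences: int   # over unique reactions, all three groups
    unique_molecules: int
    compression_ratio: Optional[float] = None   # identifier bytes / source bytes


def corpus_stats(
    corpus: RInChICorpus, source_bytes: Optional[int] = None
) -> CorpusStats:
    """Summary counts of a corpus.

    Molecule counts are taken over the unique reactions (each distinct
    identifier counted once), tallying every occurrence in all three
    groups; ``unique_molecules`` is the number of distinct InChI bodies.
    When the byte size of the source reaction files is supplied, the
    compression ratio of the one-line-per-reaction corpus is reported.
    """
    seen: set[str] = set()
    occurrences = 0
    bodies: set[str] = set()
    for i in range(len(corpus)):
        s = corpus.entries[i].rinchi
        if s in seen:
            continue
        seen.add(s)
        r = corpus.parsed(i)
        occurrences += len(r.all_bodies)
        bodies.update(r.all_bodies)
    ratio = None
    if source_bytes:
        ratio = len(corpus.to_lines().encode("utf-8")) / source_bytes
    return CorpusStats(
        entry_count=len(corpus),
        unique_reactions=len(seen),
        total_molecule_occurrences=occurrences,
        unique_molecules=len(bodies),
        compression_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# TSV report rendering
# ---------------------------------------------------------------------------

def rings_report_tsv(corpus: RInChICorpus) -> str:
    """Per-entry ring changes as TSV.

    Columns: entry index, source id, ring_count_delta,
    rings_per_molecule_delta, rings_per_cyclic_molecule_delta,
    direction_unknown, empty_denominator.
    """
    rows = ["entry\tsource_id\tring_count_delta\trings_per_molecule_delta"
            "\trings_per_cyclic_molecule_delta\tdirection_unknown\tempty_denominator"]
    for i in range(len(corpus)):
        rep = ring_change(corpus.parsed(i))
        rows.append(
            f"{i}\t{corpus.entries[i].source_id}\t{rep.ring_count_delta}"
            f"\t{float(rep.rings_per_molecule_delta):g}"
            f"\t{float(rep.rings_per_cyclic_molecule_delta):g}"
            f"\t{int(rep.direction_unknown)}\t{int(rep.empty_denominator)}"
        )
    return "\n".join(rows) + "\n"


def stereo_report_tsv(corpus: RInChICorpus, mode: str = "t_and_b") -> str:
    """Per-entry stereocentre changes as TSV.

    Columns: entry index, source id, stereocentre_delta_per_molecule,
    direction_unknown, empty_denominator.
    """
    rows = ["entry\tsource_id\tstereocentre_delta_per_molecule"
            "\tdirection_unknown\tempty_denominator"]
    for i in range(len(corpus)):
        rep = stereo_change(corpus.parsed(i), mode=mode)
        rows.append(
            f"{i}\t{corpus.entries[i].source_id}"
            f"\t{float(rep.stereocentre_delta_per_molecule):g}"
            f"\t{int(rep.direction_unknown)}\t{int(rep.empty_denominator)}"
        )
    return "\n".join(rows) + "\n"
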