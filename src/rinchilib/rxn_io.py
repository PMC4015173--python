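"""Reading and writing MDL RXNfiles and RDfiles.

RXNfiles describe a single reaction as a header plus embedded V2000
molfiles (reactants first, then products).  RDfiles bundle many reaction
records, each optionally carrying ``$DTYPE``/``$DATUM`` data fields;
molfile-valued datums whose field name looks like a catalyst, solvent,
reagent or agent entry are routed into the reaction's agent group, and
the RDfile ``RXN:VARIATION(k)`` convention tags which reaction variation
an agent belongs to.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Iterator, Optional

from .errors import RDFileError, RXNFormatError, RInChIError
from .inchi_adapter import MolRecord, molfile_to_inchi

#: Default patterns (case-insensitive regexes) deciding which RDfile data
#: fields carry agent structures.  Vendor RDfiles disagree on the exact
#: vocabulary, so this is a configuration item.
DEFAULT_AGENT_FIELD_PATTERNS = (r"catalyst", r"solvent", r"reagent", r"agent")

_VARIATION_RE = re.compile(r"VARIATION\((\d+)\)", re.IGNORECASE)


class Direction(Enum):
    """Reaction direction as recorded in the source file."""

    FORWARD = "forward"
    BACKWARD = "backward"
    EQUILIBRIUM = "equilibrium"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class ReactionRecord:
    """A reaction: reactants, products and agents as molecule records.

    Any of the three lists may be empty — a half-known reaction is still
    a reaction.  ``agent_variations`` is aligned index-by-index with
    ``agents`` and holds the RDfile variation number each agent belongs
    to (``None`` = common to all variations).
    """

    reactants: tuple[MolRecord, ...] = ()
    products: tuple[MolRecord, ...] = ()
    agents: tuple[MolRecord, ...] = ()
    direction: Direction = Direction.FORWARD
    source_id: str = ""
    agent_variations: tuple[Optional[int], ...] = ()

    def __post_init__(self):
        if self.agent_variations and len(self.agent_variations) != len(self.agents):
            raise ValueError("agent_variations must align with agents")


def _split_molfiles(body_lines: list[str]) -> list[str]:
    """Split the tail of an RXNfile into its ``$MOL``-prefixed molfiles."""
    blocks: list[str] = []
    current: Optional[list[str]] = None
    for ln in body_lines:
        if ln.startswith("$MOL"):
            if current is not None:
                blocks.append("\n".join(current))
            current = []
        elif current is not None:
            current.append(ln)
    if current is not None:
        blocks.append("\n".join(current))
    return blocks


def read_rxn(text: str) -> ReactionRecord:
    """Parse an RXNfile into a :class:`ReactionRecord`.

    The first N embedded molfiles become reactants and the following M
    become products, per the counts line.  An RXN arrow points left to
    right, so the direction defaults to forward.  Agents are empty: the
    plain RXN format has no agent slot.
    """
    lines = text.split("\n")
    if not lines or not lines[0].startswith("$RXN"):
        raise RXNFormatError("file does not start with $RXN")
    if len(lines) < 5:
        raise RXNFormatError("RXN header truncated")
    counts = lines[4]
    try:
        n_react = int(counts[0:3])
        n_prod = int(counts[3:6])
    except (ValueError, IndexError):
        raise RXNFormatError(f"unreadable RXN counts line: {counts!r}")
    blocks = _split_molfiles(lines[5:])
    if len(blocks) != n_react + n_prod:
        raise RXNFormatError(
            f"RXN declares {n_react}+{n_prod} molfiles but contains {len(blocks)}",
            molfile_index=len(blocks),
        )
    mols: list[MolRecord] = []
    for i, block in enumerate(blocks):
        try:
            mols.append(molfile_to_inchi(block))
        except RInChIError as exc:
            raise RXNFormatError(
                f"embedded molfile {i} failed to convert: {exc}", molfile_index=i
            ) from exc
    return ReactionRecord(
        reactants=tuple(mols[:n_react]),
        products=tuple(mols[n_react:]),
        direction=Direction.FORWARD,
    )


def write_rxn(rxn: ReactionRecord, include_agents: bool = False,
              program: str = "rinchilib") -> str:
    """Serialize a :class:`ReactionRecord` as RXNfile text.

    The standard RXN dialect has no agent slot; by default agents are
    dropped with a warning.  With ``include_agents=True`` an
    agent-bearing dialect is emitted: a third count on the counts line
    and the agent molfiles appended after the products.
    """
    mols = list(rxn.reactants) + list(rxn.products)
    counts = f"{len(rxn.reactants):3d}{len(rxn.products):3d}"
    if rxn.agents:
        if include_agents:
            mols += list(rxn.agents)
            counts += f"{len(rxn.agents):3d}"
        else:
            warnings.warn(
                "RXN output has no agent slot; dropping "
                f"{len(rxn.agents)} agent(s)", stacklevel=2,
            )
    header = [f"$RXN {rxn.source_id}".rstrip(), "", f"      {program}", "", counts]
    out = header
    for mol in mols:
        out.append("$MOL")
        out.append(mol.molfile_text.rstrip("\n"))
    return "\n".join(out) + "\n"


def _iter_rd_records(lines: list[str]) -> Iterator[tuple[str, list[str]]]:
    """Yield ``(registry_line, record_lines)`` per ``$RFMT`` record."""
    current: Optional[list[str]] = None
    reg = ""
    for ln in lines:
        if ln.startswith("$RFMT"):
            if current is not None:
                yield reg, current
            reg = ln[len("$RFMT"):].strip()
            current = []
        elif current is not None:
            current.append(ln)
    if current is not None:
        yield reg, current


def _parse_datums(lines: list[str]) -> list[tuple[str, str]]:
    """Collect ``$DTYPE``/``$DATUM`` pairs; molfile datums keep their block."""
    pairs: list[tuple[str, str]] = []
    i = 0
    while i < len(lines):
        if lines[i].startswith("$DTYPE"):
            name = lines[i][len("$DTYPE"):].strip()
            i += 1
            if i < len(lines) and lines[i].startswith("$DATUM"):
                value = lines[i][len("$DATUM"):].strip()
                i += 1
                if value == "$MFMT":
                    block: list[str] = []
                    while i < len(lines) and not lines[i].startswith("$DTYPE"):
                        block.append(lines[i])
                        i += 1
                        if block and block[-1].startswith("M  END"):
                            break
                    value = "$MFMT\n" + "\n".join(block)
                pairs.append((name, value))
            else:
                pairs.append((name, ""))
        else:
            i += 1
    return pairs


def _reclassify_shared_species(rxn: ReactionRecord) -> ReactionRecord:
    """Move species appearing identically on both sides into the agents.

    A molecule present unchanged among both reactants and products is,
    by definition, on both sides of the arrow — the agent group.  One
    matched pair is removed per agent occurrence.
    """
    prod_pool = list(rxn.products)
    new_react: list[MolRecord] = []
    moved: list[MolRecord] = []
    for r in rxn.reactants:
        match = next((p for p in prod_pool if p.inchi == r.inchi), None)
        if match is not None:
            prod_pool.remove(match)
            moved.append(r)
        else:
            new_react.append(r)
    if not moved:
        return rxn
    return replace(
        rxn,
        reactants=tuple(new_react),
        products=tuple(prod_pool),
        agents=rxn.agents + tuple(moved),
        agent_variations=(rxn.agent_variations or (None,) * len(rxn.agents))
        + (None,) * len(moved),
    )


def read_rdfile(
    text: str,
    agent_field_patterns: Iterable[str] = DEFAULT_AGENT_FIELD_PATTERNS,
    on_error: Optional[Callable[[int, Exception], None]] = None,
    reclassify_agents: bool = True,
) -> Iterator[ReactionRecord]:
    """Stream the reaction records of an RDfile.

    Records are yielded one at a time, so memory use is bounded per
    record rather than per file.  A malformed record is reported through
    ``on_error(record_index, exception)`` (default: a warning) and the
    remaining records are still produced.

    Molfile datums whose ``$DTYPE`` name matches one of
    ``agent_field_patterns`` (case-insensitive regex search) populate the
    agent group; a ``VARIATION(k)`` tag in the name records which
    reaction variation the agent belongs to.  Free-text datums are
    folded into ``source_id`` and do not affect reaction identity.
    """
    lines = text.split("\n")
    if not lines or not lines[0].startswith("$RDFILE"):
        raise RDFileError("file does not start with $RDFILE")
    patterns = [re.compile(p, re.IGNORECASE) for p in agent_field_patterns]

    for idx, (reg, rec_lines) in enumerate(_iter_rd_records(lines)):
        try:
            yield _parse_rd_record(reg, rec_lines, patterns, reclassify_agents)
        except RInChIError as exc:
            err = RDFileError(f"record {idx}: {exc}", record_index=idx)
            if on_error is not None:
                on_error(idx, err)
            else:
                warnings.warn(str(err), stacklevel=2)


def _parse_rd_record(
    reg: str,
    rec_lines: list[str],
    patterns: list[re.Pattern],
    reclassify: bool,
) -> ReactionRecord:
    # locate the embedded $RXN block (everything until the first $DTYPE)
    rxn_start = next((i for i, ln in enumerate(rec_lines) if ln.startswith("$RXN")), None)
    dtype_start = next(
        (i for i, ln in enumerate(rec_lines) if ln.startswith("$DTYPE")), len(rec_lines)
    )
    if rxn_start is None:
        raise RDFileError("record contains no $RXN block")
    rxn = read_rxn("\n".join(rec_lines[rxn_start:dtype_start]))

    agents: list[MolRecord] = []
    variations: list[Optional[int]] = []
    texts: list[str] = []
    for name, value in _parse_datums(rec_lines[dtype_start:]):
        if value.startswith("$MFMT"):
            if any(p.search(name) for p in patterns):
                agents.append(molfile_to_inchi(value[len("$MFMT\n"):]))
                m = _VARIATION_RE.search(name)
                variations.append(int(m.group(1)) if m else None)
            # molfile datums under unrecognized names are ignored
        else:
            texts.append(f"{name}={value}")
    source_id = reg if not texts else reg + "|" + "|".join(texts)
    rec = replace(
        rxn,
        agents=tuple(agents),
        agent_variations=tuple(variations),
        source_id=source_id.strip("|"),
    )
    if reclassify:
        rec = _reclassify_shared_species(rec)
    return rec


def expand_variations(record: ReactionRecord) -> list[ReactionRecord]:
    """Expand a variation-tagged record into one record per variation.

    Agents tagged ``VARIATION(k)`` appear only in variation ``k``;
    untagged agents are common to every variation.  Without variation
    tags the record itself (as a single variation) is returned.
    """
    tags = record.agent_variations or (None,) * len(record.agents)
    numbers = sorted({t for t in tags if t is not None})
    if not numbers:
        return [record]
    common = [a for a, t in zip(record.agents, tags) if t is None]
    out = []
    for k in numbers:
        var_agents = common + [a for a, t in zip(record.agents, tags) if t == k]
        out.append(
            replace(
                record,
                agents=tuple(var_agents),
                agent_variations=(None,) * len(var_agents),
                source_id=f"{record.source_id}#v{k}" if record.source_id else f"#v{k}",
            )
        )
    return out
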