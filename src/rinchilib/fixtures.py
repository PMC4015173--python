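"""Toy molecules, reactions and synthetic reaction databases.

Every test and demonstration in this package runs on the material
defined here: a set of small hand-curated V2000 structures with known
ring and stereocentre counts, a handful of reaction templates (an
ester-style one-to-two split, a ring-forming cycloaddition, an
enantiomeric reduction pair, a two-step chain, an equilibrium), and a
seed-deterministic RDfile generator that assembles corpora of hundreds
of distinct reactions with injected exact duplicates and agent
variations.  The generator returns a manifest of construction-time
ground truth — expected unique counts, duplicate groups, per-entry ring
and stereocentre changes — against which the analysis pipeline can be
checked end to end.

The generated corpora emulate the shape of vendor reaction databases
(records with embedded RXN blocks, catalyst/solvent data fields,
free-text comments) at toy scale; they make no attempt to sample
realistic reaction chemistry.
"""

from __future__ import annotations

import functools
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._molblocks import MOLBLOCKS
from .inchi_adapter import MolRecord, molfile_to_inchi
from .rxn_io import Direction, ReactionRecord, write_rxn

#: Ground-truth annotations: independent rings and stereocentres
#: (tetrahedral + double-bond designations) per molecule.  Verified at
#: test time against a graph-cycle oracle on the molfile graphs.
MOLECULE_INFO: dict[str, dict[str, int]] = {
    "methane":        {"rings": 0, "stereo": 0},
    "ethanol":        {"rings": 0, "stereo": 0},
    "ethene":         {"rings": 0, "stereo": 0},
    "water":          {"rings": 0, "stereo": 0},
    "benzene":        {"rings": 1, "stereo": 0},
    "butadiene":      {"rings": 0, "stereo": 0},
    "cyclohexene":    {"rings": 1, "stereo": 0},
    "acetic_acid":    {"rings": 0, "stereo": 0},
    "ethyl_acetate":  {"rings": 0, "stereo": 0},
    "butanone":       {"rings": 0, "stereo": 0},
    "r_butan_2_ol":   {"rings": 0, "stereo": 1},
    "s_butan_2_ol":   {"rings": 0, "stereo": 1},
    "r_butan_2_amine": {"rings": 0, "stereo": 1},
    "s_butan_2_amine": {"rings": 0, "stereo": 1},
    "sulfuric_acid":  {"rings": 0, "stereo": 0},
    "hexadiene":      {"rings": 0, "stereo": 0},
    "naphthalene":    {"rings": 2, "stereo": 0},
    "methanol":       {"rings": 0, "stereo": 0},
    "toluene":        {"rings": 1, "stereo": 0},
}

MOLECULE_NAMES = tuple(MOLECULE_INFO)


def molblock(name: str) -> str:
    """The V2000 block of a named fixture molecule."""
    return MOLBLOCKS[name]


@functools.lru_cache(maxsize=None)
def mol_record(name: str) -> MolRecord:
    """The fixture molecule as a converted :class:`MolRecord` (cached)."""
    return molfile_to_inchi(MOLBLOCKS[name])


@dataclass(frozen=True)
class ReactionTemplate:
    """A named toy reaction with ground-truth structural annotations."""

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    agents: tuple[str, ...] = ()
    direction: Direction = Direction.FORWARD

    def record(self) -> ReactionRecord:
        return ReactionRecord(
            reactants=tuple(mol_record(n) for n in self.reactants),
            products=tuple(mol_record(n) for n in self.products),
            agents=tuple(mol_record(n) for n in self.agents),
            direction=self.direction,
            source_id=self.name,
        )

    @property
    def ring_delta(self) -> int:
        return (sum(MOLECULE_INFO[n]["rings"] for n in self.products)
                - sum(MOLECULE_INFO[n]["rings"] for n in self.reactants))

    @property
    def stereo_delta_per_molecule(self) -> float:
        p = sum(MOLECULE_INFO[n]["stereo"] for n in self.products) / max(len(self.products), 1)
        r = sum(MOLECULE_INFO[n]["stereo"] for n in self.reactants) / max(len(self.reactants), 1)
        return p - r


REACTIONS: dict[str, ReactionTemplate] = {
    t.name: t
    for t in (
        # one reactant, two products — the classic one-to-two split
        ReactionTemplate("dehydration", ("ethanol",), ("ethene", "water"),
                         ("sulfuric_acid",)),
        # ring formation: diene + dienophile -> cyclohexene skeleton
        ReactionTemplate("diels_alder", ("butadiene", "ethene"), ("cyclohexene",)),
        # ring opening by isomerization (same formula, one ring fewer)
        ReactionTemplate("ring_opening", ("cyclohexene",), ("hexadiene",)),
        # enantiomeric reduction pair: same ketone, mirror-image alcohols
        ReactionTemplate("reduction_r", ("butanone",), ("r_butan_2_ol",)),
        ReactionTemplate("reduction_s", ("butanone",), ("s_butan_2_ol",)),
        # mirror-image substitutions: stereogenic on both sides, so the
        # two identifiers differ only in the minor (stereo) layers
        ReactionTemplate("substitution_r", ("r_butan_2_ol",), ("r_butan_2_amine",)),
        ReactionTemplate("substitution_s", ("s_butan_2_ol",), ("s_butan_2_amine",)),
        # esterification, also available as an equilibrium
        ReactionTemplate("esterification", ("acetic_acid", "ethanol"),
                         ("ethyl_acetate", "water"), ("sulfuric_acid",)),
        ReactionTemplate("esterification_eq", ("acetic_acid", "ethanol"),
                         ("ethyl_acetate", "water"), ("sulfuric_acid",),
                         Direction.EQUILIBRIUM),
        # second step of the two-step chain: the dehydration's alkene
        # is consumed by the cycloaddition
        ReactionTemplate("chain_step2", ("ethene", "butadiene"), ("cyclohexene",),
                         ("toluene",)),
        # identity entry: no structural change at all
        ReactionTemplate("identity", ("benzene",), ("benzene",)),
    )
}


def reaction_record(name: str) -> ReactionRecord:
    return REACTIONS[name].record()


def rxnfile(name: str) -> str:
    """The fixture reaction serialized as an RXNfile (agents dropped)."""
    rec = reaction_record(name)
    if rec.agents:
        rec = ReactionRecord(reactants=rec.reactants, products=rec.products,
                             direction=rec.direction, source_id=rec.source_id)
    return write_rxn(rec)


# ---------------------------------------------------------------------------
# programmatic chain molecules (corpus filler)
# ---------------------------------------------------------------------------

def _v2000(atoms: Sequence[str], bonds: Sequence[tuple[int, int, int]]) -> str:
    lines = ["", "  rinchilib", "", f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for sym in atoms:
        lines.append(f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {sym:<3} 0  0  0  0  0  0  0  0  0  0  0  0")
    for a, b, order in bonds:
        lines.append(f"{a:3d}{b:3d}{order:3d}  0")
    lines.append("M  END")
    return "\n".join(lines)


def chain_alcohol_molblock(n: int, k: int) -> str:
    """A linear C``n`` alkanol with the hydroxyl on carbon ``k``.

    ``k`` must not exceed ``(n + 1) // 2``: the mirror-image positions
    describe the same molecule and would not yield a distinct InChI.
    """
    if not (1 <= k <= (n + 1) // 2):
        raise ValueError("hydroxyl position beyond the symmetry-unique range")
    atoms = ["C"] * n + ["O"]
    bonds = [(i, i + 1, 1) for i in range(1, n)] + [(k, n + 1, 1)]
    return _v2000(atoms, bonds)


def chain_alkene_molblock(n: int) -> str:
    """The linear 1-alkene with ``n`` carbons."""
    atoms = ["C"] * n
    bonds = [(1, 2, 2)] + [(i, i + 1, 1) for i in range(2, n)]
    return _v2000(atoms, bonds)


@functools.lru_cache(maxsize=None)
def _chain_reaction(n: int, k: int) -> ReactionRecord:
    """Dehydration of the (n, k) alkanol to the 1-alkene plus water."""
    return ReactionRecord(
        reactants=(molfile_to_inchi(chain_alcohol_molblock(n, k)),),
        products=(molfile_to_inchi(chain_alkene_molblock(n)), mol_record("water")),
    )


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusRecipe:
    """Parameters of a synthetic reaction database.

    ``n_reactions`` counts reactions *after* variation expansion;
    ``duplicate_fraction`` of them are exact repeats of earlier entries
    distinguished only by a free-text comment; ``agent_fraction`` of the
    distinct cores carry a catalyst/solvent data field; half of those
    agent-bearing cores are written as two catalyst variations of one
    record (each variation counting as one reaction).
    """

    n_reactions: int = 100
    duplicate_fraction: float = 0.1
    agent_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")


@dataclass(frozen=True)
class EntrySpec:
    """Construction-time ground truth for one expanded corpus entry."""

    reactant_names: tuple[str, ...]
    product_names: tuple[str, ...]
    agent_names: tuple[str, ...]
    ring_delta: int
    stereo_total_reactants: int
    stereo_total_products: int
    duplicate_of: Optional[int] = None


@dataclass(frozen=True)
class CorpusManifest:
    """What the generated RDfile is known to contain."""

    entries: tuple[EntrySpec, ...]
    duplicate_groups: tuple[tuple[int, ...], ...]

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_duplicates(self) -> int:
        return sum(1 for e in self.entries if e.duplicate_of is not None)

    @property
    def n_unique(self) -> int:
        return self.n_entries - self.n_duplicates

    @property
    def unique_molecule_names(self) -> frozenset[str]:
        names: set[str] = set()
        for e in self.entries:
            if e.duplicate_of is None:
                names.update(e.reactant_names, e.product_names, e.agent_names)
        return frozenset(names)

    @property
    def total_molecule_occurrences(self) -> int:
        return sum(
            len(e.reactant_names) + len(e.product_names) + len(e.agent_names)
            for e in self.entries
            if e.duplicate_of is None
        )

    def to_tsv(self) -> str:
        rows = ["entry\treactants\tproducts\tagents\tring_delta"
                "\tstereo_reactants\tstereo_products\tduplicate_of"]
        for i, e in enumerate(self.entries):
            dup = "" if e.duplicate_of is None else str(e.duplicate_of)
            rows.append(
                f"{i}\t{','.join(e.reactant_names)}\t{','.join(e.product_names)}"
                f"\t{','.join(e.agent_names)}\t{e.ring_delta}"
                f"\t{e.stereo_total_reactants}\t{e.stereo_total_products}\t{dup}"
            )
        return "\n".join(rows) + "\n"


_AGENT_POOL = ("sulfuric_acid", "toluene", "methanol")

#: Reaction templates eligible for corpus records (single-direction,
#: agent-free cores; agents are injected by the recipe).
_CORPUS_TEMPLATES = ("diels_alder", "ring_opening", "reduction_r", "reduction_s")


@dataclass(frozen=True)
class _Core:
    """One distinct reaction core before agent decoration."""

    reactant_names: tuple[str, ...]
    product_names: tuple[str, ...]
    reactant_blocks: tuple[str, ...]
    product_blocks: tuple[str, ...]


def _core_pool() -> list[_Core]:
    pool = []
    for tname in _CORPUS_TEMPLATES:
        t = REACTIONS[tname]
        pool.append(_Core(
            t.reactants, t.products,
            tuple(MOLBLOCKS[n] for n in t.reactants),
            tuple(MOLBLOCKS[n] for n in t.products),
        ))
    return pool


def _chain_core(n: int, k: int) -> _Core:
    return _Core(
        (f"alkanol_{n}_{k}",), (f"alkene_{n}", "water"),
        (chain_alcohol_molblock(n, k),),
        (chain_alkene_molblock(n), MOLBLOCKS["water"]),
    )


def _iter_chain_cores():
    n = 3
    while True:
        for k in range(1, (n + 1) // 2 + 1):
            yield _chain_core(n, k)
        n += 1


def _entry_spec(core: _Core, agents: tuple[str, ...],
                duplicate_of: Optional[int]) -> EntrySpec:
    def info(names, key):
        return sum(MOLECULE_INFO.get(n, {"rings": 0, "stereo": 0})[key] for n in names)
    return EntrySpec(
        reactant_names=core.reactant_names,
        product_names=core.product_names,
        agent_names=agents,
        ring_delta=info(core.product_names, "rings") - info(core.reactant_names, "rings"),
        stereo_total_reactants=info(core.reactant_names, "stereo"),
        stereo_total_products=info(core.product_names, "stereo"),
        duplicate_of=duplicate_of,
    )


def make_corpus(recipe: CorpusRecipe) -> tuple[str, CorpusManifest]:
    """Assemble a synthetic RDfile and its ground-truth manifest.

    Seed-deterministic: the same recipe yields byte-identical text.  The
    file contains ``recipe.n_reactions`` reactions after variation
    expansion; duplicates are injected as exact copies of earlier
    records whose only difference is a free-text comment datum, so they
    collapse to the same identifier.
    """
    rng = random.Random(recipe.seed)
    n = recipe.n_reactions
    n_dup = min(int(round(n * recipe.duplicate_fraction)), n - 1)
    n_distinct = n - n_dup

    # records are (core, agents-per-variation tuple, comment, duplicate_of)
    records: list[tuple[_Core, tuple[tuple[str, ...], ...], str, Optional[int]]] = []
    entry_specs: list[EntrySpec] = []
    #: entry index ranges per record, to resolve duplicate references
    entry_of_record: list[list[int]] = []

    chain_iter = _iter_chain_cores()
    cores = _core_pool()
    while True:
        have = sum(len(v) for _, v, _, _ in records)
        if have >= n_distinct:
            break
        core = cores.pop(0) if cores else next(chain_iter)
        remaining = n_distinct - have
        variations: tuple[tuple[str, ...], ...]
        roll = rng.random()
        if roll < recipe.agent_fraction / 2 and remaining >= 2:
            # one record, two catalyst variations
            a, b = rng.sample(_AGENT_POOL, 2)
            variations = ((a,), (b,))
        elif roll < recipe.agent_fraction:
            variations = ((rng.choice(_AGENT_POOL),),)
        else:
            variations = ((),)
        idxs = []
        for agents in variations:
            idxs.append(len(entry_specs))
            entry_specs.append(_entry_spec(core, agents, None))
        entry_of_record.append(idxs)
        records.append((core, variations, "", None))

    # inject duplicates: copies of random earlier records, new comment;
    # a copied record contributes as many entries as it has variations
    n_base_records = len(records)
    d = 0
    while len(entry_specs) < n:
        remaining = n - len(entry_specs)
        src = rng.randrange(n_base_records)
        core, variations, _, orig = records[src]
        if len(variations) > remaining:
            continue
        target = orig if orig is not None else src
        idxs = []
        for vi, agents in enumerate(variations):
            idxs.append(len(entry_specs))
            entry_specs.append(
                _entry_spec(core, agents, entry_of_record[target][vi])
            )
        entry_of_record.append(idxs)
        d += 1
        records.append((core, variations, f"replicate run {d}", target))

    # duplicate groups over expanded entries
    groups: dict[int, list[int]] = {}
    for i, e in enumerate(entry_specs):
        root = e.duplicate_of if e.duplicate_of is not None else i
        groups.setdefault(root, []).append(i)
    duplicate_groups = tuple(
        tuple(v) for v in groups.values() if len(v) > 1
    )

    # render the RDfile
    out = ["$RDFILE 1", "$DATM 1"]
    for ri, (core, variations, comment, _) in enumerate(records):
        out.append(f"$RFMT $RIREG {ri + 1}")
        out.append("$RXN")
        out.append("")
        out.append("  rinchilib")
        out.append("")
        out.append(f"{len(core.reactant_blocks):3d}{len(core.product_blocks):3d}")
        for block in core.reactant_blocks + core.product_blocks:
            out.append("$MOL")
            out.append(block.rstrip("\n"))
        multi = len(variations) > 1
        for vi, agents in enumerate(variations):
            for an in agents:
                tag = f"RXN:VARIATION({vi + 1}):CATALYST" if multi else "RXN:CATALYST"
                out.append(f"$DTYPE {tag}")
                out.append("$DATUM $MFMT")
                out.append(MOLBLOCKS[an].rstrip("\n"))
        if comment:
            out.append("$DTYPE RXN:COMMENT")
            out.append(f"$DATUM {comment}")
    text = "\n".join(out) + "\n"

    manifest = CorpusManifest(
        entries=tuple(entry_specs), duplicate_groups=duplicate_groups
    )
    return text, manifest
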