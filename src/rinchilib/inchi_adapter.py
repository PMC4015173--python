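"""Bridge between structure files and InChI strings.

This module isolates the single external dependency on an InChI engine
(RDKit's bundled implementation of the IUPAC algorithm) behind a small
contract: molfile text in, standard InChI (version 1S) plus AuxInfo out,
and the reverse.  The engine's output is treated as ground truth and is
never re-canonicalized here.

It also contains a parser that decomposes an InChI into its named layers
— chemical formula, heavy-atom connectivity, hydrogen, charge,
protonation and stereo layers — turning the ``/c`` connection-table
grammar into an explicit edge list.  Ring statistics downstream rely on
that edge list: for a connected component the number of independent
rings (the cyclomatic number) is ``edges - atoms + 1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import AllChem

from .errors import (
    InChIConversionError,
    InChIDecodeError,
    LayerParseError,
    MolfileParseError,
)

RDLogger.DisableLog("rdApp.*")

INCHI_PREFIX = "InChI=1S/"
AUXINFO_PREFIX = "AuxInfo="

#: Layer prefixes that belong to the major part of an InChI (together
#: with the leading formula): connectivity, hydrogen and charge.  All
#: remaining layers (stereo, isotope, ...) form the minor part; the
#: protonation layer ``/p`` is carried separately.
_MAJOR_PREFIXES = ("c", "h", "q")

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA_RE = re.compile(r"^(\d*)((?:[A-Z][a-z]?\d*)+)$")


@dataclass(frozen=True)
class MolRecord:
    """One molecular species: its CTAB V2000 block and derived InChI.

    ``auxinfo`` carries the engine's auxiliary information (atom
    numbering and 2D coordinates) needed to regenerate a drawable
    molfile; it may be absent for species reconstructed from a bare
    identifier.
    """

    molfile_text: str
    inchi: str
    auxinfo: Optional[str] = None

    @property
    def inchi_body(self) -> str:
        """The InChI with its ``InChI=1S/`` prefix stripped."""
        return strip_inchi_prefix(self.inchi)


@dataclass(frozen=True)
class InChIComponent:
    """One covalently connected component of an InChI."""

    formula: str
    heavy_atoms: int
    edges: tuple[tuple[int, int], ...]  # 1-based, local to the component
    stereo_t: tuple[str, ...] = ()
    stereo_b: tuple[str, ...] = ()

    @property
    def ring_count(self) -> int:
        # A single InChI component is connected by construction, so the
        # cyclomatic number reduces to E - V + 1 (0 for an isolated atom).
        if self.heavy_atoms == 0:
            return 0
        return len(self.edges) - self.heavy_atoms + 1


@dataclass(frozen=True)
class ParsedInChI:
    """An InChI decomposed into named layers.

    ``connectivity`` is the global heavy-atom edge list with 1-based
    indices; atoms of successive components are offset so that every
    index is unique within the molecule.  ``components`` holds the
    per-component view used for "per molecule" statistics.
    """

    formula: str
    connectivity: tuple[tuple[int, int], ...]
    h_layer: str
    charge_q: int
    protonation_p: int
    stereo_t: tuple[str, ...]
    stereo_b: tuple[str, ...]
    stereo_m_s: tuple[str, ...]
    component_count: int
    components: tuple[InChIComponent, ...] = field(default=())

    @property
    def heavy_atom_count(self) -> int:
        return sum(c.heavy_atoms for c in self.components)

    @property
    def ring_count(self) -> int:
        """Total number of independent rings (cyclomatic number)."""
        return sum(c.ring_count for c in self.components)

    @property
    def stereocentre_count(self) -> int:
        """Stereocentres counted as tetrahedral plus double-bond designations."""
        return len(self.stereo_t) + len(self.stereo_b)


def strip_inchi_prefix(inchi: str) -> str:
    if not inchi.startswith(INCHI_PREFIX):
        raise LayerParseError(
            f"not a standard (1S) InChI: {inchi[:20]!r}...", layer="prefix"
        )
    return inchi[len(INCHI_PREFIX):]


def _molfile_precheck(molfile: str) -> int:
    """Light structural validation of a V2000 block.

    Returns the declared atom count.  Raises :class:`MolfileParseError`
    with a 1-based line number for truncated or malformed blocks.
    """
    lines = molfile.split("\n")
    if len(lines) < 4:
        raise MolfileParseError("molfile truncated before counts line", line=len(lines))
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileParseError(
            "V3000 CTAB blocks are not supported; supply V2000", line=4
        )
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolfileParseError(f"unreadable counts line: {counts!r}", line=4)
    needed = 4 + n_atoms + n_bonds
    if len(lines) < needed:
        raise MolfileParseError(
            f"molfile declares {n_atoms} atoms / {n_bonds} bonds but is truncated",
            line=len(lines),
        )
    for i in range(n_atoms):
        ln = lines[4 + i]
        try:
            float(ln[0:10]); float(ln[10:20]); float(ln[20:30])
        except (ValueError, IndexError):
            raise MolfileParseError(f"bad atom line: {ln!r}", line=5 + i)
    return n_atoms


def molfile_to_inchi(molfile: str) -> MolRecord:
    """Convert a CTAB V2000 block to a :class:`MolRecord`.

    The result carries the standard (1S) InChI and the engine's AuxInfo
    string.  Deterministic for fixed input.  An empty structure (zero
    atoms) is a conversion error: there is nothing to identify.
    """
    n_atoms = _molfile_precheck(molfile)
    if n_atoms == 0:
        raise InChIConversionError("molfile contains no atoms")
    res = Chem.MolBlockToInchiAndAuxInfo(molfile, treatWarningAsError=False)
    inchi, auxinfo = res[0], res[1]
    if not inchi:
        mol = Chem.MolFromMolBlock(molfile, sanitize=False)
        msg = "InChI engine returned no identifier"
        if mol is None:
            raise MolfileParseError("molfile rejected by structure parser", line=0)
        raise InChIConversionError(msg, engine_message=msg)
    if not inchi.startswith(INCHI_PREFIX):
        raise InChIConversionError(
            f"engine produced a non-standard identifier: {inchi[:20]!r}",
            engine_message=inchi,
        )
    return MolRecord(molfile_text=molfile, inchi=inchi, auxinfo=auxinfo)


def _auxinfo_coordinates(auxinfo: str) -> Optional[list[tuple[float, float, float]]]:
    """Extract per-atom coordinates from an AuxInfo string, reordered to
    canonical (InChI) atom order via the ``/N:`` numbering layer."""
    m = re.search(r"/rC:([^/]*)", auxinfo)
    if not m:
        return None
    coords = []
    for entry in m.group(1).split(";"):
        if not entry:
            continue
        parts = entry.split(",")
        coords.append(tuple(float(p) if p not in ("", "-") else 0.0 for p in parts[:3]))
    n_layer = re.search(r"/N:([^/]*)", auxinfo)
    if n_layer:
        order: list[int] = []
        for seg in n_layer.group(1).split(";"):
            for tok in seg.split(","):
                if tok:
                    order.append(int(tok))
        if len(order) == len(coords):
            coords = [coords[i - 1] for i in order]
    return coords


def _inchi_has_stereo(inchi: str) -> bool:
    body = strip_inchi_prefix(inchi)
    return any(lay[:1] in ("t", "b", "m") for lay in body.split("/")[1:])


def inchi_to_molfile(
    inchi: str, auxinfo: Optional[str] = None, layout: str = "auto"
) -> str:
    """Convert an InChI back into a CTAB V2000 block.

    Coordinates are taken from ``auxinfo`` when supplied.  Without
    AuxInfo the fallback depends on ``layout``:

    ``"auto"`` (default)
        all-zero coordinates, except that structures carrying stereo
        layers receive a freshly computed 2D depiction so that wedge
        bonds can express the stereochemistry and the block re-encodes
        to the same InChI;
    ``"zero"``
        always all-zero coordinates (stereo layers cannot survive);
    ``"depict"``
        always a computed 2D depiction.

    The re-derived InChI of the returned block equals the input InChI
    (for ``layout="zero"`` this holds up to stereo layers).
    """
    if not inchi.startswith(INCHI_PREFIX):
        raise InChIDecodeError(f"not a standard (1S) InChI: {inchi[:20]!r}")
    mol = Chem.MolFromInchi(inchi, sanitize=True, removeHs=True)
    if mol is None:
        raise InChIDecodeError(f"InChI engine could not decode {inchi!r}")

    coords = _auxinfo_coordinates(auxinfo) if auxinfo else None
    if coords is not None and len(coords) == mol.GetNumAtoms():
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y, z) in enumerate(coords):
            conf.SetAtomPosition(i, (x, y, z))
        mol.RemoveAllConformers()
        mol.AddConformer(conf, assignId=True)
        Chem.WedgeMolBonds(mol, mol.GetConformer())
    else:
        want_depict = layout == "depict" or (
            layout == "auto" and _inchi_has_stereo(inchi)
        )
        if want_depict:
            AllChem.Compute2DCoords(mol)
            Chem.WedgeMolBonds(mol, mol.GetConformer())
        else:
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i in range(mol.GetNumAtoms()):
                conf.SetAtomPosition(i, (0.0, 0.0, 0.0))
            mol.RemoveAllConformers()
            mol.AddConformer(conf, assignId=True)
    return Chem.MolToMolBlock(mol, kekulize=True)


# ---------------------------------------------------------------------------
# Layer parsing
# ---------------------------------------------------------------------------

def _parse_formula_components(formula: str) -> list[tuple[str, int]]:
    """Split a Hill formula on '.' and expand leading multipliers.

    Returns ``[(component_formula, heavy_atom_count), ...]``.
    """
    out: list[tuple[str, int]] = []
    for part in formula.split("."):
        if not part:
            raise LayerParseError(f"empty formula component in {formula!r}", layer="formula")
        m = _FORMULA_RE.match(part)
        if not m:
            raise LayerParseError(f"unparseable formula component {part!r}", layer="formula")
        mult = int(m.group(1)) if m.group(1) else 1
        heavy = 0
        for sym, count in _ELEMENT_RE.findall(m.group(2)):
            if sym != "H":
                heavy += int(count) if count else 1
        out.extend([(m.group(2), heavy)] * mult)
    return out


def _expand_multipliers(layer_text: str, layer_name: str) -> list[str]:
    """Split a per-component layer on ';' and expand ``k*seg`` repeats."""
    out: list[str] = []
    for seg in layer_text.split(";"):
        m = re.match(r"^(\d+)\*(.*)$", seg)
        if m:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(seg)
    return out


def _decode_connections(seg: str, heavy_atoms: int) -> tuple[tuple[int, int], ...]:
    """Decode one component's ``/c`` expression into an edge list.

    The expression is a depth-first walk over the canonical atom
    numbering: numbers are atoms, ``-`` links successive atoms, ``(``
    ... ``)`` brackets branches, ``,`` starts a further branch from the
    same branch point, and a repeated atom number closes a ring.
    """
    if not seg:
        return ()
    edges: list[tuple[int, int]] = []
    stack: list[int] = []
    prev: Optional[int] = None
    i = 0
    while i < len(seg):
        ch = seg[i]
        if ch.isdigit():
            j = i
            while j < len(seg) and seg[j].isdigit():
                j += 1
            atom = int(seg[i:j])
            if atom < 1 or atom > heavy_atoms:
                raise LayerParseError(
                    f"atom index {atom} outside heavy-atom count {heavy_atoms}",
                    layer="c",
                )
            if prev is not None:
                a, b = min(prev, atom), max(prev, atom)
                edges.append((a, b))
            prev = atom
            i = j
        elif ch == "-":
            i += 1
        elif ch == "(":
            if prev is None:
                raise LayerParseError("branch opened before any atom", layer="c")
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise LayerParseError("unbalanced ')' in connection layer", layer="c")
            prev = stack.pop()
            i += 1
        elif ch == ",":
            if not stack:
                raise LayerParseError("',' outside a branch in connection layer", layer="c")
            prev = stack[-1]
            i += 1
        elif ch == "?":
            # undefined connection marker: skip
            prev = None
            i += 1
        else:
            raise LayerParseError(f"unexpected character {ch!r} in connection layer", layer="c")
    if stack:
        raise LayerParseError("unbalanced '(' in connection layer", layer="c")
    return tuple(edges)


def _split_stereo_entries(seg: str) -> tuple[str, ...]:
    return tuple(e for e in seg.split(",") if e)


def _signed_total(layer_text: str, layer_name: str) -> int:
    total = 0
    for seg in _expand_multipliers(layer_text, layer_name):
        if not seg:
            continue
        try:
            total += int(seg)
        except ValueError:
            raise LayerParseError(
                f"non-integer entry {seg!r} in /{layer_name} layer", layer=layer_name
            )
    return total


def parse_inchi_layers(inchi: str) -> ParsedInChI:
    """Decompose a standard InChI into a :class:`ParsedInChI`.

    Absent layers yield empty/zero defaults.  Multi-component InChIs
    (``;``-separated sublayers, ``.``-separated formulas) produce one
    :class:`InChIComponent` per covalent component, with the global edge
    list offset so indices stay unique.
    """
    body = strip_inchi_prefix(inchi)
    layers = body.split("/")
    formula = layers[0]
    components_f = _parse_formula_components(formula) if formula else []

    raw: dict[str, str] = {}
    m_s: list[str] = []
    for lay in layers[1:]:
        if not lay:
            continue
        pre = lay[0]
        if pre in ("m", "s"):
            m_s.append(lay)
        elif pre in ("c", "h", "q", "p", "t", "b", "i"):
            # a layer letter may legitimately repeat after /i (isotopic
            # block); keep only the first (main) occurrence of each.
            raw.setdefault(pre, lay[1:])
        else:
            raw.setdefault(pre, lay[1:])

    n_comp = len(components_f)

    c_segments = _expand_multipliers(raw.get("c", ""), "c") if "c" in raw else []
    if c_segments and len(c_segments) != n_comp:
        # single-segment layers for single-component molecules are the norm;
        # anything else must line up with the formula components
        if n_comp == 1 and len(c_segments) == 1:
            pass
        else:
            raise LayerParseError(
                f"/c layer has {len(c_segments)} components, formula has {n_comp}",
                layer="c",
            )

    t_segments = _expand_multipliers(raw.get("t", ""), "t") if "t" in raw else []
    b_segments = _expand_multipliers(raw.get("b", ""), "b") if "b" in raw else []

    def seg_for(segments: list[str], idx: int) -> str:
        if not segments:
            return ""
        if len(segments) == 1 and n_comp == 1:
            return segments[0]
        return segments[idx] if idx < len(segments) else ""

    components: list[InChIComponent] = []
    global_edges: list[tuple[int, int]] = []
    offset = 0
    for idx, (cf, heavy) in enumerate(components_f):
        edges = _decode_connections(seg_for(c_segments, idx), heavy)
        st = _split_stereo_entries(seg_for(t_segments, idx))
        sb = _split_stereo_entries(seg_for(b_segments, idx))
        components.append(
            InChIComponent(formula=cf, heavy_atoms=heavy, edges=edges,
                           stereo_t=st, stereo_b=sb)
        )
        global_edges.extend((a + offset, b + offset) for a, b in edges)
        offset += heavy

    return ParsedInChI(
        formula=formula,
        connectivity=tuple(global_edges),
        h_layer=raw.get("h", ""),
        charge_q=_signed_total(raw.get("q", ""), "q") if "q" in raw else 0,
        protonation_p=_signed_total(raw.get("p", ""), "p") if "p" in raw else 0,
        stereo_t=tuple(e for seg in t_segments for e in _split_stereo_entries(seg)),
        stereo_b=tuple(e for seg in b_segments for e in _split_stereo_entries(seg)),
        stereo_m_s=tuple(m_s),
        component_count=n_comp,
        components=tuple(components),
    )


def split_major_minor(body: str) -> tuple[str, str, int]:
    """Split an InChI body into its major part, minor part and protonation.

    The major part comprises the formula and the ``/c``, ``/h`` and
    ``/q`` layers; the minor part is everything that follows (with its
    leading slash), except that the ``/p`` protonation layer is removed
    and returned as an integer.  This is the partition used both by the
    27-character molecule key and by the major/minor reaction keys.
    """
    layers = body.split("/")
    major = [layers[0]]
    minor: list[str] = []
    p = 0
    in_minor = False
    for lay in layers[1:]:
        pre = lay[:1]
        if pre == "p" and not in_minor:
            try:
                p = _signed_total(lay[1:], "p")
            except LayerParseError:
                p = 0
            continue
        if pre in _MAJOR_PREFIXES and not in_minor:
            major.append(lay)
        else:
            in_minor = True
            minor.append(lay)
    smaj = "/".join(major)
    smin = ("/" + "/".join(minor)) if minor else ""
    return smaj, smin, p
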