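# rinchilib

Canonical, layered text identifiers for chemical reactions — plus the
hashed fixed-length keys and the database tooling that make them useful.

A molecule has a canonical text descriptor (the IUPAC InChI); a
*reaction* needs one too, so that two scientists encoding the same
transformation — regardless of drawing order, file dialect or vendor
database — arrive at the same string, and so that reaction collections
can be deduplicated, indexed and searched with nothing more than text
tools.  `rinchilib` implements the 0.02 format of the reaction
identifier (RInChI) as a reusable Python library and command-line tool:

* **Conversion** — RXNfiles and RDfiles (MDL CTAB V2000) in, reaction
  identifiers and auxiliary information (RAuxInfo) out, and back again.
* **Keys** — four hashed RInChIKey variants: long A/B (one 27-character
  InChIKey per molecule) and short A/B (fixed length, hashed directly
  from the identifier), including a from-scratch, byte-exact
  implementation of the official InChIKey algorithm.
* **Multistep** — collapse an ordered sequence of single-step
  identifiers into the overall reaction, cancelling intermediates.
* **Analysis** — deduplication, reaction-partner search, ring-change and
  stereocentre-change statistics, corpus summaries — all computed from
  the identifier strings alone.

## The identifier

A reaction identifier consists of a version label, up to three groups of
molecule InChI bodies and an optional direction layer:

```
RInChI=0.02.1S/<group1>///<group2>///<group3>/d+
```

* Within a group, InChIs are separated by `//` and sorted byte-wise
  (`LC_ALL=C` order); groups are separated by `///`.
* Group 1 and group 2 are the two sides of the arrow, ordered by
  byte-wise comparison of their contents — *not* by chemistry.  Group 3
  holds the agents: catalysts and solvents, species present on both
  sides of the arrow.
* Which side holds the starting materials is recorded by the direction
  layer: `/d+` (group 1), `/d-` (group 2), `/d=` (equilibrium).  A
  reaction of uncertain direction omits the layer and is still valid.

Because every ordering is canonicalized away, the identifier is a pure
function of the reaction: permuting molecules in the input file, or
swapping the roles of the two sides, can only toggle `/d+` ↔ `/d-`.

## Worked example

A Diels–Alder reaction (butadiene + ethene → cyclohexene), as an
RXNfile, converted with the bundled fixtures:

```bash
python -c "from rinchilib import fixtures; open('da.rxn','w').write(fixtures.rxnfile('diels_alder'))"
rinchi create da.rxn --long-key b --short-key b
```

prints

```
RInChI=0.02.1S/C2H4/c1-2/h1-2H2//C4H6/c1-3-4-2/h3-4H,1-2H2///C6H10/c1-2-4-6-5-3-1/h1-2H,3-6H2/d+
bSA-FUHFF-VGGSQFUCUMXWEO-UHFFFAOYSA-N-KAKZBPTYRLMSJV-UHFFFAOYSA-N--HGCIXCUEYOPUTN-UHFFFAOYSA-N
bSA-FUHFF-BWDIXXBKWV-HGCIXCUEYO-UHFFFADPSC-NAZYK-NUHFF-NUHFF
```

Line 1 is the identifier: ethene and butadiene (sorted byte-wise) form
group 1, cyclohexene is group 2, there are no agents, and `/d+` says the
reactants sit in group 1.  Line 2 is the long key, version B: the `F`
opening block 2 encodes the forward direction, each 27-character block
is one molecule's InChIKey, and `--` marks the group boundary.  Line 3
is the fixed-length short key, version B: three 10-letter blocks hash
each group's major layers (formula, connectivity, hydrogens, charge) and
three 5-letter blocks flag each group's net protonation (`N` = 0) and
hash its minor (stereo) layers — so the enantiomer of a chiral reaction
would differ only in those minor blocks.

The other subcommands follow the same pattern: `rinchi decode` writes an
RXNfile back from an identifier (with coordinates when RAuxInfo is
supplied), `rinchi combine` merges a file of single-step identifiers,
and `rinchi search | rings | stereo | stats` analyse a one-identifier-
per-line corpus.  See `rinchi --help`.

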