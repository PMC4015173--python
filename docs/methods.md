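# Methods

This note records how the identifier, the hashed keys and the analysis
tools are computed, the design choices made where the format leaves room,
and what the synthetic test data does and does not establish.

## Canonicalization model

A reaction is reduced to three multisets of standard-InChI (1S) bodies:
the two sides of the arrow and the agents (species present on both
sides).  The per-molecule prefix `InChI=1S` is stripped before
embedding — the InChI version is declared once in the identifier label
(`RInChI=0.02.1S`) — and re-attached on decode.  Canonical form is
reached in two sorting passes:

1. within each group, bodies are sorted byte-wise (UTF-8 / `LC_ALL=C`
   order);
2. the two reaction-side groups are ordered by byte-wise comparison of
   their `//`-joined contents, the smaller becoming group 1.

The direction layer then records where the reactants landed (`/d+`,
`/d-`), `/d=` marks an equilibrium (the groups stay in canonical order;
the layer alone carries the semantics), and an unknown direction omits
the layer.  Consequences worth stating explicitly:

* **Empty groups sort last.**  Byte-wise comparison would place an empty
  group first; instead a reaction with only one known side keeps that
  side in group 1, so trailing empty groups (and their `///`
  separators) can be dropped from the string and a reactants-only
  reaction reads as a single group.
* **Identity reactions** (group 1 = group 2) force the direction layer
  off: forward and backward would be indistinguishable claims.
* **Duplicates are preserved** (`A + A → B` keeps `A//A`).  Collapsing
  them would silently destroy the only stoichiometry-like signal the
  format retains.  The format otherwise carries no stoichiometry.
* **Serialization is injective** on the value object; `parse` is its
  exact inverse, validates group sortedness and group order, accepts
  both label punctuations (`0.02.1S` and `0.02.1.S`, emitting the
  former) and an optional trailing slash, and preserves unknown
  trailing layers verbatim.
* An opt-in `major_then_minor` sort mode orders bodies by their major
  layers first with the full body as tiebreak, so that minor-layer
  edits (e.g. a stereo reassignment) cannot reshuffle a group.  The
  default remains plain byte-wise order.

The auxiliary companion (`RAuxInfo=0.02.1/…`) mirrors the identifier
group-by-group and index-by-index with the engine's AuxInfo bodies; its
header text is this package's convention.

## InChI handling

RDKit's bundled IUPAC InChI engine is the single structure backend,
isolated behind `inchi_adapter`.  Engine output is treated as ground
truth and never re-canonicalized.  The connectivity (`/c`) layer is
decoded by this package into an explicit edge list — numbers are atoms
in canonical order, `-` chains, parentheses branch, `,` resumes from the
branch point, and a repeated atom number closes a ring.  Ring statistics
use the cyclomatic number: for a connected component, independent rings
= edges − atoms + 1; multi-component InChIs (`.`/`;` sublayers,
including `k*` repeat shorthand) are split so that each covalent
component counts as one molecule.

Decoding an identifier back to structure files takes coordinates from
the RAuxInfo when available.  Without it, the fallback is all-zero
coordinates, *except* that structures carrying stereo layers receive a
freshly computed 2D depiction: wedge bonds cannot exist at zero
coordinates, and the round-trip law (re-encoding the written molfile
reproduces the identifier) takes precedence over coordinate neutrality.
Both behaviours are available explicitly (`layout="zero"` /
`"depict"`).

## Hashed keys

The molecule key (InChIKey) is implemented from scratch and is
byte-identical to the reference engine's output: the InChI body is split
into a major part (formula, `/c`, `/h`, `/q`) and a minor part
(everything else, with `/p` lifted out); a non-empty minor part shorter
than 255 characters is doubled; each part is SHA-256-hashed and encoded
in uppercase letters — 14-bit triplet values mapped through a base-26
table that skips the 676 triplets beginning with `E` and the 516-triplet
run `TAA`–`TTV` (leaving exactly 2^14 entries), 9-bit doublet values
through plain base-26 — followed by the `SA` flags and a protonation
character (`N` = 0, `A` when out of ±12).

The reaction keys reuse the same digest-to-letters encoding through
`hash_block(text, length)` (SHA-256, truncation is a prefix operation):

| key | shape |
|---|---|
| long A | `aSA` – 5-letter hash of all additional layers (direction included) – InChIKeys in identifier order, `-` within and `--` between groups |
| long B | `bSA` – direction letter (`F/B/E/U`) + 4-letter hash of remaining layers – same molecule blocks |
| short A | `aSA` – block 2 as long A – three 15-letter group hashes (present even for empty groups) |
| short B | `bSA` – block 2 as long B – three 10-letter major-part hashes – three 5-letter minor blocks (group protonation flag + 4-letter minor hash) |

The block lengths and hash construction are fixed constants of this
implementation.  Hashed keys are comparable only between
implementations sharing the same conventions; all structural guarantees
(fixed length, block equality patterns between related reactions,
direction sensitivity of the B versions) are independent of the hash
choice.  Key collisions are possible by construction and deliberately
unhandled; a brute-force scan over 10^4 distinct inputs is part of the
test suite as a sanity check, not a guarantee.  For short-B keys the
group protonation flag clamps to `A`/`Z` beyond ±12/±13 with a warning.

## Multistep combination

Steps are oriented (equilibrium steps require an explicit override;
direction-less steps read group 1 as reactants by default, or error
under `omitted_rule="error"`) and species are tracked as *sets* of
bodies — endpoint semantics: only each species' first and last
appearance classify it.  Consumed-first/consumed-last species are
overall reactants, produced/produced are overall products,
produced-then-consumed intermediates cancel, and a species consumed
first but produced last (e.g. regenerated at the end) is present at
both ends and therefore filed with the agents.  All step agents merge
into group 3 — the combined identifier cannot distinguish the reagents,
solvents and catalysts of individual steps — with terminal roles taking
precedence when a species is both.  The result is rebuilt through the
canonical constructor, so all sorting and direction rules apply.

## Analysis tools

All analyses read identifier strings only.  Deduplication is exact
string grouping (the canonical form makes this equivalent to sorting a
corpus file); a `core` mode ignoring agents and direction is available
but off by default.  Partner search resolves roles through the
direction layer (under `/d-`, group 1 holds the products); species of
equilibrium and direction-less entries match both reactant and product
queries, and "equilibrium agents" are group-3 members of `/d=` entries.
Ring and stereocentre changes are reported as products-minus-reactants;
stereocentres count `/t` plus `/b` designations by default (`t_only`
switches to tetrahedral centres), per-molecule means use covalent
components as molecules, and ratios with an empty denominator (no
molecules, or no cyclic molecule on a side) are reported as 0 with an
explicit flag so corpus scans stay total.  Entries without a direction
layer report absolute deltas, flagged.

## Synthetic data

The fixture module supplies hand-curated V2000 structures with known
ring/stereocentre counts (verified against a graph-cycle oracle at test
time) and reaction templates covering the properties under test: a
one-to-two split, a ring-forming cycloaddition, a ring opening, an
enantiomeric reduction pair, a mirrored substitution pair that is
stereogenic on *both* sides (needed so that enantiomeric reactions
differ in both reaction-side key blocks), a two-step chain, an
equilibrium and an identity reaction.

`make_corpus` assembles RDfiles of arbitrary size: template reactions
plus a family of chain-alkanol dehydrations (distinct by chain length
and hydroxyl position) guarantee pairwise-distinct reactions; a recipe
fraction of entries are exact duplicates of earlier records
distinguished only by a free-text comment datum; a fraction carry
catalyst data fields, some as two-variation records.  Generation is
seed-deterministic (byte-identical output per recipe), and the manifest
records construction-time ground truth: expected unique counts,
duplicate groups and per-entry ring/stereo changes.

Default study sizes — a 500-reaction corpus with 10 % duplicates for
the pipeline check, 1 200 generated identifiers for the grammar check —
keep the whole suite in the seconds range while exercising every code
path at corpus scale.  What passing these tests shows is internal
consistency and format correctness at database scale; the corpora do
not emulate the chemical diversity, drawing noise or field-name
variability of real vendor databases, so agent-field routing on
real-world RDfiles may need the configurable field patterns.

## Known limitations

* V3000 CTAB blocks are rejected; the supported dialect is V2000.
* Reaction-condition layers, atom–atom mapping and stoichiometry are
  outside the format.
* Double-bond geometry cannot survive a zero-coordinate decode; only
  the depiction fallback preserves it.
* The byte-wise group sort keys on minor layers too, so minor-layer
  edits can reorder groups under the default mode (hence the opt-in
  `major_then_minor` sort).
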