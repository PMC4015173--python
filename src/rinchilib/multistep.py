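"""Combining an ordered sequence of single-step identifiers.

The overall identifier of a linear multistep sequence shows the initial
starting materials, the final products, and any species that passed
through unchanged.  Intermediates — species produced by one step and
consumed by a later one — cancel out of the reaction-side groups, and
because the combined identifier cannot distinguish reagents, solvents
and catalysts of the individual steps, every step's agents merge into
one agent group.

Species bookkeeping is by *set* of InChI bodies ("endpoint semantics"):
only each species' first and last appearance matter.

================================  =========================
first appearance / last appearance  classification
================================  =========================
consumed … consumed                overall reactant
produced … produced                overall product
produced … consumed                intermediate (cancelled)
consumed … produced                agent (present at both ends)
================================  =========================

The identifier retains no stoichiometry, so no attempt is made to
balance counts across steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import OrientationError
from .rinchi_core import RDirection, RInChI, from_groups
from .rxn_io import Direction


@dataclass(frozen=True)
class StepSequence:
    """An ordered chain of single-step identifiers.

    ``omitted_rule`` decides how steps without a direction layer are
    oriented: ``"as_written"`` (group1 are the reactants — the only
    information available) or ``"error"``.  Equilibrium steps carry no
    usable orientation at all and must be resolved explicitly through
    ``equilibrium_orientations`` (step index → ``"forward"`` to read
    group1 as reactants, ``"backward"`` for the reverse).
    """

    steps: tuple[RInChI, ...]
    omitted_rule: str = "as_written"
    equilibrium_orientations: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.steps) < 1:
            raise ValueError("a step sequence needs at least one step")
        if self.omitted_rule not in ("as_written", "error"):
            raise ValueError(f"unknown omitted_rule {self.omitted_rule!r}")


def _orient(seq: StepSequence, k: int) -> tuple[frozenset, frozenset, frozenset]:
    """Resolve step ``k`` into (reactants, products, agents) body sets."""
    step = seq.steps[k]
    if step.direction is RDirection.EQUILIBRIUM:
        how = seq.equilibrium_orientations.get(k)
        if how is None:
            raise OrientationError(
                f"step {k} is an equilibrium; supply an orientation override"
            )
        if how not in ("forward", "backward"):
            raise OrientationError(f"bad orientation override {how!r} for step {k}")
        forward = how == "forward"
    elif step.direction is RDirection.OMITTED:
        if seq.omitted_rule == "error":
            raise OrientationError(
                f"step {k} has no direction layer and omitted_rule='error'"
            )
        forward = True
    else:
        forward = step.direction is RDirection.PLUS
    g1, g2 = frozenset(step.group1), frozenset(step.group2)
    r, p = (g1, g2) if forward else (g2, g1)
    return r, p, frozenset(step.group3)


def combine(seq: StepSequence) -> RInChI:
    """Collapse a step sequence into the overall reaction identifier.

    A species consumed somewhere and never produced earlier is an
    overall reactant; one produced somewhere and never consumed later is
    an overall product; one produced then later consumed cancels; one
    present before its first consumption and after its last production
    (first consumed, last produced — e.g. a regenerated species) is
    filed with the agents.  All step agents merge into group3 of the
    result, which is rebuilt through the canonical constructor so the
    usual sorting and direction rules apply.
    """
    oriented = [_orient(seq, k) for k in range(len(seq.steps))]

    first: dict[str, str] = {}   # species -> role at first appearance
    last: dict[str, str] = {}    # species -> role at last appearance
    both_same_step: set[str] = set()
    agents_pool: set[str] = set()

    for r, p, a in oriented:
        agents_pool |= a
        both_same_step |= r & p
        for s in r - p:
            first.setdefault(s, "consumed")
            last[s] = "consumed"
        for s in p - r:
            first.setdefault(s, "produced")
            last[s] = "produced"

    reactants: set[str] = set()
    products: set[str] = set()
    agents: set[str] = set(agents_pool)

    for s in first:
        f, l = first[s], last[s]
        if f == "consumed" and l == "consumed":
            reactants.add(s)
        elif f == "produced" and l == "produced":
            products.add(s)
        elif f == "produced" and l == "consumed":
            pass  # cancelled intermediate
        else:  # consumed first, produced last: present at both ends
            agents.add(s)

    # a species on both sides of one step behaves as an agent of that step
    agents |= both_same_step - set(first)
    # terminal roles win over incidental agent appearances
    agents -= reactants | products

    return from_groups(reactants, products, agents, direction=Direction.FORWARD)


def combine_strings(rinchis: Sequence[str], **kwargs) -> RInChI:
    """Convenience wrapper: combine serialized identifiers (one per step)."""
    from .rinchi_core import parse

    return combine(StepSequence(steps=tuple(parse(s) for s in rinchis), **kwargs))
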