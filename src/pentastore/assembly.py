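"""Staged-ligation layout: adaptor attachment, grouping, fragment lengths.

Oligos are extended with an 8-nt adaptor for sequential ligation and
partitioned into groups of 27 (labelled A, B, C, ... in order).  Within a
group the first 15 units are ligated five at a time and then joined into
one subfragment; the remaining 12 units are ligated four at a time into a
second subfragment.  With 108-nt units the two subfragments measure
1,620 bp and 1,288 bp — the second under the convention that the final
unit of the 12-unit subfragment carries no trailing adaptor.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

from .packets import Oligo

__all__ = [
    "AssemblyGroup",
    "AssemblyPlan",
    "attach_adaptor",
    "strip_adaptor",
    "plan_groups",
    "expected_fragment_lengths",
]

GROUP_SIZE = 27
SUBFRAGMENT_SPLIT = 15  # units 1..15 form subfragment 1; 16..27 subfragment 2
ADAPTOR_LENGTH = 8


def attach_adaptor(oligo_letters: str, adaptor: str, oligo_length: int = 100) -> str:
    """Append an adaptor 3' of the oligo payload, yielding a 108-nt unit."""
    if len(oligo_letters) != oligo_length:
        raise ValueError(f"oligo must be {oligo_length} letters, got {len(oligo_letters)}")
    if len(adaptor) != ADAPTOR_LENGTH:
        raise ValueError(f"adaptor must be {ADAPTOR_LENGTH} letters, got {len(adaptor)}")
    return oligo_letters + adaptor


def strip_adaptor(unit: str, oligo_length: int = 100) -> str:
    """Inverse of :func:`attach_adaptor`."""
    if len(unit) != oligo_length + ADAPTOR_LENGTH:
        raise ValueError(f"unit must be {oligo_length + ADAPTOR_LENGTH} letters")
    return unit[:oligo_length]


def _group_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — the paper-style alphabetic labels."""
    labels = []
    for i in range(n):
        s, j = "", i
        while True:
            s = string.ascii_uppercase[j % 26] + s
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(s)
    return labels


@dataclass(frozen=True)
class AssemblyGroup:
    """One ligation group: ordered units with their adaptors."""

    label: str
    addresses: tuple[int, ...]  # member oligo addresses, ligation order
    adaptors: tuple[str, ...]  # adaptor per unit, pairwise distinct
    units: tuple[str, ...]  # oligo+adaptor sequences (terminal convention applied)

    @property
    def subfragment_1(self) -> tuple[str, ...]:
        return self.units[:SUBFRAGMENT_SPLIT]

    @property
    def subfragment_2(self) -> tuple[str, ...]:
        return self.units[SUBFRAGMENT_SPLIT:]


@dataclass(frozen=True)
class AssemblyPlan:
    groups: tuple[AssemblyGroup, ...]
    group_size: int = GROUP_SIZE
    omit_terminal_adaptor: bool = True

    def fragment_sequences(self) -> list[tuple[str, str]]:
        """Per group, the two expected assembled subfragment sequences."""
        return [
            ("".join(g.subfragment_1), "".join(g.subfragment_2)) for g in self.groups
        ]


def plan_groups(
    oligos: list[Oligo] | list[str],
    adaptor_pool: list[str],
    group_size: int = GROUP_SIZE,
    omit_terminal_adaptor: bool = True,
    oligo_length: int = 100,
) -> AssemblyPlan:
    """Partition oligos into consecutive-address ligation groups.

    ``adaptor_pool`` must hold at least ``group_size`` distinct adaptors;
    unit *i* of every group receives adaptor *i*, so adaptors within a
    group are pairwise distinct.  With the default terminal convention the
    last unit of each group's second subfragment carries no adaptor,
    reproducing the 1,620 + 1,288 bp fragment pair for 27-unit groups.

    Raises a ``ValueError`` for a non-divisible oligo count, suggesting
    the padding needed.
    """
    letters = [o.letters if isinstance(o, Oligo) else o for o in oligos]
    addresses = [
        o.address if isinstance(o, Oligo) else i for i, o in enumerate(oligos)
    ]
    n = len(letters)
    if n == 0:
        raise ValueError("no oligos to plan")
    if n % group_size:
        pad = group_size - n % group_size
        raise ValueError(
            f"{n} oligos is not divisible into groups of {group_size}; "
            f"pad with {pad} filler oligos or change group_size"
        )
    if len(set(adaptor_pool[:group_size])) < group_size:
        raise ValueError(
            f"adaptor pool must hold {group_size} distinct adaptors, "
            f"got {len(set(adaptor_pool[:group_size]))}"
        )
    order = sorted(range(n), key=lambda i: addresses[i])
    groups = []
    labels = _group_labels(n // group_size)
    for g in range(n // group_size):
        idx = order[g * group_size : (g + 1) * group_size]
        adaptors = tuple(adaptor_pool[:group_size])
        units = []
        for pos, i in enumerate(idx):
            terminal = omit_terminal_adaptor and pos == group_size - 1
            units.append(
                letters[i]
                if terminal
                else attach_adaptor(letters[i], adaptors[pos], oligo_length)
            )
        groups.append(
            AssemblyGroup(
                labels[g],
                tuple(addresses[i] for i in idx),
                adaptors,
                tuple(units),
            )
        )
    return AssemblyPlan(tuple(groups), group_size, omit_terminal_adaptor)


def expected_fragment_lengths(
    plan: AssemblyPlan,
) -> list[tuple[int, int]]:
    """Per-group (subfragment-1, subfragment-2) assembled lengths in bp.

    For the canonical 27-unit groups of 108-nt units with the terminal
    adaptor omitted: 15 x 108 = 1,620 bp and 12 x 108 - 8 = 1,288 bp.
    """
    return [
        (sum(len(u) for u in g.subfragment_1), sum(len(u) for u in g.subfragment_2))
        for g in plan.groups
    ]
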