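"""Presence/absence matrices, Dollo loss mapping, and completeness arithmetic.

Assembles per-(family, taxon) presence calls into a matrix, reconstructs a
single-gain / minimal-loss history for each family on the species tree
(Dollo parsimony: one origin at the MRCA of the present tips, one loss on
the branch to each maximal subtree below it with no present tip), summarises
protein complexes as full/partial/absent per taxon, and computes BUSCO-style
completeness percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

from .screen import PresenceCall
from .trees import SpeciesTree

STATES = ("present", "present_genome_only", "absent")
PRESENT_STATES = ("present", "present_genome_only")


@dataclass
class PresenceMatrix:
    """Complete family x taxon grid of presence states."""

    states: pd.DataFrame  # index = families, columns = taxa, values in STATES
    paralogs: Optional[pd.DataFrame] = None

    @property
    def families(self) -> List[str]:
        return list(self.states.index)

    @property
    def taxa(self) -> List[str]:
        return list(self.states.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean grid; genome-only detections count as present."""
        return self.states.isin(PRESENT_STATES)


@dataclass
class ComplexDefinition:
    complex_id: str
    members: List[str]
    color: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"complex {self.complex_id!r} has no members")


@dataclass
class LossEvent:
    family_id: str
    branch: str  # child-node id of the branch the event sits on
    event: str  # "loss" or "gain"


@dataclass
class DolloReconstruction:
    family_id: str
    origin: Optional[str]  # node id, or None when no tip is present
    losses: List[LossEvent] = field(default_factory=list)

    @property
    def no_origin(self) -> bool:
        return self.origin is None

    def events(self) -> List[LossEvent]:
        ev = []
        if self.origin is not None:
            ev.append(LossEvent(self.family_id, self.origin, "gain"))
        ev.extend(self.losses)
        return ev


def build_matrix(calls: Iterable[PresenceCall]) -> PresenceMatrix:
    """Assemble calls into a complete grid; duplicates or holes are errors."""
    seen = {}
    families: List[str] = []
    taxa: List[str] = []
    for call in calls:
        key = (call.family_id, call.taxon)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen[key] = call
        if call.family_id not in families:
            families.append(call.family_id)
        if call.taxon not in taxa:
            taxa.append(call.taxon)
    grid = {}
    counts = {}
    for fam in families:
        row, crow = [], []
        for tax in taxa:
            call = seen.get((fam, tax))
            if call is None:
                raise ValueError(f"missing call for ({fam!r}, {tax!r})")
            if call.state not in STATES:
                raise ValueError(f"unknown state {call.state!r}")
            row.append(call.state)
            crow.append(call.paralogs)
        grid[fam] = row
        counts[fam] = crow
    states = pd.DataFrame.from_dict(grid, orient="index", columns=taxa)
    paralogs = pd.DataFrame.from_dict(counts, orient="index", columns=taxa)
    return PresenceMatrix(states, paralogs)


def dollo_reconstruct(
    tree: SpeciesTree,
    column: Mapping[str, Union[str, bool]],
    family_id: str = "",
) -> DolloReconstruction:
    """Minimal-loss single-gain history for one family.

    ``column`` maps tip -> state (a string from the presence vocabulary or a
    bool).  The origin is the MRCA of the present tips; a loss is placed on
    the branch to every maximal subtree below the origin containing no
    present tip.  All-absent columns return a no-origin reconstruction.
    """
    present = set()
    for tip, state in column.items():
        if isinstance(state, str):
            if state in PRESENT_STATES:
                present.add(tip)
        elif state:
            present.add(tip)
    unknown = present - set(tree.tip_labels)
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    if not present:
        return DolloReconstruction(family_id, None)
    origin = tree.mrca(sorted(present))
    losses: List[LossEvent] = []

    def descend(node_id: str) -> None:
        for child in tree.children(node_id):
            below = set(tree.tips_below(child))
            if below & present:
                descend(child)
            else:
                losses.append(LossEvent(family_id, child, "loss"))

    descend(origin)
    return DolloReconstruction(family_id, origin, losses)


def complex_status(
    matrix: PresenceMatrix, complexes: Sequence[ComplexDefinition]
) -> pd.DataFrame:
    """Per-(taxon, complex) status: full / partial / absent."""
    known = set(matrix.families)
    for cx in complexes:
        missing = [m for m in cx.members if m not in known]
        if missing:
            raise ValueError(f"complex {cx.complex_id!r} members not in matrix: {missing}")
    presence = matrix.presence()
    out = {}
    for cx in complexes:
        sub = presence.loc[cx.members]
        n_present = sub.sum(axis=0)
        status = pd.Series("partial", index=matrix.taxa, dtype=object)
        status[n_present == len(cx.members)] = "full"
        status[n_present == 0] = "absent"
        out[cx.complex_id] = status
    return pd.DataFrame(out)


def busco_percentage(n_found: int, n_max: int) -> int:
    """Completeness percent, rounded to the nearest integer, half away from
    zero (so 217/245 -> 88.57 -> 89 and 207/245 -> 84.49 -> 84)."""
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    if not 0 <= n_found <= n_max:
        raise ValueError("n_found must be in [0, n_max]")
    return int(math.floor(100.0 * n_found / n_max + 0.5))


def branch_loss_summary(
    tree: SpeciesTree,
    events: Iterable[LossEvent],
    family_to_complex: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Loss counts per branch (rows, child-node id) per complex (columns).

    Families without a complex assignment are tallied under ``unassigned``.
    Column/row sums conserve the total number of loss events.
    """
    family_to_complex = dict(family_to_complex or {})
    branch_ids = [nid for nid in tree.node_ids() if nid != tree.root_id]
    groups: List[str] = []
    tallies: Dict[str, Dict[str, int]] = {b: {} for b in branch_ids}
    for ev in events:
        if ev.event != "loss":
            continue
        group = family_to_complex.get(ev.family_id, "unassigned")
        if group not in groups:
            groups.append(group)
        if ev.branch not in tallies:
            raise ValueError(f"loss on unknown branch {ev.branch!r}")
        tallies[ev.branch][group] = tallies[ev.branch].get(group, 0) + 1
    if not groups:
        groups = ["unassigned"]
    data = {g: [tallies[b].get(g, 0) for b in branch_ids] for g in groups}
    return pd.DataFrame(data, index=branch_ids)
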