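"""Phase 1: retrosynthetic expansion of a target into a reaction network.

Starting from the target compound, applicable retro-templates generate
candidate one-step disconnections; each candidate is scored by the
template's feasibility classifier and kept only if the score reaches the
rejection threshold (0.2 by default).  Kept reactions register their
reactants, and expansion continues on non-terminal ("open") reactants until
the generated-reaction budget is exhausted or the frontier empties.
Terminal compounds - purchasable building blocks or known products of the
fixed reaction database - are never expanded.

Which open compound (or reaction) is expanded next is the algorithm:

* ``breadth_first``       - FIFO; systematic, finds shortest routes first.
* ``depth_first``         - LIFO with a depth cutoff; finds deep routes early.
* ``best_first_compound`` - pop the open compound with minimum complexity
  score ``heavy_atoms * d**alpha`` (d = depth from the target, alpha = 1.1).
* ``best_first_reaction`` - pop the kept reaction with minimum score
  ``max(reactant heavy atoms) * d**alpha`` and one-step expand all of its
  open reactants.

The depth factor ``d**alpha`` discounts deep reactants so that, at similar
complexity, compounds closer to the target are preferred, biasing toward
shorter routes.
"""
from __future__ import annotations

import heapq
import itertools
import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .chemdb import BuildingBlockDB, FixedReactionDB
from .core import canonicalize, heavy_atoms
from .feasibility import ClassifierStore
from .routesearch import ReactionEdge
from .templates import TemplateLibrary, apply_retro

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "breadth_first",
    "depth_first",
    "best_first_compound",
    "best_first_reaction",
)

PURCHASABLE = "purchasable"
KNOWN_SYNTHESIZABLE = "known_synthesizable"
OPEN = "open"


@dataclass(frozen=True)
class ExpansionConfig:
    algorithm: str = "best_first_reaction"
    alpha: float = 1.1
    max_generated: int = 1000
    max_depth: int = 10
    score_threshold: float = 0.2
    seed: int = 0
    early_stop: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 <= self.score_threshold <= 1):
            raise ValueError("score_threshold must be in [0, 1]")
        if self.max_generated < 0 or self.max_depth < 1:
            raise ValueError("invalid budget or depth")


def terminal_status(
    compound: str,
    building_blocks: Optional[BuildingBlockDB],
    fixed_db: Optional[FixedReactionDB],
) -> str:
    """purchasable > known_synthesizable > open."""
    if building_blocks is not None and compound in building_blocks:
        return PURCHASABLE
    if fixed_db is not None and fixed_db.is_product(compound):
        return KNOWN_SYNTHESIZABLE
    return OPEN


def compound_priority(compound: str, depth: int, alpha: float = 1.1) -> float:
    """Complexity score heavy_atoms * depth**alpha; lower is expanded first."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return heavy_atoms(compound) * depth ** alpha


def reaction_priority(
    reactants: Sequence[str], depth: int, alpha: float = 1.1
) -> float:
    """max over reactants of heavy atoms, times depth**alpha; lower first."""
    if not reactants:
        raise ValueError("reaction must have at least one reactant")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return max(heavy_atoms(r) for r in reactants) * depth ** alpha


@dataclass
class _CompoundNode:
    depth: int  # minimum observed depth (target = 0)
    status: str
    ancestors: FrozenSet[str]  # product chain at first discovery
    expanded: bool = False


class ExpansionNetwork:
    """Result of phase 1: generated reactions plus compound bookkeeping."""

    def __init__(self, target: str) -> None:
        self.target = target
        self.nodes: Dict[str, _CompoundNode] = {}
        self.reactions: List[ReactionEdge] = []
        self.reaction_depth: Dict[str, int] = {}
        self.generated_count = 0
        self.rejected_count = 0
        self._solvable: Set[str] = set()
        self._consumers: Dict[str, List[int]] = {}
        self._edge_keys: Set[Tuple[Tuple[str, ...], str, str]] = set()

    @property
    def compounds(self) -> List[str]:
        return list(self.nodes)

    def status(self, compound: str) -> str:
        return self.nodes[compound].status

    def depth(self, compound: str) -> int:
        return self.nodes[compound].depth

    @property
    def solved(self) -> bool:
        return self.target in self._solvable or (
            self.target in self.nodes
            and self.nodes[self.target].status != OPEN
        )

    def _mark_solvable(self, compound: str) -> None:
        stack = [compound]
        while stack:
            c = stack.pop()
            if c in self._solvable:
                continue
            self._solvable.add(c)
            for idx in self._consumers.get(c, []):
                edge = self.reactions[idx]
                if all(self._is_solvable(r) for r in edge.reactants):
                    if edge.product not in self._solvable:
                        stack.append(edge.product)

    def _is_solvable(self, compound: str) -> bool:
        node = self.nodes.get(compound)
        return compound in self._solvable or (
            node is not None and node.status != OPEN
        )


def expand(
    target: str,
    library: TemplateLibrary,
    classifiers: Optional[ClassifierStore],
    building_blocks: Optional[BuildingBlockDB],
    fixed_db: Optional[FixedReactionDB],
    cfg: ExpansionConfig = ExpansionConfig(),
) -> ExpansionNetwork:
    """Grow the generated-reaction network from ``target``.

    Stops when the budget ``cfg.max_generated`` kept reactions is reached,
    the frontier empties, or (with ``cfg.early_stop``) a first route to
    terminal compounds exists.  Deterministic for identical inputs.
    """
    target = canonicalize(target)
    if "." in target:
        raise ValueError(f"target must be a single molecule: {target!r}")
    scores = classifiers if classifiers is not None else ClassifierStore()

    net = ExpansionNetwork(target)
    net.nodes[target] = _CompoundNode(
        depth=0,
        status=terminal_status(target, building_blocks, fixed_db),
        ancestors=frozenset(),
    )
    if net.nodes[target].status == PURCHASABLE:
        return net  # nothing to do: the target is a building block

    seq = itertools.count()
    # frontiers
    fifo: deque = deque()
    lifo: List[str] = []
    compound_heap: List[Tuple[float, int, str]] = []
    reaction_heap: List[Tuple[float, int, int]] = []  # (priority, seq, rxn index)

    retro_cache: Dict[str, List[Tuple[str, str, Tuple[str, ...]]]] = {}

    def disconnections(compound: str):
        """Cached template applications: (template_id, name, reactant set)."""
        cached = retro_cache.get(compound)
        if cached is None:
            cached = []
            for t in library.applicable(compound):
                for rset in apply_retro(t, compound):
                    cached.append((t.template_id, t.reaction_name, rset))
            retro_cache[compound] = cached
        return cached

    def register_compound(compound: str, depth: int, ancestors: FrozenSet[str]) -> _CompoundNode:
        node = net.nodes.get(compound)
        if node is None:
            node = _CompoundNode(
                depth=depth,
                status=terminal_status(compound, building_blocks, fixed_db),
                ancestors=ancestors,
            )
            net.nodes[compound] = node
            if node.status != OPEN:
                net._mark_solvable(compound)
        elif depth < node.depth:
            node.depth = depth
        return node

    def push_compound(compound: str) -> None:
        node = net.nodes[compound]
        if cfg.algorithm == "breadth_first":
            fifo.append(compound)
        elif cfg.algorithm == "depth_first":
            lifo.append(compound)
        elif cfg.algorithm == "best_first_compound":
            prio = compound_priority(compound, max(node.depth, 1), cfg.alpha)
            heapq.heappush(compound_heap, (prio, next(seq), compound))

    budget_exhausted = False

    def expand_one(compound: str) -> List[int]:
        """One-step expansion; returns indices of newly kept reactions."""
        nonlocal budget_exhausted
        node = net.nodes[compound]
        if node.expanded or node.status != OPEN:
            return []
        node.expanded = True
        if node.depth >= cfg.max_depth:
            return []
        new_indices: List[int] = []
        rxn_depth = node.depth + 1
        for template_id, name, rset in disconnections(compound):
            if net.generated_count >= cfg.max_generated:
                budget_exhausted = True
                break
            if compound in rset or any(r in node.ancestors for r in rset):
                continue  # would repeat a compound on the expansion path
            key = (tuple(sorted(rset)), compound, template_id)
            if key in net._edge_keys:
                continue
            score = scores.score(template_id, rset, compound)
            if score < cfg.score_threshold:
                net.rejected_count += 1
                continue
            net._edge_keys.add(key)
            idx = len(net.reactions)
            edge = ReactionEdge(
                rid=f"G{idx}",
                reactants=rset,
                product=compound,
                origin="generated",
                score=score,
                template_id=template_id,
                name=name,
            )
            net.reactions.append(edge)
            net.reaction_depth[edge.rid] = rxn_depth
            net.generated_count += 1
            child_ancestors = node.ancestors | {compound}
            for r in rset:
                net._consumers.setdefault(r, []).append(idx)
                register_compound(r, rxn_depth, child_ancestors)
            if all(net._is_solvable(r) for r in rset):
                net._mark_solvable(compound)
            new_indices.append(idx)
        return new_indices

    def enqueue_new(indices: List[int]) -> None:
        for idx in indices:
            edge = net.reactions[idx]
            if cfg.algorithm == "best_first_reaction":
                prio = reaction_priority(
                    edge.reactants, net.reaction_depth[edge.rid], cfg.alpha
                )
                heapq.heappush(reaction_heap, (prio, next(seq), idx))
            else:
                for r in edge.reactants:
                    if net.nodes[r].status == OPEN and not net.nodes[r].expanded:
                        push_compound(r)

    # seed with the target
    if cfg.algorithm == "best_first_reaction":
        enqueue_new(expand_one(target))
    else:
        push_compound(target)

    while not budget_exhausted:
        if cfg.early_stop and net.solved:
            break
        if cfg.algorithm == "best_first_reaction":
            if not reaction_heap:
                break
            _, _, idx = heapq.heappop(reaction_heap)
            edge = net.reactions[idx]
            for r in edge.reactants:
                if net.nodes[r].status == OPEN and not net.nodes[r].expanded:
                    enqueue_new(expand_one(r))
        else:
            if cfg.algorithm == "breadth_first":
                if not fifo:
                    break
                compound = fifo.popleft()
            elif cfg.algorithm == "depth_first":
                if not lifo:
                    break
                compound = lifo.pop()
            else:
                if not compound_heap:
                    break
                _, _, compound = heapq.heappop(compound_heap)
            node = net.nodes[compound]
            if node.expanded or node.status != OPEN:
                continue
            enqueue_new(expand_one(compound))

    logger.info(
        "expand[%s]: %d generated, %d rejected, %d compounds, solved=%s",
        cfg.algorithm, net.generated_count, net.rejected_count,
        len(net.nodes), net.solved,
    )
    return net
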