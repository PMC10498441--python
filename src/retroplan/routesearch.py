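"""Optimal-route extraction over an AND-OR synthesis network.

The synthesis network is an AND-OR hypergraph: compounds are OR nodes (any
producing reaction suffices) and reactions are AND hyperarcs (all reactants
required).  Phase 2 (`build_subnetwork`) restricts to everything reachable
retrosynthetically from the target within a depth bound, merging
template-generated reactions with fixed-database reactions.  Phase 3
(`k_best_routes`) runs a vectorized Dijkstra in which every compound node may
hold up to k (cost, route) values instead of one; the k lowest-cost
diversified routes to the target are returned.

Cost model: a purchasable leaf costs its catalog price; a reaction's product
costs (sum of reactant costs) / effective yield + overhead.  Fixed reactions
use their reported yield or a 50% default; generated reactions use their
feasibility score capped at 70%, which deliberately favors reported
chemistry over generated steps.  Routes whose leaves include a compound with
no known supplier are "partial" and carry a large per-leaf penalty.

This module is chemistry-agnostic: compounds are opaque string keys
(canonical SMILES in the full pipeline, synthetic ids in graph fixtures).
"""
from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .chemdb import BuildingBlockDB, FixedReactionDB

__all__ = [
    "CostModel",
    "ReactionEdge",
    "Subnetwork",
    "Route",
    "Strategy",
    "SearchParams",
    "build_subnetwork",
    "effective_yield",
    "reaction_cost",
    "k_best_routes",
    "constrained_search",
    "group_strategies",
    "brute_force_k_best",
    "routes_document",
]


@dataclass(frozen=True)
class CostModel:
    """Parameters of the route cost recursion."""

    default_fixed_yield: float = 0.50
    generated_yield_cap: float = 0.70
    partial_leaf_penalty: float = 10_000.0
    per_reaction_overhead: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.default_fixed_yield <= 1):
            raise ValueError("default_fixed_yield must be in (0, 1]")
        if not (0 < self.generated_yield_cap <= 1):
            raise ValueError("generated_yield_cap must be in (0, 1]")
        if self.partial_leaf_penalty <= 0 or self.per_reaction_overhead < 0:
            raise ValueError("invalid cost model")


@dataclass(frozen=True)
class ReactionEdge:
    """A reaction hyperarc: 1-2 reactants -> 1 product.

    ``origin`` is "fixed" (database record, optional reported yield) or
    "generated" (template application, feasibility score in [0, 1]).
    """

    rid: str
    reactants: Tuple[str, ...]
    product: str
    origin: str  # "fixed" | "generated"
    yield_: Optional[float] = None
    score: Optional[float] = None
    template_id: Optional[str] = None
    name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ("fixed", "generated"):
            raise ValueError(f"bad origin {self.origin!r}")
        if not (1 <= len(self.reactants) <= 2):
            raise ValueError("reaction must have 1 or 2 reactants")
        if self.product in self.reactants:
            raise ValueError("reaction product among its reactants")


class Subnetwork:
    """Compounds + reaction hyperarcs with purchasability annotations."""

    def __init__(self) -> None:
        self.compounds: Dict[str, dict] = {}
        self.reactions: Dict[str, ReactionEdge] = {}
        self._producing: Dict[str, List[str]] = {}
        self._consuming: Dict[str, List[str]] = {}

    def add_compound(self, key: str, purchasable: bool = False,
                     price: Optional[float] = None) -> None:
        if key not in self.compounds:
            self.compounds[key] = {"purchasable": purchasable, "price": price}
        elif purchasable:
            self.compounds[key] = {"purchasable": True, "price": price}

    def add_reaction(self, edge: ReactionEdge) -> None:
        if edge.rid in self.reactions:
            return
        self.add_compound(edge.product)
        for r in edge.reactants:
            self.add_compound(r)
        self.reactions[edge.rid] = edge
        self._producing.setdefault(edge.product, []).append(edge.rid)
        for r in set(edge.reactants):
            self._consuming.setdefault(r, []).append(edge.rid)

    def producing(self, key: str) -> List[str]:
        return self._producing.get(key, [])

    def consuming(self, key: str) -> List[str]:
        return self._consuming.get(key, [])

    def is_purchasable(self, key: str) -> bool:
        info = self.compounds.get(key)
        return bool(info and info["purchasable"])

    def price(self, key: str) -> Optional[float]:
        info = self.compounds.get(key)
        return info["price"] if info else None

    def is_open(self, key: str) -> bool:
        """Non-purchasable with no producing reaction (an open leaf)."""
        return not self.is_purchasable(key) and not self.producing(key)

    def pruned(self, avoid: Set[str]) -> "Subnetwork":
        """Copy with avoided compounds and reactions removed."""
        sub = Subnetwork()
        for key, info in self.compounds.items():
            if key not in avoid:
                sub.add_compound(key, info["purchasable"], info["price"])
        for rid, edge in self.reactions.items():
            if rid in avoid or edge.product in avoid or any(
                r in avoid for r in edge.reactants
            ):
                continue
            sub.add_reaction(edge)
        return sub


@dataclass(frozen=True)
class SearchParams:
    k: int = 5
    max_depth: int = 10
    keep: FrozenSet[str] = frozenset()
    avoid: FrozenSet[str] = frozenset()
    allow_partial: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.keep & self.avoid:
            raise ValueError(
                f"keep and avoid overlap: {sorted(self.keep & self.avoid)}"
            )


@dataclass(frozen=True)
class Route:
    """A synthesis tree rooted at the target.

    ``tree`` maps every non-leaf compound of the route to the id of the
    single reaction producing it; ``leaves`` is the multiset of terminal
    compounds (purchased building blocks, plus open leaves when partial).
    """

    root: str
    tree: Dict[str, str]
    leaves: Tuple[str, ...]
    cost: float
    n_reactions: int
    is_partial: bool

    @property
    def reaction_set(self) -> FrozenSet[str]:
        return frozenset(self.tree.values())

    @property
    def final_reaction(self) -> str:
        return self.tree[self.root]

    def compounds(self) -> Set[str]:
        return set(self.tree) | set(self.leaves)

    def items(self) -> Set[str]:
        """All identifiers in the route (compounds and reaction ids)."""
        return self.compounds() | set(self.tree.values())

    def ordered_reactions(self, net: Subnetwork) -> List[ReactionEdge]:
        """Reactions in dependency order (precursor steps first)."""
        order: List[str] = []
        seen: Set[str] = set()

        def visit(compound: str) -> None:
            rid = self.tree.get(compound)
            if rid is None or rid in seen:
                return
            seen.add(rid)
            for r in net.reactions[rid].reactants:
                visit(r)
            order.append(rid)

        visit(self.root)
        return [net.reactions[rid] for rid in order]


@dataclass(frozen=True)
class Strategy:
    """All routes sharing the reaction that directly produces the target."""

    final_reaction: str
    routes: Tuple[Route, ...]

    @property
    def best_cost(self) -> float:
        return self.routes[0].cost


# ---------------------------------------------------------------------------
# phase 2: reachable subnetwork
# ---------------------------------------------------------------------------

def build_subnetwork(
    target: str,
    generated: Iterable[ReactionEdge],
    fixed_db: Optional[FixedReactionDB],
    building_blocks: Optional[BuildingBlockDB],
    max_depth: int = 10,
) -> Subnetwork:
    """Everything retrosynthetically reachable from ``target`` within ``max_depth``.

    Starts from the target, repeatedly adds reactions (generated or fixed)
    producing any included compound, and recurses into their reactants.
    Generated reactions thus stitch onto fixed-database chemistry wherever a
    generated leaf is a known product of the database.  Purchasability and
    prices are annotated from the building-block database.
    """
    gen_by_product: Dict[str, List[ReactionEdge]] = {}
    for e in generated:
        gen_by_product.setdefault(e.product, []).append(e)
    # a target with no producers yields a one-node subnetwork (no routes)
    sub = Subnetwork()
    n_fixed = 0

    def annotate(key: str) -> None:
        if building_blocks is not None and key in building_blocks:
            sub.add_compound(key, True, building_blocks.price(key))
        else:
            sub.add_compound(key)

    annotate(target)
    frontier = [(target, 0)]
    best_depth = {target: 0}
    while frontier:
        compound, depth = frontier.pop(0)
        if depth >= max_depth:
            continue
        edges = list(gen_by_product.get(compound, []))
        if fixed_db is not None:
            for fr in fixed_db.producing(compound):
                nonlocal_id = f"F{n_fixed}"
                n_fixed += 1
                edges.append(
                    ReactionEdge(
                        rid=nonlocal_id,
                        reactants=fr.reactants,
                        product=fr.product,
                        origin="fixed",
                        yield_=fr.yield_,
                        name=fr.name,
                        source=fr.source,
                    )
                )
        for edge in edges:
            already = edge.rid in sub.reactions or any(
                e.rid != edge.rid
                and e.product == edge.product
                and tuple(sorted(e.reactants)) == tuple(sorted(edge.reactants))
                and e.origin == edge.origin
                for e in (sub.reactions[r] for r in sub.producing(compound))
            )
            if already:
                continue
            sub.add_reaction(edge)
            for r in edge.reactants:
                annotate(r)
                if r not in best_depth or depth + 1 < best_depth[r]:
                    best_depth[r] = depth + 1
                    frontier.append((r, depth + 1))
    return sub


# ---------------------------------------------------------------------------
# cost rules
# ---------------------------------------------------------------------------

def effective_yield(edge: ReactionEdge, cost_model: CostModel) -> float:
    """Yield used in the cost recursion.

    Fixed reactions: reported yield if known, else the 50% default (which
    favors reactions with published yields).  Generated reactions: the
    feasibility score capped at 70%, favoring reported chemistry.
    """
    if edge.origin == "fixed":
        if edge.yield_ is None:
            return cost_model.default_fixed_yield
        if not (0 < edge.yield_ <= 1):
            raise ValueError(f"reaction {edge.rid}: yield {edge.yield_} outside (0, 1]")
        return edge.yield_
    if edge.score is None or not (0 <= edge.score <= 1):
        raise ValueError(f"generated reaction {edge.rid} lacks a valid score")
    return min(edge.score, cost_model.generated_yield_cap)


def reaction_cost(
    reactant_costs: Sequence[float], yield_: float, cost_model: CostModel
) -> float:
    """(sum of reactant costs) / yield + per-reaction overhead."""
    if yield_ <= 0:
        raise ValueError("yield must be positive")
    if any(c <= 0 for c in reactant_costs):
        raise ValueError("reactant costs must be positive")
    return sum(reactant_costs) / yield_ + cost_model.per_reaction_overhead


# ---------------------------------------------------------------------------
# phase 3: vectorized Dijkstra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Entry:
    """One (cost, route) value stored at a compound node."""

    cost: float
    tree: Tuple[Tuple[str, str], ...]  # sorted (compound, rid) pairs
    bought: Tuple[str, ...]  # multiset of purchased leaves
    open_leaves: Tuple[str, ...]  # multiset of penalized open leaves
    rxn_set: FrozenSet[str]
    compounds: FrozenSet[str]  # every compound in the subtree incl. its root
    partial: bool


def _merge_entries(
    product: str,
    rid: str,
    parts: Sequence[_Entry],
    cost: float,
) -> Optional[_Entry]:
    """Combine one entry per reactant into an entry for ``product``.

    Returns None when the combination is not a valid synthesis tree:
    the product already occurs in a subtree (path repetition), a compound is
    produced by two different reactions in different branches, or a compound
    is purchased in one branch and synthesized in another.
    """
    tree: Dict[str, str] = {}
    made: Set[str] = set()
    bought: List[str] = []
    open_leaves: List[str] = []
    for e in parts:
        if product in e.compounds:
            return None
        for c, r in e.tree:
            prev = tree.get(c)
            if prev is not None and prev != r:
                return None
            tree[c] = r
        bought.extend(e.bought)
        open_leaves.extend(e.open_leaves)
    made = set(tree)
    if made & set(bought) or made & set(open_leaves):
        return None
    tree[product] = rid
    rxn_set = frozenset(tree.values())
    compounds = frozenset(
        itertools.chain([product], *(e.compounds for e in parts))
    )
    return _Entry(
        cost=cost,
        tree=tuple(sorted(tree.items())),
        bought=tuple(sorted(bought)),
        open_leaves=tuple(sorted(open_leaves)),
        rxn_set=rxn_set,
        compounds=compounds,
        partial=any(e.partial for e in parts),
    )


def _entry_to_route(root: str, entry: _Entry) -> Route:
    return Route(
        root=root,
        tree=dict(entry.tree),
        leaves=tuple(sorted(entry.bought + entry.open_leaves)),
        cost=entry.cost,
        n_reactions=len(entry.rxn_set),
        is_partial=entry.partial,
    )


def k_best_routes(
    net: Subnetwork,
    target: str,
    params: SearchParams,
    cost_model: CostModel = CostModel(),
    node_capacity: Optional[int] = None,
) -> List[Route]:
    """The k lowest-cost diversified routes from building blocks to ``target``.

    Every compound node accumulates (cost, route) entries; the target
    accumulates route entries until k of them (satisfying any keep
    constraint) are found.  Candidates enter a min-heap; because yields are
    <= 1 and costs positive, a candidate's cost is >= each constituent
    entry's cost, so admissions occur in non-decreasing cost order even when
    the hypergraph is cyclic.  Two routes are considered distinct iff their
    reaction sets differ; duplicates arriving via different heap paths are
    merged.  Ties are broken by insertion sequence (deterministic).

    With the default unbounded ``node_capacity`` the search is lazily
    exhaustive and returns exactly the k best valid routes (it agrees with
    brute-force enumeration).  A finite capacity (e.g. k) bounds memory on
    large dense networks but can, rarely, miss a route whose subroute at
    some node is displaced beyond the cap by entries that later fail the
    tree-consistency check at a 2-reactant combination.
    """
    if target not in net.compounds:
        return []
    keep = params.keep
    k = params.k
    heap: List[Tuple[float, int, str, _Entry]] = []
    seq = itertools.count()

    def push(node: str, entry: _Entry) -> None:
        heapq.heappush(heap, (entry.cost, next(seq), node, entry))

    # seed: buy-candidates for purchasables, penalty-candidates for open leaves
    for key, info in net.compounds.items():
        if info["purchasable"]:
            push(key, _Entry(
                cost=float(info["price"]),
                tree=(), bought=(key,), open_leaves=(),
                rxn_set=frozenset(), compounds=frozenset([key]), partial=False,
            ))
        elif params.allow_partial and net.is_open(key):
            push(key, _Entry(
                cost=cost_model.partial_leaf_penalty,
                tree=(), bought=(), open_leaves=(key,),
                rxn_set=frozenset(), compounds=frozenset([key]), partial=True,
            ))

    store: Dict[str, List[_Entry]] = {c: [] for c in net.compounds}
    results: List[Route] = []
    n_satisfying = 0

    def admit(node: str, entry: _Entry) -> bool:
        entries = store[node]
        if (node != target and node_capacity is not None
                and len(entries) >= node_capacity):
            return False
        if any(e.rxn_set == entry.rxn_set for e in entries):
            return False
        entries.append(entry)
        return True

    while heap and n_satisfying < k:
        _, _, node, entry = heapq.heappop(heap)
        if not admit(node, entry):
            continue
        if node == target and entry.rxn_set:
            route = _entry_to_route(target, entry)
            if not keep or keep <= route.items():
                results.append(route)
                n_satisfying += 1
                if n_satisfying >= k:
                    break
        # propagate: combine the new entry into every consuming reaction
        for rid in net.consuming(node):
            edge = net.reactions[rid]
            y = effective_yield(edge, cost_model)
            slots: List[List[_Entry]] = []
            if len(edge.reactants) == 2 and edge.reactants[0] == edge.reactants[1]:
                combos: Iterable[Tuple[_Entry, ...]] = [(entry, entry)]
            else:
                for r in edge.reactants:
                    slots.append([entry] if r == node else store[r])
                combos = itertools.product(*slots)
            for parts in combos:
                if not all(parts):
                    continue
                cost = reaction_cost([p.cost for p in parts], y, cost_model)
                merged = _merge_entries(edge.product, rid, parts, cost)
                if merged is not None:
                    push(edge.product, merged)
    return results


def constrained_search(
    net: Subnetwork,
    target: str,
    params: SearchParams,
    cost_model: CostModel = CostModel(),
) -> List[Route]:
    """k-best search honoring keep/avoid constraints.

    Avoided compounds/reactions are pruned from the subnetwork before the
    search; returned routes each contain every keep item.
    """
    if params.avoid:
        if target in params.avoid:
            raise ValueError("cannot avoid the target compound")
        net = net.pruned(set(params.avoid))
    return k_best_routes(net, target, params, cost_model)


def group_strategies(routes: Sequence[Route]) -> List[Strategy]:
    """Partition routes by their target-producing reaction.

    Strategies are ordered by their best member's cost; members are kept in
    cost order.
    """
    groups: Dict[str, List[Route]] = {}
    for r in routes:
        groups.setdefault(r.final_reaction, []).append(r)
    strategies = [
        Strategy(final_reaction=fr, routes=tuple(sorted(rs, key=lambda r: r.cost)))
        for fr, rs in groups.items()
    ]
    strategies.sort(key=lambda s: s.best_cost)
    return strategies


# ---------------------------------------------------------------------------
# exhaustive oracle (test use only)
# ---------------------------------------------------------------------------

def brute_force_k_best(
    net: Subnetwork,
    target: str,
    k: int,
    cost_model: CostModel = CostModel(),
    allow_partial: bool = False,
    max_compounds: int = 15,
    max_reactions: int = 22,
) -> List[Route]:
    """Exhaustively enumerate all valid synthesis trees, cost, sort, truncate.

    Independent of the Dijkstra path: plain recursive enumeration with an
    ancestor set guaranteeing repetition-free root-to-leaf paths.  Guarded to
    small networks; the heap search should be used for anything real.
    """
    if len(net.compounds) > max_compounds or len(net.reactions) > max_reactions:
        raise ValueError("network too large for the brute-force oracle")
    if target not in net.compounds:
        return []

    def enumerate_options(compound: str, ancestors: FrozenSet[str]):
        options = []
        info = net.compounds[compound]
        if info["purchasable"]:
            options.append(
                ({}, {compound: 1}, {}, float(info["price"]), False)
            )
        elif allow_partial and net.is_open(compound):
            options.append(
                ({}, {}, {compound: 1}, cost_model.partial_leaf_penalty, True)
            )
        blocked = ancestors | {compound}
        for rid in net.producing(compound):
            edge = net.reactions[rid]
            if any(r in blocked for r in edge.reactants):
                continue
            y = effective_yield(edge, cost_model)
            if len(edge.reactants) == 2 and edge.reactants[0] == edge.reactants[1]:
                sub = enumerate_options(edge.reactants[0], blocked)
                combos = [(o, o) for o in sub]
            else:
                subs = [enumerate_options(r, blocked) for r in edge.reactants]
                combos = itertools.product(*subs)
            for parts in combos:
                tree: Dict[str, str] = {}
                bought: Dict[str, int] = {}
                open_leaves: Dict[str, int] = {}
                ok = True
                for ptree, pbought, popen, _, _ in parts:
                    for c, r in ptree.items():
                        if tree.get(c, r) != r:
                            ok = False
                            break
                        tree[c] = r
                    if not ok:
                        break
                    for c, n in pbought.items():
                        bought[c] = bought.get(c, 0) + n
                    for c, n in popen.items():
                        open_leaves[c] = open_leaves.get(c, 0) + n
                if not ok:
                    continue
                if set(tree) & (set(bought) | set(open_leaves)):
                    continue
                tree[compound] = rid
                cost = reaction_cost([p[3] for p in parts], y, cost_model)
                partial = any(p[4] for p in parts)
                options.append((tree, bought, open_leaves, cost, partial))
        return options

    routes: List[Route] = []
    seen: Set[FrozenSet[str]] = set()
    for tree, bought, open_leaves, cost, partial in enumerate_options(
        target, frozenset()
    ):
        if not tree:
            continue  # buying the target is not a synthesis route
        key = frozenset(tree.values())
        if key in seen:
            continue
        seen.add(key)
        leaves = tuple(sorted(
            itertools.chain(
                *([c] * n for c, n in bought.items()),
                *([c] * n for c, n in open_leaves.items()),
            )
        ))
        routes.append(Route(
            root=target, tree=tree, leaves=leaves, cost=cost,
            n_reactions=len(set(tree.values())), is_partial=partial,
        ))
    routes.sort(key=lambda r: r.cost)
    return routes[:k]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def routes_document(
    target: str,
    params: SearchParams,
    strategies: Sequence[Strategy],
    net: Subnetwork,
    cost_model: CostModel = CostModel(),
) -> dict:
    """JSON-able document for a route-search result."""
    def edge_record(edge: ReactionEdge) -> dict:
        rec = {
            "id": edge.rid,
            "reactants": list(edge.reactants),
            "product": edge.product,
            "origin": edge.origin,
            "effective_yield": effective_yield(edge, cost_model),
        }
        if edge.origin == "generated":
            rec["template"] = edge.name or edge.template_id
            rec["feasibility_score"] = edge.score
        else:
            rec["source"] = edge.source
            if edge.name:
                rec["name"] = edge.name
        return rec

    def route_record(route: Route, rank: int) -> dict:
        leaves = []
        for leaf in route.leaves:
            info = net.compounds.get(leaf, {})
            leaves.append({
                "smiles": leaf,
                "purchasable": bool(info.get("purchasable")),
                "price": info.get("price"),
            })
        return {
            "rank": rank,
            "cost": route.cost,
            "n_reactions": route.n_reactions,
            "is_partial": route.is_partial,
            "reactions": [edge_record(e) for e in route.ordered_reactions(net)],
            "leaves": leaves,
        }

    rank = itertools.count(1)
    return {
        "target": target,
        "params": {
            "k": params.k,
            "max_depth": params.max_depth,
            "keep": sorted(params.keep),
            "avoid": sorted(params.avoid),
            "allow_partial": params.allow_partial,
        },
        "strategies": [
            {
                "final_reaction": s.final_reaction,
                "best_cost": s.best_cost,
                "routes": [route_record(r, next(rank)) for r in s.routes],
            }
            for s in strategies
        ],
    }
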