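"""Seeded generators for every input the planner needs.

Everything here is a pure function of its parameters and seed: synthetic
AND-OR networks with at least one complete route (for exercising the route
search against the brute-force oracle), synthetic labeled training corpora
(standing in for a literature reaction database), small chemistry fixtures
for the expansion algorithms, and the hand-computed worked examples used
throughout the tests.

Emitted files use the exact chemdb formats, so fixtures double as format
tests.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from itertools import product as iproduct
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem

from .chemdb import BuildingBlock, BuildingBlockDB, FixedReaction, FixedReactionDB
from .core import canonicalize
from .feasibility import LabeledExample, label_examples
from .routesearch import ReactionEdge, Subnetwork
from .templates import RetroTemplate, apply_forward


class GenerationError(ValueError):
    """Raised when a fixture spec cannot be satisfied."""


# ---------------------------------------------------------------------------
# fragment pool
# ---------------------------------------------------------------------------

def fragment_pool() -> List[str]:
    """The shipped pool of ~100 small building-block-grade molecules."""
    text = (resources.files("retroplan.data") / "fragments.smi").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(canonicalize(line))
    return out


def make_building_blocks(prices: Dict[str, float], vendor: str = "fixture") -> BuildingBlockDB:
    """A building-block database from a {smiles: price} mapping."""
    db = BuildingBlockDB()
    for i, (smi, price) in enumerate(prices.items()):
        db.add(BuildingBlock(canonicalize(smi), f"BB-{i}", price, vendor, 1))
    return db


# ---------------------------------------------------------------------------
# synthetic AND-OR networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkSpec:
    n_compounds: int = 12
    n_reactions: int = 18
    fraction_two_reactant: float = 0.5
    yield_range: Tuple[float, float] = (0.3, 1.0)
    price_range: Tuple[float, float] = (1.0, 100.0)
    fraction_generated: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 3 or self.n_reactions < 1:
            raise GenerationError("need at least 3 compounds and 1 reaction")
        lo, hi = self.yield_range
        if not (0 < lo <= hi <= 1):
            raise GenerationError("yield_range must lie in (0, 1]")
        if self.price_range[0] <= 0:
            raise GenerationError("prices must be positive")


def make_synthetic_network(spec: NetworkSpec) -> Tuple[Subnetwork, str, Dict[str, float]]:
    """A random layered reaction hypergraph with >= 1 complete route.

    Purchasable leaves sit in layer 0; every non-leaf compound receives one
    backbone reaction whose reactants come from strictly lower layers, which
    guarantees by induction that the designated target (top layer) admits a
    complete route.  Extra reactions are added at random.  Reaction origins
    mix "fixed" (explicit yield) and "generated" (feasibility score), so the
    cost rules for both kinds are exercised.
    """
    rng = random.Random(spec.seed)
    n_leaves = max(2, spec.n_compounds // 3)
    n_nonleaf = spec.n_compounds - n_leaves
    if n_nonleaf < 1:
        raise GenerationError("spec leaves no room for a target compound")
    if spec.n_reactions < n_nonleaf:
        raise GenerationError(
            f"{spec.n_reactions} reactions cannot produce {n_nonleaf} compounds"
        )

    leaves = [f"B{i}" for i in range(n_leaves)]
    inner = [f"C{i}" for i in range(n_nonleaf)]
    n_layers = min(3, n_nonleaf)
    layer_of: Dict[str, int] = {b: 0 for b in leaves}
    for i, c in enumerate(inner):
        # last compound is the target in the top layer
        layer_of[c] = n_layers if i == n_nonleaf - 1 else 1 + (i % n_layers)
    target = inner[-1]

    prices = {b: round(rng.uniform(*spec.price_range), 2) for b in leaves}
    net = Subnetwork()
    for b in leaves:
        net.add_compound(b, purchasable=True, price=prices[b])
    for c in inner:
        net.add_compound(c)

    def sample_reactants(product: str) -> Optional[Tuple[str, ...]]:
        lower = [c for c in layer_of if layer_of[c] < layer_of[product]]
        if not lower:
            return None
        n_r = 2 if (len(lower) >= 2 and rng.random() < spec.fraction_two_reactant) else 1
        return tuple(rng.sample(lower, n_r))

    def make_edge(rid: str, product: str, reactants: Tuple[str, ...]) -> ReactionEdge:
        y = round(rng.uniform(*spec.yield_range), 3)
        if rng.random() < spec.fraction_generated:
            return ReactionEdge(rid=rid, reactants=reactants, product=product,
                                origin="generated", score=y, template_id="Tsyn",
                                name="synthetic transform")
        return ReactionEdge(rid=rid, reactants=reactants, product=product,
                            origin="fixed", yield_=y, source="synthetic")

    seen = set()
    rid_counter = 0
    # backbone: every inner compound gets one producing reaction
    for c in sorted(inner, key=lambda c: layer_of[c]):
        reactants = sample_reactants(c)
        if reactants is None:
            raise GenerationError("layering left a compound without precursors")
        seen.add((tuple(sorted(reactants)), c))
        net.add_reaction(make_edge(f"R{rid_counter}", c, reactants))
        rid_counter += 1
    # extras
    attempts = 0
    while rid_counter < spec.n_reactions and attempts < 50 * spec.n_reactions:
        attempts += 1
        product = rng.choice(inner)
        reactants = sample_reactants(product)
        if reactants is None:
            continue
        key = (tuple(sorted(reactants)), product)
        if key in seen:
            continue
        seen.add(key)
        net.add_reaction(make_edge(f"R{rid_counter}", product, reactants))
        rid_counter += 1
    return net, target, prices


def write_network_files(spec: NetworkSpec, out_dir) -> Tuple[Path, Path, str]:
    """Emit a synthetic network as building-block CSV + fixed-reaction TSV.

    Abstract compound keys are mapped to distinct linear alkanes so the
    files are chemically valid and load cleanly through the chemdb readers
    (the chemistry itself is placeholder; these are graph fixtures).
    Returns (bb_path, reactions_path, target_smiles).
    """
    net, target, prices = make_synthetic_network(spec)
    out_dir = Path(out_dir)
    mapping = {key: "C" * (i + 1) for i, key in enumerate(net.compounds)}
    bb = BuildingBlockDB()
    for i, (key, price) in enumerate(prices.items()):
        bb.add(BuildingBlock(mapping[key], f"SYN-{i}", price, "synthetic", 1))
    db = FixedReactionDB()
    for edge in net.reactions.values():
        y = edge.yield_ if edge.origin == "fixed" else edge.score
        db.add(FixedReaction(
            reactants=tuple(mapping[r] for r in edge.reactants),
            product=mapping[edge.product],
            yield_=y, name=edge.rid, source="synthetic",
        ))
    from .chemdb import write_building_blocks, write_reaction_db
    bb_path = out_dir / "building_blocks.csv"
    rxn_path = out_dir / "reactions.tsv"
    write_building_blocks(bb, bb_path)
    write_reaction_db(db, rxn_path)
    return bb_path, rxn_path, mapping[target]


# ---------------------------------------------------------------------------
# synthetic training corpora
# ---------------------------------------------------------------------------

def _forward_combos(template: RetroTemplate, pool: Sequence[str]):
    """All pool combos filling the template's forward reactant slots, with
    their forward products."""
    mols = [(s, Chem.MolFromSmiles(s)) for s in pool]
    slots = []
    for i in range(template.n_reactants):
        patt = template._forward_rxn.GetReactantTemplate(i)
        slots.append([s for s, m in mols if m is not None and m.HasSubstructMatch(patt)])
    combos = []
    for combo in iproduct(*slots):
        try:
            prods = apply_forward(template, combo)
        except Exception:
            continue
        if prods:
            combos.append((tuple(combo), prods))
    return combos


def make_training_corpus(
    template: RetroTemplate,
    n_pos: int,
    n_neg: int,
    seed: int = 0,
    low_yield_fraction: float = 0.05,
    no_yield_fraction: float = 0.3,
    pool: Optional[Sequence[str]] = None,
) -> List[FixedReaction]:
    """A synthetic reaction corpus for one template.

    Positives: forward applications of the template to pool fragments with
    yield >= 10% or unreported.  Negatives: the same full matches with yield
    < 10% (a small fraction - reported low-yield failures are rare compared
    to wrong-product records), plus reactant-matching records whose product
    is scrambled (replaced by an unrelated pool molecule), at any yield.
    The scrambled products are structurally unrelated to the true forward
    product, so the corpus is separable by construction.
    """
    rng = random.Random(seed)
    pool = list(pool) if pool is not None else fragment_pool()
    combos = _forward_combos(template, pool)
    if not combos:
        raise GenerationError(
            f"template {template.template_id} matches nothing in the fragment pool"
        )
    records: List[FixedReaction] = []

    def draw_positive_yield() -> Optional[float]:
        if rng.random() < no_yield_fraction:
            return None
        return round(rng.uniform(0.10, 0.95), 3)

    for _ in range(n_pos):
        reactants, prods = combos[rng.randrange(len(combos))]
        records.append(FixedReaction(
            reactants=reactants, product=prods[0],
            yield_=draw_positive_yield(), name="synthetic", source="fixtures",
        ))
    n_low = int(round(low_yield_fraction * n_neg))
    for _ in range(n_low):
        reactants, prods = combos[rng.randrange(len(combos))]
        records.append(FixedReaction(
            reactants=reactants, product=prods[0],
            yield_=round(rng.uniform(0.0, 0.099), 3),
            name="synthetic", source="fixtures",
        ))
    guard = 0
    while len(records) < n_pos + n_neg and guard < 100 * (n_pos + n_neg):
        guard += 1
        reactants, prods = combos[rng.randrange(len(combos))]
        wrong = rng.choice(pool)
        if wrong in prods or wrong in reactants:
            continue
        y = None if rng.random() < no_yield_fraction else round(rng.uniform(0.0, 0.95), 3)
        records.append(FixedReaction(
            reactants=reactants, product=wrong, yield_=y,
            name="synthetic", source="fixtures",
        ))
    if len(records) < n_pos + n_neg:
        raise GenerationError("could not scramble enough negative products")
    rng.shuffle(records)
    return records


def make_training_set(
    template: RetroTemplate, n_pos: int, n_neg: int, seed: int = 0,
    pool: Optional[Sequence[str]] = None,
) -> List[LabeledExample]:
    """Labeled examples for one template; labels come from the labeling
    rules applied to the generated corpus, never hard-coded, so generator
    and labeler must agree."""
    corpus = make_training_corpus(template, n_pos, n_neg, seed=seed, pool=pool)
    examples = label_examples(corpus, template)
    n_pos_got = sum(1 for e in examples if e.label == "positive")
    if len(examples) != len(corpus) or n_pos_got != n_pos:
        raise GenerationError(
            f"generator/labeler disagree: {n_pos_got}/{len(examples)} labeled "
            f"positive, intended {n_pos}/{len(corpus)}"
        )
    return examples


def corpus_db(records: Sequence[FixedReaction]) -> FixedReactionDB:
    return FixedReactionDB(records)


# ---------------------------------------------------------------------------
# worked examples (hand-computed)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkedExample:
    name: str
    net: Subnetwork
    target: str
    expected_costs: Tuple[float, ...]
    description: str = ""


def worked_example_suite() -> Dict[str, WorkedExample]:
    """The hand-computed fixtures used across the tests.

    chain    : BB(price 2) -r1(y=0.5)-> X -r2(y=0.5)-> T; cost (2/0.5)/0.5 = 8.
    diamond  : T via r_a (reactant price 10, y=1.0) or r_b (price 4, y=0.5);
               costs 8 then 10.
    cycle    : a 2-reaction cycle A<->B plus a real route; search must
               terminate with repetition-free routes.
    threeroutes : three single-strategy-distinct routes, one passing through
               compound X (for keep-constraint tests).
    """
    examples: Dict[str, WorkedExample] = {}

    chain = Subnetwork()
    chain.add_compound("BB", True, 2.0)
    chain.add_reaction(ReactionEdge("r1", ("BB",), "X", "fixed", yield_=0.5))
    chain.add_reaction(ReactionEdge("r2", ("X",), "T", "fixed", yield_=0.5))
    examples["chain"] = WorkedExample(
        "chain", chain, "T", (8.0,), "linear 2-step route, cost (2/0.5)/0.5")

    diamond = Subnetwork()
    diamond.add_compound("A", True, 10.0)
    diamond.add_compound("B", True, 4.0)
    diamond.add_reaction(ReactionEdge("r_a", ("A",), "T", "fixed", yield_=1.0))
    diamond.add_reaction(ReactionEdge("r_b", ("B",), "T", "fixed", yield_=0.5))
    examples["diamond"] = WorkedExample(
        "diamond", diamond, "T", (8.0, 10.0), "4/0.5 = 8 beats 10/1.0")

    cycle = Subnetwork()
    cycle.add_compound("BB", True, 1.0)
    cycle.add_reaction(ReactionEdge("rab", ("A",), "B", "fixed", yield_=1.0))
    cycle.add_reaction(ReactionEdge("rba", ("B",), "A", "fixed", yield_=1.0))
    cycle.add_reaction(ReactionEdge("rb", ("BB",), "B", "fixed", yield_=0.5))
    cycle.add_reaction(ReactionEdge("rt", ("A", "B"), "T", "fixed", yield_=0.5))
    # only valid route: B from BB (2), A from B (2), A+B -> T: (2+2)/0.5 = 8
    examples["cycle"] = WorkedExample(
        "cycle", cycle, "T", (8.0,), "2-reaction cycle must not loop the search")

    three = Subnetwork()
    three.add_compound("BB1", True, 2.0)
    three.add_compound("BB2", True, 3.0)
    three.add_compound("BB3", True, 1.0)
    three.add_reaction(ReactionEdge("q1", ("BB1",), "T", "fixed", yield_=1.0))
    three.add_reaction(ReactionEdge("q2a", ("BB2",), "X", "fixed", yield_=0.5))
    three.add_reaction(ReactionEdge("q2b", ("X",), "T", "fixed", yield_=1.0))
    three.add_reaction(ReactionEdge("q3", ("BB3",), "T", "fixed", yield_=0.5))
    # costs: q1: 2.0; via X: (3/0.5)/1 = 6.0; q3: 1/0.5 = 2.0
    examples["threeroutes"] = WorkedExample(
        "threeroutes", three, "T", (2.0, 2.0, 6.0),
        "route through X is the only one containing X")

    return examples


# ---------------------------------------------------------------------------
# chemistry fixture for the expansion algorithms
# ---------------------------------------------------------------------------

def expansion_fixture() -> Tuple[str, BuildingBlockDB]:
    """A target admitting both a 2-step and a 4-step route.

    Target: an acetanilide bearing a (biphenylyl)methyl ether.
    Short route (2 reactions): amide disconnection (acetic acid + the
    aminophenol ether), then ether disconnection to 4-aminophenol and the
    purchasable 4-(bromomethyl)biphenyl.
    Long route (4 reactions): build 4-(bromomethyl)biphenyl instead of
    buying it - biaryl coupling from 4-bromobenzyl bromide (itself from
    benzyl bromide by ring bromination) and phenylboronic acid.
    """
    target = canonicalize("CC(=O)Nc1ccc(OCc2ccc(-c3ccccc3)cc2)cc1")
    bbs = make_building_blocks({
        "CC(=O)O": 1.0,                     # acetic acid
        "Nc1ccc(O)cc1": 2.0,                # 4-aminophenol
        "OB(O)c1ccccc1": 5.0,               # phenylboronic acid
        "BrCc1ccc(-c2ccccc2)cc1": 40.0,     # 4-(bromomethyl)biphenyl
        "BrCc1ccccc1": 3.0,                 # benzyl bromide
        "CO": 1.0,                          # methanol
        "COC(=O)C": 2.0,                    # methyl acetate
    })
    return target, bbs
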