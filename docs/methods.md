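# Methods

## The synthesis network

Compounds are keyed by RDKit canonical SMILES (stereochemistry retained),
so any two spellings of one structure collapse to a single node.
Multi-fragment inputs are rejected as targets: every reaction in the
network has one product and one or two reactants. The network is an AND-OR
hypergraph: a compound is made by *any one* of the reactions producing it,
and a reaction needs *all* of its reactants.

A **route** is a repetition-free synthesis tree rooted at the target: each
non-leaf compound is assigned exactly one producing reaction, no compound
repeats along any root-to-leaf path, and the leaves are purchasable
building blocks (or penalized open leaves in a partial route). A compound
may not be bought in one branch and synthesized in another; the tree
mapping is route-wide.

## Retro-templates

Templates are SMIRKS transformations written retrosynthetically
(`product >> reactants`), restricted to one product and one or two
reactants; the forward transformation is the same string with its sides
swapped, and every shipped template is valid in both directions. Matching
is stereo-agnostic substructure matching; atoms outside the reaction
center keep their stereocenters. Symmetric matches producing identical
canonical reactant multisets are deduplicated.

The shipped library (`data/templates.tsv`, 29 rows) covers general
medicinal-chemistry transformations — amide/ester couplings, N-, O- and
S-alkylations, reductive amination, Suzuki / Buchwald–Hartwig /
Sonogashira couplings, SNAr on azines, Boc protection, carbamate / urea /
sulfonamide formation, Grignard addition, nitro/ketone reductions,
nitrile chemistry, aldol condensation, epoxide aminolysis, bromination,
oxidation and hydrogenation. Two ether templates exist deliberately:
Williamson (aliphatic alcohol) and phenol O-benzylation, because one
stereo-agnostic SMARTS covering both cleanly is not expressible without
over-matching esters. The TSV format (template_id, reaction_name, smirks,
n_reactants) is append-to-extend; `load_templates` validates SMIRKS parse
and arity on load.

## Feasibility classifiers

One binary classifier per template estimates the probability that a
generated reaction would work. Corpus labeling rules:

* **positive** — the record fully matches the template (the retro product
  pattern matches the product *and* forward application of the template to
  the record's reactants reproduces the product, canonical equality, both
  reactant orders tried) with yield ≥ 10% or no reported yield;
* **negative** — a full match with yield < 10%, or a record whose
  reactants fill the template's reactant patterns but whose product
  differs, at any yield;
* everything else is excluded.

Encoding: 2048-bit radius-2 Morgan fingerprints (ECFP4) per molecule,
concatenated as [reactant 1 | reactant 2 | product] (6144 bits; the middle
slot is zero for single-reactant templates). Slot order for corpus records
is descending heavy-atom count with canonical-SMILES ties; reactions
generated from a template use the template's reactant-pattern order.

Model: scikit-learn `MLPClassifier` with one hidden layer of 10 units,
max 500 iterations, fixed seed; examples are shuffled once (seeded) and
split 80/10/10 into train/test/evaluation, with the reported accuracy
taken on the held-out 10% evaluation split. A template needs ≥ 20
positive examples for a classifier; otherwise it is skipped and its
generated reactions score a configurable neutral default of 0.5 — above
the 0.2 rejection threshold, so classifier-less templates stay usable.
No class reweighting is applied.

## Expansion

Depth convention: the target is depth 0; a reaction disconnecting a
depth-*d* compound, and its reactants, are at depth *d* + 1. First-level
terms therefore use *d* = 1 and are undiscounted. Priorities (lower is
expanded first):

* compound: `heavy_atoms × d^α`;
* reaction: `max(reactant heavy atoms) × d^α`, the depth factor applied
  once (applying it twice — once inside the reactant score and once on the
  reaction — only rescales within a depth but distorts comparisons across
  depths).

α defaults to 1.1. Ties pop in insertion order, so all four algorithms are
deterministic. Per-compound template applications are cached; a compound
re-encountered at a new depth keeps its minimum observed depth. A
candidate reaction is discarded when a reactant already occurs on the
expansion path of its product (ancestor check), when it duplicates an
existing (reactants, product, template) edge, or when its feasibility
score is below the threshold (0.2). The budget counts *kept* reactions,
so the network invariant `generated ≤ max_generated` is literal; rejected
candidates are counted separately and logged. Early stopping on the first
complete route is available but off by default — the budget and frontier
exhaustion are the stopping criteria. Purchasable and known-synthesizable
compounds are never template-expanded.

## Route extraction

Phase 2 walks retrosynthetically from the target to a depth bound,
merging generated reactions with fixed-database reactions producing any
included compound, and annotates prices.

Phase 3 is a vectorized Dijkstra: compound nodes hold multiple
(cost, route) values. Seeds are buy-entries (catalog price) for
purchasable compounds and, when partial routes are enabled, penalty
entries (default 10 000) for open leaves. A candidate for a reaction
combines one stored entry per reactant (cross-combinations for 2-reactant
reactions, the diagonal when both slots are the same compound) at cost
`(Σ entry costs) / effective_yield + overhead`; it is valid only if the
product does not occur in any chosen subtree and the subtrees agree on
every shared compound's producer. Effective yield: reported yield for
fixed reactions, 50% default when unreported (deliberately favoring
reactions with published yields); `min(score, 70%)` for generated
reactions (the cap favors reported chemistry over generated steps).
Because yields ≤ 1, overhead ≥ 0 and costs are positive, a candidate
costs at least as much as each constituent, so heap admissions occur in
non-decreasing cost order even in cyclic networks — the search terminates
on cycles by rejecting path repetitions rather than by depth cutoffs.

Two routes are distinct iff their reaction sets differ; duplicates
arriving by different heap paths merge. The target accumulates routes
until k of them (satisfying any keep constraint) are found. Intermediate
node stores are **unbounded by default**: admissions in cost order then
make the search lazily exhaustive, and it provably returns exactly the
k cheapest valid routes (the test suite checks identity with brute-force
enumeration over hundreds of random networks). A finite `node_capacity`
(the classical "k values per node") is available for large dense
networks; it can in rare convergent topologies displace a subroute that
the k-th best route needs, which is why it is not the default.

Keep/avoid: avoided compounds and reactions are pruned from the
subnetwork before the search; keep membership is filtered at target
admission, so fewer than k routes are returned when fewer satisfy it.
Convergent branches are costed independently (tree semantics: the literal
sum-over-reactants recursion); shared-intermediate discounting is out of
scope. Prices are per catalog pack, no normalization. Route and strategy
output is a JSON document (target, parameters, strategies each holding
cost-ordered routes with reactions in dependency order).

## Synthetic data

The generators in `fixtures` are pure functions of their spec and seed.

* **Random networks** (`make_synthetic_network`, default 12 compounds /
  18 reactions): purchasable leaves in layer 0 with prices uniform in
  [1, 100]; every non-leaf compound gets one backbone reaction drawing
  reactants from strictly lower layers, guaranteeing a complete route by
  induction; extra reactions are random; yields uniform in [0.3, 1.0];
  ~30% of edges are "generated" (score instead of yield) so both cost
  rules are exercised. Layering makes these networks acyclic — cyclic
  behavior is covered by the hand-built cycle fixture.
* **Training corpora** (`make_training_corpus`): positives are true
  forward applications of a template to a shipped ~100-fragment pool with
  yields ≥ 10% or absent (30% unreported); negatives are the same full
  matches with yield < 10% (5% of negatives) plus reactant-matching
  records with the product replaced by an unrelated pool molecule.
  Low-yield negatives are feature-identical to positives — the same
  reaction, different outcome — so their fraction is an irreducible error
  floor; at 5% the intended accuracy ceiling is ≈ 97.5%, and the corpus
  is otherwise separable by construction (scrambled products are
  structurally unrelated to the true ones). Labels are always assigned by
  the labeling rules, never hard-coded, so generator and labeler must
  agree. What passing classifier tests shows is that the training
  pipeline recovers a learnable signal reproducibly; it says nothing
  about accuracy on real literature data, where negatives are subtler
  (wrong conditions, unreported failures) and fingerprint overlap between
  classes is far larger.
* **Chemistry fixture** (`expansion_fixture`): a target admitting a
  2-step route (buy an advanced intermediate) and a 4-step route (build
  it via bromination + Suzuki), used to test shortest-route behavior and
  budgets with real template chemistry.

## Numerical and degenerate-input choices

Costs are double-precision floats with no rounding during search; the
oracle-equivalence tests compare at 1e-9 relative tolerance but observed
agreement is exact (identical arithmetic on both paths). Heap ties break
by insertion sequence. Building-block duplicates keep the minimum price.
Reaction records with more than two reactants, multiple products, a
product equal to a reactant, or out-of-range yields are dropped or
demoted to unreported at ingestion, with logged counts. An empty template
library or a zero budget are valid inputs (the search then relies on
fixed reactions alone); a purchasable target expands to nothing.

## Problem sizes

Defaults used by the test suite and the acceptance script: 200 random
networks of ≤ 12 compounds / 18 reactions with k ∈ {1, 3, 5};
classifier corpora of 500 + 500 examples for one template; expansion
budgets of 10–500 on the chemistry fixture. These sizes exercise every
code path (both reaction arities, both origins, cycles, partial routes)
while brute-force enumeration remains exact and cheap; the planner itself
accepts arbitrarily larger budgets and catalogs.

## Known limitations

* Stereochemistry is matched agnostically; templates neither set nor
  check stereocenters at the reaction center, so stereoselective steps
  are not modeled (targets with many chiral centers will be handled
  naively).
* The shipped 29-template library covers common transformations only;
  heterocycle-forming and specialized ring chemistry are absent (the
  format is extensible).
* Feasibility classifiers trained on the synthetic corpora are test
  artifacts; real deployments should train on a literature corpus in the
  same TSV format.
* Reaction conditions (solvent, temperature, reagents) are carried as
  metadata only, never predicted.
* Convergent-route costing double-counts shared intermediates by design
  (tree semantics).
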