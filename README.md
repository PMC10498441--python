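# retroplan

Template-based retrosynthetic route planning for drug-like small molecules.

Given a target compound (SMILES), a building-block catalog with prices, and
optionally a database of reported single-step reactions, `retroplan` finds
the *k* lowest-cost synthetic routes that end in purchasable starting
materials. It is built for the medicinal-chemistry setting where a chemist
wants several diversified, explainable route suggestions — every generated
step carries the name of a classical transformation (amide coupling, Suzuki
coupling, reductive amination, ...) rather than an opaque model prediction.

## How it works

The search runs in three phases over an AND-OR synthesis graph (compounds
are OR nodes — any producing reaction suffices; reactions are AND hyperarcs
— all reactants are required):

1. **Retrosynthetic expansion.** A library of general named-reaction
   retro-templates (SMIRKS, applied with RDKit, each valid in both the
   forward and retro direction) disconnects the target one step at a time.
   Each candidate reaction gets a feasibility score in [0, 1] from a
   per-template classifier — a one-hidden-layer MLP (10 units) over
   concatenated 2048-bit ECFP4 fingerprints of reactant 1, reactant 2 and
   product — and is rejected below a 0.2 threshold. Four selection
   strategies decide what to expand next: breadth-first, depth-first,
   best-first on compounds, or best-first on reactions, the informed ones
   using the complexity score `heavy_atoms × d^α` (depth *d* from the
   target, α = 1.1), so deeper and bigger reactants are deprioritized.
   Expansion stops at purchasable or known-synthesizable compounds, or when
   the generated-reaction budget is spent.

2. **Subnetwork extraction.** Everything retrosynthetically reachable from
   the target within a depth bound is collected, stitching the generated
   reactions together with fixed-database reactions and annotating
   purchasability and catalog prices.

3. **Vectorized Dijkstra route search.** A min-cost search in which each
   compound node holds multiple (cost, route) values instead of one. Leaf
   cost is the catalog price; a product's cost is
   `(Σ reactant costs) / yield`, with the reported yield for fixed
   reactions (default 50% when unreported) and the feasibility score capped
   at 70% for generated ones. Routes are diversified (distinct reaction
   sets), grouped into *strategies* by the reaction that directly produces
   the target, and can be constrained to keep or avoid chosen compounds and
   reactions. Routes whose leaves have no supplier are flagged partial and
   heavily penalized.

A brute-force route enumerator (`brute_force_k_best`) serves as an
independent test oracle: on small networks the heap search reproduces its
cost list exactly.

## Worked example

The test fixture target `CC(=O)Nc1ccc(OCc2ccc(-c3ccccc3)cc2)cc1` (an
acetanilide bearing a biphenylylmethyl ether) against a seven-compound
building-block catalog:

```sh
retroplan search "CC(=O)Nc1ccc(OCc2ccc(-c3ccccc3)cc2)cc1" \
    --building-blocks bb_demo.csv --algorithm best_first_reaction \
    --max-generated 100 --k 5 -o routes.json
```

prints

```
target: CC(=O)Nc1ccc(OCc2ccc(-c3ccccc3)cc2)cc1
generated 60 reactions (0 rejected); subnetwork 35 compounds / 60 reactions
 strategy routes  best cost steps partial
        1      5      58.00     4   False
```

and the best route in `routes.json` reads, in dependency order: amide
coupling of acetic acid (1.0) with 4-aminophenol (2.0); ring bromination of
benzyl bromide (3.0); O-benzylation of the phenol with the dibromide;
Suzuki coupling with phenylboronic acid (5.0) to install the biphenyl.
Total cost 58.0 = the four building-block prices compounded by one division
per step by the effective yield (0.5 here: template reactions without a
trained classifier score the neutral default 0.5). Buying
4-(bromomethyl)biphenyl at 40.0 instead gives the 2-step route at cost
82.0 — ranked below. Costs are unitless catalog-pack prices.

Classifiers are trained from a reaction corpus TSV with
`retroplan train --corpus corpus.tsv --out-dir models/`; labeling follows
the yield rules (full template match with yield ≥ 10% or unreported →
positive; full match below 10%, or matching reactants with a different
product at any yield → negative), and templates with fewer than 20
positive examples are skipped and fall back to the default score.
`retroplan simulate` writes seeded synthetic fixture files (networks,
corpora) in the same CSV/TSV formats.

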