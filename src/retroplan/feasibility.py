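"""Reaction-feasibility classifiers, one per template.

A template application is only a formal disconnection; whether the implied
forward reaction would actually work is estimated by a per-template binary
classifier trained on reported reactions.  Labeling rules over a reaction
corpus:

* positive  - the record fully matches the template (reactants and product)
  and its yield is >= 10% or unreported;
* negative  - a full match with yield < 10%, or a record whose reactant(s)
  match the template but whose product differs, at any yield;
* excluded  - everything else.

Reactions are encoded as the concatenation of 2048-bit ECFP4 fingerprints
for reactant 1, reactant 2 and the product (the middle slot is all-zero for
single-reactant templates).  The model is a multilayer perceptron with one
hidden layer of 10 units; a template needs at least 20 positive examples to
receive a classifier, otherwise reactions it generates fall back to a
neutral default score.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.neural_network import MLPClassifier

from .chemdb import FixedReaction
from .core import canonicalize, heavy_atoms
from .templates import RetroTemplate, apply_forward

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

FULL_MATCH_HIGH_YIELD = "full-match-high-yield"
FULL_MATCH_NO_YIELD = "full-match-no-yield"
FULL_MATCH_LOW_YIELD = "full-match-low-yield"
PRODUCT_MISMATCH = "product-mismatch"

DEFAULT_SCORE = 0.5  # neutral score for templates without a classifier


class NotTrainableError(RuntimeError):
    """Too few positive examples to train a classifier for this template."""


@dataclass(frozen=True)
class LabeledExample:
    reactants: Tuple[str, ...]
    product: str
    label: str
    provenance: str

    def __post_init__(self) -> None:
        positive = self.provenance in (FULL_MATCH_HIGH_YIELD, FULL_MATCH_NO_YIELD)
        if (self.label == POSITIVE) != positive:
            raise ValueError(
                f"label {self.label!r} inconsistent with provenance {self.provenance!r}"
            )


@dataclass(frozen=True)
class EncoderConfig:
    bits_per_molecule: int = 2048
    radius: int = 2  # ECFP4
    # slots fixed at 3: reactant 1, reactant 2, product

    @property
    def vector_length(self) -> int:
        return 3 * self.bits_per_molecule


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_layer_sizes: Tuple[int, ...] = (10,)
    min_positive_examples: int = 20
    split_fractions: Tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0
    max_iter: int = 500

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.min_positive_examples < 1:
            raise ValueError("min_positive_examples must be >= 1")


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def _reactant_side_match(template: RetroTemplate, reactants: Sequence[str]) -> bool:
    """True iff the record's reactants can fill the template's reactant slots."""
    if len(reactants) != template.n_reactants:
        return False
    patterns = [
        template._forward_rxn.GetReactantTemplate(i)
        for i in range(template.n_reactants)
    ]
    mols = [Chem.MolFromSmiles(s) for s in reactants]
    if any(m is None for m in mols):
        return False
    if template.n_reactants == 1:
        return mols[0].HasSubstructMatch(patterns[0])
    a, b = mols
    p0, p1 = patterns
    return (a.HasSubstructMatch(p0) and b.HasSubstructMatch(p1)) or (
        b.HasSubstructMatch(p0) and a.HasSubstructMatch(p1)
    )


def _full_match(template: RetroTemplate, reactants: Sequence[str], product: str) -> bool:
    """Reactants and product both match: forward application of the template
    to the record's reactants produces the record's product."""
    if not template.matches(product):
        return False
    orders = [tuple(reactants)]
    if len(reactants) == 2:
        orders.append((reactants[1], reactants[0]))
    target = canonicalize(product)
    for order in orders:
        if len(order) != template.n_reactants:
            continue
        try:
            if target in apply_forward(template, order):
                return True
        except Exception:
            continue
    return False


def label_examples(
    corpus: Iterable[FixedReaction], template: RetroTemplate
) -> List[LabeledExample]:
    """Partition corpus records into positive/negative examples for one template.

    Every record maps to exactly one of {positive, negative, excluded}.
    Malformed records are skipped (counted in the log).
    """
    out: List[LabeledExample] = []
    skipped = 0
    for rec in corpus:
        if not (1 <= len(rec.reactants) <= 2):
            skipped += 1
            continue
        try:
            full = _full_match(template, rec.reactants, rec.product)
            side = full or _reactant_side_match(template, rec.reactants)
        except Exception:
            skipped += 1
            continue
        if full:
            if rec.yield_ is None:
                out.append(LabeledExample(rec.reactants, rec.product,
                                          POSITIVE, FULL_MATCH_NO_YIELD))
            elif rec.yield_ >= 0.10:
                out.append(LabeledExample(rec.reactants, rec.product,
                                          POSITIVE, FULL_MATCH_HIGH_YIELD))
            else:
                out.append(LabeledExample(rec.reactants, rec.product,
                                          NEGATIVE, FULL_MATCH_LOW_YIELD))
        elif side:
            out.append(LabeledExample(rec.reactants, rec.product,
                                      NEGATIVE, PRODUCT_MISMATCH))
        # else: excluded entirely
    if skipped:
        logger.warning("label_examples: skipped %d malformed records", skipped)
    return out


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def corpus_reactant_order(reactants: Sequence[str]) -> Tuple[str, ...]:
    """Deterministic slot order for corpus records: descending heavy-atom
    count, ties broken by canonical SMILES lexicographic order."""
    canon = [canonicalize(s) for s in reactants]
    return tuple(sorted(canon, key=lambda s: (-heavy_atoms(s), s)))


def encode_reaction(
    reactants: Sequence[str],
    product: str,
    cfg: EncoderConfig = EncoderConfig(),
) -> np.ndarray:
    """Concatenated [reactant1 | reactant2 | product] circular fingerprint.

    A missing second reactant leaves the middle slot all-zero.  Reactants are
    encoded in the order given (callers apply the appropriate ordering rule:
    template-role order for generated reactions, `corpus_reactant_order` for
    corpus records).
    """
    if not (1 <= len(reactants) <= 2):
        raise ValueError(f"expected 1 or 2 reactants, got {len(reactants)}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.radius, fpSize=cfg.bits_per_molecule
    )
    vec = np.zeros(cfg.vector_length, dtype=np.float32)
    slots = [reactants[0], reactants[1] if len(reactants) == 2 else None, product]
    for i, smi in enumerate(slots):
        if smi is None:
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES in reaction encoding: {smi!r}")
        fp = gen.GetFingerprintAsNumPy(mol)
        vec[i * cfg.bits_per_molecule:(i + 1) * cfg.bits_per_molecule] = fp
    return vec


def encode_examples(
    examples: Sequence[LabeledExample], cfg: EncoderConfig = EncoderConfig()
) -> Tuple[np.ndarray, np.ndarray]:
    X = np.zeros((len(examples), cfg.vector_length), dtype=np.float32)
    y = np.zeros(len(examples), dtype=np.int64)
    for i, ex in enumerate(examples):
        X[i] = encode_reaction(corpus_reactant_order(ex.reactants), ex.product, cfg)
        y[i] = 1 if ex.label == POSITIVE else 0
    return X, y


# ---------------------------------------------------------------------------
# training and scoring
# ---------------------------------------------------------------------------

@dataclass
class TemplateClassifier:
    template_id: str
    model: MLPClassifier
    evaluation_accuracy: float
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def score(self, reactants: Sequence[str], product: str) -> float:
        vec = encode_reaction(reactants, product, self.encoder).reshape(1, -1)
        proba = self.model.predict_proba(vec)[0]
        idx = list(self.model.classes_).index(1)
        return float(proba[idx])


def train_template_classifier(
    examples: Sequence[LabeledExample],
    cfg: ClassifierConfig = ClassifierConfig(),
    template_id: str = "",
    encoder: EncoderConfig = EncoderConfig(),
) -> TemplateClassifier:
    """Train one template's MLP on an 80/10/10 train/test/evaluation split.

    Raises NotTrainableError when positives are below the minimum (the
    template then stays usable at the default score) and ValueError when no
    negative examples exist.
    """
    n_pos = sum(1 for e in examples if e.label == POSITIVE)
    n_neg = len(examples) - n_pos
    if n_pos < cfg.min_positive_examples:
        raise NotTrainableError(
            f"template {template_id or '?'}: {n_pos} positive examples "
            f"(< {cfg.min_positive_examples}); classifier not trainable"
        )
    if n_neg == 0:
        raise ValueError("cannot train a classifier without negative examples")

    X, y = encode_examples(examples, encoder)
    rng = np.random.RandomState(cfg.seed)
    order = rng.permutation(len(examples))
    X, y = X[order], y[order]
    n = len(examples)
    n_train = int(round(cfg.split_fractions[0] * n))
    n_test = int(round(cfg.split_fractions[1] * n))
    X_train, y_train = X[:n_train], y[:n_train]
    X_eval, y_eval = X[n_train + n_test:], y[n_train + n_test:]
    if len(y_eval) == 0 or len(set(y_train)) < 2:
        raise ValueError("splits leave no evaluation data or a single-class train set")

    model = MLPClassifier(
        hidden_layer_sizes=cfg.hidden_layer_sizes,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    model.fit(X_train, y_train)
    acc = float(np.mean(model.predict(X_eval) == y_eval))
    return TemplateClassifier(
        template_id=template_id, model=model,
        evaluation_accuracy=acc, encoder=encoder,
    )


class ClassifierStore:
    """Trained classifiers keyed by template_id, with a JSON manifest."""

    def __init__(self, default_score: float = DEFAULT_SCORE) -> None:
        self.default_score = default_score
        self._classifiers: Dict[str, TemplateClassifier] = {}
        self.skipped: Dict[str, str] = {}  # template_id -> reason

    def add(self, clf: TemplateClassifier) -> None:
        self._classifiers[clf.template_id] = clf

    def get(self, template_id: str) -> Optional[TemplateClassifier]:
        return self._classifiers.get(template_id)

    def __contains__(self, template_id: str) -> bool:
        return template_id in self._classifiers

    def __len__(self) -> int:
        return len(self._classifiers)

    def template_ids(self) -> List[str]:
        return sorted(self._classifiers)

    def score(
        self, template_id: str, reactants: Sequence[str], product: str
    ) -> float:
        """Feasibility score in [0, 1]; the default when no classifier exists."""
        clf = self._classifiers.get(template_id)
        if clf is None:
            return self.default_score
        return min(1.0, max(0.0, clf.score(reactants, product)))

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "default_score": self.default_score,
            "classifiers": [],
            "skipped": self.skipped,
        }
        for tid in self.template_ids():
            clf = self._classifiers[tid]
            fname = f"{tid}.joblib"
            joblib.dump(clf.model, directory / fname)
            manifest["classifiers"].append({
                "template_id": tid,
                "file": fname,
                "evaluation_accuracy": clf.evaluation_accuracy,
                "encoder": {
                    "bits_per_molecule": clf.encoder.bits_per_molecule,
                    "radius": clf.encoder.radius,
                },
            })
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, directory) -> "ClassifierStore":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        store = cls(default_score=manifest.get("default_score", DEFAULT_SCORE))
        store.skipped = dict(manifest.get("skipped", {}))
        for rec in manifest["classifiers"]:
            enc = EncoderConfig(**rec["encoder"])
            model = joblib.load(directory / rec["file"])
            store.add(TemplateClassifier(
                template_id=rec["template_id"], model=model,
                evaluation_accuracy=rec["evaluation_accuracy"], encoder=enc,
            ))
        return store


def feasibility_score(
    clf: Optional[TemplateClassifier],
    reactants: Sequence[str],
    product: str,
    default_score: float = DEFAULT_SCORE,
) -> float:
    """Score a generated reaction; the configured default when no classifier."""
    if clf is None:
        return default_score
    return min(1.0, max(0.0, clf.score(reactants, product)))
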