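"""Building-block and fixed-reaction databases, plus route serialization.

Building blocks come from a CSV (``smiles,id,price,vendor,tier``) emulating a
vendor catalog extract; only tiers in a configurable allow-list (default
{1, 2}, i.e. fast-shipping stock) are kept.  Fixed reactions come from a TSV
of single-step reaction SMILES (``reactants>agents>product``) with optional
yields, emulating a literature/patent-derived reaction database.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .core import SmilesParseError, canonicalize

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for files that do not match the expected schema."""


@dataclass(frozen=True)
class BuildingBlock:
    smiles: str
    bb_id: str
    price: float
    vendor: str
    tier: int


class BuildingBlockDB:
    """Mapping canonical SMILES -> building block (min price on duplicates)."""

    def __init__(self) -> None:
        self._blocks: Dict[str, BuildingBlock] = {}

    def add(self, block: BuildingBlock) -> None:
        existing = self._blocks.get(block.smiles)
        if existing is None or block.price < existing.price:
            self._blocks[block.smiles] = block

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._blocks

    def __len__(self) -> int:
        return len(self._blocks)

    def get(self, smiles: str) -> Optional[BuildingBlock]:
        return self._blocks.get(smiles)

    def price(self, smiles: str) -> Optional[float]:
        b = self._blocks.get(smiles)
        return None if b is None else b.price

    def smiles(self) -> Set[str]:
        return set(self._blocks)

    def __eq__(self, other) -> bool:
        return isinstance(other, BuildingBlockDB) and self._blocks == other._blocks


def read_building_blocks(path, allowed_tiers: Sequence[int] = (1, 2)) -> BuildingBlockDB:
    """Load a building-block CSV, applying the tier filter and min-price rule."""
    path = Path(path)
    db = BuildingBlockDB()
    allowed = set(allowed_tiers)
    skipped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"smiles", "id", "price", "vendor", "tier"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            try:
                tier = int(row["tier"])
                price = float(row["price"])
                smi = canonicalize(row["smiles"])
            except (ValueError, SmilesParseError):
                skipped += 1
                continue
            if tier not in allowed or price <= 0:
                continue
            db.add(BuildingBlock(smi, row["id"], price, row["vendor"], tier))
    if skipped:
        logger.warning("read_building_blocks: skipped %d malformed rows", skipped)
    return db


@dataclass(frozen=True)
class FixedReaction:
    """A reported single-step reaction: 1-2 reactants, 1 product."""

    reactants: Tuple[str, ...]
    product: str
    yield_: Optional[float] = None
    agents: Tuple[str, ...] = ()
    name: str = ""
    source: str = ""

    @property
    def reaction_id(self) -> str:
        return f"fixed:{'.'.join(self.reactants)}>>{self.product}"


class FixedReactionDB:
    """Fixed reactions indexed by producing (product) SMILES."""

    def __init__(self, reactions: Sequence[FixedReaction] = ()) -> None:
        self.reactions: List[FixedReaction] = []
        self._by_product: Dict[str, List[FixedReaction]] = {}
        self._seen: Set[Tuple[Tuple[str, ...], str]] = set()
        for r in reactions:
            self.add(r)

    def add(self, rxn: FixedReaction) -> None:
        key = (tuple(sorted(rxn.reactants)), rxn.product)
        if key in self._seen:
            return
        self._seen.add(key)
        self.reactions.append(rxn)
        self._by_product.setdefault(rxn.product, []).append(rxn)

    def producing(self, smiles: str) -> List[FixedReaction]:
        return self._by_product.get(smiles, [])

    def is_product(self, smiles: str) -> bool:
        return smiles in self._by_product

    def __len__(self) -> int:
        return len(self.reactions)

    def __eq__(self, other) -> bool:
        return isinstance(other, FixedReactionDB) and self.reactions == other.reactions


def parse_reaction_smiles(rxn_smiles: str) -> Tuple[List[str], List[str], List[str]]:
    """Split ``reactants>agents>product`` into canonical SMILES lists."""
    parts = rxn_smiles.split(">")
    if len(parts) == 2:  # "A.B>>P" splits into 3 with empty middle; bare "A>P" invalid
        raise FormatError(f"bad reaction SMILES {rxn_smiles!r}")
    if len(parts) != 3:
        raise FormatError(f"bad reaction SMILES {rxn_smiles!r}")
    def split_side(side: str) -> List[str]:
        return [canonicalize(s) for s in side.split(".") if s]
    return split_side(parts[0]), split_side(parts[1]), split_side(parts[2])


def read_reaction_db(path) -> FixedReactionDB:
    """Load a fixed-reaction TSV (reaction_smiles, yield, name, source).

    Records with more than two reactants or not exactly one product, and
    degenerate records whose product equals a reactant, are dropped and
    counted.  Yields outside (0, 1] are treated as absent.
    """
    path = Path(path)
    db = FixedReactionDB()
    dropped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"reaction_smiles", "yield", "name", "source"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            try:
                reactants, agents, products = parse_reaction_smiles(row["reaction_smiles"])
            except (FormatError, SmilesParseError):
                dropped += 1
                continue
            if not (1 <= len(reactants) <= 2) or len(products) != 1:
                dropped += 1
                continue
            product = products[0]
            if product in reactants:
                dropped += 1
                continue
            y: Optional[float] = None
            raw = (row.get("yield") or "").strip()
            if raw:
                try:
                    y = float(raw)
                except ValueError:
                    y = None
                if y is not None and not (0 < y <= 1):
                    logger.warning(
                        "read_reaction_db: yield %r outside (0,1], treated as absent", raw
                    )
                    y = None
            db.add(
                FixedReaction(
                    reactants=tuple(reactants),
                    product=product,
                    yield_=y,
                    agents=tuple(agents),
                    name=row.get("name", ""),
                    source=row.get("source", ""),
                )
            )
    if dropped:
        logger.warning("read_reaction_db: dropped %d malformed/out-of-shape rows", dropped)
    return db


def write_building_blocks(db: BuildingBlockDB, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "id", "price", "vendor", "tier"])
        for smi in sorted(db.smiles()):
            b = db.get(smi)
            w.writerow([b.smiles, b.bb_id, b.price, b.vendor, b.tier])


def write_reaction_db(db: FixedReactionDB, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["reaction_smiles", "yield", "name", "source"])
        for r in db.reactions:
            agents = ".".join(r.agents)
            rs = ".".join(r.reactants)
            w.writerow([f"{rs}>{agents}>{r.product}",
                        "" if r.yield_ is None else r.yield_, r.name, r.source])


def write_routes(result: dict, path) -> None:
    """Write a route-search result document (see routesearch.routes_document)."""
    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_routes(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
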