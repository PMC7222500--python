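"""Chemical gene-set libraries from CTD-style interaction records.

Keeps only chemical--mRNA records backed by at least one literature
reference whose action parses to increases/decreases, then builds three
gene-set dialects per chemical: *up* (genes increased), *down* (genes
decreased) and *composite* (their union), each restricted to the
signature's gene universe and subject to a minimum-size filter applied
independently per dialect — a chemical may survive in composite but not in
a directional library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, NamedTuple, Tuple

import pandas as pd

from .io import FormatError, INTERACTION_COLUMNS

logger = logging.getLogger(__name__)

DIALECTS = ("composite", "up", "down")


class InteractionRecord(NamedTuple):
    chemical_id: str
    chemical_name: str
    gene_id: str
    target_type: str
    action: str                       # "increases" | "decreases"
    pubmed_refs: Tuple[str, ...]


@dataclass(frozen=True)
class ChemicalLibrary:
    """Named gene sets per chemical, restricted to a gene universe."""

    dialect: str
    sets: Dict[str, FrozenSet[str]]
    universe: FrozenSet[str]
    names: Dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"dialect must be one of {DIALECTS}")

    def __len__(self) -> int:
        return len(self.sets)

    def set_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sets.items()}

    def size_range(self) -> Tuple[int, int]:
        sizes = [len(s) for s in self.sets.values()]
        return (min(sizes), max(sizes)) if sizes else (0, 0)


def _parse_action(raw: str) -> str | None:
    """Map an action string like 'increases^expression' to its direction."""
    head = str(raw).split("^")[0].split("|")[0].strip().lower()
    if head.startswith("increases"):
        return "increases"
    if head.startswith("decreases"):
        return "decreases"
    return None


def parse_interactions(table: pd.DataFrame) -> List[InteractionRecord]:
    """Filter raw interaction rows down to usable mRNA records.

    Retains rows with ``target_type == 'mRNA'``, a non-empty reference
    field, and an action parseable to increases/decreases; collapses
    duplicates of the same (chemical, gene, action). Unparseable actions
    are dropped with a logged count.
    """
    missing = [c for c in INTERACTION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"interaction table missing required column(s): {missing}")

    records: List[InteractionRecord] = []
    seen = set()
    n_unparseable = 0
    for row in table.itertuples(index=False):
        if row.target_type != "mRNA":
            continue
        refs = tuple(r for r in str(row.pubmed_ids).split("|") if r.strip())
        if not refs:
            continue
        action = _parse_action(row.action)
        if action is None:
            n_unparseable += 1
            continue
        key = (row.chemical_id, row.gene_id, action)
        if key in seen:
            continue
        seen.add(key)
        records.append(
            InteractionRecord(
                chemical_id=row.chemical_id,
                chemical_name=row.chemical_name,
                gene_id=row.gene_id,
                target_type=row.target_type,
                action=action,
                pubmed_refs=refs,
            )
        )
    if n_unparseable:
        logger.info("dropped %d records with unparseable actions", n_unparseable)
    return records


def build_libraries(
    records: Iterable[InteractionRecord],
    universe: Iterable[str],
    min_size: int = 3,
) -> Dict[str, ChemicalLibrary]:
    """Build the composite / up / down libraries from parsed records.

    Genes outside the universe are removed before the size filter; the
    minimum-size filter is applied to each dialect independently, with
    composite membership recomputed on the union.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("gene universe is empty")

    up: Dict[str, set] = {}
    down: Dict[str, set] = {}
    names: Dict[str, str] = {}
    for rec in records:
        if rec.gene_id not in universe:
            continue
        target = up if rec.action == "increases" else down
        target.setdefault(rec.chemical_id, set()).add(rec.gene_id)
        names.setdefault(rec.chemical_id, rec.chemical_name)

    def _filtered(sets: Dict[str, set]) -> Dict[str, FrozenSet[str]]:
        return {
            c: frozenset(s)
            for c, s in sorted(sets.items())
            if len(s) >= min_size
        }

    composite: Dict[str, set] = {}
    for c in set(up) | set(down):
        composite[c] = up.get(c, set()) | down.get(c, set())

    libraries = {
        "composite": ChemicalLibrary("composite", _filtered(composite), universe, names),
        "up": ChemicalLibrary("up", _filtered(up), universe, names),
        "down": ChemicalLibrary("down", _filtered(down), universe, names),
    }
    for dialect, lib in libraries.items():
        lo, hi = lib.size_range()
        logger.info(
            "library %s: %d chemicals, %d-%d genes per set", dialect, len(lib), lo, hi
        )
    return libraries
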