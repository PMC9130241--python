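"""Regulator-target interaction tables and multi-source consensus mapping.

Loads lncRNA-miRNA and miRNA-mRNA pair tables (TSV dialect: columns
``regulator``, ``target``, optional extras), intersects the miRNA-target
sources into a consensus map, and restricts pair lists to differentially
expressed molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionTable",
    "ConsensusTargetMap",
    "load_interaction_table",
    "write_interaction_table",
    "consensus_targets",
    "filter_pairs_to_de",
]


@dataclass(frozen=True)
class InteractionTable:
    """De-duplicated set of (regulator, target) pairs from one source."""

    source: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for reg, tgt in self.pairs:
            if not reg or not tgt:
                raise ValueError("regulator and target IDs must be non-empty")


@dataclass
class ConsensusTargetMap:
    """miRNA-mRNA pairs supported by at least min_sources sources."""

    pairs: frozenset[tuple[str, str]]
    support: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    min_sources: int = 1


def load_interaction_table(path, source_label: str) -> InteractionTable:
    """Read a two-or-more-column TSV of regulator/target pairs.

    A header row naming the first two columns ``regulator``/``target``
    (any case) is tolerated; extra columns (e.g. scores) are ignored.
    Malformed rows raise with their line number.
    """
    pairs: set[tuple[str, str]] = set()
    n_rows = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >= 2 tab-separated fields")
            reg, tgt = fields[0].strip(), fields[1].strip()
            if lineno == 1 and reg.lower() == "regulator" and tgt.lower() == "target":
                continue
            if not reg or not tgt:
                raise ValueError(f"{path}: line {lineno}: empty regulator or target ID")
            n_rows += 1
            if (reg, tgt) in pairs:
                n_dup += 1
            pairs.add((reg, tgt))
    if n_rows == 0:
        logger.warning("%s: empty interaction table for source %s", path, source_label)
    logger.info(
        "loaded %s: %d rows, %d duplicates, %d unique pairs",
        source_label, n_rows, n_dup, len(pairs),
    )
    return InteractionTable(source=source_label, pairs=frozenset(pairs))


def write_interaction_table(table: InteractionTable, path) -> None:
    df = pd.DataFrame(sorted(table.pairs), columns=["regulator", "target"])
    df["source"] = table.source
    df.to_csv(path, sep="\t", index=False)


def consensus_targets(
    tables: list[InteractionTable], min_sources: int = 3
) -> ConsensusTargetMap:
    """Retain pairs appearing in >= min_sources distinct sources.

    The default (all three miRNA-target databases) is the strict
    intersection reading; lower it for a union-like map.
    """
    if not tables:
        raise ValueError("at least one interaction table required")
    if not 1 <= min_sources <= len(tables):
        raise ValueError(
            f"min_sources must lie in [1, {len(tables)}], got {min_sources}"
        )
    support: dict[tuple[str, str], set[str]] = {}
    for t in tables:
        for pair in t.pairs:
            support.setdefault(pair, set()).add(t.source)
    kept = {p: frozenset(s) for p, s in support.items() if len(s) >= min_sources}
    logger.info(
        "consensus: %d/%d pairs supported by >= %d sources",
        len(kept), len(support), min_sources,
    )
    return ConsensusTargetMap(
        pairs=frozenset(kept), support=kept, min_sources=min_sources
    )


def write_consensus(cmap: ConsensusTargetMap, path) -> None:
    rows = [
        {"mirna": m, "mrna": g, "sources": ",".join(sorted(cmap.support[(m, g)]))}
        for m, g in sorted(cmap.pairs)
    ]
    pd.DataFrame(rows, columns=["mirna", "mrna", "sources"]).to_csv(
        path, sep="\t", index=False
    )


def filter_pairs_to_de(
    lnc_mir: InteractionTable,
    consensus: ConsensusTargetMap,
    deg_lnc: dict[str, str],
    deg_mir: dict[str, str],
    deg_mrna: dict[str, str],
) -> tuple[frozenset[tuple[str, str]], frozenset[tuple[str, str]]]:
    """Keep only pairs whose both members are DEGs of their class.

    The DEG dicts map gene -> direction ("up"/"down"). An ID appearing in
    more than one class is a namespace collision and raises.
    """
    classes = [("lncRNA", set(deg_lnc)), ("miRNA", set(deg_mir)), ("mRNA", set(deg_mrna))]
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            clash = classes[i][1] & classes[j][1]
            if clash:
                raise ValueError(
                    f"ID(s) present in both {classes[i][0]} and {classes[j][0]} "
                    f"DEG sets: {sorted(clash)[:5]}"
                )
    lm = frozenset(
        (l, m) for l, m in lnc_mir.pairs if l in deg_lnc and m in deg_mir
    )
    mg = frozenset(
        (m, g) for m, g in consensus.pairs if m in deg_mir and g in deg_mrna
    )
    logger.info(
        "DE filter: %d/%d lnc-mir pairs, %d/%d mir-mRNA pairs retained",
        len(lm), len(lnc_mir.pairs), len(mg), len(consensus.pairs),
    )
    return lm, mg
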