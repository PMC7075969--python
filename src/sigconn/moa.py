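"""Second-order drug similarity and mechanism-of-action tallies.

Querying the database with a *drug's own* signature returns the compounds
whose transcriptional effect most resembles that drug; mechanism-of-action
(MOA) classes over-represented among the nearest neighbours suggest
candidate mechanisms for the query drug.  The tally itself is descriptive
— counting class labels among the top-k hits mirrors how such result
tables are read — with an optional hypergeometric over-representation
test against the database background as a clearly marked extension.
"""

from __future__ import annotations

import logging
import os
import re
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .connectivity import QueryConfig, QueryResult, run_query
from .errors import InputError, SchemaError
from .instance_db import InstanceDatabase
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = ["MoaAnnotation", "second_order_query", "class_tally"]

UNANNOTATED = "unannotated"


def _norm(name: str) -> str:
    """Case-insensitive, whitespace-normalised compound-name key."""
    return re.sub(r"\s+", " ", str(name).strip()).lower()


class MoaAnnotation:
    """Compound → MOA class labels (multi-label; unannotated allowed)."""

    def __init__(self, labels: Mapping[str, Iterable[str]]):
        self._labels: dict[str, tuple[str, ...]] = {}
        for compound, classes in labels.items():
            key = _norm(compound)
            merged = list(self._labels.get(key, ()))
            for cl in classes:
                if cl not in merged:
                    merged.append(cl)
            self._labels[key] = tuple(merged)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "MoaAnnotation":
        """Read a two-column TSV (compound, class), one row per label."""
        if not os.path.exists(path):
            raise InputError(f"annotation file not found: {path}")
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("compound", "class"):
            if col not in df.columns:
                raise SchemaError(f"annotation table missing column {col!r}")
        labels: dict[str, list[str]] = {}
        for compound, cl in zip(df["compound"], df["class"]):
            labels.setdefault(compound, []).append(cl)
        return cls(labels)

    def classes(self, compound: str) -> tuple[str, ...]:
        return self._labels.get(_norm(compound), ())

    def __len__(self) -> int:
        return len(self._labels)


def second_order_query(
    db: InstanceDatabase,
    drug_signature: GeneSignature,
    config: QueryConfig | None = None,
    k: int = 10,
) -> tuple[pd.DataFrame, QueryResult]:
    """Rank compounds by similarity to a drug's own signature; keep top k.

    Returns the top-k group table with a ``relation`` column — "similar"
    for positive similarity mean, "oppositional" for negative, "null" for
    zero — plus the full query result.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    result = run_query(db, drug_signature, config)
    n_groups = len(result.results)
    if k > n_groups:
        logger.warning(
            "second_order_query: k=%d exceeds the %d groups; returning all", k, n_groups
        )
        k = n_groups
    top = result.results.head(k).copy()
    top["relation"] = [
        "similar" if m > 0 else ("oppositional" if m < 0 else "null")
        for m in top["similarity_mean"]
    ]
    return top, result


def class_tally(
    hits: pd.DataFrame,
    annotations: MoaAnnotation,
    k: int,
    background: Sequence[str] | None = None,
    test: bool = False,
) -> pd.DataFrame:
    """Tally MOA classes among the top-k hits of a ranked result table.

    Distinct compounds are counted once per class label (a compound hit in
    two cell lines contributes once).  Hits without any annotation are
    tallied under ``"unannotated"``.  ``background`` is the compound set
    the database offers (defaults to every compound in ``hits``); with
    ``test``, a hypergeometric upper-tail over-representation p is added
    per class (empty for the "unannotated" row).
    """
    if k > len(hits):
        raise InputError(f"k={k} exceeds the {len(hits)} available hits")
    top_compounds = list(dict.fromkeys(_norm(c) for c in hits["compound"].head(k)))
    if background is None:
        background = list(hits["compound"])
    bg_compounds = list(dict.fromkeys(_norm(c) for c in background))

    def tally(compounds: Iterable[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cpd in compounds:
            classes = annotations.classes(cpd) or (UNANNOTATED,)
            for cl in classes:
                counts[cl] = counts.get(cl, 0) + 1
        return counts

    top_counts = tally(top_compounds)
    bg_counts = tally(bg_compounds)
    rows = []
    for cl in sorted(top_counts, key=lambda c: (-top_counts[c], c)):
        count, bg = top_counts[cl], bg_counts.get(cl, top_counts[cl])
        if test and cl != UNANNOTATED:
            # draw |top| compounds from |background|, bg of which carry cl
            p = float(
                hypergeom.sf(count - 1, len(bg_compounds), bg, len(top_compounds))
            )
        else:
            p = None
        rows.append(
            {
                "class": cl,
                "count_topk": count,
                "count_background": bg,
                "p_hypergeometric": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["class", "count_topk", "count_background", "p_hypergeometric"]
    )
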