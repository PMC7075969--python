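"""Up/down gene signatures: construction, cross-namespace mapping, GRP I/O.

A *signature* is a pair of disjoint, ordered tag sets — identifiers of
up-regulated and down-regulated genes (or probes) — describing either a
biological state (a disease signature built from a differential-expression
table) or a perturbation (a drug signature built from treated vs. control
expression matrices).  Signatures are the query objects consumed by
:mod:`sigconn.connectivity`.

Disease signatures start life in the organism's own namespace (e.g. mouse
gene symbols) and are mapped onto the probe namespace of the reference
database through an offline many-to-many lookup table
(:class:`ProbeMap`); no ortholog inference is attempted.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateEntryError,
    EmptySignatureError,
    InputError,
    SchemaError,
    AlignmentError,
    ConfigError,
    SizeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialExpressionRecord",
    "DeTable",
    "ProbeMap",
    "GeneSignature",
    "SelectionRule",
    "load_de_table",
    "build_disease_signature",
    "map_to_probes",
    "build_drug_signature",
    "read_grp",
    "write_grp",
    "read_signature",
    "write_signature",
]


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One row of a differential-expression table.

    ``log2fc`` is the signed log2 fold change of the condition of interest
    (mutant / treated) over the reference; ``qvalue`` the multiple-testing
    adjusted significance in [0, 1].
    """

    gene_id: str
    log2fc: float
    qvalue: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc not finite for {self.gene_id!r}")
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"qvalue out of [0,1] for {self.gene_id!r}")


@dataclass
class DeTable:
    """Parsed DE table: records in file order plus a malformed-row count."""

    records: list[DifferentialExpressionRecord]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneSignature:
    """Paired up/down tag sets defining a connectivity query.

    Tags within each side are ordered (insertion order is meaningful; the
    builders order by effect magnitude) and duplicate-free; the two sides
    are disjoint.  ``namespace`` labels the identifier space ("symbol",
    "probe", ...); ``provenance`` records how the signature was built.
    """

    up_tags: tuple[str, ...] = ()
    down_tags: tuple[str, ...] = ()
    namespace: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side, tags in (("up", self.up_tags), ("down", self.down_tags)):
            if len(set(tags)) != len(tags):
                raise ValueError(f"duplicate tags in {side} set")
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise ValueError(f"up/down sets not disjoint: {sorted(overlap)[:5]}")

    @property
    def is_empty(self) -> bool:
        return not self.up_tags and not self.down_tags

    def require_nonempty(self) -> "GeneSignature":
        if self.is_empty:
            raise EmptySignatureError("both signature sides are empty")
        return self

    def swapped(self) -> "GeneSignature":
        """Return the signature with up and down sides exchanged."""
        return GeneSignature(
            self.down_tags,
            self.up_tags,
            self.namespace,
            {**self.provenance, "swapped": True},
        )


class ProbeMap:
    """Many-to-many gene → probe lookup table.

    Absent genes map to the empty tuple, never an error.  Duplicate
    (gene, probe) pairs are collapsed on construction.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]], target_namespace: str = "probe"):
        table: dict[str, list[str]] = {}
        seen: set[tuple[str, str]] = set()
        for gene, probe in pairs:
            key = (gene, probe)
            if key in seen:
                continue
            seen.add(key)
            table.setdefault(gene, []).append(probe)
        self._table = {g: tuple(ps) for g, ps in table.items()}
        self.target_namespace = target_namespace

    @classmethod
    def from_tsv(
        cls,
        path: str | os.PathLike,
        gene_col: str = "gene_id",
        probe_col: str = "probe_id",
        target_namespace: str = "probe",
    ) -> "ProbeMap":
        if not os.path.exists(path):
            raise InputError(f"probe map not found: {path}")
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in (gene_col, probe_col):
            if col not in df.columns:
                raise SchemaError(f"probe map missing column {col!r}")
        return cls(zip(df[gene_col], df[probe_col]), target_namespace)

    def lookup(self, gene: str) -> tuple[str, ...]:
        return self._table.get(gene, ())

    def __len__(self) -> int:
        return len(self._table)

    @property
    def target_probes(self) -> set[str]:
        return {p for ps in self._table.values() for p in ps}


def load_de_table(
    path: str | os.PathLike,
    column_spec: Mapping[str, str] | None = None,
) -> DeTable:
    """Read a tab-separated differential-expression table.

    ``column_spec`` maps the logical names ``gene``, ``log2fc`` and
    ``qvalue`` to the actual header names (defaults are the logical names
    themselves).  Rows whose numeric fields do not parse, or whose values
    violate the record invariants, are skipped and counted; order of the
    surviving rows is preserved.
    """
    spec = {"gene": "gene", "log2fc": "log2fc", "qvalue": "qvalue"}
    if column_spec:
        spec.update(column_spec)
    if not os.path.exists(path):
        raise InputError(f"DE table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for logical, col in spec.items():
        if col not in df.columns:
            raise SchemaError(f"DE table missing column {col!r} (for {logical})")
    records: list[DifferentialExpressionRecord] = []
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            rec = DifferentialExpressionRecord(
                gene_id=str(row[spec["gene"]]),
                log2fc=float(row[spec["log2fc"]]),
                qvalue=float(row[spec["qvalue"]]),
            )
        except (TypeError, ValueError):
            n_skipped += 1
            continue
        records.append(rec)
    if n_skipped:
        logger.warning("load_de_table: skipped %d malformed rows in %s", n_skipped, path)
    if not records:
        logger.warning("load_de_table: no valid rows in %s", path)
    return DeTable(records, n_skipped)


def build_disease_signature(
    records: Iterable[DifferentialExpressionRecord],
    q_threshold: float = 0.05,
    top_k: int | None = None,
) -> GeneSignature:
    """Select significant up/down genes into a disease signature.

    Genes with ``qvalue <= q_threshold`` enter the side given by the sign of
    their log2 fold change (zero fold changes are excluded).  Each side is
    ordered by decreasing |log2fc| (ties broken by gene identifier) and, if
    ``top_k`` is given, truncated to its ``top_k`` strongest genes.
    """
    if not (0.0 < q_threshold <= 1.0):
        raise ConfigError(f"q_threshold must be in (0,1], got {q_threshold}")
    if top_k is not None and top_k < 1:
        raise ConfigError(f"top_k must be >= 1, got {top_k}")
    up = [r for r in records if r.qvalue <= q_threshold and r.log2fc > 0]
    down = [r for r in records if r.qvalue <= q_threshold and r.log2fc < 0]
    key = lambda r: (-abs(r.log2fc), r.gene_id)
    up.sort(key=key)
    down.sort(key=key)
    if top_k is not None:
        up, down = up[:top_k], down[:top_k]
    sig = GeneSignature(
        up_tags=tuple(r.gene_id for r in up),
        down_tags=tuple(r.gene_id for r in down),
        namespace="gene",
        provenance={"builder": "disease", "q_threshold": q_threshold, "top_k": top_k},
    )
    return sig.require_nonempty()


def map_to_probes(
    sig: GeneSignature,
    probe_map: ProbeMap,
    case_fold: bool = False,
) -> GeneSignature:
    """Translate a gene signature into the probe namespace of a database.

    Each gene expands to all of its mapped probes.  Unmapped genes are
    dropped and counted; a probe reached from both an up and a down gene is
    removed from both sides and counted as a conflict.  With ``case_fold``,
    gene symbols are upper-cased before lookup (the usual mouse symbol →
    human symbol convention).  Counts land in the output provenance.
    """
    if len(probe_map) == 0:
        raise ConfigError("probe map is empty")

    def expand(tags: Sequence[str]) -> tuple[list[str], list[str]]:
        probes: list[str] = []
        seen: set[str] = set()
        dropped: list[str] = []
        for gene in tags:
            hits = probe_map.lookup(gene.upper() if case_fold else gene)
            if not hits:
                dropped.append(gene)
                continue
            for p in hits:
                if p not in seen:
                    seen.add(p)
                    probes.append(p)
        return probes, dropped

    up_probes, up_dropped = expand(sig.up_tags)
    down_probes, down_dropped = expand(sig.down_tags)
    conflicts = set(up_probes) & set(down_probes)
    up_probes = [p for p in up_probes if p not in conflicts]
    down_probes = [p for p in down_probes if p not in conflicts]
    if up_dropped or down_dropped or conflicts:
        logger.info(
            "map_to_probes: dropped %d unmapped genes, removed %d conflicting probes",
            len(up_dropped) + len(down_dropped),
            len(conflicts),
        )
    return GeneSignature(
        up_tags=tuple(up_probes),
        down_tags=tuple(down_probes),
        namespace=probe_map.target_namespace,
        provenance={
            **sig.provenance,
            "mapped_from": sig.namespace,
            "case_fold": case_fold,
            "n_dropped": len(up_dropped) + len(down_dropped),
            "dropped_genes": tuple(up_dropped + down_dropped),
            "n_conflicts": len(conflicts),
            "conflict_probes": tuple(sorted(conflicts)),
        },
    )


@dataclass(frozen=True)
class SelectionRule:
    """How drug-signature probes are selected from the amplitude ranking.

    ``method="rank"`` takes the ``top`` largest and ``bottom`` smallest
    amplitudes; ``method="threshold"`` takes amplitudes ``>= up_threshold``
    and ``<= down_threshold``.  ``amplitude`` chooses the per-probe
    statistic: ``"difference"`` (mean treated − mean control, for matrices
    already on a log-like scale) or ``"log_ratio"``
    (log2 of the ratio of means of linear intensities).
    """

    method: str = "rank"
    top: int = 50
    bottom: int = 50
    up_threshold: float | None = None
    down_threshold: float | None = None
    amplitude: str = "difference"

    def __post_init__(self) -> None:
        if self.method not in ("rank", "threshold"):
            raise ConfigError(f"unknown selection method {self.method!r}")
        if self.amplitude not in ("difference", "log_ratio"):
            raise ConfigError(f"unknown amplitude mode {self.amplitude!r}")
        if self.method == "rank" and (self.top < 1 or self.bottom < 1):
            raise ConfigError("rank selection needs top >= 1 and bottom >= 1")
        if self.method == "threshold" and (
            self.up_threshold is None or self.down_threshold is None
        ):
            raise ConfigError("threshold selection needs up_threshold and down_threshold")


def build_drug_signature(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    selection: SelectionRule | None = None,
) -> GeneSignature:
    """Build a perturbation signature from treated vs. control matrices.

    Both matrices are probes × samples with probe identifiers as index.
    The per-probe amplitude is the difference of sample means (or the
    log-ratio of means, per the rule); probes are ordered by decreasing
    amplitude with lexicographic tie-breaks, and the selection rule picks
    the up and down tag sets.
    """
    selection = selection or SelectionRule()
    if treated.shape[1] < 1 or control.shape[1] < 1:
        raise SizeError("treated and control need at least one column each")
    if set(treated.index) != set(control.index):
        diff = set(treated.index) ^ set(control.index)
        raise AlignmentError(
            f"treated/control probe universes differ (symmetric difference {len(diff)})"
        )
    control = control.loc[treated.index]
    if selection.amplitude == "difference":
        amp = treated.mean(axis=1) - control.mean(axis=1)
    else:
        amp = np.log2(treated.mean(axis=1) / control.mean(axis=1))
    order = sorted(amp.index, key=lambda p: (-amp[p], p))
    if selection.method == "rank":
        up = order[: selection.top]
        down = order[-selection.bottom :][::-1]  # strongest-down first
        overlap = set(up) & set(down)
        up = [p for p in up if p not in overlap]
        down = [p for p in down if p not in overlap]
    else:
        up = [p for p in order if amp[p] >= selection.up_threshold]
        down = [p for p in reversed(order) if amp[p] <= selection.down_threshold]
    sig = GeneSignature(
        up_tags=tuple(up),
        down_tags=tuple(down),
        namespace="probe",
        provenance={"builder": "drug", "selection": selection.__dict__.copy()},
    )
    return sig.require_nonempty()


def read_grp(path: str | os.PathLike) -> tuple[str, ...]:
    """Read a GRP file: one identifier per line; '#' comments and blank
    lines ignored; duplicates are an error."""
    if not os.path.exists(path):
        raise InputError(f"GRP file not found: {path}")
    tags: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            ident = line.strip()
            if not ident or ident.startswith("#"):
                continue
            if ident in seen:
                raise DuplicateEntryError(f"duplicate identifier {ident!r} in {path}")
            seen.add(ident)
            tags.append(ident)
    return tuple(tags)


def write_grp(tags: Iterable[str], path: str | os.PathLike) -> None:
    """Write identifiers one per line (no comments, no blank lines)."""
    with open(path, "w") as fh:
        for ident in tags:
            fh.write(f"{ident}\n")


def read_signature(
    up_path: str | os.PathLike,
    down_path: str | os.PathLike,
    namespace: str = "probe",
) -> GeneSignature:
    """Load a signature from an ``_up.grp`` / ``_down.grp`` pair."""
    return GeneSignature(
        up_tags=read_grp(up_path),
        down_tags=read_grp(down_path),
        namespace=namespace,
        provenance={"up_path": str(up_path), "down_path": str(down_path)},
    ).require_nonempty()


def write_signature(sig: GeneSignature, prefix: str | os.PathLike) -> tuple[str, str]:
    """Write a signature as ``<prefix>_up.grp`` and ``<prefix>_down.grp``."""
    up_path, down_path = f"{prefix}_up.grp", f"{prefix}_down.grp"
    write_grp(sig.up_tags, up_path)
    write_grp(sig.down_tags, down_path)
    return up_path, down_path
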