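"""Drug-perturbation instances as ranked probe profiles.

An *instance* is one treatment experiment (compound × cell line × arrays)
reduced to a full ranking of the probe universe by treatment-induced
expression change.  Rank 1 is the probe most up-regulated by the
treatment, rank n the most down-regulated — every downstream score's sign
depends on this convention.  Ranks, not raw amplitudes, are the persisted
unit: the KS scoring in :mod:`sigconn.connectivity` consumes ranks only,
which makes the database format normalization-free.

On disk a database is a rank-matrix TSV (first column ``probe_id``, one
integer column per instance) plus a metadata TSV (``instance_id``,
``compound``, ``cell_line``, extra columns preserved).  Gzip-compressed
variants are read and written transparently (pandas infers from the
``.gz`` suffix).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    IdentifierError,
    InputError,
    JoinError,
    SizeError,
    ValidationError,
)

__all__ = [
    "InstanceProfile",
    "InstanceDatabase",
    "rank_profile_from_amplitudes",
    "ranks_from_amplitudes",
    "build_database",
    "read_rank_matrix",
    "write_rank_matrix",
]

META_COLUMNS = ("compound", "cell_line")


def ranks_from_amplitudes(amplitudes: np.ndarray, probe_ids: Sequence[str]) -> np.ndarray:
    """Rank amplitudes: 1 = largest, n = smallest; ties broken by probe id.

    Vectorised core shared by :func:`rank_profile_from_amplitudes` and the
    synthetic generator.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(amplitudes)):
        raise ValidationError("amplitudes must all be finite")
    probe_arr = np.asarray(probe_ids)
    # lexsort: last key is primary -> descending amplitude, then probe id.
    order = np.lexsort((probe_arr, -amplitudes))
    ranks = np.empty(len(amplitudes), dtype=np.int64)
    ranks[order] = np.arange(1, len(amplitudes) + 1)
    return ranks


@dataclass
class InstanceProfile:
    """One instance: a bijective probe → rank mapping plus metadata."""

    instance_id: str
    compound: str
    cell_line: str
    ranks: pd.Series  # index: probe ids, values: ranks 1..n
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ranks = self.ranks.astype(np.int64)
        n = len(self.ranks)
        if n < 2:
            raise SizeError(f"instance {self.instance_id!r}: need >= 2 probes, got {n}")
        values = np.sort(self.ranks.to_numpy())
        if not np.array_equal(values, np.arange(1, n + 1)):
            raise ValidationError(
                f"instance {self.instance_id!r}: ranks are not a permutation of 1..{n}"
            )

    @property
    def n(self) -> int:
        return len(self.ranks)


def rank_profile_from_amplitudes(
    amplitudes: Mapping[str, float] | pd.Series,
    instance_id: str,
    compound: str,
    cell_line: str,
    **extra,
) -> InstanceProfile:
    """Turn per-probe amplitudes (treated − control change) into a profile.

    The largest amplitude gets rank 1, the smallest rank n; exact ties are
    broken lexicographically by probe identifier so the ranking is
    platform-independent.
    """
    series = pd.Series(amplitudes, dtype=float)
    if len(series) < 2:
        raise SizeError(f"instance {instance_id!r}: need >= 2 probes, got {len(series)}")
    ranks = ranks_from_amplitudes(series.to_numpy(), series.index.to_numpy())
    return InstanceProfile(
        instance_id=instance_id,
        compound=compound,
        cell_line=cell_line,
        ranks=pd.Series(ranks, index=series.index),
        extra=dict(extra),
    )


@dataclass
class InstanceDatabase:
    """A searchable collection of instances over one probe universe.

    ``matrix`` is probes × instances (int ranks); ``meta`` is indexed by
    instance id with at least ``compound`` and ``cell_line`` columns, in
    matrix column order.
    """

    probe_ids: pd.Index
    matrix: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.probe_ids = pd.Index(self.probe_ids)
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(self.probe_ids), len(self.meta)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.meta)} instances"
            )
        if self.N < 1:
            raise SizeError("database needs at least one instance")
        if self.meta.index.has_duplicates:
            dups = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate instance ids: {dups[:5]}")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise JoinError(f"metadata missing column {col!r}")
        self.validate_permutations()

    @property
    def n(self) -> int:
        """Probe-universe size."""
        return len(self.probe_ids)

    @property
    def N(self) -> int:
        """Number of instances."""
        return len(self.meta)

    @property
    def instance_ids(self) -> list[str]:
        return list(self.meta.index)

    def validate_permutations(self) -> None:
        expected = np.arange(1, self.n + 1)
        sorted_cols = np.sort(self.matrix, axis=0)
        bad = np.nonzero(~np.all(sorted_cols == expected[:, None], axis=0))[0]
        if bad.size:
            raise ValidationError(
                f"instance {self.meta.index[bad[0]]!r}: rank column is not a "
                f"permutation of 1..{self.n}"
            )

    def profile(self, instance_id: str) -> InstanceProfile:
        j = self.meta.index.get_loc(instance_id)
        row = self.meta.iloc[j]
        return InstanceProfile(
            instance_id=instance_id,
            compound=row["compound"],
            cell_line=row["cell_line"],
            ranks=pd.Series(self.matrix[:, j], index=self.probe_ids),
        )


def build_database(profiles: Sequence[InstanceProfile]) -> InstanceDatabase:
    """Assemble validated profiles into a database.

    All profiles must share one probe universe (the first profile's probe
    order becomes canonical); instance ids must be unique.
    """
    if not profiles:
        raise SizeError("need at least one profile")
    probe_ids = profiles[0].ranks.index
    universe = set(probe_ids)
    columns = []
    for p in profiles:
        if set(p.ranks.index) != universe:
            diff = set(p.ranks.index) ^ universe
            raise AlignmentError(
                f"instance {p.instance_id!r}: probe universe differs "
                f"(symmetric difference {len(diff)})"
            )
        columns.append(p.ranks.reindex(probe_ids).to_numpy())
    ids = [p.instance_id for p in profiles]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise IdentifierError(f"duplicate instance ids: {dups[:5]}")
    meta = pd.DataFrame(
        {
            "compound": [p.compound for p in profiles],
            "cell_line": [p.cell_line for p in profiles],
        },
        index=pd.Index(ids, name="instance_id"),
    )
    return InstanceDatabase(probe_ids=probe_ids, matrix=np.column_stack(columns), meta=meta)


def read_rank_matrix(
    path: str | os.PathLike, meta_path: str | os.PathLike
) -> InstanceDatabase:
    """Load a database from a rank-matrix TSV and its metadata TSV."""
    for p in (path, meta_path):
        if not os.path.exists(p):
            raise InputError(f"file not found: {p}")
    matrix_df = pd.read_csv(path, sep="\t", index_col="probe_id")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("instance_id")
    matrix_only = [c for c in matrix_df.columns if c not in meta.index]
    if matrix_only:
        raise JoinError(f"matrix instance {matrix_only[0]!r} absent from metadata")
    meta_only = [i for i in meta.index if i not in set(matrix_df.columns)]
    if meta_only:
        raise JoinError(f"metadata instance {meta_only[0]!r} absent from matrix")
    meta = meta.loc[list(matrix_df.columns)]
    if not np.issubdtype(matrix_df.to_numpy().dtype, np.integer):
        try:
            matrix_df = matrix_df.astype(np.int64)
        except ValueError as exc:
            raise ValidationError(f"non-integer ranks in {path}: {exc}") from exc
    return InstanceDatabase(
        probe_ids=matrix_df.index, matrix=matrix_df.to_numpy(), meta=meta
    )


def write_rank_matrix(
    db: InstanceDatabase, path: str | os.PathLike, meta_path: str | os.PathLike
) -> None:
    """Write the rank matrix and metadata TSVs (``.gz`` suffix compresses)."""
    matrix_df = pd.DataFrame(db.matrix, index=db.probe_ids, columns=db.meta.index)
    matrix_df.index.name = "probe_id"
    matrix_df.to_csv(path, sep="\t")
    db.meta.to_csv(meta_path, sep="\t")
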