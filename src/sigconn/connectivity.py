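"""Connectivity scoring of a signature against an instance database.

The scoring scheme is the classic connectivity-map procedure:

1.  For each instance, the up and the down tag set of the query are each
    scored with a signed Kolmogorov–Smirnov enrichment statistic ``es``
    against the instance's probe ranking.  With tag ranks
    ``V(1) < ... < V(t)`` in a list of length ``n``::

        a  = max_j ( j/t  −  V(j)/n )        (tags crowd the top)
        b  = max_j ( V(j)/n − (j−1)/t )      (tags crowd the bottom)
        es = a  if a ≥ b  else  −b

    so ``es`` is the signed sup-deviation between the tag step function
    and the uniform reference; ``es = +1`` means the tags sit at the very
    top of the ranking.

2.  The raw bidirectional score is ``s = es_up − es_down`` when the two
    statistics disagree in sign (the informative case: query-up genes
    pushed one way, query-down genes the other); when both point the same
    way the instance is *null*, ``s = 0``.

3.  Raw scores are scaled database-wide: positive ``s`` by the maximum
    positive score ``p_max``, negative by the most negative ``q_min``,
    giving connectivity scores ``c`` in [−1, 1] with at least one instance
    at each attained extreme.

4.  Instances are grouped by compound (or compound × cell line); a group's
    *similarity mean* is the mean of its members' ``c``, its *enrichment*
    the same KS statistic applied to the group's positions within all N
    instances ordered by descending ``c``, and its *p-value* the fraction
    of random same-size instance sets whose enrichment is at least as
    extreme (exact enumeration when the number of subsets is small).

5.  Groups are ranked by (p ascending, |enrichment| descending,
    |similarity mean| descending, group key).

A *negative* similarity mean marks a compound whose transcriptional effect
opposes the query state — the drug-repurposing hypothesis selects exactly
those compounds when the query is a disease signature.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, asdict
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError, InputError
from .instance_db import InstanceDatabase
from .signatures import GeneSignature

logger = logging.getLogger(__name__)

__all__ = [
    "KSResult",
    "InstanceConnectivity",
    "ScalingFactors",
    "CompoundResult",
    "QueryConfig",
    "QueryResult",
    "ks_statistic",
    "instance_connectivity",
    "scale_scores",
    "aggregate_compound",
    "set_enrichment",
    "permutation_p",
    "sample_null_enrichment",
    "enumerate_null_enrichment",
    "rank_results",
    "run_query",
    "write_results_tsv",
    "write_instances_tsv",
]

RESULT_COLUMNS = [
    "rank",
    "group_key",
    "compound",
    "cell_line",
    "n_instances",
    "similarity_mean",
    "enrichment",
    "p_value",
    "n_nonnull",
]
INSTANCE_COLUMNS = ["instance_id", "compound", "cell_line", "ks_up", "ks_down", "s", "c"]


@dataclass(frozen=True)
class KSResult:
    """Signed KS enrichment statistic with both one-sided deviations.

    ``a`` and ``b`` are exposed so audits can detect the a = b tie, which
    deterministically resolves to the positive branch.
    """

    es: float
    a: float
    b: float
    t: int
    n: int


@dataclass
class InstanceConnectivity:
    """Per-instance scores; ``c`` is filled in after database-wide scaling."""

    instance_id: str
    ks_up: KSResult | None
    ks_down: KSResult | None
    s: float
    c: float | None = None


@dataclass(frozen=True)
class ScalingFactors:
    """Database-wide scaling extremes: p_max ≥ 0 ≥ q_min."""

    p_max: float
    q_min: float


@dataclass
class CompoundResult:
    """Group-level result row (one compound or compound × cell line)."""

    group_key: str
    compound: str
    cell_line: str
    n: int
    similarity_mean: float
    n_nonnull: int
    enrichment: float = np.nan
    p_value: float = np.nan
    rank: int = 0


@dataclass(frozen=True)
class QueryConfig:
    """Query-time knobs.

    ``direction_rule`` sets the permutation tail: ``"signed"`` counts null
    sets with the same sign and at-least-as-large |es| (one-sided,
    direction-aware, the default); ``"absolute"`` ignores the sign.
    ``include_null_instances`` keeps s = 0 members in the similarity-mean
    denominator (on by default: the group statistic covers *all* arrays of
    a compound).  Exact enumeration replaces sampling whenever
    C(N, group size) ≤ ``enumeration_cap``.  ``pseudo_count`` reports
    (count+1)/(n_perm+1) instead of count/n_perm, avoiding exact zeros.
    """

    group_by: str = "compound_cell_line"
    n_perm: int = 100_000
    seed: int = 0
    direction_rule: str = "signed"
    include_null_instances: bool = True
    enumeration_cap: int = 100_000
    pseudo_count: bool = False

    def __post_init__(self) -> None:
        if self.group_by not in ("compound", "compound_cell_line"):
            raise ConfigError(f"unknown group_by {self.group_by!r}")
        if self.direction_rule not in ("signed", "absolute"):
            raise ConfigError(f"unknown direction_rule {self.direction_rule!r}")
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")


@dataclass
class QueryResult:
    """Ranked group table + per-instance table + provenance."""

    results: pd.DataFrame
    instances: pd.DataFrame
    scaling: ScalingFactors
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# KS core


def _es_batch(V: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised KS statistic for many tag-rank vectors at once.

    ``V`` is (m, t), each row sorted ascending.  Returns (es, a, b) arrays.
    """
    t = V.shape[1]
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - V / n).max(axis=1)
    b = (V / n - (j - 1) / t).max(axis=1)
    return np.where(a >= b, a, -b), a, b


def ks_statistic(tag_ranks: Sequence[int], n: int) -> KSResult:
    """Signed KS enrichment of a sorted tag-rank vector in a list of length n.

    ``tag_ranks`` must be strictly increasing integers within 1..n.
    The a = b tie resolves to the positive branch.
    """
    V = np.asarray(tag_ranks, dtype=np.int64)
    t = len(V)
    if t < 1 or t > n:
        raise InputError(f"need 1 <= t <= n, got t={t}, n={n}")
    if V[0] < 1 or V[-1] > n or (t > 1 and np.any(np.diff(V) <= 0)):
        raise InputError("tag ranks must be strictly increasing within 1..n")
    es, a, b = _es_batch(V[None, :].astype(float), n)
    return KSResult(es=float(es[0]), a=float(a[0]), b=float(b[0]), t=t, n=n)


# ---------------------------------------------------------------------------
# Instance-level scoring


def _combine(es_up: float | None, es_down: float | None) -> float:
    """Raw score s from the two one-sided statistics.

    Bidirectional queries: s = es_up − es_down unless both share a strict
    sign (then 0).  One-sided queries keep the sign convention of the
    bidirectional formula: s = +es_up, or s = −es_down.
    """
    if es_up is None and es_down is None:
        raise CoverageError("both signature sides empty")
    if es_down is None:
        return es_up
    if es_up is None:
        return -es_down
    if (es_up > 0 and es_down > 0) or (es_up < 0 and es_down < 0):
        return 0.0
    return es_up - es_down


def instance_connectivity(
    profile, query: GeneSignature
) -> InstanceConnectivity:
    """Score one instance profile against a query signature (c left unset).

    Query tags must already lie within the profile's probe universe
    (``run_query`` filters and counts absentees beforehand).
    """
    n = profile.n

    def side(tags: Sequence[str]) -> KSResult | None:
        if not tags:
            return None
        missing = [t for t in tags if t not in profile.ranks.index]
        if missing:
            raise CoverageError(f"tags absent from probe universe: {missing[:5]}")
        ranks = np.sort(profile.ranks.loc[list(tags)].to_numpy())
        return ks_statistic(ranks, n)

    ks_up = side(query.up_tags)
    ks_down = side(query.down_tags)
    s = _combine(
        None if ks_up is None else ks_up.es,
        None if ks_down is None else ks_down.es,
    )
    return InstanceConnectivity(
        instance_id=profile.instance_id, ks_up=ks_up, ks_down=ks_down, s=s
    )


def scale_scores(all_s: Sequence[float]) -> tuple[ScalingFactors, np.ndarray]:
    """Scale raw scores to connectivity scores c in [−1, 1].

    Positive s divide by the database maximum p_max, negative by the
    database minimum q_min (so the extreme instances attain ±1); zeros stay
    zero.  c depends on s only through positive rescaling.
    """
    s = np.asarray(all_s, dtype=float)
    if s.size < 1:
        raise InputError("need at least one instance score")
    pos, neg = s[s > 0], s[s < 0]
    p_max = float(pos.max()) if pos.size else 0.0
    q_min = float(neg.min()) if neg.size else 0.0
    c = np.zeros_like(s)
    if p_max > 0:
        c[s > 0] = s[s > 0] / p_max
    if q_min < 0:
        c[s < 0] = -(s[s < 0] / q_min)
    return ScalingFactors(p_max=p_max, q_min=q_min), c


# ---------------------------------------------------------------------------
# Group-level statistics


def _group_keys(meta: pd.DataFrame, group_by: str) -> pd.Series:
    if group_by == "compound":
        return meta["compound"].astype(str)
    return meta["compound"].astype(str) + "::" + meta["cell_line"].astype(str)


def aggregate_compound(
    scores: Sequence[InstanceConnectivity],
    meta: pd.DataFrame,
    config: QueryConfig,
) -> list[CompoundResult]:
    """Group instances and compute each group's similarity mean.

    ``n`` is always the total member count ("number of arrays"); when
    ``include_null_instances`` is off the mean runs over the non-null
    members only (a group of all-null instances gets mean 0).
    """
    by_id = {sc.instance_id: sc for sc in scores}
    keys = _group_keys(meta, config.group_by)
    out: list[CompoundResult] = []
    for key in sorted(keys.unique()):
        ids = keys.index[keys == key]
        member_c = np.array([by_id[i].c for i in ids], dtype=float)
        nonnull = np.array([by_id[i].s != 0.0 for i in ids])
        if config.include_null_instances or not nonnull.any():
            mean = float(member_c.mean()) if config.include_null_instances else 0.0
        else:
            mean = float(member_c[nonnull].mean())
        first = meta.loc[ids[0]]
        out.append(
            CompoundResult(
                group_key=key,
                compound=str(first["compound"]),
                cell_line=str(first["cell_line"]) if config.group_by != "compound" else "",
                n=len(ids),
                similarity_mean=mean,
                n_nonnull=int(nonnull.sum()),
            )
        )
    return out


def _tie_key(instance_id: str) -> str:
    """Deterministic, group-uncorrelated tie-break key for equal c values."""
    import hashlib

    return hashlib.md5(instance_id.encode()).hexdigest()


def set_enrichment(member_positions: Sequence[int], n_members: int, N: int) -> float:
    """KS enrichment of a group's positions within the c-ordered instance list.

    Positions are 1-based within all N instances sorted by descending c
    (ties broken upstream by a hash of the instance identifier).
    """
    if n_members != len(member_positions):
        raise InputError("n_members does not match positions")
    return ks_statistic(member_positions, N).es


def sample_null_enrichment(
    n_members: int, N: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n_perm uniform random n_members-subsets of 1..N; return their es.

    Subsets are without replacement within a draw, draws independent.
    Chunked so memory stays modest at the 100,000-draw default.
    """
    out = np.empty(n_perm, dtype=float)
    chunk = max(1, 2_000_000 // N)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        u = rng.random((m, N))
        picks = np.argpartition(u, n_members - 1, axis=1)[:, :n_members]
        V = np.sort(picks + 1, axis=1).astype(float)
        out[done : done + m] = _es_batch(V, N)[0]
        done += m
    return out


def enumerate_null_enrichment(n_members: int, N: int) -> np.ndarray:
    """es of every n_members-subset of 1..N (exact null distribution)."""
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(1, N + 1), n_members)),
        dtype=np.int64,
        count=comb(N, n_members) * n_members,
    ).reshape(-1, n_members)
    return _es_batch(combos.astype(float), N)[0]


def _tail_p(observed: float, null_es: np.ndarray, direction_rule: str) -> float:
    if direction_rule == "absolute":
        count = int(np.count_nonzero(np.abs(null_es) >= abs(observed)))
    elif observed > 0:
        count = int(np.count_nonzero(null_es >= observed))
    elif observed < 0:
        count = int(np.count_nonzero(null_es <= observed))
    else:
        return 1.0
    return count / len(null_es)


def permutation_p(
    observed: float,
    n_members: int,
    N: int,
    config: QueryConfig,
    rng: np.random.Generator | None = None,
    null_es: np.ndarray | None = None,
) -> float:
    """Empirical p-value of a group's enrichment.

    Exact enumeration of all C(N, n_members) subsets when that count is
    within ``config.enumeration_cap``; otherwise ``config.n_perm`` sampled
    subsets.  A pre-computed null (``null_es``) may be supplied so groups
    of equal size share one sample.  p may be exactly 0 in sampling mode
    unless ``pseudo_count`` is on.
    """
    if not (1 <= n_members <= N):
        raise InputError(f"need 1 <= n_members <= N, got {n_members}, {N}")
    if null_es is None:
        if comb(N, n_members) <= config.enumeration_cap:
            null_es = enumerate_null_enrichment(n_members, N)
        else:
            if rng is None:
                rng = np.random.default_rng(config.seed)
            null_es = sample_null_enrichment(n_members, N, config.n_perm, rng)
    p = _tail_p(observed, null_es, config.direction_rule)
    if config.pseudo_count:
        p = (p * len(null_es) + 1) / (len(null_es) + 1)
    return p


def rank_results(groups: Iterable[CompoundResult]) -> list[CompoundResult]:
    """Sort groups by (p ↑, |enrichment| ↓, |similarity mean| ↓, key) and
    assign 1-based ranks."""
    ordered = sorted(
        groups,
        key=lambda g: (
            g.p_value,
            -abs(g.enrichment),
            -abs(g.similarity_mean),
            g.group_key,
        ),
    )
    for i, g in enumerate(ordered, start=1):
        g.rank = i
    return ordered


# ---------------------------------------------------------------------------
# Full query


def _filter_tags(
    tags: Sequence[str], universe: set[str]
) -> tuple[tuple[str, ...], int]:
    kept = tuple(t for t in tags if t in universe)
    return kept, len(tags) - len(kept)


def run_query(
    db: InstanceDatabase, query: GeneSignature, config: QueryConfig | None = None
) -> QueryResult:
    """Score a signature against a database end to end.

    Pipeline: filter query tags to the probe universe → per-instance KS
    scores and raw s → database-wide scaling to c → group aggregation →
    group enrichment in the c-ordering → empirical permutation p → final
    ranking.  Deterministic given (inputs, config.seed).
    """
    config = config or QueryConfig()
    query.require_nonempty()
    universe = set(db.probe_ids)
    up, up_dropped = _filter_tags(query.up_tags, universe)
    down, down_dropped = _filter_tags(query.down_tags, universe)
    if up_dropped or down_dropped:
        logger.info(
            "run_query: dropped %d query tags absent from probe universe",
            up_dropped + down_dropped,
        )
    if not up and not down:
        raise CoverageError("no query tag overlaps the database probe universe")
    n, N = db.n, db.N

    # Per-instance KS, vectorised across instances.
    pos = {p: i for i, p in enumerate(db.probe_ids)}

    def side_es(tags: tuple[str, ...]) -> np.ndarray | None:
        if not tags:
            return None
        rows = np.array([pos[t] for t in tags])
        V = np.sort(db.matrix[rows, :], axis=0).T.astype(float)  # (N, t)
        return _es_batch(V, n)[0]

    es_up = side_es(up)
    es_down = side_es(down)
    if es_up is None:
        s = -es_down
    elif es_down is None:
        s = es_up.copy()
    else:
        same_strict = ((es_up > 0) & (es_down > 0)) | ((es_up < 0) & (es_down < 0))
        s = np.where(same_strict, 0.0, es_up - es_down)

    scaling, c = scale_scores(s)
    ids = db.instance_ids
    scores = [
        InstanceConnectivity(
            instance_id=ids[i],
            ks_up=None if es_up is None else KSResult(float(es_up[i]), np.nan, np.nan, len(up), n),
            ks_down=None
            if es_down is None
            else KSResult(float(es_down[i]), np.nan, np.nan, len(down), n),
            s=float(s[i]),
            c=float(c[i]),
        )
        for i in range(N)
    ]

    groups = aggregate_compound(scores, db.meta, config)

    # Positions in the c-descending ordering.  Ties (chiefly the block of
    # null instances at c = 0) are broken by a stable hash of the instance
    # id, NOT the id itself: ids typically share a compound prefix, so a
    # lexicographic tie-break would place a compound's instances adjacently
    # and fabricate group enrichment out of nothing.  The hash keeps the
    # ordering deterministic while decorrelating it from group membership.
    order = sorted(range(N), key=lambda i: (-c[i], _tie_key(ids[i])))
    position = {ids[i]: rank for rank, i in enumerate(order, start=1)}
    keys = _group_keys(db.meta, config.group_by)
    members_of = {key: list(keys.index[keys == key]) for key in keys.unique()}

    rng = np.random.default_rng(config.seed)
    null_cache: dict[int, np.ndarray] = {}
    for g in groups:
        positions = sorted(position[i] for i in members_of[g.group_key])
        g.enrichment = set_enrichment(positions, g.n, N)
    # Deterministic null construction: sizes in ascending order.
    for size in sorted({g.n for g in groups}):
        if comb(N, size) <= config.enumeration_cap:
            null_cache[size] = enumerate_null_enrichment(size, N)
        else:
            null_cache[size] = sample_null_enrichment(size, N, config.n_perm, rng)
    for g in groups:
        g.p_value = permutation_p(
            g.enrichment, g.n, N, config, null_es=null_cache[g.n]
        )

    ranked = rank_results(groups)

    results = pd.DataFrame(
        [
            {
                "rank": g.rank,
                "group_key": g.group_key,
                "compound": g.compound,
                "cell_line": g.cell_line,
                "n_instances": g.n,
                "similarity_mean": g.similarity_mean,
                "enrichment": g.enrichment,
                "p_value": g.p_value,
                "n_nonnull": g.n_nonnull,
            }
            for g in ranked
        ],
        columns=RESULT_COLUMNS,
    )
    instances = pd.DataFrame(
        [
            {
                "instance_id": sc.instance_id,
                "compound": db.meta.loc[sc.instance_id, "compound"],
                "cell_line": db.meta.loc[sc.instance_id, "cell_line"],
                "ks_up": np.nan if sc.ks_up is None else sc.ks_up.es,
                "ks_down": np.nan if sc.ks_down is None else sc.ks_down.es,
                "s": sc.s,
                "c": sc.c,
            }
            for sc in scores
        ],
        columns=INSTANCE_COLUMNS,
    )
    provenance = {
        "config": asdict(config),
        "seed": config.seed,
        "n_probes": n,
        "n_instances": N,
        "n_up_tags": len(up),
        "n_down_tags": len(down),
        "dropped_up_tags": up_dropped,
        "dropped_down_tags": down_dropped,
    }
    return QueryResult(
        results=results, instances=instances, scaling=scaling, provenance=provenance
    )


# ---------------------------------------------------------------------------
# TSV output (deterministic formatting: floats at 6 significant digits)


def _fmt(x) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return format(x, ".6g")
    return str(x)


def _write_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_results_tsv(result: QueryResult, path) -> None:
    """Write the ranked group table with stable 6-significant-digit floats."""
    _write_tsv(result.results, path)


def write_instances_tsv(result: QueryResult, path) -> None:
    """Write the per-instance score table."""
    _write_tsv(result.instances, path)
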