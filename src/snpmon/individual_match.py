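"""Individual identification by pairwise allele matching and clustering.

Two samples from the same animal differ only through genotyping error and
missing data, so their allele-mismatch count over jointly called loci is
near zero, while even full siblings at ~80 high-MAF SNPs differ at dozens of
loci.  Samples are linked when they overlap at enough loci and mismatch at
no more than a threshold; connected components of that graph are the unique
individuals.  No genetic model is assumed — the method tolerates allelic
dropout and missing data by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeTable

AUTO = "AUTO"


@dataclass
class MatchConfig:
    """Matching thresholds.

    ``min_overlap`` is the minimum number of jointly called loci before a
    pair may be linked (the practical floor for robust identification);
    ``mismatch_threshold`` is the largest mismatch count still treated as
    "same individual", or AUTO to derive it from the mismatch histogram.
    """

    min_overlap: int = 79
    mismatch_threshold: int | str = 16
    auto_min_gap: int = 3
    fallback_threshold: int = 16

    def __post_init__(self) -> None:
        if isinstance(self.mismatch_threshold, int) and self.mismatch_threshold < 0:
            raise ValueError("mismatch threshold must be >= 0")
        if self.min_overlap < 0:
            raise ValueError("min_overlap must be >= 0")


def pairwise_mismatch(
    a_calls: np.ndarray, b_calls: np.ndarray
) -> tuple[int, int]:
    """(mismatching loci, jointly called loci) for two call vectors.

    A locus counts toward the overlap only when both samples carry a call;
    it mismatches when the unordered allele pairs differ.  The Y presence
    marker participates through its encoding: two detected samples match,
    detected-vs-absent contributes nothing (absence is indistinguishable
    from a failed reaction at a presence-only assay).
    """
    a = np.asarray(a_calls, dtype=object)
    b = np.asarray(b_calls, dtype=object)
    if a.shape != b.shape:
        raise ValueError("call vectors must share the same marker universe")
    both = (a != MISSING) & (b != MISSING)
    n_overlap = int(both.sum())
    n_mismatch = int(np.sum(a[both] != b[both]))
    return n_mismatch, n_overlap


def mismatch_matrix(
    table: GenotypeTable, min_overlap: int = 0
) -> pd.DataFrame:
    """Long-form table of every pairwise (mismatch, overlap) comparison."""
    rows = []
    for i in range(table.n_samples):
        for j in range(i + 1, table.n_samples):
            mm, ov = pairwise_mismatch(table.calls[i], table.calls[j])
            rows.append(
                {"sample_a": table.sample_ids[i], "sample_b": table.sample_ids[j],
                 "n_mismatch": mm, "n_overlap": ov,
                 "qualifies": ov >= min_overlap}
            )
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "n_mismatch", "n_overlap",
                       "qualifies"]
    )


def auto_threshold(
    pair_mismatches: Sequence[int],
    config: MatchConfig | None = None,
) -> tuple[int, bool]:
    """Derive the mismatch threshold from the pairwise histogram.

    Same-individual pairs (replicates, resampled animals) pile up near zero
    and different-individual pairs form a distant mass; the threshold is the
    midpoint of the widest empty gap between the low mode and the rest.
    Returns (threshold, used_fallback); the configured fallback is used when
    fewer than 20 qualifying pairs exist or no gap of the minimum width
    appears.
    """
    cfg = config or MatchConfig()
    values = sorted(int(v) for v in pair_mismatches)
    if len(values) < 20:
        return cfg.fallback_threshold, True
    distinct = sorted(set(values))
    if len(distinct) < 2:
        return cfg.fallback_threshold, True
    best_gap = 0
    best_mid = None
    for lo, hi in zip(distinct, distinct[1:]):
        gap = hi - lo - 1
        if gap > best_gap:
            best_gap = gap
            best_mid = (lo + hi) // 2
    if best_gap < cfg.auto_min_gap or best_mid is None:
        return cfg.fallback_threshold, True
    return best_mid, False


@dataclass
class IndividualCluster:
    individual_id: str
    member_sample_ids: list[str]
    consensus: dict[str, str]
    pair_stats: list[tuple[str, str, int, int]] = field(default_factory=list)


@dataclass
class ClusterResult:
    clusters: list[IndividualCluster]
    threshold_used: int
    threshold_was_fallback: bool
    insufficient_overlap_pairs: pd.DataFrame
    assignment: pd.Series  # sample -> individual id


def _consensus_calls(table: GenotypeTable, rows: list[int]) -> dict[str, str]:
    out = {}
    for j, mid in enumerate(table.marker_ids):
        counts = Counter(
            table.calls[i, j] for i in rows if table.calls[i, j] != MISSING
        )
        if not counts:
            out[mid] = MISSING
            continue
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            out[mid] = MISSING  # tie -> conservative missing
        else:
            out[mid] = ranked[0][0]
    return out


def cluster_individuals(
    table: GenotypeTable,
    config: MatchConfig | None = None,
    id_prefix: str = "IND",
) -> ClusterResult:
    """Partition passing samples into unique individuals.

    Builds a graph with an edge for every pair with overlap >= min_overlap
    and mismatch <= threshold; connected components become individuals
    (single linkage — the monitoring semantics of "same animal sampled
    repeatedly" is transitive).  Pairs below the overlap floor are never
    linked and are reported separately.  Individual ids are assigned in
    first-seen sample order, and consensus genotypes use per-locus majority
    with ties recoded missing.
    """
    cfg = config or MatchConfig()
    pairs = mismatch_matrix(table, cfg.min_overlap)

    if cfg.mismatch_threshold == AUTO:
        qualifying = pairs.loc[pairs["qualifies"], "n_mismatch"]
        threshold, fallback = auto_threshold(qualifying.tolist(), cfg)
    else:
        threshold, fallback = int(cfg.mismatch_threshold), False

    g = nx.Graph()
    g.add_nodes_from(table.sample_ids)
    for row in pairs.itertuples(index=False):
        if row.qualifies and row.n_mismatch <= threshold:
            g.add_edge(row.sample_a, row.sample_b,
                       mismatch=row.n_mismatch, overlap=row.n_overlap)

    order = {s: i for i, s in enumerate(table.sample_ids)}
    components = sorted(
        (sorted(c, key=order.get) for c in nx.connected_components(g)),
        key=lambda c: order[c[0]],
    )
    clusters = []
    assignment = {}
    for k, comp in enumerate(components, start=1):
        ind_id = f"{id_prefix}_{k:04d}"
        rows = [order[s] for s in comp]
        stats = [
            (a, b, g.edges[a, b]["mismatch"], g.edges[a, b]["overlap"])
            for a in comp for b in comp
            if a < b and g.has_edge(a, b)
        ]
        clusters.append(
            IndividualCluster(
                individual_id=ind_id,
                member_sample_ids=comp,
                consensus=_consensus_calls(table, rows),
                pair_stats=stats,
            )
        )
        for s in comp:
            assignment[s] = ind_id

    low = pairs[~pairs["qualifies"]].reset_index(drop=True)
    return ClusterResult(
        clusters=clusters,
        threshold_used=threshold,
        threshold_was_fallback=fallback,
        insufficient_overlap_pairs=low,
        assignment=pd.Series(assignment, name="individual_id"),
    )


def consensus_table(result: ClusterResult, marker_ids: Sequence[str]) -> GenotypeTable:
    """Stack per-cluster consensus genotypes into a GenotypeTable."""
    ids = [c.individual_id for c in result.clusters]
    calls = np.array(
        [[c.consensus.get(m, MISSING) for m in marker_ids] for c in result.clusters],
        dtype=object,
    ).reshape(len(ids), len(marker_ids))
    return GenotypeTable(ids, list(marker_ids), calls)
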