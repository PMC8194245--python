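"""The ceRNA screening procedure.

A candidate sponge network is narrowed in stages:

1. resource intersection — a regulator->target pair is trusted only if
   two independent prediction resources both report it;
2. differential-expression intersection — endpoints must survive the
   two-group filter (miRNAs down, lncRNA/mRNAs up in tumor);
3. Pearson correlation with ceRNA sign constraints — lncRNA-miRNA and
   miRNA-mRNA correlations must be significantly negative, the
   lncRNA-mRNA correlation significantly positive;
4. triplet assembly — a lncRNA/miRNA/mRNA triple is kept iff all three
   of its pairwise relations survived.

Correlations are computed on tumor-group samples on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    CeRNANetwork,
    CeRNATriplet,
    CorrelationRecord,
    DifferentialExpressionRecord,
    ExpressionMatrix,
    InteractionPair,
    PAIR_LNC_M,
    PAIR_LNC_MI,
    PAIR_MI_M,
)
from .diffexpr import apply_de_filter, compute_differential_expression


# ------------------------------------------------------------ intersections

def intersect_resources(
    pairs_a: Sequence[InteractionPair],
    pairs_b: Sequence[InteractionPair],
) -> list[InteractionPair]:
    """Pairs predicted by both resources, tagged ``consensus``.

    Both inputs must hold the same pair kind (e.g. all miRNA->mRNA).
    """
    kinds = {p.pair_kind for p in pairs_a} | {p.pair_kind for p in pairs_b}
    if len(kinds) > 1:
        raise ValueError(f"mixed pair kinds in resource intersection: {sorted(kinds)}")
    keys_b = {p.key for p in pairs_b}
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs_a:
        if p.key in keys_b and p.key not in seen:
            seen.add(p.key)
            out.append(
                InteractionPair(
                    p.source_id, p.source_class, p.target_id, p.target_class,
                    resource="consensus",
                )
            )
    return sorted(out, key=lambda p: p.key)


def intersect_with_de(
    pairs: Sequence[InteractionPair],
    de_kept: Sequence[DifferentialExpressionRecord],
    side: str,
) -> list[InteractionPair]:
    """Keep pairs whose ``source`` or ``target`` endpoint passed the DE filter."""
    if side not in ("source", "target"):
        raise ValueError(f"side must be 'source' or 'target', got {side!r}")
    kept_ids = {r.feature_id for r in de_kept}
    if side == "source":
        return [p for p in pairs if p.source_id in kept_ids]
    return [p for p in pairs if p.target_id in kept_ids]


# ------------------------------------------------------------ correlations

def pearson(
    x: np.ndarray,
    y: np.ndarray,
    id_a: str = "x",
    id_b: str = "y",
    pair_kind: str = PAIR_LNC_M,
) -> CorrelationRecord:
    """Sample Pearson correlation with a two-sided t-distribution p-value.

    The p-value follows from ``t = r * sqrt((n-2) / (1-r^2))`` on n-2
    degrees of freedom; a perfect correlation gets the smallest
    representable positive p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            f"correlation of ({id_a}, {id_b}) undefined: constant input vector"
        )
    r, p = stats.pearsonr(x, y)
    tiny = float(np.nextafter(0, 1))
    p = float(min(max(p, tiny), 1.0))
    return CorrelationRecord(
        id_a=id_a, id_b=id_b, pair_kind=pair_kind,
        pearson_r=float(np.clip(r, -1.0, 1.0)), p_value=p, n=n,
    )


def correlate_pairs(
    pairs: Sequence[InteractionPair],
    matrices: Mapping[str, ExpressionMatrix],
    group: str = "tumor",
    pseudocount: float = 1.0,
) -> list[CorrelationRecord]:
    """One correlation record per pair, over the shared ``group`` samples.

    ``matrices`` maps each feature class to its expression matrix; the
    correlation is computed on log2 values.  Raises ``KeyError`` naming
    any pair endpoint absent from its class matrix.
    """
    log2 = {cls: m.log2_values(pseudocount=pseudocount) for cls, m in matrices.items()}
    samples = {cls: m.samples_in_group(group) for cls, m in matrices.items()}
    records = []
    for p in pairs:
        for fid, cls in ((p.source_id, p.source_class), (p.target_id, p.target_class)):
            if cls not in matrices or fid not in log2[cls].index:
                raise KeyError(f"feature {fid!r} ({cls}) not found in its matrix")
        shared = [s for s in samples[p.source_class] if s in set(samples[p.target_class])]
        x = log2[p.source_class].loc[p.source_id, shared].to_numpy(dtype=float)
        y = log2[p.target_class].loc[p.target_id, shared].to_numpy(dtype=float)
        records.append(pearson(x, y, p.source_id, p.target_id, p.pair_kind))
    return records


def screen_sign_consistent(
    records: Iterable[CorrelationRecord],
    level: float = 0.05,
) -> list[CorrelationRecord]:
    """Keep records matching the ceRNA sign rule at significance ``level``:
    negative lncRNA-miRNA and miRNA-mRNA, positive lncRNA-mRNA."""
    kept = []
    for r in records:
        if r.p_value >= level:
            continue
        if r.pair_kind in (PAIR_LNC_MI, PAIR_MI_M) and r.pearson_r < 0:
            kept.append(r)
        elif r.pair_kind == PAIR_LNC_M and r.pearson_r > 0:
            kept.append(r)
    return kept


# ------------------------------------------------------------ assembly

def _pair_key(item) -> tuple[str, str]:
    if isinstance(item, CorrelationRecord):
        return (item.id_a, item.id_b)
    if isinstance(item, InteractionPair):
        return item.key
    a, b = item
    return (str(a), str(b))


def assemble_triplets(
    lnc_mi: Sequence,
    mi_m: Sequence,
    lnc_m: Sequence,
) -> list[CeRNATriplet]:
    """Emit every (L, M, G) with (L,M), (M,G) and (L,G) all present.

    Inputs are already screened pair collections; elements may be
    :class:`CorrelationRecord`, :class:`InteractionPair` or bare id
    tuples.  Output is sorted by (lncRNA, miRNA, mRNA) id.
    """
    def as_map(items) -> dict[tuple[str, str], CorrelationRecord | None]:
        out = {}
        for it in items:
            out.setdefault(_pair_key(it), it if isinstance(it, CorrelationRecord) else None)
        return out

    lnc_mi_map = as_map(lnc_mi)
    mi_m_map = as_map(mi_m)
    lnc_m_map = as_map(lnc_m)
    by_mirna: dict[str, list[str]] = {}
    for (m, g) in mi_m_map:
        by_mirna.setdefault(m, []).append(g)

    triplets = []
    for (lnc, mi) in lnc_mi_map:
        for gene in by_mirna.get(mi, ()):
            if (lnc, gene) in lnc_m_map:
                triplets.append(
                    CeRNATriplet(
                        lncRNA_id=lnc, miRNA_id=mi, mRNA_id=gene,
                        corr_lnc_mi=lnc_mi_map[(lnc, mi)],
                        corr_mi_m=mi_m_map[(mi, gene)],
                        corr_lnc_m=lnc_m_map[(lnc, gene)],
                    )
                )
    return sorted(triplets, key=lambda t: t.ids)


def build_full_network(
    lnc_id: str,
    candidate_miRNAs: Sequence[str],
    candidate_mRNAs: Sequence[str],
    pairs: Sequence[InteractionPair],
) -> CeRNANetwork:
    """Star-plus-bipartite candidate network around one lncRNA.

    The lncRNA connects to every candidate miRNA; miRNA->mRNA edges come
    from ``pairs`` restricted to the candidate sets, de-duplicated.
    """
    mi_set = dict.fromkeys(candidate_miRNAs)
    m_set = set(candidate_mRNAs)
    edges: list[tuple[str, str, str, None]] = [
        (lnc_id, mi, PAIR_LNC_MI, None) for mi in mi_set
    ]
    seen: set[tuple[str, str]] = set()
    m_nodes: dict[str, None] = {}
    for p in sorted(pairs, key=lambda p: p.key):
        if p.pair_kind != PAIR_MI_M:
            continue
        if p.source_id in mi_set and p.target_id in m_set and p.key not in seen:
            seen.add(p.key)
            edges.append((p.source_id, p.target_id, PAIR_MI_M, None))
            m_nodes[p.target_id] = None
    nodes = [(lnc_id, "lncRNA")]
    nodes += [(mi, "miRNA") for mi in mi_set]
    nodes += [(m, "mRNA") for m in sorted(m_nodes)]
    return CeRNANetwork(nodes=nodes, edges=edges)


# ------------------------------------------------------------ full pipeline

@dataclass
class ScreenResult:
    """Everything the staged screen produced, plus the audit funnel."""

    de_lnc_up: list[DifferentialExpressionRecord]
    de_mi_down: list[DifferentialExpressionRecord]
    de_m_up: list[DifferentialExpressionRecord]
    kept_lnc_mi: list[CorrelationRecord]
    kept_mi_m: list[CorrelationRecord]
    kept_lnc_m: list[CorrelationRecord]
    triplets: list[CeRNATriplet]
    funnel: dict[str, int] = field(default_factory=dict)


def run_screen(
    matrices: Mapping[str, ExpressionMatrix],
    lnc_mi_resources: Sequence[Sequence[InteractionPair]],
    mi_m_resources: Sequence[Sequence[InteractionPair]],
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
    corr_level: float = 0.05,
    corr_group: str = "tumor",
) -> ScreenResult:
    """Run the full staged screen and return triplets plus funnel counts.

    ``matrices`` maps ``lncRNA``/``miRNA``/``mRNA`` to expression
    matrices; each ``*_resources`` argument holds one pair table per
    prediction resource (two or more; consecutive tables are
    intersected).
    """
    de = {cls: compute_differential_expression(m) for cls, m in matrices.items()}
    lnc_up = apply_de_filter(de["lncRNA"], min_abs_log2fc, max_p, "up")
    mi_down = apply_de_filter(de["miRNA"], min_abs_log2fc, max_p, "down")
    m_up = apply_de_filter(de["mRNA"], min_abs_log2fc, max_p, "up")

    def consensus(tables: Sequence[Sequence[InteractionPair]]) -> list[InteractionPair]:
        if len(tables) < 2:
            raise ValueError("need at least two prediction resources to intersect")
        merged = list(tables[0])
        for t in tables[1:]:
            merged = intersect_resources(merged, t)
        return merged

    lnc_mi = consensus(lnc_mi_resources)
    mi_m = consensus(mi_m_resources)
    funnel = {
        "lnc_mi_consensus": len(lnc_mi),
        "mi_m_consensus": len(mi_m),
    }
    lnc_mi = intersect_with_de(lnc_mi, lnc_up, "source")
    lnc_mi = intersect_with_de(lnc_mi, mi_down, "target")
    mi_m = intersect_with_de(mi_m, mi_down, "source")
    mi_m = intersect_with_de(mi_m, m_up, "target")
    funnel["lnc_mi_after_de"] = len(lnc_mi)
    funnel["mi_m_after_de"] = len(mi_m)

    # candidate lncRNA-mRNA links: every chain L -> M -> G
    targets_of = {}
    for p in mi_m:
        targets_of.setdefault(p.source_id, set()).add(p.target_id)
    lnc_m_keys: dict[tuple[str, str], None] = {}
    for p in lnc_mi:
        for gene in sorted(targets_of.get(p.target_id, ())):
            lnc_m_keys.setdefault((p.source_id, gene), None)
    lnc_m = [
        InteractionPair(lnc, "lncRNA", gene, "mRNA", "chain")
        for (lnc, gene) in sorted(lnc_m_keys)
    ]
    funnel["lnc_m_candidates"] = len(lnc_m)

    corr_lnc_mi = correlate_pairs(lnc_mi, matrices, group=corr_group)
    corr_mi_m = correlate_pairs(mi_m, matrices, group=corr_group)
    corr_lnc_m = correlate_pairs(lnc_m, matrices, group=corr_group)
    kept_lnc_mi = screen_sign_consistent(corr_lnc_mi, corr_level)
    kept_mi_m = screen_sign_consistent(corr_mi_m, corr_level)
    kept_lnc_m = screen_sign_consistent(corr_lnc_m, corr_level)
    funnel["lnc_mi_sign_consistent"] = len(kept_lnc_mi)
    funnel["mi_m_sign_consistent"] = len(kept_mi_m)
    funnel["lnc_m_sign_consistent"] = len(kept_lnc_m)

    triplets = assemble_triplets(kept_lnc_mi, kept_mi_m, kept_lnc_m)
    funnel["triplets"] = len(triplets)
    return ScreenResult(
        de_lnc_up=lnc_up, de_mi_down=mi_down, de_m_up=m_up,
        kept_lnc_mi=kept_lnc_mi, kept_mi_m=kept_mi_m, kept_lnc_m=kept_lnc_m,
        triplets=triplets, funnel=funnel,
    )
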