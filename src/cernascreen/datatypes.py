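"""Core domain types for ceRNA-triplet screening.

The screening model works on three feature classes — lncRNA, miRNA and
mRNA — measured over two sample groups (tumor, normal).  A competing
endogenous RNA (ceRNA) relationship between a lncRNA L, a miRNA M and an
mRNA G predicts negative L–M and M–G expression correlations and a
positive L–G correlation; :class:`CeRNATriplet` enforces exactly that
sign pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("lncRNA", "miRNA", "mRNA")
SAMPLE_GROUPS = ("tumor", "normal")

#: pair kinds used throughout: lncRNA-miRNA, miRNA-mRNA, lncRNA-mRNA
PAIR_LNC_MI = "lnc-mi"
PAIR_MI_M = "mi-m"
PAIR_LNC_M = "lnc-m"
PAIR_KINDS = (PAIR_LNC_MI, PAIR_MI_M, PAIR_LNC_M)

#: class combinations allowed for a regulator->target pair.  The
#: lncRNA->mRNA combination carries reported ceRNA-consistent pairs
#: (correlation evidence), not a binding prediction.
ALLOWED_PAIR_CLASSES = {
    ("lncRNA", "miRNA"): PAIR_LNC_MI,
    ("miRNA", "mRNA"): PAIR_MI_M,
    ("lncRNA", "mRNA"): PAIR_LNC_M,
}

_DASHES = {"‐": "-", "‑": "-", "‒": "-", "–": "-",
           "—": "-", "−": "-"}

# known typographic variants -> canonical miRBase-style id (lowercase key)
_MIRNA_ALIASES = {
    "hsa-mir-29-2-5p": "hsa-miR-29b-2-5p",
}


def normalize_mirna_id(raw: str) -> str:
    """Normalize a miRNA identifier to canonical ``hsa-miR-...`` form.

    Handles unicode dashes, a missing ``hsa-`` prefix, case variation,
    and known typographic variants (``miR-29-2-5p`` for
    ``hsa-miR-29b-2-5p``).
    """
    s = raw.strip()
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    low = s.lower()
    if not low.startswith("hsa-"):
        low = "hsa-" + low
    if low in _MIRNA_ALIASES:
        return _MIRNA_ALIASES[low]
    if low.startswith("hsa-mir-"):
        return "hsa-miR-" + low[len("hsa-mir-"):]
    return s


@dataclass
class ExpressionMatrix:
    """A features x samples expression table with class and group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids.
    feature_class
        Maps every feature id to one of ``lncRNA``/``miRNA``/``mRNA``.
    sample_group
        Maps every sample id to ``tumor`` or ``normal``.
    scale
        ``linear`` (non-negative) or ``log2``.
    """

    values: pd.DataFrame
    feature_class: Mapping[str, str]
    sample_group: Mapping[str, str]
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_group[s] == group]

    def feature_vector(self, feature_id: str, group: str | None = None) -> np.ndarray:
        """Expression of one feature, optionally restricted to a group."""
        if feature_id not in self.values.index:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        row = self.values.loc[feature_id]
        if group is not None:
            row = row[self.samples_in_group(group)]
        return row.to_numpy(dtype=float)

    def log2_values(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Values on log2 scale (identity if already log2)."""
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + pseudocount)

    # -- validation ------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = [f for f in idx if f not in self.feature_class]
        if missing:
            raise ValueError(f"features without class label: {missing[:5]}")
        bad = {f: c for f in idx
               if (c := self.feature_class[f]) not in FEATURE_CLASSES}
        if bad:
            raise ValueError(f"unknown feature classes: {bad}")
        missing = [s for s in cols if s not in self.sample_group]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = {s: g for s in cols
               if (g := self.sample_group[s]) not in SAMPLE_GROUPS}
        if bad:
            raise ValueError(f"unknown sample groups: {bad}")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise ValueError("linear-scale expression values must be >= 0")


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """Per-feature two-group contrast: log2 fold change (tumor - normal) and p-value."""

    feature_id: str
    feature_class: str
    log2fc: float
    p_value: float

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if not np.isfinite(self.log2fc):
            raise ValueError(f"{self.feature_id}: log2fc must be finite")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"{self.feature_id}: p_value must be in (0, 1]")


@dataclass(frozen=True)
class InteractionPair:
    """A predicted (or reported) regulator -> target pair from one resource."""

    source_id: str
    source_class: str
    target_id: str
    target_class: str
    resource: str

    def __post_init__(self) -> None:
        key = (self.source_class, self.target_class)
        if key not in ALLOWED_PAIR_CLASSES:
            raise ValueError(
                f"illegal pair classes {key} for {self.source_id}->{self.target_id}"
            )
        if self.source_id == self.target_id:
            raise ValueError(f"self-pair {self.source_id!r}")

    @property
    def pair_kind(self) -> str:
        return ALLOWED_PAIR_CLASSES[(self.source_class, self.target_class)]

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_id, self.target_id)


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson correlation between two features over n samples."""

    id_a: str
    id_b: str
    pair_kind: str
    pearson_r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.pair_kind not in PAIR_KINDS:
            raise ValueError(f"unknown pair kind {self.pair_kind!r}")
        if not abs(self.pearson_r) <= 1.0:
            raise ValueError("pearson_r must lie in [-1, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")

    def is_significant(self, level: float = 0.05) -> bool:
        return self.p_value < level


@dataclass(frozen=True)
class CeRNATriplet:
    """One lncRNA/miRNA/mRNA triple with ceRNA-consistent correlation signs.

    Correlation records are optional: triplets assembled from reported
    pair lists carry ids only.  When present, the records must show
    r < 0 for lncRNA-miRNA and miRNA-mRNA and r > 0 for lncRNA-mRNA.
    """

    lncRNA_id: str
    miRNA_id: str
    mRNA_id: str
    corr_lnc_mi: Optional[CorrelationRecord] = None
    corr_mi_m: Optional[CorrelationRecord] = None
    corr_lnc_m: Optional[CorrelationRecord] = None

    def __post_init__(self) -> None:
        if self.corr_lnc_mi is not None and not self.corr_lnc_mi.pearson_r < 0:
            raise ValueError("lncRNA-miRNA correlation must be negative")
        if self.corr_mi_m is not None and not self.corr_mi_m.pearson_r < 0:
            raise ValueError("miRNA-mRNA correlation must be negative")
        if self.corr_lnc_m is not None and not self.corr_lnc_m.pearson_r > 0:
            raise ValueError("lncRNA-mRNA correlation must be positive")

    @property
    def ids(self) -> tuple[str, str, str]:
        return (self.lncRNA_id, self.miRNA_id, self.mRNA_id)


@dataclass
class CeRNANetwork:
    """A ceRNA graph: typed nodes and typed, optionally weighted edges."""

    nodes: list[tuple[str, str]] = field(default_factory=list)
    edges: list[tuple[str, str, str, Optional[float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        classes = {}
        for node_id, node_class in self.nodes:
            if node_id in seen:
                raise ValueError(f"duplicate node {node_id!r}")
            if node_class not in FEATURE_CLASSES:
                raise ValueError(f"unknown node class {node_class!r}")
            seen.add(node_id)
            classes[node_id] = node_class
        kind_of = {
            (ca, cb): kind for (ca, cb), kind in ALLOWED_PAIR_CLASSES.items()
        }
        for a, b, kind, r in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            for endpoint in (a, b):
                if endpoint not in classes:
                    raise ValueError(f"edge endpoint {endpoint!r} is not a node")
            expected = kind_of.get((classes[a], classes[b]))
            if expected != kind:
                raise ValueError(
                    f"edge {a}->{b} tagged {kind!r}, classes imply {expected!r}"
                )
            if r is not None and not abs(r) <= 1.0:
                raise ValueError(f"edge {a}->{b}: |r| must be <= 1")

    @property
    def node_ids(self) -> set[str]:
        return {n for n, _ in self.nodes}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node_id, node_class in self.nodes:
            g.add_node(node_id, feature_class=node_class)
        for a, b, kind, r in self.edges:
            attrs = {"pair_kind": kind}
            if r is not None:
                attrs["pearson_r"] = float(r)
            g.add_edge(a, b, **attrs)
        return g

    @classmethod
    def from_triplets(cls, triplets: Sequence[CeRNATriplet]) -> "CeRNANetwork":
        nodes: dict[str, str] = {}
        edges: dict[tuple[str, str, str], Optional[float]] = {}
        for t in sorted(triplets, key=lambda t: t.ids):
            nodes.setdefault(t.lncRNA_id, "lncRNA")
            nodes.setdefault(t.miRNA_id, "miRNA")
            nodes.setdefault(t.mRNA_id, "mRNA")
            for a, b, kind, rec in (
                (t.lncRNA_id, t.miRNA_id, PAIR_LNC_MI, t.corr_lnc_mi),
                (t.miRNA_id, t.mRNA_id, PAIR_MI_M, t.corr_mi_m),
                (t.lncRNA_id, t.mRNA_id, PAIR_LNC_M, t.corr_lnc_m),
            ):
                edges.setdefault((a, b, kind), rec.pearson_r if rec else None)
        return cls(
            nodes=sorted(nodes.items()),
            edges=[(a, b, k, r) for (a, b, k), r in sorted(edges.items())],
        )


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time (months), event flag, expression group."""

    subject_id: str
    time: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"{self.subject_id}: follow-up time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"{self.subject_id}: event must be 0 or 1")
        if self.group not in ("high", "low"):
            raise ValueError(f"{self.subject_id}: group must be 'high' or 'low'")
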