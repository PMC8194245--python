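"""Synthetic tumor/normal datasets with planted ceRNA triplets.

The generator emulates the statistical structure the screen assumes: a
two-group (tumor/normal) study with log2-scale expression, differential
shifts on the features of interest, and per-triplet correlation induced
by a shared latent miRNA signal.

Generative model (all on log2 scale, linear-Gaussian):

* planted miRNA M:   ``M = mu_M - de_shift * is_tumor + eps``,
  ``eps ~ N(0, 1)`` (within-group sd fixed at 1);
* planted lncRNA L:  ``L = mu_L + de_shift * is_tumor - b (M - E[M|group]) + e``,
  ``e ~ N(0, noise_sd)``; the planted mRNA G is built the same way with
  independent noise.

The slope ``b = noise_sd * c / sqrt(1 - c^2)`` makes the within-group
population correlation corr(L, M) = corr(G, M) = -c for target coupling
``c``, and corr(L, G) = +c^2 — exactly the ceRNA sign pattern.  Decoy
features are independent N(mu, 1) noise with no group shift.  Matrices
are emitted on linear scale (``2**log2``).

Prediction pair tables for two pseudo-resources contain every planted
edge plus independent decoy pairs at ``false_pair_rate`` per resource.
One global seed drives named substreams (expression / pairs / survival)
so adding decoys or pairs never perturbs the planted expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, InteractionPair, SurvivalRecord
from .survival import split_by_median

RESOURCES = ("resourceA", "resourceB")

# fixed within-group sd of the latent miRNA signal (log2 units)
_MIRNA_SD = 1.0
# baseline log2 abundance range features are drawn from
_MU_RANGE = (4.0, 10.0)
# survival scale: baseline exponential median 24 months, censoring U(0, 60)
_BASELINE_MEDIAN_MONTHS = 24.0
_CENSOR_MAX_MONTHS = 60.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic ceRNA dataset.

    Defaults mirror a modest two-group expression study: 50 tumor and
    50 normal samples, a 2-log2-unit differential shift on planted
    features, coupling 0.7 on planted edges, residual sd 0.5, and a 10%
    decoy rate in each prediction resource.
    """

    seed: int
    n_tumor: int = 50
    n_normal: int = 50
    n_planted_triplets: int = 5
    n_decoy_lnc: int = 20
    n_decoy_mi: int = 20
    n_decoy_m: int = 40
    de_shift: float = 2.0
    coupling: float = 0.7
    noise_sd: float = 0.5
    false_pair_rate: float = 0.1
    survival_beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be >= 3")
        for name in ("n_planted_triplets", "n_decoy_lnc", "n_decoy_mi", "n_decoy_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.coupling < 1.0):
            raise ValueError("coupling must lie in (0, 1)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.false_pair_rate <= 1.0):
            raise ValueError("false_pair_rate must lie in [0, 1]")
        if not np.isfinite(self.de_shift):
            raise ValueError("de_shift must be finite")

    @property
    def coupling_slope(self) -> float:
        """Slope b with corr(partner, miRNA) = -coupling given noise_sd."""
        c = self.coupling
        return self.noise_sd * c / np.sqrt(1.0 - c * c)


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    planted_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    planted_de_features: set[str] = field(default_factory=set)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        name: np.random.default_rng(ss)
        for name, ss in zip(("expression", "pairs", "survival"), children)
    }


def generate_cerna_dataset(
    config: SimulationConfig,
) -> tuple[
    ExpressionMatrix,
    ExpressionMatrix,
    ExpressionMatrix,
    dict[str, list[InteractionPair]],
    dict[str, list[InteractionPair]],
    GroundTruth,
]:
    """Generate (lncRNA, miRNA, mRNA) matrices, pair tables and truth.

    Returns ``(expr_lnc, expr_mi, expr_m, lnc_mi_tables, mi_m_tables,
    truth)`` where each ``*_tables`` dict maps a resource name to its
    pair list.  Deterministic given ``config.seed``.
    """
    rng = _substreams(config.seed)["expression"]
    pair_rng = _substreams(config.seed)["pairs"]

    n = config.n_tumor + config.n_normal
    samples = [f"T{i+1:03d}" for i in range(config.n_tumor)] + [
        f"N{i+1:03d}" for i in range(config.n_normal)
    ]
    groups = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    is_tumor = np.array([groups[s] == "tumor" for s in samples], dtype=float)

    lnc_ids = [f"lnc_planted_{i+1}" for i in range(config.n_planted_triplets)] + [
        f"lnc_decoy_{i+1}" for i in range(config.n_decoy_lnc)
    ]
    mi_ids = [f"mir_planted_{i+1}" for i in range(config.n_planted_triplets)] + [
        f"mir_decoy_{i+1}" for i in range(config.n_decoy_mi)
    ]
    m_ids = [f"mrna_planted_{i+1}" for i in range(config.n_planted_triplets)] + [
        f"mrna_decoy_{i+1}" for i in range(config.n_decoy_m)
    ]

    b = config.coupling_slope
    rows: dict[str, dict[str, np.ndarray]] = {"lncRNA": {}, "miRNA": {}, "mRNA": {}}
    truth = GroundTruth()

    for i in range(config.n_planted_triplets):
        lnc, mi, gene = lnc_ids[i], mi_ids[i], m_ids[i]
        mus = rng.uniform(*_MU_RANGE, size=3)
        eps = rng.normal(0.0, _MIRNA_SD, size=n)
        m_log2 = mus[0] - config.de_shift * is_tumor + eps
        # partners couple to the miRNA's within-group deviation only,
        # so the group shift does not inflate the within-group correlation
        for fid, cls, mu in ((lnc, "lncRNA", mus[1]), (gene, "mRNA", mus[2])):
            noise = rng.normal(0.0, config.noise_sd, size=n)
            rows[cls][fid] = mu + config.de_shift * is_tumor - b * eps + noise
        rows["miRNA"][mi] = m_log2
        truth.planted_triplets.append((lnc, mi, gene))
        truth.planted_de_features.update((lnc, mi, gene))

    for cls, ids, n_planted in (
        ("lncRNA", lnc_ids, config.n_planted_triplets),
        ("miRNA", mi_ids, config.n_planted_triplets),
        ("mRNA", m_ids, config.n_planted_triplets),
    ):
        for fid in ids[n_planted:]:
            mu = rng.uniform(*_MU_RANGE)
            rows[cls][fid] = mu + rng.normal(0.0, _MIRNA_SD, size=n)

    def as_matrix(cls: str, ids: list[str]) -> ExpressionMatrix:
        log2 = pd.DataFrame(
            np.vstack([rows[cls][f] for f in ids]), index=ids, columns=samples
        )
        return ExpressionMatrix(
            values=np.power(2.0, log2),
            feature_class={f: cls for f in ids},
            sample_group=groups,
            scale="linear",
        )

    expr_lnc = as_matrix("lncRNA", lnc_ids)
    expr_mi = as_matrix("miRNA", mi_ids)
    expr_m = as_matrix("mRNA", m_ids)

    planted_lnc_mi = {(t[0], t[1]) for t in truth.planted_triplets}
    planted_mi_m = {(t[1], t[2]) for t in truth.planted_triplets}

    def pair_tables(
        sources: list[str], source_class: str,
        targets: list[str], target_class: str,
        planted: set[tuple[str, str]],
    ) -> dict[str, list[InteractionPair]]:
        decoy_space = [
            (s, t) for s in sources for t in targets
            if s != t and (s, t) not in planted
        ]
        tables: dict[str, list[InteractionPair]] = {}
        for resource in RESOURCES:
            keep = pair_rng.random(len(decoy_space)) < config.false_pair_rate
            keys = sorted(planted) + [d for d, k in zip(decoy_space, keep) if k]
            tables[resource] = [
                InteractionPair(s, source_class, t, target_class, resource)
                for s, t in sorted(keys)
            ]
        return tables

    lnc_mi_tables = pair_tables(lnc_ids, "lncRNA", mi_ids, "miRNA", planted_lnc_mi)
    mi_m_tables = pair_tables(mi_ids, "miRNA", m_ids, "mRNA", planted_mi_m)
    return expr_lnc, expr_mi, expr_m, lnc_mi_tables, mi_m_tables, truth


def generate_survival_data(
    expression: Mapping[str, float] | pd.Series,
    config: SimulationConfig,
) -> list[SurvivalRecord]:
    """Exponential event times tied to a per-subject expression value.

    The per-subject hazard is ``lambda_0 * exp(survival_beta * z)`` with
    ``z`` the standardized expression; censoring is independent
    U(0, 60) months.  Groups come from the median split of the same
    expression values.  Deterministic given ``config.seed``.
    """
    series = pd.Series(dict(expression), dtype=float)
    if series.size < 4:
        raise ValueError("survival simulation needs n >= 4 subjects")
    sd = float(series.std(ddof=0))
    z = (series - series.mean()) / sd if sd > 0 else series * 0.0
    lambda0 = np.log(2.0) / _BASELINE_MEDIAN_MONTHS
    rates = lambda0 * np.exp(config.survival_beta * z.to_numpy())
    if not (np.isfinite(rates).all() and (rates > 0).all()):
        raise ValueError("non-positive or non-finite hazard rate")
    rng = _substreams(config.seed)["survival"]
    event_times = rng.exponential(1.0 / rates)
    censor_times = rng.uniform(0.0, _CENSOR_MAX_MONTHS, size=series.size)
    groups = split_by_median(series)
    records = []
    for subject, t_event, t_cens in zip(series.index, event_times, censor_times):
        observed = t_event <= t_cens
        t = float(t_event if observed else t_cens)
        records.append(
            SurvivalRecord(
                subject_id=str(subject),
                time=max(t, np.nextafter(0, 1)),
                event=int(observed),
                group=groups[str(subject)],
            )
        )
    return records
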