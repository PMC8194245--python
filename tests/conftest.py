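"""Shared fixtures: small hand-built matrices and one simulated dataset."""

from __future__ import annotations

import pandas as pd
import pytest

from cernascreen import ExpressionMatrix, SimulationConfig, generate_cerna_dataset


def make_matrix(
    rows: dict[str, list[float]],
    n_tumor: int,
    n_normal: int,
    feature_class: dict[str, str] | str = "mRNA",
    scale: str = "linear",
) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-feature value lists.

    Samples are named T1..Tn then N1..Nm; a single class string applies
    to every feature.
    """
    samples = [f"T{i+1}" for i in range(n_tumor)] + [f"N{i+1}" for i in range(n_normal)]
    if isinstance(feature_class, str):
        feature_class = {f: feature_class for f in rows}
    return ExpressionMatrix(
        values=pd.DataFrame(rows, index=samples).T,
        feature_class=feature_class,
        sample_group={s: ("tumor" if s.startswith("T") else "normal") for s in samples},
        scale=scale,
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1234)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """One default-config synthetic dataset, shared across tests."""
    return generate_cerna_dataset(sim_config)
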