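"""Loaders for the packaged worked-example tables.

Three small TSVs ship with the package:

* ``table3_mirnas.tsv`` — the 11 candidate sponge-target miRNAs of
  LINC00922 that are down-regulated in ovarian-cancer tissue, with
  their log2 fold changes and p-values.
* ``table4_mirna_targets.tsv`` — per-miRNA blocks of predicted target
  genes that are up-regulated in ovarian-cancer tissue (gene symbols
  recur across blocks; 307 unique genes in total).
* ``consistent_pairs.tsv`` — the six pairwise relations that survive
  the ceRNA sign-consistency screen on ovarian-cancer tumor expression,
  from which the LINC00922 / hsa-miR-361-3p / CLDN1 triple follows.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

from .datatypes import DifferentialExpressionRecord, InteractionPair, normalize_mirna_id
from .io import ParseError, read_pair_table

LINC00922 = "LINC00922"


def fixture_path(name: str) -> Path:
    path = resources.files("cernascreen").joinpath("data", name)
    with resources.as_file(path) as p:
        if not p.exists():
            raise FileNotFoundError(f"packaged fixture {name!r} is missing")
        return Path(p)


def _require_columns(header: list[str], expected: tuple[str, ...], name: str) -> None:
    if [h.strip() for h in header] != list(expected):
        raise ParseError(f"fixture {name}: unexpected header {header!r}")


@lru_cache(maxsize=None)
def _table3() -> tuple[DifferentialExpressionRecord, ...]:
    name = "table3_mirnas.tsv"
    lines = fixture_path(name).read_text(encoding="utf-8").splitlines()
    _require_columns(lines[0].split("\t"), ("lncRNA", "miRNA", "log2fc", "p_value"), name)
    records = []
    for line in lines[1:]:
        lnc, mirna, log2fc, p = line.split("\t")
        if lnc != LINC00922:
            raise ParseError(f"fixture {name}: unexpected lncRNA {lnc!r}")
        records.append(
            DifferentialExpressionRecord(
                feature_id=normalize_mirna_id(mirna),
                feature_class="miRNA",
                log2fc=float(log2fc),
                p_value=float(p),
            )
        )
    return tuple(records)


def load_table3_fixture() -> list[DifferentialExpressionRecord]:
    """The 11 down-regulated candidate binding miRNAs of LINC00922."""
    return list(_table3())


@lru_cache(maxsize=None)
def _table4() -> tuple[tuple[str, DifferentialExpressionRecord], ...]:
    name = "table4_mirna_targets.tsv"
    lines = fixture_path(name).read_text(encoding="utf-8").splitlines()
    _require_columns(lines[0].split("\t"), ("miRNA", "gene", "log2fc", "p_value"), name)
    entries = []
    for line in lines[1:]:
        mirna, gene, log2fc, p = line.split("\t")
        entries.append(
            (
                normalize_mirna_id(mirna),
                DifferentialExpressionRecord(
                    feature_id=gene.strip(),
                    feature_class="mRNA",
                    log2fc=float(log2fc),
                    p_value=float(p),
                ),
            )
        )
    return tuple(entries)


def load_table4_fixture() -> list[tuple[str, DifferentialExpressionRecord]]:
    """Per-miRNA blocks of up-regulated predicted target genes.

    Returns one ``(miRNA_id, record)`` entry per printed row; gene
    symbols may repeat across miRNA blocks.
    """
    return list(_table4())


def load_consistent_pairs_fixture() -> list[InteractionPair]:
    """The six reported ceRNA-sign-consistent pairs around LINC00922."""
    return read_pair_table(fixture_path("consistent_pairs.tsv"))
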