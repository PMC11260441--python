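"""Reading and writing the package's plain-text file formats.

Pedigree CSV: header ``id,sire,dam``; unknown parent is an empty field or
the literal ``NA``.  Phenotype CSV: header ``id,rbw,sex,brood,dam,sire,
condition`` (only ``id`` and ``rbw`` are required); ``rbw`` is a
proportion in (0, 1) — values like 33.1 trip a unit guard, catching
percent-vs-proportion mistakes in hand-edited files.
"""

from __future__ import annotations

import logging

import pandas as pd

from .pedigree import Pedigree

__all__ = ["read_pedigree", "write_pedigree", "read_phenotypes",
           "write_phenotypes"]

logger = logging.getLogger("pedvar")

PHENOTYPE_COLUMNS = ("id", "rbw", "sex", "brood", "dam", "sire", "condition")


def read_pedigree(path) -> Pedigree:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "sire", "dam"):
        if col not in frame.columns:
            raise ValueError(f"pedigree file {path} lacks required column {col!r}")
    return Pedigree.from_frame(frame)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


def read_phenotypes(path, required=("id", "rbw")) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"id": str})
    for col in required:
        if col not in table.columns:
            raise ValueError(f"phenotype file {path} lacks required column "
                             f"{col!r}")
    n_missing = int(table["rbw"].isna().sum())
    if n_missing:
        logger.info("dropping %d row(s) with missing rbw from %s",
                    n_missing, path)
        table = table[table["rbw"].notna()].reset_index(drop=True)
    bad = table[(table["rbw"] <= 0) | (table["rbw"] >= 1)]
    if len(bad):
        raise ValueError(
            f"rbw values outside (0, 1) in {path} (e.g. {bad['rbw'].iloc[0]}); "
            "relative bar width must be a proportion, not a percentage")
    for col in PHENOTYPE_COLUMNS:
        if col not in table.columns:
            continue
        if col != "rbw":
            table[col] = table[col].fillna("").astype(str)
    return table


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
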