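"""Readers and atomic writers for the plain-text formats the tools exchange.

Formats: gene x tissue expression TSV (column 1 = gene id, header = tissue
names), GMT gene-set lines, one-id-per-line lists, particle CSV, count TSV
with a sample->group label TSV, and JSON reports. All writes go through a
write-temp-then-rename step so interrupted runs never leave truncated files.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager

import pandas as pd

__all__ = [
    "read_expression_tsv",
    "read_gmt",
    "read_id_list",
    "read_particles_csv",
    "read_counts_tsv",
    "read_groups_tsv",
    "atomic_write_text",
    "atomic_write_json",
    "atomic_to_csv",
]


def read_expression_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    return table


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member ids."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT needs name, description, >=1 id")
            sets[fields[0]] = set(fields[2:])
    return sets


def read_id_list(path) -> set[str]:
    with open(path, encoding="utf-8") as handle:
        return {line.strip() for line in handle if line.strip() and not line.startswith("#")}


def read_particles_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "diameter_nm" not in table.columns:
        raise ValueError("particle CSV must have a diameter_nm column")
    return table


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    return counts


def read_groups_tsv(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0].astype(str)


@contextmanager
def _replacing(path):
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-", text=True)
    os.close(fd)
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def atomic_write_text(text: str, path) -> None:
    with _replacing(path) as tmp:
        with open(tmp, "w", encoding="utf-8") as handle:
            handle.write(text)


def atomic_write_json(obj, path) -> None:
    atomic_write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n", path)


def atomic_to_csv(frame: pd.DataFrame, path, **kwargs) -> None:
    with _replacing(path) as tmp:
        frame.to_csv(tmp, **kwargs)
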