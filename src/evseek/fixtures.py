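"""Bundled reference datasets for worked examples and regression checks.

Three small fixtures ship with the package:

``proteome_overlap``
    Two protein-identifier sets whose Venn partition is 239 / 285 / 127
    (exclusive-to-A / shared / exclusive-to-B), the overlap structure
    reported for brain-organoid-derived EVs versus APLP1+ EVs. Only the
    partition counts are published, so the identifiers themselves are
    synthetic placeholders generated deterministically here.

``ev_concentrations``
    Total plasma EV concentration and APLP1+ EV concentration (particles/ml)
    as reported for human plasma: 5.2e11 total, 5.2e10 marker-positive.

``mirna_signatures``
    The 13 miRNAs reported as significantly differential between APLP1+ EVs
    and residual EVs, with their printed direction (+1 up-regulated in
    APLP1+ EVs, -1 down-regulated).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("proteome_overlap", "ev_concentrations", "mirna_signatures")

_MIRNA_DIRECTIONS = {
    # up-regulated in APLP1+ EVs
    "hsa-miR-30d-5p": 1,
    "hsa-miR-21-5p": 1,
    "hsa-miR-12136": 1,
    "hsa-miR-223-3p": 1,
    "hsa-miR-146a-5p": 1,
    "hsa-miR-423-3p": 1,
    # down-regulated in APLP1+ EVs (up in residual EVs)
    "hsa-miR-122-5p": -1,
    "hsa-miR-204-5p": -1,
    "hsa-miR-451a": -1,
    "hsa-miR-99b-5p": -1,
    "hsa-miR-139-5p": -1,
    "hsa-miR-99a-5p": -1,
    "hsa-miR-10a-5p": -1,
}


def _proteome_overlap() -> tuple[set[str], set[str]]:
    """Synthetic id sets realizing the published 239/285/127 partition."""
    only_a = {f"ORGEV{i:04d}" for i in range(1, 240)}
    shared = {f"SHARED{i:04d}" for i in range(1, 286)}
    only_b = {f"APEV{i:04d}" for i in range(1, 128)}
    return only_a | shared, only_b | shared


def load_fixture(name: str):
    """Return a packaged fixture by name; see the module docstring."""
    if name == "proteome_overlap":
        return _proteome_overlap()
    if name == "ev_concentrations":
        return 5.2e11, 5.2e10
    if name == "mirna_signatures":
        return pd.Series(_MIRNA_DIRECTIONS, name="direction")
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
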