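"""Provenance reports: what ran, on which inputs, with which settings."""

from __future__ import annotations

import hashlib
from importlib import metadata

from .io import atomic_write_json

__all__ = ["ProvenanceReport"]


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class ProvenanceReport:
    """Accumulates config, input digests, stage counts and warnings.

    Emitted for every run — including failed ones, where a partial report
    plus the error text is still written.
    """

    def __init__(self, command: str, config: dict | None = None):
        try:
            version = metadata.version("evseek")
        except metadata.PackageNotFoundError:  # pragma: no cover
            version = "unknown"
        self.payload: dict = {
            "tool": "evseek",
            "version": version,
            "command": command,
            "config": dict(config or {}),
            "inputs": {},
            "stage_counts": {},
            "warnings": [],
            "status": "running",
        }

    def add_input(self, label: str, path) -> None:
        self.payload["inputs"][label] = {"path": str(path), "sha256": _digest(path)}

    def add_stage_counts(self, counts: dict) -> None:
        self.payload["stage_counts"].update(counts)

    def warn(self, message: str) -> None:
        self.payload["warnings"].append(message)

    def finish(self, path, error: str | None = None, **extra) -> None:
        self.payload.update(extra)
        self.payload["status"] = "error" if error else "ok"
        if error:
            self.payload["error"] = error
        atomic_write_json(self.payload, path)
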