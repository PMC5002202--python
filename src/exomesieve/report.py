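"""Funnel reports and run manifests shared by the prioritization stages."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = ["FunnelStage", "FunnelReport", "RunManifest", "file_digest"]


@dataclass(frozen=True)
class FunnelStage:
    label: str
    rule: str
    count: int


@dataclass
class FunnelReport:
    """Ordered filtration stages with surviving-variant counts.

    Counts are non-increasing; stage 0 is the unfiltered input.
    """

    stages: list[FunnelStage]

    def __post_init__(self) -> None:
        counts = [s.count for s in self.stages]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"funnel counts must be non-increasing, got {counts}")

    @property
    def counts(self) -> list[int]:
        return [s.count for s in self.stages]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.stages]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": range(len(self.stages)),
                "label": self.labels,
                "rule": [s.rule for s in self.stages],
                "count": self.counts,
            }
        )

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"label": s.label, "rule": s.rule, "count": s.count}
                for s in self.stages
            ]
        }


def file_digest(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance sidecar for a pipeline run (timestamps excluded from any
    byte-identity comparison of primary outputs)."""

    tool_version: str
    subcommand: str
    seed: int | None = None
    config_digest: str | None = None
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    timestamp: str | None = None

    def add_input(self, path: str | os.PathLike) -> None:
        self.input_digests[os.path.basename(os.fspath(path))] = file_digest(path)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
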