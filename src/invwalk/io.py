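"""Run configuration, provenance headers and small serialisation helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__


@dataclass
class RunConfig:
    """A serialisable record of one CLI run.

    Round-trips exactly through YAML: ``RunConfig.from_yaml(cfg.to_yaml())
    == cfg``.
    """

    subcommand: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    out: str | None = None
    verbose: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def provenance_lines(self) -> list[str]:
        """Header lines stamped into every tabular output."""
        return [
            f"invwalk {__version__} | {self.subcommand}",
            f"config_hash={self.config_hash()} seed={self.seed}",
        ]


def write_tsv_rows(path: str | Path, header: list[str], rows, provenance=()) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_jsonl(path: str | Path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
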