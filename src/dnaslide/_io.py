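"""Plain-text table and manifest writers shared by the CLI and sweep code.

Tables are TSV with '#'-prefixed ``key=value`` metadata header lines, so
every artifact carries the parameters and seed needed to regenerate it.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_table", "read_table", "write_manifest"]


def write_table(path: str | Path, frame: pd.DataFrame, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t")
    return frame, meta


def write_manifest(path: str | Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
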