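"""Run manifests, JSON-line logging and markdown summaries for pipeline runs."""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

from . import __version__


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class JsonLineFormatter(logging.Formatter):
    """One JSON object per log line: stage, level, message."""

    def format(self, record: logging.LogRecord) -> str:
        payload = {
            "stage": getattr(record, "stage", record.name),
            "level": record.levelname,
            "message": record.getMessage(),
        }
        return json.dumps(payload)


def attach_json_log(out_dir: str | Path) -> logging.Handler:
    handler = logging.FileHandler(Path(out_dir) / "run.log")
    handler.setFormatter(JsonLineFormatter())
    handler.setLevel(logging.INFO)
    root = logging.getLogger("dirseq")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def detach_json_log(handler: logging.Handler) -> None:
    logging.getLogger("dirseq").removeHandler(handler)
    handler.close()


def write_run_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: dict[str, str | Path],
) -> Path:
    """Write the single run manifest for an output directory.

    Input digests and the config hash are deterministic for identical inputs;
    the timestamp records when the run happened and is informational only.
    """
    manifest = {
        "command": command,
        "config_sha256": sha256_obj(config),
        "seed": seed,
        "inputs": {name: sha256_file(p) for name, p in inputs.items() if Path(p).exists()},
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = Path(out_dir) / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path


def write_summary_md(out_dir: str | Path, sections: dict[str, str]) -> Path:
    path = Path(out_dir) / "summary.md"
    with open(path, "w") as fh:
        fh.write("# DiR-seq run summary\n\n")
        for title, body in sections.items():
            fh.write(f"## {title}\n\n{body}\n\n")
    return path
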