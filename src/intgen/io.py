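"""Run-directory I/O: TSV writers, manifests with content hashes."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def build_manifest(run_dir, config_echo: dict, stage_info: dict) -> dict:
    """Manifest of a run: resolved config, per-stage counts, and a content
    hash for every file under the run directory."""
    run_dir = Path(run_dir)
    files = {
        str(p.relative_to(run_dir)): sha256_file(p)
        for p in sorted(run_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    return {"config": config_echo, "stages": stage_info, "files": files}
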