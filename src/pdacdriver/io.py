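"""Shared table readers/writers and the run manifest.

All pipeline tables are TSV with a fixed float format so that reruns with
the same configuration are byte-identical; the manifest records sha256
checksums of every stage output to make silent changes detectable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a genes × samples matrix with the gene index as first column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index=True, float_format=FLOAT_FORMAT)
    return path


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path: str | Path, parameters: Mapping, outputs: Mapping[str, str | Path]
) -> Path:
    """Write a JSON manifest of parameters and per-output sha256 checksums."""
    path = Path(path)
    manifest = {
        "parameters": dict(parameters),
        "outputs": {
            name: {"path": str(p), "sha256": sha256_of(p)} for name, p in outputs.items()
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path
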