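"""Readers/writers and run manifests.

Everything is tab-separated text with fixed column orders and 9
significant digits, so reruns with identical inputs are byte-identical.
Every CLI run emits one ``manifest.json`` recording the command, a hash
of the resolved configuration, the seed, input/output paths and the
package version.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.9g"

__all__ = ["FLOAT_FMT", "write_table", "write_distance_matrix",
           "read_distance_matrix", "write_ordination", "write_manifest",
           "config_hash"]


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
    return path


def write_distance_matrix(D: pd.DataFrame, path) -> Path:
    return write_table(D.rename_axis("sample_id"), path, index=True)


def read_distance_matrix(path) -> pd.DataFrame:
    D = pd.read_csv(path, sep="\t", index_col=0)
    D.columns = D.columns.astype(str)
    D.index = D.index.astype(str)
    return D


def write_ordination(ordination, path) -> Path:
    """Tidy (sample, axis, coordinate, eigenvalue, proportion) text."""
    rows = []
    coords = ordination.coordinates_
    for j in range(coords.shape[1]):
        for i, sid in enumerate(ordination.sample_ids_):
            rows.append({
                "sample_id": sid, "axis": f"PCo{j + 1}",
                "coordinate": coords[i, j],
                "eigenvalue": ordination.eigenvalues_[j],
                "proportion_explained": ordination.proportion_explained_[j],
            })
    return write_table(pd.DataFrame(rows), path)


def config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(outdir, command: str, config, seed, inputs=(), outputs=()) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
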