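"""Plain-text readers and writers for the pipeline's exchange formats.

Expression matrices travel as TSV with the row identifier (brain structure or
cell type) in the first column and gene symbols as the remaining column
headers.  Gene sets travel as GMT (set id, description, then member genes,
tab-separated).  Configuration is YAML and run manifests are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml


def read_matrix_tsv(path: str | Path, index_name: str | None = None) -> pd.DataFrame:
    """Read a row-id × column-id real matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if index_name is not None:
        df.index.name = index_name
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a GMT file.

    Returns ``(sets, descriptions)`` where ``sets`` maps set id to a set of
    (uppercased, stripped) gene symbols and ``descriptions`` carries the second
    GMT column (used here for the GBD class label).
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need id, description, genes): {line!r}")
        set_id, desc = parts[0], parts[1]
        sets[set_id] = {g.strip().upper() for g in parts[2:] if g.strip()}
        descriptions[set_id] = desc
    return sets, descriptions


def write_gmt(
    sets: dict[str, set[str]], path: str | Path, descriptions: dict[str, str] | None = None
) -> None:
    descriptions = descriptions or {}
    lines = []
    for set_id in sets:
        genes = sorted(sets[set_id])
        lines.append("\t".join([set_id, descriptions.get(set_id, "na"), *genes]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_disease_tsv(path: str | Path) -> pd.DataFrame:
    """Read a DisGeNET-style long table (one record per disease–gene pair)."""
    df = pd.read_csv(path, sep="\t", dtype={"disease_id": str, "gene": str})
    required = {
        "disease_id", "disease_name", "gbd_class", "gene",
        "n_curated", "n_animal", "n_inferred", "n_literature",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene–disease table missing columns: {sorted(missing)}")
    return df


def write_gene_disease_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
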