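"""Plain-text readers and writers for the pipeline's exchange formats.

Everything is tab-separated: fold-change tables, expression matrices with a
sidecar sample sheet, pairing manifests, BED-like coverage tracks (0-based
half-open) and cohort tables. Candidate splicing events travel as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import FormatError

COVERAGE_COLUMNS = ["chrom", "start", "end", "depth", "mappability"]
MANIFEST_COLUMNS = ["sample_id", "cell_line", "condition", "biological_rep", "technical_rep"]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_fc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_line", "gene", "fold_change"} - set(df.columns)
    if missing:
        raise FormatError(f"fold-change table missing columns: {sorted(missing)}")
    return df


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Expression / signal matrix: first column is the row id."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "condition"} - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"pairing manifest missing columns: {sorted(missing)}")
    return df


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"coverage track missing columns: {sorted(missing)}")
    return df


def write_events(events: Mapping[str, Sequence[tuple[str, float]]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    serializable = {t: [[label, score] for label, score in cands] for t, cands in events.items()}
    Path(path).write_text(json.dumps(serializable, sort_keys=True))


def read_events(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    raw = json.loads(Path(path).read_text())
    return {t: [(str(lab), float(score)) for lab, score in cands] for t, cands in raw.items()}


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
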