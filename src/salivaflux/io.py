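"""Readers and writers for the pipeline's table dialects.

Metabolite tables are written as a trio of tab-separated files
(``<stem>_values.tsv``, ``<stem>_samples.tsv``, ``<stem>_metabolites.tsv``);
feature tables as ``<stem>_values.tsv`` + ``<stem>_features.tsv``.
Floats are serialized with repr-round-trip precision so re-running a
pipeline with the same seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import FeatureTable, MetaboliteTable

FLOAT_FMT = "%.12g"


def write_metabolite_table(table: MetaboliteTable, directory, stem: str) -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [
        directory / f"{stem}_values.tsv",
        directory / f"{stem}_samples.tsv",
        directory / f"{stem}_metabolites.tsv",
    ]
    table.values.to_csv(paths[0], sep="\t", float_format=FLOAT_FMT, index_label="sample_id")
    table.sample_meta.to_csv(paths[1], sep="\t", float_format=FLOAT_FMT, index_label="sample_id")
    table.metabolite_meta.to_csv(paths[2], sep="\t", index_label="metabolite")
    return paths


def read_metabolite_table(directory, stem: str) -> MetaboliteTable:
    directory = Path(directory)
    values = pd.read_csv(directory / f"{stem}_values.tsv", sep="\t", index_col="sample_id")
    sample_meta = pd.read_csv(directory / f"{stem}_samples.tsv", sep="\t", index_col="sample_id")
    metabolite_meta = pd.read_csv(
        directory / f"{stem}_metabolites.tsv", sep="\t", index_col="metabolite"
    )
    return MetaboliteTable(values, sample_meta, metabolite_meta)


def write_feature_table(table: FeatureTable, directory, stem: str) -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / f"{stem}_values.tsv", directory / f"{stem}_features.tsv"]
    table.values.to_csv(paths[0], sep="\t", float_format=FLOAT_FMT, index_label="feature")
    table.feature_meta.to_csv(paths[1], sep="\t", index_label="feature")
    return paths


def read_feature_table(directory, stem: str) -> FeatureTable:
    directory = Path(directory)
    values = pd.read_csv(directory / f"{stem}_values.tsv", sep="\t", index_col="feature")
    meta = pd.read_csv(directory / f"{stem}_features.tsv", sep="\t", index_col="feature")
    return FeatureTable(values, meta)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def write_tsv(df: pd.DataFrame, path, index_label: str = "id") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)
    return path
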