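"""Tabular I/O: TSV feature tables and metadata, YAML config, run logging."""

from __future__ import annotations

import json
import logging
import sys

import pandas as pd
import yaml

from .core import FeatureTable, validate_sample_meta


def setup_logging(stage: str, seed: "int | None" = None, level=logging.INFO):
    logger = logging.getLogger("acutephys")
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    logger.setLevel(level)
    logger.info("stage=%s seed=%s", stage, seed)
    return logger


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    return validate_sample_meta(meta)


def read_feature_table(path, ome: str, feature_meta_path=None) -> FeatureTable:
    """Features x samples TSV (first column = feature id)."""
    v = pd.read_csv(path, sep="\t", index_col=0)
    fm = (
        pd.read_csv(feature_meta_path, sep="\t", index_col=0)
        if feature_meta_path
        else None
    )
    return FeatureTable(v, ome, fm)


def write_feature_table(table: "FeatureTable | pd.DataFrame", path) -> None:
    v = table.values if isinstance(table, FeatureTable) else table
    v.to_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
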