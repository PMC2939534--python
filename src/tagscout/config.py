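"""Run configuration: defaults <- config file <- command-line flags.

The config file is flat key-value YAML.  Recognized keys: seed_k, match,
mismatch, xdrop, min_len, min_identity, max_query_len (alignment) and
insert_mean, insert_sd, insert_min, insert_max (pair geometry).
"""

from __future__ import annotations

import os

import yaml

from .errors import ValidationError
from .pairing import InsertModel
from .seedalign import AlignParams

_ALIGN_KEYS = {
    "seed_k": "k",
    "match": "match_score",
    "mismatch": "mismatch_score",
    "xdrop": "xdrop",
    "min_len": "min_aligned_len",
    "min_identity": "min_identity",
    "max_query_len": "max_query_len",
}
_INSERT_KEYS = {"insert_mean", "insert_sd", "insert_min", "insert_max"}


def load_config(path: str | os.PathLike | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} is not a flat key-value mapping")
    unknown = set(data) - set(_ALIGN_KEYS) - _INSERT_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    return data


def resolve_align_params(config: dict, overrides: dict) -> AlignParams:
    """defaults <- config file <- non-None CLI overrides (later wins)."""
    kwargs: dict = {}
    for file_key, field in _ALIGN_KEYS.items():
        if file_key in config:
            kwargs[field] = config[file_key]
    for field, value in overrides.items():
        if value is not None:
            kwargs[field] = value
    return AlignParams(**kwargs)


def resolve_insert_model(config: dict, overrides: dict) -> InsertModel:
    vals = {
        "mean": config.get("insert_mean", 1000),
        "sd": config.get("insert_sd", 50),
        "L_min": config.get("insert_min", 850),
        "L_max": config.get("insert_max", 1150),
    }
    for key, value in overrides.items():
        if value is not None:
            vals[key] = value
    return InsertModel(**vals)


def write_params_log(path: str | os.PathLike, params: AlignParams, insert: InsertModel, extra: dict | None = None) -> None:
    """Record the fully resolved run configuration."""
    with open(path, "w", newline="\n") as fh:
        for field in ("k", "match_score", "mismatch_score", "xdrop", "min_aligned_len", "min_identity", "max_query_len"):
            fh.write(f"align.{field} = {getattr(params, field)}\n")
        for field in ("mean", "sd", "L_min", "L_max", "orientation"):
            fh.write(f"insert.{field} = {getattr(insert, field)}\n")
        for key, value in (extra or {}).items():
            fh.write(f"{key} = {value}\n")
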