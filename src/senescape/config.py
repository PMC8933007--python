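"""Declarative pipeline configuration.

A single flat key -> scalar/list mapping, validated against the schema
below at load time.  Every analysis threshold used by the pipeline is a
key here so a run is fully described by one file.
"""

from __future__ import annotations

import logging

import yaml

logger = logging.getLogger(__name__)

#: key -> (default, type).  Lists are validated element-wise.
SCHEMA: dict[str, tuple] = {
    # significance cutoffs
    "peak_sig_cutoff": (0.001, float),       # adjusted-p cutoff for changing peaks
    "trajectory_p_cutoff": (0.001, float),
    "trajectory_top_n": (5000, int),
    "de_fdr_cutoff": (0.01, float),
    # interval analysis
    "near_gene_window_bp": (50_000, int),
    "n_perm": (1000, int),
    "expr_match_bins": (10, int),
    # single cell
    "score_n_bins": (24, int),
    "score_n_ctrl": (100, int),
    "pseudobulk_min_cells": (15, int),
    "pseudobulk_top_n_genes": (8000, int),
    # trajectory
    "pt_n_bins": (60, int),
    "kmedians_k": (25, int),
    "kmedians_max_iter": (100, int),
    "category_boundaries": ([20, 40], list),
    # trend / metabolomics
    "protein_norm_multiply": (True, bool),   # as printed; False divides instead
    "scale_timepoints": (False, bool),       # rescale T to fraction-complete
    # motif model
    "ridge_penalty": (1.0, float),
    "ridge_split_fraction": (2 / 3, float),
    "ridge_n_models": (10, int),
    "ridge_bootstrap": (True, bool),         # False: 10 identical full-data fits
}


def default_config() -> dict:
    return {k: v for k, (v, _) in SCHEMA.items()}


def load_config(path=None) -> dict:
    """Load a YAML config, overlay it on the defaults and validate."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must be a mapping")
        unknown = set(user) - set(SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    _validate(cfg)
    logger.info("config loaded (%d keys)", len(cfg))
    return cfg


def _validate(cfg: dict) -> None:
    for key, (_, typ) in SCHEMA.items():
        val = cfg[key]
        if typ is float and isinstance(val, int) and not isinstance(val, bool):
            val = cfg[key] = float(val)
        if typ is bool:
            ok = isinstance(val, bool)
        elif typ is list:
            ok = isinstance(val, (list, tuple))
        else:
            ok = isinstance(val, typ) and not isinstance(val, bool)
        if not ok:
            raise ValueError(f"config key {key!r}: expected {typ.__name__}, got {val!r}")
    for key in ("peak_sig_cutoff", "trajectory_p_cutoff", "de_fdr_cutoff"):
        if not 0 < cfg[key] <= 1:
            raise ValueError(f"config key {key!r} must be in (0, 1]")
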