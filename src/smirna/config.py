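"""Pipeline configuration: defaults, YAML loading, validation.

Every stage threshold lives here with its default; the defaults are the
values of the published rule set where one exists (18-nt minimum insert,
1 mismatch, -18 kcal/mol, 14 duplex pairs, 4-nt bulge, 5-nt asymmetry,
35-nt loop spacing, 10-nt flank, copy number 20, cut-site depth 3,
5-read noise filter, <1 per-million expression filter, 0.01 zero
sentinel, and the 4.0 / 2.5 / 0.75 duplex thresholds) and explicit,
documented choices elsewhere.  ``validate_config`` type- and
range-checks everything and rejects unknown keys before any computation
runs.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "validate_config"]


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 42,
    "simulate": {
        "n_mirnas": 30,
        "n_decoys": 12,
        "n_novel": 2,
        "depths": [20000, 20000],
        "error_rate": 0.001,
        "adaptor3": "TGGAATTCTCGGGTGCCAAG",
        "de_spec": {"mir-002": 4.0, "mir-003": 4.0, "mir-004": 0.25, "mir-005": 0.25},
        "dominant_share": 0.65,
        "decoy_fraction": 0.01,
        "novel_fraction": 0.02,
        "isomir_rate": 0.1,
    },
    "preprocess": {
        "min_len": 18,
        "max_len": 30,
        "min_mean_quality": 20.0,
        "min_overlap": 6,
    },
    "annotate": {
        "max_mismatch": 1,
        "isomir": True,
    },
    "references": {},   # class name -> FASTA path, for non-simulated runs
    "diffexpr": {
        "alpha": 0.01,
        "min_abs_log2fc": 1.0,
        "min_total_count": 5,
        "pvalue_method": "doubled",
        "zero_sentinel": 0.01,
        "min_norm_expression": 1.0,
    },
    "hairpin": {
        "min_reads": 5,
        "tag_len_min": 18,
        "tag_len_max": 26,
        "mature_len_min": 20,
        "mature_len_max": 24,
        "min_cut_depth": 3,
        "max_copy_number": 20,
        "max_mfe": -18.0,
        "max_spacing": 35,
        "min_duplex_pairs": 14,
        "max_bulge": 4,
        "max_asymmetry": 5,
        "flank": 10,
    },
    "targets": {
        "max_weighted_mismatches": 4.0,
        "max_weighted_mismatches_1_12": 2.5,
        "min_mfe_ratio": 0.75,
    },
    "qpcr": {
        "path": None,   # TSV: sample, group, ct_target, ct_reference
    },
}

# (type, min, max) for range-checked numeric leaves; None bound = open
_RANGES: dict[tuple[str, str], tuple[type, float | None, float | None]] = {
    ("simulate", "n_mirnas"): (int, 1, None),
    ("simulate", "n_decoys"): (int, 0, None),
    ("simulate", "n_novel"): (int, 0, None),
    ("simulate", "error_rate"): (float, 0.0, 1.0),
    ("simulate", "dominant_share"): (float, 0.0, 1.0),
    ("simulate", "decoy_fraction"): (float, 0.0, 1.0),
    ("simulate", "novel_fraction"): (float, 0.0, 1.0),
    ("simulate", "isomir_rate"): (float, 0.0, 1.0),
    ("preprocess", "min_len"): (int, 1, None),
    ("preprocess", "max_len"): (int, 1, None),
    ("preprocess", "min_mean_quality"): (float, 0.0, 60.0),
    ("preprocess", "min_overlap"): (int, 1, None),
    ("annotate", "max_mismatch"): (int, 0, 2),
    ("diffexpr", "alpha"): (float, 0.0, 1.0),
    ("diffexpr", "min_abs_log2fc"): (float, 0.0, None),
    ("diffexpr", "min_total_count"): (int, 0, None),
    ("diffexpr", "zero_sentinel"): (float, 0.0, 1.0),
    ("diffexpr", "min_norm_expression"): (float, 0.0, None),
    ("hairpin", "min_reads"): (int, 1, None),
    ("hairpin", "tag_len_min"): (int, 1, None),
    ("hairpin", "tag_len_max"): (int, 1, None),
    ("hairpin", "mature_len_min"): (int, 1, None),
    ("hairpin", "mature_len_max"): (int, 1, None),
    ("hairpin", "min_cut_depth"): (int, 0, None),
    ("hairpin", "max_copy_number"): (int, 1, None),
    ("hairpin", "max_mfe"): (float, None, 0.0),
    ("hairpin", "max_spacing"): (int, 0, None),
    ("hairpin", "min_duplex_pairs"): (int, 0, None),
    ("hairpin", "max_bulge"): (int, 0, None),
    ("hairpin", "max_asymmetry"): (int, 0, None),
    ("hairpin", "flank"): (int, 0, None),
    ("targets", "max_weighted_mismatches"): (float, 0.0, None),
    ("targets", "max_weighted_mismatches_1_12"): (float, 0.0, None),
    ("targets", "min_mfe_ratio"): (float, 0.0, 1.0),
}


def merge_config(overrides: dict[str, Any] | None) -> dict[str, Any]:
    """Defaults overlaid with a (possibly partial) override mapping."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if not overrides:
        return cfg
    for section, value in overrides.items():
        if isinstance(value, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(value)
        else:
            cfg[section] = value
    return cfg


def load_config(path: str | None) -> dict[str, Any]:
    """Load a YAML config file over the defaults and validate it."""
    overrides = None
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
    cfg = merge_config(overrides)
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def validate_config(cfg: dict[str, Any]) -> list[str]:
    """Return a list of problems (empty = valid); never raises."""
    errors: list[str] = []
    known_sections = set(DEFAULT_CONFIG)
    for section in cfg:
        if section not in known_sections:
            errors.append(f"unknown config section: {section!r}")
    if not isinstance(cfg.get("seed"), int):
        errors.append("seed must be an integer")
    _CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "miRNA", "genome")
    for section, defaults in DEFAULT_CONFIG.items():
        if not isinstance(defaults, dict):
            continue
        sub = cfg.get(section, {})
        if not isinstance(sub, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        if section == "references":
            for key in sub:
                if key not in _CLASSES:
                    errors.append(f"unknown reference class: {key!r}")
            continue
        for key in sub:
            if key not in defaults:
                errors.append(f"unknown key {section}.{key}")
        for key in defaults:
            if key not in sub:
                errors.append(f"missing key {section}.{key}")
    for (section, key), (typ, lo, hi) in _RANGES.items():
        sub = cfg.get(section)
        if not isinstance(sub, dict) or key not in sub:
            continue
        val = sub[key]
        if typ is float and isinstance(val, int) and not isinstance(val, bool):
            val = float(val)
        if not isinstance(val, typ) or isinstance(val, bool):
            errors.append(f"{section}.{key} must be {typ.__name__}, got {val!r}")
            continue
        if lo is not None and val < lo:
            errors.append(f"{section}.{key}={val} below minimum {lo}")
        if hi is not None and val > hi:
            errors.append(f"{section}.{key}={val} above maximum {hi}")
    # cross-field checks
    pre = cfg.get("preprocess", {})
    if (
        isinstance(pre.get("min_len"), int)
        and isinstance(pre.get("max_len"), int)
        and pre["min_len"] > pre["max_len"]
    ):
        errors.append("preprocess.min_len exceeds preprocess.max_len")
    sim = cfg.get("simulate", {})
    depths = sim.get("depths")
    if depths is not None:
        if (
            not isinstance(depths, (list, tuple))
            or len(depths) != 2
            or not all(isinstance(d, int) and d >= 0 for d in depths)
        ):
            errors.append("simulate.depths must be a pair of non-negative integers")
    de_spec = sim.get("de_spec")
    if de_spec is not None:
        if not isinstance(de_spec, dict):
            errors.append("simulate.de_spec must be a mapping name -> fold change")
        else:
            for name, fc in de_spec.items():
                if not isinstance(fc, (int, float)) or fc <= 0:
                    errors.append(f"simulate.de_spec[{name!r}] must be > 0")
    de = cfg.get("diffexpr", {})
    if de.get("pvalue_method") not in ("doubled", "sum"):
        errors.append("diffexpr.pvalue_method must be 'doubled' or 'sum'")
    return errors
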