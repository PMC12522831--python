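"""Workflow configuration (YAML) and sample sheet handling.

A single YAML file controls every stage; unknown or misspelled keys are hard
errors naming the offending key path, and a resolved copy (defaults filled
in) is written into the output directory for provenance.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml


class ConfigError(ValueError):
    pass


DEFAULTS: Dict = {
    "paths": {
        "fasta": None,
        "gtf": None,
        "mask_bed": None,
        "decoy_fasta": None,
        "sample_sheet": None,
        "out_dir": "damtrack_results",
    },
    "ingest": {
        "min_mapq": 30,
        "paired": False,
        "extend_to": 300,
        "decoy_seed_length": 21,
    },
    "normalize": {
        "pseudocount": 0.5,
        "offset_method": "kde-mode",
        "quantile_normalize": True,
        "exclude_mode": "both",
    },
    "peaks": {
        "min_score_threshold": 0.0,
        "min_fragments": 2,
        "merge_gap": 0,
        "n_permutations": 100,
        "fdr_threshold": 0.05,
        "rng_seed": 1,
    },
    "consensus": {
        "min_support": 2,
        "extra_extension": 0,
    },
    "annotate": {
        "promoter_window": 5000,
        "downstream_window": 3000,
    },
    "threads": 1,
}


def _merge(defaults: Dict, user: Dict, path: str = "") -> Dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict):
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            default = defaults[key]
            if default is not None and value is not None:
                bad = False
                if isinstance(default, bool):
                    bad = not isinstance(value, bool)
                elif isinstance(default, int):
                    bad = isinstance(value, bool) or not isinstance(value, int)
                elif isinstance(default, float):
                    bad = isinstance(value, bool) or not isinstance(value, (int, float))
                    if not bad:
                        value = float(value)
                else:
                    bad = not isinstance(value, type(default))
                if bad:
                    raise ConfigError(
                        f"configuration key {here!r} has type {type(value).__name__}, "
                        f"expected {type(default).__name__}"
                    )
            out[key] = value
    return out


def load_config(path: Optional[str] = None, overrides: Optional[Dict] = None) -> Dict:
    """Load and validate a YAML workflow config; missing keys take defaults."""
    user: Dict = {}
    if path is not None:
        with open(path) as handle:
            user = yaml.safe_load(handle) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} is not a YAML mapping")
    cfg = _merge(DEFAULTS, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: Dict, path) -> None:
    with open(path, "w") as out:
        yaml.safe_dump(cfg, out, sort_keys=False)


class SampleSheet:
    """Rows of (sample_id, role, group, path); ids unique and each group must
    contain at least one Dam-fusion and one Dam-only sample."""

    ROLES = ("fusion", "dam_only")

    def __init__(self, rows: List[Tuple[str, str, str, str]]):
        seen = set()
        for sid, role, group, _ in rows:
            if sid in seen:
                raise ConfigError(f"duplicate sample_id {sid!r} in sample sheet")
            seen.add(sid)
            if role not in self.ROLES:
                raise ConfigError(f"sample {sid!r} has unknown role {role!r} (use fusion/dam_only)")
        self.rows = rows
        for group in self.groups:
            if not self.fusion_ids(group) or not self.dam_ids(group):
                raise ConfigError(
                    f"group {group!r} needs at least one fusion and one dam_only sample"
                )

    @property
    def groups(self) -> List[str]:
        out = []
        for _, _, g, _ in self.rows:
            if g not in out:
                out.append(g)
        return out

    def fusion_ids(self, group: str) -> List[str]:
        return [sid for sid, role, g, _ in self.rows if g == group and role == "fusion"]

    def dam_ids(self, group: str) -> List[str]:
        return [sid for sid, role, g, _ in self.rows if g == group and role == "dam_only"]

    def path(self, sample_id: str) -> str:
        for sid, _, _, p in self.rows:
            if sid == sample_id:
                return p
        raise KeyError(sample_id)

    def role(self, sample_id: str) -> str:
        for sid, role, _, _ in self.rows:
            if sid == sample_id:
                return role
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> List[str]:
        return [sid for sid, _, _, _ in self.rows]

    @classmethod
    def read_tsv(cls, path, base_dir: Optional[Path] = None) -> "SampleSheet":
        rows: List[Tuple[str, str, str, str]] = []
        with open(path) as handle:
            header = handle.readline().strip().split("\t")
            required = ["sample_id", "role", "group", "path"]
            if header[: len(required)] != required:
                raise ConfigError(
                    f"sample sheet {path} must have columns {required}, got {header}"
                )
            for i, line in enumerate(handle, 2):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ConfigError(f"malformed sample sheet line {i} in {path}")
                p = parts[3]
                if base_dir is not None and not Path(p).is_absolute():
                    p = str(base_dir / p)
                rows.append((parts[0], parts[1], parts[2], p))
        return cls(rows)
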