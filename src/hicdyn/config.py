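"""Run configuration: defaults, validation, and unit normalisation.

The configuration is a plain mapping (YAML on disk) validated into a
:class:`RunConfig`. Unknown keys are rejected, genomic sizes given as strings
("40kb", "2Mb") are normalised to bp, and the four-stage design is enforced
because the flip and trend logic is defined over exactly four stages.
"""

from __future__ import annotations

import copy
import hashlib
import json
import re
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "validate_config", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_SIZE_RE = re.compile(r"^\s*([\d.]+)\s*(bp|kb|mb|gb)?\s*$", re.IGNORECASE)
_UNITS = {"bp": 1, "kb": 1_000, "mb": 1_000_000, "gb": 1_000_000_000, None: 1}


def parse_size(value) -> int:
    """Normalise '40kb' / '2Mb' / 40000 to integer bp."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return int(value)
    m = _SIZE_RE.match(str(value))
    if not m:
        raise ConfigError(f"cannot parse genomic size {value!r}")
    return int(float(m.group(1)) * _UNITS[m.group(2).lower() if m.group(2) else None])


DEFAULTS: dict = {
    "stages": ["eAEC", "HEC", "pre-HSC", "LT-HSC"],
    "seed": 0,
    "genome": {
        "n_chroms": 1,
        "chrom_length_bp": 20_000_000,
        "bin_size_bp": 40_000,
        "n_genes": 200,
    },
    "architecture": {
        "flip_fraction": 0.1078,
        "tad_count": 10,
        "loop_count": 30,
        "trajectory_mix": {"increasing": 0.3, "decreasing": 0.3,
                           "ephemeral": 0.2, "stable": 0.2},
        "ep_engaged_fraction": 0.409,
    },
    "matrix": {
        "depth_pairs": 1_000_000,
        "decay_exponent": 1.0,
        "comp_factor": 1.5,
        "n_replicates": 2,
    },
    "resolutions": {
        "compartments": 100_000,
        "domains": 40_000,
        "loops": 10_000,
        "fine": 5_000,
    },
    "balance": {"filter_low_count_fraction": 0.05, "tol": 1e-6, "max_iter": 3000},
    # Compartment calling balances the coarse (100 kb) matrices without the
    # quantile filter: at full depth every coarse bin is well covered, and a
    # quantile filter preferentially drops minority-compartment bins -- exactly
    # the bins whose flips the analysis is meant to classify. Only bins with a
    # zero marginal are dropped.
    "compartments": {"filter_low_count_fraction": 0.0},
    "insulation": {"window_bins": 5, "min_prominence": 0.1,
                   "min_strength_quantile": 0.0},
    "domain_score": {"n_sim": 1000, "fdr_cutoff": 0.001, "top_k": 1000},
    "loops": {"min_dist": 50_000, "max_dist": 2_000_000, "neighborhood_bins": 5,
              "fold_min": 1.5, "p_max": 0.05, "apa_flank_bins": 5},
    "annotate": {"trend_eps": 0.25, "gene_max_dist": 20_000},
}

_SIZE_KEYS = {
    ("genome", "chrom_length_bp"), ("genome", "bin_size_bp"),
    ("resolutions", "compartments"), ("resolutions", "domains"),
    ("resolutions", "loops"), ("resolutions", "fine"),
    ("loops", "min_dist"), ("loops", "max_dist"),
    ("annotate", "gene_max_dist"),
}


@dataclass
class RunConfig:
    params: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key):
        return self.params[key]

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.params["stages"])

    @property
    def seed(self) -> int:
        return int(self.params["seed"])

    def hash(self) -> str:
        blob = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(config: dict | None) -> RunConfig:
    """Merge a user mapping over the defaults and validate it.

    Raises :class:`ConfigError` listing every problem found.
    """
    merged = copy.deepcopy(DEFAULTS)
    errors: list[str] = []
    config = config or {}
    for key, val in config.items():
        if key not in merged:
            errors.append(f"unknown config section or key: {key!r}")
            continue
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                errors.append(f"section {key!r} must be a mapping")
                continue
            for k2, v2 in val.items():
                if k2 not in merged[key]:
                    errors.append(f"unknown key {key}.{k2}")
                else:
                    merged[key][k2] = v2
        else:
            merged[key] = val

    for sec, k in _SIZE_KEYS:
        try:
            merged[sec][k] = parse_size(merged[sec][k])
        except ConfigError as e:
            errors.append(str(e))

    if len(merged["stages"]) != 4:
        errors.append("exactly 4 stages are required for flip/trend logic")
    if merged["genome"]["bin_size_bp"] <= 0:
        errors.append("genome.bin_size_bp must be positive")
    if merged["genome"]["chrom_length_bp"] <= 0:
        errors.append("genome.chrom_length_bp must be positive")
    if merged["loops"]["max_dist"] <= merged["loops"]["min_dist"]:
        errors.append("loops.max_dist must exceed loops.min_dist")
    if not 0 <= merged["architecture"]["flip_fraction"] <= 1:
        errors.append("architecture.flip_fraction must be in [0, 1]")
    if merged["resolutions"]["domains"] != merged["genome"]["bin_size_bp"]:
        # the TAD grid is the genome grid; contradictory resolutions are an error
        errors.append("resolutions.domains must equal genome.bin_size_bp")
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(params=merged)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for k, v in overrides.items():
            data[k] = v
    return validate_config(data)
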