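"""Scoring configuration: every named threshold in one place.

Defaults follow the published framework's operating point: ENCODE-dialect
peak score 1000, DAF rarity cutoff 0.005, motif disruption threshold 3
(on the −10·log10 scale), reference-match gate 5e−4, knockdown fold-change
2.5, hot/ultra-hot hub quantiles 5%/1%, 500-bp GC bins, 1-Mbp burden
windows and q < 0.05 throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    # peak ingestion
    min_peak_score: float = 1000.0
    peak_score_exact: bool = True  # True: score == min; False: score >= min
    merge_cell_lines: bool = True

    # population panel
    daf_threshold: float = 0.005
    af_info_key: str = "AF"

    # GC background
    gc_bin_size: int = 500
    gc_min_bins_per_group: int = 50

    # hub scoring
    hub_hot_quantile: float = 0.05
    hub_ultra_quantile: float = 0.01
    hub_smoother_bandwidth: float = 1.0

    # cross-species conservation sigmoid
    gerp_midpoint: float = 2.0
    gerp_steepness: float = 2.9444389791664403  # ln(19): maps midpoint±1 to 0.05/0.95

    # motif disruption
    d_score_threshold: float = 3.0
    p_ref_gate: float = 5e-4
    p_ref_gate_direction: str = "le"  # "le": ref must match significantly; "ge": literal
    pwm_pseudocount: float = 0.001
    pwm_granularity: int = 1000  # score-range discretization steps for the p-value DP

    # knockdown association
    kd_fold_change: float = 2.5
    kd_two_sided: bool = True

    # tissue components
    beta_p_threshold: float = 0.05
    beta_bh_adjust: bool = False
    burden_window_bp: int = 1_000_000
    burden_q_threshold: float = 0.05
    de_q_threshold: float = 0.05

    # scoring scope
    score_outside_regulome: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))
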