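"""Pipeline and simulation configuration.

Defaults mirror the analysis conventions used throughout the package: cleft
confidence >= 50, partner/regional minima of 5 synapses, 40 nm density bins
smoothed with a 10-bin Gaussian, 314.15 um^2 annuli, and 20 %/50 % receptive
field contour levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Thresholds and numerical settings shared by the analysis stages."""

    cleft_threshold: int = 50
    min_partner_synapses: int = 5
    min_regional_connections: int = 5
    density_bin_nm: float = 40.0
    density_sigma_bins: float = 10.0
    annulus_area_um2: float = 314.15
    contour_levels: tuple = (0.2, 0.5)
    random_seed: int = 0
    #: per-axis multiplicative factors applied once at read time to convert
    #: voxel coordinates to nm; (1, 1, 1) means input is already in nm.
    coordinate_scale: tuple = (1.0, 1.0, 1.0)
    #: 'input' divides regional weights by the post neuron's input synapses
    #: in the region; 'both' uses input+output synapses.
    denominator_side: str = "input"

    def __post_init__(self) -> None:
        if self.cleft_threshold < 0 or self.min_partner_synapses < 0 or self.min_regional_connections < 0:
            raise ConfigError("thresholds must be >= 0")
        if self.density_bin_nm <= 0 or self.density_sigma_bins <= 0 or self.annulus_area_um2 <= 0:
            raise ConfigError("bin size, sigma and annulus area must be > 0")
        if not all(0.0 < lv < 1.0 for lv in self.contour_levels):
            raise ConfigError("contour levels must lie in (0, 1)")
        if self.denominator_side not in ("input", "both"):
            raise ConfigError("denominator_side must be 'input' or 'both'")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["contour_levels"] = list(self.contour_levels)
        d["coordinate_scale"] = list(self.coordinate_scale)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if "contour_levels" in d:
            d["contour_levels"] = tuple(d["contour_levels"])
        if "coordinate_scale" in d:
            d["coordinate_scale"] = tuple(d["coordinate_scale"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "contour_levels" in d:
            d["contour_levels"] = tuple(d["contour_levels"])
        if "coordinate_scale" in d:
            d["coordinate_scale"] = tuple(d["coordinate_scale"])
        return cls(**d)


@dataclass
class SynthConfig:
    """Parameters of the synthetic connectome generator.

    The default connectome plants ten MeTu-like subtypes with fifty neurons
    each on a hexagonal medulla lattice of side eleven (331 columns, 5 um
    pitch), retinotopic MeTu->TuBu convergence of ten, TuBu->ER divergence
    of two, and 5 % of contacts degraded below the cleft-confidence
    threshold.
    """

    columns_per_side: int = 11
    neurons_per_subtype: int = 50
    dendritic_synapses: int = 120
    presynaptic_sites: int = 40
    axonal_synapses: int = 30
    anchor_synapses: int = 60
    lobula_synapses: int = 25
    tubu_er_synapses: int = 40
    tutu_synapses: int = 10
    convergence: int = 10
    divergence: int = 2
    span_sigma_nm: float = 6000.0
    span_ratio_vertical: float = 3.0
    span_ratio_tiling: float = 1.2
    positional_noise_nm: float = 300.0
    cleft_low: int = 50
    cleft_high: int = 200
    low_cleft_fraction: float = 0.05
    n_background_contacts: int = 20
    n_autapses: int = 5
    lattice_pitch_nm: float = 5000.0
    column_depth_nm: float = 40000.0
    fingerprint_concentration: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.columns_per_side, self.neurons_per_subtype, self.dendritic_synapses,
            self.presynaptic_sites, self.axonal_synapses, self.anchor_synapses,
            self.tubu_er_synapses, self.tutu_synapses, self.convergence, self.divergence,
        )
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be >= 1")
        if self.positional_noise_nm < 0:
            raise ConfigError("positional noise sd must be >= 0")
        if not (0.0 <= self.low_cleft_fraction < 1.0):
            raise ConfigError("low_cleft_fraction must lie in [0, 1)")
        if self.convergence > self.neurons_per_subtype:
            raise ConfigError(
                f"convergence factor {self.convergence} exceeds available MeTu "
                f"count {self.neurons_per_subtype}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)
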