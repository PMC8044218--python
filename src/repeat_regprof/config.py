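"""Analysis configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml


@dataclass
class AnalysisConfig:
    """Constants governing the whole pipeline.

    Attributes
    ----------
    window_width
        Width in bp of the region centred on each element for meta-profiles.
    profile_bin
        Bin width in bp for meta-profiles; must divide ``window_width``.
    overlap_fraction
        Minimum fraction of a TFBS that must overlap an element for the
        site to be assigned to it (the ``-f`` style rule).
    coloc_window
        Two sites co-localise when their gap is strictly less than this
        many bp (half-open window extension).
    up_fc, down_fc
        Strict fold-change thresholds classifying transcripts as up- or
        down-regulated (case/reference ratio).
    de_p_cut
        Optional p-value cut applied on top of the fold-change classes.
    motif_p
        p-value threshold for motif hits under the exact background null.
    motif_bin
        Bin width in bp for consensus-coordinate histograms.
    proximity_max, proximity_step
        Range and increment in bp of the element-to-TSS proximity profile.
    n_permutations
        Number of genome rotations for the TSS enrichment null.
    alpha
        Familywise significance level; per-test level is ``alpha / k**2``
        for a k-TF co-localisation matrix.
    rng_seed
        Seed for every stochastic step.
    """

    window_width: int = 20_000
    profile_bin: int = 100
    overlap_fraction: float = 0.5
    coloc_window: int = 500
    up_fc: float = 2.0
    down_fc: float = 0.5
    de_p_cut: float = 0.05
    motif_p: float = 1e-4
    motif_bin: int = 5
    proximity_max: int = 20_000
    proximity_step: int = 1_000
    n_permutations: int = 10_000
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "window_width", "profile_bin", "coloc_window", "up_fc", "motif_p",
            "motif_bin", "proximity_max", "proximity_step", "n_permutations",
            "alpha",
        ]
        for field in positive:
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.window_width % self.profile_bin != 0:
            raise ValueError("profile_bin must divide window_width")
        if self.proximity_max % self.proximity_step != 0:
            raise ValueError("proximity_step must divide proximity_max")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if not 0 < self.down_fc < 1 < self.up_fc:
            raise ValueError("require 0 < down_fc < 1 < up_fc")
        if self.de_p_cut is not None and not 0 < self.de_p_cut <= 1:
            raise ValueError("de_p_cut must be in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
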