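"""Run configuration shared by the CLI stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional


@dataclass
class RunConfig:
    """Pipeline-wide parameters with their conventional defaults.

    Defaults: assumed capture efficiency 0.35; cell QC thresholds of 50,000
    exon reads and 50% exon mapping rate; low-expression cutoff of 2
    transcripts/cell for co-expression; group minima of 8 genes per TAD and 4
    per boundary; 10,000 bootstrap resamples of the median CV; detection-rate
    sliding window 9 with step 1; telegraph-parameter fit bounds 1e-3..1e3 in
    degradation units.
    """

    # capture / noise
    p_capture: float = 0.35
    # cell QC
    min_exon_reads: int = 50_000
    min_mapping_rate: float = 0.5
    # burst fitting
    fit_bounds: tuple = (1e-3, 1e3)
    min_cells: int = 50
    gof_alpha: float = 0.01
    # TAD analysis
    min_tad_genes: int = 8
    min_boundary_genes: int = 4
    boundary_fraction: float = 0.05
    n_boot: int = 10_000
    # co-expression
    low_expression_threshold: float = 2.0
    n_random_pairs: int = 10_000
    # detection rate
    window: int = 9
    step: int = 1
    # simulation geometry / effects
    n_tads: int = 20
    genes_per_tad: int = 10
    boundary_genes_per_boundary: int = 5
    n_cells: int = 150
    expression_regime: str = "well_expressed"  # or "wide"; see DatasetConfig
    share_tad_kon: bool = False
    kon_jitter_sigma: float = 0.0
    boundary_coexpr_sigma: float = 0.0
    # reproducibility
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_capture <= 1.0):
            raise ValueError(f"p_capture must be in (0, 1], got {self.p_capture}")
        if not (0.0 < self.boundary_fraction < 0.5):
            raise ValueError("boundary_fraction must be in (0, 0.5)")
        if self.expression_regime not in ("wide", "well_expressed"):
            raise ValueError(
                f"unknown expression_regime {self.expression_regime!r}; "
                "expected 'wide' or 'well_expressed'"
            )
        if not (0.0 <= self.min_mapping_rate <= 1.0):
            raise ValueError("min_mapping_rate must be in [0, 1]")
        lo, hi = self.fit_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid fit bounds {self.fit_bounds}")
        for name in (
            "min_exon_reads",
            "min_cells",
            "min_tad_genes",
            "min_boundary_genes",
            "n_boot",
            "window",
            "step",
            "n_tads",
            "genes_per_tad",
            "n_cells",
            "n_random_pairs",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "fit_bounds" in data:
            data["fit_bounds"] = tuple(data["fit_bounds"])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
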