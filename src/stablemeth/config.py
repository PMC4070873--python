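"""Configuration objects for the simulator and the pipeline.

Defaults encode the study design this package targets: two liver cancer
cell lines, a cytokine treatment applied for four days with a further
four-day release (timepoints T4 and T8), biological triplicates for the
treatment arrays and duplicates for the sorted CD133 fractions, and the
standard analysis thresholds (FDR < 0.05 with |delta-beta| >= 0.10 for the
persistent treatment signature; p < 0.001 with |delta-beta| >= 0.05 in both
cell lines for the CD133 comparison; DMRs of >= 2 probes within 100 bp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is out of its valid range."""


@dataclass
class SimConfig:
    """Parameters of the synthetic HM450-style dataset.

    Planted effects come in three classes: *persistent* (same signed
    delta-beta in both cell lines at both timepoints), *transient* (effect
    at T4 only) and *line-specific* (effect in one cell line only).
    """

    n_probes: int = 10_000
    n_samples_per_cell: int = 3            # replicates per line x treatment x timepoint
    frac_persistent: float = 0.05
    frac_transient: float = 0.05
    frac_line_specific: float = 0.05
    delta_effect: float = 0.15             # planted |delta-beta|
    noise_precision: float = 50.0          # beta-distribution concentration
    batch_sd: float = 0.2                  # per-probe batch shift SD, M scale
    n_batches: int = 2
    n_dmr_clusters: int = 0
    cluster_span_bp: int = 300
    type2_distortion: float = 1.3          # type II compression toward 0.5
    seed: int = 0
    # CD133 fraction arrays (sorted subpopulations); 0 disables them.
    n_cd133_replicates: int = 0
    frac_cd133: float = 0.0                # CD133-only differential probes
    cd133_overlap: float = 0.0             # share of persistent probes also CD133-differential
    frac_cross_reactive: float = 0.01
    low_mode: float = 0.10                 # baseline bimodal mixture modes
    high_mode: float = 0.85
    mode_concentration: float = 50.0
    clip: float = 0.02                     # keep shifted means inside (clip, 1-clip)

    def validate(self) -> None:
        def bad(name: str, msg: str) -> None:
            raise ConfigError(f"SimConfig.{name}: {msg}")

        if self.n_probes < 1:
            bad("n_probes", "must be a positive integer")
        if self.n_samples_per_cell < 1:
            bad("n_samples_per_cell", "must be a positive integer")
        for name in ("frac_persistent", "frac_transient", "frac_line_specific",
                     "frac_cd133", "cd133_overlap", "frac_cross_reactive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, f"must be in [0, 1], got {v}")
        total = self.frac_persistent + self.frac_transient + self.frac_line_specific
        if total > 1.0 + 1e-12:
            bad("frac_persistent", f"effect fractions sum to {total:.3f} > 1")
        if not 0.0 < self.delta_effect <= 0.5:
            bad("delta_effect", f"must be in (0, 0.5], got {self.delta_effect}")
        if not (self.noise_precision > 0):
            bad("noise_precision", "must be positive (math.inf allowed for noiseless)")
        if self.batch_sd < 0:
            bad("batch_sd", "must be nonnegative")
        if self.n_dmr_clusters < 0:
            bad("n_dmr_clusters", "must be nonnegative")
        if self.cluster_span_bp < 1:
            bad("cluster_span_bp", "must be a positive integer")
        if self.type2_distortion < 1.0:
            bad("type2_distortion", "must be >= 1")
        if self.n_cd133_replicates < 0:
            bad("n_cd133_replicates", "must be nonnegative")
        if not 0.0 < self.clip < 0.5:
            bad("clip", "must be in (0, 0.5)")
        # planted shift must stay observable after clipping on at least one side
        if self.delta_effect >= 1.0 - 2 * self.clip:
            bad("delta_effect", "delta does not fit inside the clipped (0,1) interval")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration with the default analysis thresholds."""

    # input paths (ignored when simulate=True)
    beta: str | None = None
    detection_p: str | None = None
    bead_count: str | None = None
    manifest: str | None = None
    sample_sheet: str | None = None
    expression: str | None = None
    cross_reactive: str | None = None
    outdir: str = "stablemeth_out"

    # stage toggles
    simulate: bool = True
    run_qc: bool = True
    run_quantile_norm: bool = True
    run_bmiq: bool = True
    run_sva: bool = True
    run_cd133: bool = False
    run_dmr: bool = True
    run_enrichment: bool = True
    run_expression: bool = False

    # analysis thresholds
    detp_threshold: float = 0.05
    min_beads: int = 3
    q_max: float = 0.05
    delta_min_tgfb: float = 0.10
    p_max_cd133: float = 0.001
    delta_min_cd133: float = 0.05
    max_gap: int = 100
    min_probes: int = 2
    n_draws: int = 999
    max_surrogates: int = 5
    m_eps: float = 0.001
    seed: int = 0

    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        def bad(name: str, msg: str) -> None:
            raise ConfigError(f"PipelineConfig.{name}: {msg}")

        for name in ("detp_threshold", "q_max", "p_max_cd133"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                bad(name, f"must be in (0, 1], got {v}")
        for name in ("delta_min_tgfb", "delta_min_cd133"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, f"must be in [0, 1], got {v}")
        if self.min_beads < 0:
            bad("min_beads", "must be nonnegative")
        if self.max_gap < 1:
            bad("max_gap", "must be positive")
        if self.min_probes < 1:
            bad("min_probes", "must be positive")
        if self.n_draws < 1:
            bad("n_draws", "must be positive")
        if not 0.0 < self.m_eps < 0.1:
            bad("m_eps", "must be in (0, 0.1)")
        if not self.simulate and self.beta is None:
            bad("beta", "required when simulate is off")
        self.sim.validate()

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig fields: {sorted(unknown)}")
        cfg = cls(**d, sim=SimConfig.from_dict(sim) if isinstance(sim, dict) else sim)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full configuration, for the run manifest."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def infinite_precision(x: float) -> bool:
    return math.isinf(x)
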