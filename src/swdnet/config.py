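"""Experiment configuration: one serializable record that re-runs identically.

The configuration covers every stage (layout, probabilities, weights, node
parameters, integration, screening, protocols, detector, coupling-analysis
parameters) plus a master seed.  Per-stage child seeds derive from the
master seed by a fixed mapping, so stages can be re-run independently.
All times in configurations and outputs are seconds of renormalized time;
indices are 0-based; intervals are half-open ``[start, end)``.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .connectivity import ProbabilityTable
from .granger import GCParams
from .layout import NetworkLayout, Population, Region
from .observables import DetectorConfig
from .screening import ScreeningCriteria

__all__ = ["ExperimentConfig", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage (below 2**31)."""
    import zlib

    h = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentConfig:
    master_seed: int = 0
    output_dir: str = "swdnet_out"
    # network generation
    counts: dict = field(default_factory=dict)  # "POP:region" -> int
    probabilities: dict = field(default_factory=dict)  # "TPOP<-SPOP:region" -> p
    w_exc: float = 0.1
    w_inh: float = 0.1
    tau_steps: list = field(default_factory=lambda: [9, 10, 11, 12, 13])
    collateral_rule: str = "mixed"
    copy_fraction: float = 0.15
    # node / integration
    a: float = 0.8
    b: float = 0.008
    gamma: float = 0.0033
    dt_model: float = 0.5
    time_scale: float = 1.0 / 1700.0
    duration_s: float = 25.0
    # screening
    n_candidates: int = 200
    prominence_threshold: float = 0.25
    min_std: float = 0.5
    max_swd_duration_s: float = 60.0
    # detector
    k_on: float = 3.0
    k_off: float = 2.0
    band_hz: list = field(default_factory=lambda: [4.0, 12.0])
    # coupling analysis
    gc_f0_hz: float = 8.0
    gc_window_s: float = 1.0
    gc_step_s: float = 0.25

    # ------------------------------------------------------------------

    def layout(self) -> NetworkLayout:
        if not self.counts:
            return NetworkLayout.default()
        counts = {}
        for key, n in self.counts.items():
            pop_s, reg_s = key.split(":")
            counts[(Population(pop_s), Region(reg_s))] = int(n)
        return NetworkLayout(counts)

    def probability_table(self) -> ProbabilityTable:
        if not self.probabilities:
            return ProbabilityTable.default()
        probs = {}
        for key, p in self.probabilities.items():
            pair, reg_s = key.split(":")
            tpop_s, spop_s = pair.split("<-")
            probs[(Population(tpop_s), Population(spop_s), Region(reg_s))] = float(p)
        return ProbabilityTable(probs)

    def screening_criteria(self) -> ScreeningCriteria:
        return ScreeningCriteria(
            prominence_threshold=self.prominence_threshold,
            min_std=self.min_std,
            max_swd_duration_s=self.max_swd_duration_s,
            copy_fraction=self.copy_fraction,
            detector=self.detector(),
        )

    def detector(self) -> DetectorConfig:
        return DetectorConfig(
            k_on=self.k_on, k_off=self.k_off, band_hz=tuple(self.band_hz)
        )

    def gc_params(self, f_samp: float = 3400.0) -> GCParams:
        return GCParams(
            f_samp=f_samp,
            f0=self.gc_f0_hz,
            window_s=self.gc_window_s,
            step_s=self.gc_step_s,
        )

    # ------------------------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
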