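"""Timed perturbations that initiate, maintain and terminate discharges.

Three seizure-initiation mechanisms are modelled: a brief gradual rise of
intracortical excitability (focal PY→PY coupling ramped 0.1 → 0.115 over
0.3 s), a transient doubling of the trigeminal drive onto thalamic relay
cells (NT→TC coupling stepped 0.1 → 0.2 for 0.3 s), and 0.3 s of 8 Hz
sinusoidal stimulation of the cortical populations.  A maintenance process
raises reticular-to-cortex coupling magnitude by 15% for 5 s shortly after
seizure onset, lengthening the discharge, and a 130 Hz / 1 s pulse train
on the focal cortex can abort an ongoing discharge.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .layout import NetworkLayout, Population, Region

__all__ = [
    "ProtocolEvent",
    "initiation_excitability",
    "initiation_trigeminal",
    "initiation_lowfreq",
    "maintenance",
    "termination_hfs",
]

#: (population, region) selector; region ``None`` means any region.
PopSel = tuple[Population, Region | None]


@dataclass
class ProtocolEvent:
    """A timed modification of the network during integration.

    ``coupling_scale`` events multiply a selected edge set by a factor
    (restoring baseline exactly at ``t_end``); ``additive_sinusoid`` and
    ``additive_pulse_train`` add a drive term to dx/dt of selected nodes.
    """

    kind: str  # coupling_scale | additive_sinusoid | additive_pulse_train
    t_start: float
    t_end: float
    # coupling_scale
    target_pops: tuple[PopSel, ...] = ()
    source_pops: tuple[PopSel, ...] = ()
    factor: float = 1.0
    ramp: str = "step"  # step | linear
    # additive drives
    nodes: tuple[PopSel, ...] = ()
    amplitude: float = 0.0
    frequency_hz: float = 0.0
    pulse_width_s: float = 0.0
    pulse_period_s: float = 0.0
    label: str = ""
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("event must satisfy t_start < t_end")
        if self.kind not in (
            "coupling_scale",
            "additive_sinusoid",
            "additive_pulse_train",
        ):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.ramp not in ("step", "linear"):
            raise ValueError(f"unknown ramp shape {self.ramp!r}")
        if self.kind == "additive_pulse_train" and self.pulse_period_s <= 0:
            raise ValueError("pulse train needs a positive period")

    # -- selectors ---------------------------------------------------------

    def _select(self, layout: NetworkLayout, sels: tuple[PopSel, ...]) -> list[int]:
        idx: list[int] = []
        for pop, region in sels:
            found = layout.indices(pop, region)
            if not found:
                raise ValueError(
                    f"selector ({pop.value}, {region.value if region else 'any'}) "
                    "matches no nodes in this layout"
                )
            idx.extend(found)
        return sorted(set(idx))

    def node_indices(self, layout: NetworkLayout) -> list[int]:
        return self._select(layout, self.nodes)

    def edge_mask(self, layout: NetworkLayout):
        import numpy as np

        ti = self._select(layout, self.target_pops)
        sj = self._select(layout, self.source_pops)
        mask = np.zeros((layout.n_total, layout.n_total), dtype=bool)
        mask[np.ix_(ti, sj)] = True
        return mask

    # -- time courses ------------------------------------------------------

    def scale_factor(self, t_s: float) -> float:
        """Multiplier applied to the selected edges at time ``t_s``."""
        if not (self.t_start <= t_s < self.t_end):
            return 1.0
        if self.ramp == "linear":
            frac = (t_s - self.t_start) / (self.t_end - self.t_start)
            return 1.0 + (self.factor - 1.0) * frac
        return self.factor

    def drive_value(self, t_s: float) -> float:
        """Additive drive (model units) at time ``t_s``."""
        if not (self.t_start <= t_s < self.t_end):
            return 0.0
        rel = t_s - self.t_start
        if self.kind == "additive_sinusoid":
            return self.amplitude * math.sin(2.0 * math.pi * self.frequency_hz * rel)
        if self.kind == "additive_pulse_train":
            return self.amplitude if (rel % self.pulse_period_s) < self.pulse_width_s else 0.0
        return 0.0

    def describe(self) -> dict:
        return {
            "kind": self.kind,
            "label": self.label,
            "t_start": self.t_start,
            "t_end": self.t_end,
            "factor": self.factor,
            "amplitude": self.amplitude,
        }


# ---------------------------------------------------------------------------
# standard protocol constructors


def initiation_excitability(
    t0: float,
    *,
    duration_s: float = 0.3,
    factor: float = 1.15,
    region: Region | None = Region.FOCAL,
) -> ProtocolEvent:
    """Preictal rise of intracortical excitability.

    Focal PY→PY coupling is ramped linearly from its basic value 0.1 up to
    0.115 (factor 1.15) over 0.3 s and then returns instantly to baseline;
    the discharge starts after the ramp ends, not during it.
    """
    return ProtocolEvent(
        kind="coupling_scale",
        t_start=t0,
        t_end=t0 + duration_s,
        target_pops=((Population.PY, region),),
        source_pops=((Population.PY, region),),
        factor=factor,
        ramp="linear",
        label="initiation_excitability",
    )


def initiation_trigeminal(
    t0: float, *, duration_s: float = 0.3, factor: float = 2.0
) -> ProtocolEvent:
    """External drive from n. trigeminus onto thalamic relay (VPM) cells.

    NT→TC coupling is stepped from 0.1 to 0.2 for 0.3 s.
    """
    return ProtocolEvent(
        kind="coupling_scale",
        t_start=t0,
        t_end=t0 + duration_s,
        target_pops=((Population.TC, None),),
        source_pops=((Population.NT, None),),
        factor=factor,
        ramp="step",
        label="initiation_trigeminal",
    )


def initiation_lowfreq(
    t0: float,
    *,
    duration_s: float = 0.3,
    amplitude: float = 1.0,
    frequency_hz: float = 8.0,
    region: Region | None = None,
) -> ProtocolEvent:
    """Low-frequency (8 Hz) sinusoidal stimulation of the cortex.

    The sinusoid (amplitude 1 in model units, zero phase at onset) is added
    to dx/dt of all PY and IN nodes for 0.3 s; discharges elicited this way
    begin within the stimulation window.
    """
    return ProtocolEvent(
        kind="additive_sinusoid",
        t_start=t0,
        t_end=t0 + duration_s,
        nodes=((Population.PY, region), (Population.IN, region)),
        amplitude=amplitude,
        frequency_hz=frequency_hz,
        label="initiation_lowfreq",
    )


def maintenance(
    t_onset: float,
    *,
    delay_s: float = 1.0,
    duration_s: float = 5.0,
    factor: float = 1.15,
    pathway: str = "py_to_tc",
    region: Region | None = None,
) -> ProtocolEvent:
    """Seizure-maintenance coupling increase.

    Starting ``delay_s`` (0.5–1.5 s window) after the detected onset, the
    selected pathway's coupling magnitude is raised by 15% (0.1 → 0.115)
    for 5 s.  The default pathway scales the corticothalamic feedforward
    (PY → TC), which in this network reliably sustains a running
    discharge; the alternative ``pathway="re_to_cortex"`` scales
    reticular-to-cortex inhibition instead (sign preserved, −0.1 →
    −0.115), which damps rather than sustains the cortical rhythm here.
    """
    if pathway == "re_to_cortex":
        targets: tuple[PopSel, ...] = (
            (Population.PY, region),
            (Population.IN, region),
        )
        sources: tuple[PopSel, ...] = ((Population.RE, region),)
    elif pathway == "py_to_tc":
        targets = ((Population.TC, region),)
        sources = ((Population.PY, region),)
    else:
        raise ValueError(f"unknown maintenance pathway {pathway!r}")
    return ProtocolEvent(
        kind="coupling_scale",
        t_start=t_onset + delay_s,
        t_end=t_onset + delay_s + duration_s,
        target_pops=targets,
        source_pops=sources,
        factor=factor,
        ramp="step",
        label="maintenance",
    )


def termination_hfs(
    t_stim: float,
    *,
    duration_s: float = 1.0,
    amplitude: float = 1.0,
    pulse_rate_hz: float = 130.0,
    pulse_width_s: float = 0.0006,
    pulse_period_s: float | None = None,
    region: Region | None = Region.FOCAL,
) -> ProtocolEvent:
    """High-frequency stimulation aborting an ongoing discharge.

    A rectangular pulse train (amplitude 1 model unit, 0.6 ms pulses at
    130 Hz, 1 s total) applied to all focal PY and IN nodes.  Setting
    ``pulse_period_s`` overrides the rate, e.g. 0.0086 for the
    0.6 ms-pulse + 8 ms-gap variant.
    """
    period = pulse_period_s if pulse_period_s is not None else 1.0 / pulse_rate_hz
    return ProtocolEvent(
        kind="additive_pulse_train",
        t_start=t_stim,
        t_end=t_stim + duration_s,
        nodes=((Population.PY, region), (Population.IN, region)),
        amplitude=amplitude,
        pulse_width_s=pulse_width_s,
        pulse_period_s=period,
        label="termination_hfs",
    )
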