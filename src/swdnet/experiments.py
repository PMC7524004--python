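"""Reference experiments: seizure trials, duration statistics, twin runs.

A *pair* is an accepted focal + surrounding matrix combination composed
into the full 500-node circuit.  A *trial* initiates one discharge with a
chosen mechanism on top of a settled interictal state (set by the trial
seed), applies the maintenance process relative to the initiation, and
detects discharges on the cortex LFP.  Because the dynamics are
deterministic, a protocoled run and a protocol-free (or reduced-protocol)
twin coincide up to the first perturbed sample, which makes paired
comparisons (maintenance effect, stimulation-induced termination) exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .connectivity import CouplingMatrix, compose_network, sample_matrix
from .dynamics import SimulationConfig, simulate
from .layout import NetworkLayout
from .observables import (
    DetectorConfig,
    LFPSet,
    SWDEvent,
    compute_lfp,
    detect_swd,
)
from .protocols import (
    initiation_excitability,
    initiation_lowfreq,
    initiation_trigeminal,
    maintenance,
    termination_hfs,
)

__all__ = [
    "PairSpec",
    "build_pair",
    "seizure_trial",
    "TrialResult",
    "REFERENCE_PAIRS",
    "reference_pair_specs",
    "trial_seed_for",
    "run_duration_trials",
    "maintenance_twin",
    "hfs_twin",
]

#: Accepted focal/surrounding pair seeds, frozen from the screening
#: pipeline run at the default criteria (the first four pairs accepted in
#: screening order; see docs/methods.md).  Each entry is
#: (focal_seed, surround_seed, compose_seed, tau_steps).
REFERENCE_PAIRS: list[tuple[int, int, int, int]] = [
    (3, 103, 203, 12),
    (9, 109, 209, 13),
    (21, 121, 221, 10),
    (33, 133, 233, 12),
]


@dataclass(frozen=True)
class PairSpec:
    """Seeds and delay identifying one composed focal/surrounding pair."""

    focal_seed: int
    surround_seed: int
    compose_seed: int
    tau_steps: int
    copy_fraction: float = 0.15

    def key(self) -> tuple:
        return (self.focal_seed, self.surround_seed, self.compose_seed, self.tau_steps)


def build_pair(spec: PairSpec) -> CouplingMatrix:
    """Regenerate the composed network of one pair deterministically."""
    mf = sample_matrix(
        NetworkLayout.focal_only(),
        tau_steps=spec.tau_steps,
        seed=spec.focal_seed,
        copy_fraction=spec.copy_fraction,
    )
    ms = sample_matrix(
        NetworkLayout.surround_only(),
        tau_steps=spec.tau_steps,
        seed=spec.surround_seed,
        copy_fraction=spec.copy_fraction,
    )
    return compose_network(
        mf, ms, seed=spec.compose_seed, copy_fraction=spec.copy_fraction
    )


def reference_pair_specs(copy_fraction: float = 0.15) -> list[PairSpec]:
    """The frozen accepted pairs as :class:`PairSpec` objects."""
    return [
        PairSpec(f, s, c, tau, copy_fraction=copy_fraction)
        for f, s, c, tau in REFERENCE_PAIRS
    ]


def trial_seed_for(base_seed: int, pair_index: int, k: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    import numpy as np

    ss = np.random.SeedSequence([base_seed, pair_index, k])
    return int(ss.generate_state(1)[0] % (2**31))


_INITIATORS = {
    "excitability": initiation_excitability,
    "trigeminal": initiation_trigeminal,
    "lowfreq": initiation_lowfreq,
}


@dataclass
class TrialResult:
    """Outcome of one initiation trial."""

    events: list[SWDEvent]
    lfp: LFPSet
    t0_s: float
    onset_estimate_s: float
    protocol_labels: list[str] = field(default_factory=list)

    @property
    def discharge(self) -> SWDEvent | None:
        """First event starting at or after the initiation."""
        for ev in self.events:
            if ev.onset_s >= self.t0_s - 0.5:
                return ev
        return None


def seizure_trial(
    full: CouplingMatrix,
    trial_seed: int,
    *,
    mechanism: str = "lowfreq",
    t0_s: float = 8.0,
    with_maintenance: bool = True,
    maintenance_delay_s: float = 0.5,
    maintenance_duration_s: float = 5.0,
    maintenance_pathway: str = "py_to_tc",
    hfs_after_onset_s: float | None = None,
    duration_s: float = 25.0,
    detector: DetectorConfig | None = None,
) -> TrialResult:
    """Run one deterministic discharge trial and detect events.

    The initiation mechanism fires at ``t0_s`` over a settled interictal
    state (the trial seed fixes the initial conditions, hence the network
    state at initiation).  The maintenance process is anchored to the
    mechanism's expected onset: the stimulation start for the driven
    mechanisms, the end of the ramp for the excitability mechanism.
    ``hfs_after_onset_s`` adds the 130 Hz pulse train that many seconds
    after the expected onset.
    """
    if mechanism not in _INITIATORS:
        raise ValueError(f"unknown initiation mechanism {mechanism!r}")
    init_ev = _INITIATORS[mechanism](t0_s)
    onset_est = init_ev.t_end if mechanism == "excitability" else t0_s
    protocol = [init_ev]
    if with_maintenance:
        protocol.append(
            maintenance(
                onset_est,
                delay_s=maintenance_delay_s,
                duration_s=maintenance_duration_s,
                pathway=maintenance_pathway,
            )
        )
    if hfs_after_onset_s is not None:
        protocol.append(termination_hfs(onset_est + hfs_after_onset_s))
    cfg = SimulationConfig(duration_s=duration_s, seed=trial_seed, record="compartments")
    res = simulate(full, cfg, protocol=protocol)
    lfp = compute_lfp(res)
    det = detector or DetectorConfig(baseline=(max(t0_s - 5.0, 1.0), t0_s - 0.5))
    if det.baseline is None:
        det = replace(det, baseline=(max(t0_s - 5.0, 1.0), t0_s - 0.5))
    events = detect_swd(lfp, det)
    return TrialResult(
        events=events,
        lfp=lfp,
        t0_s=t0_s,
        onset_estimate_s=onset_est,
        protocol_labels=[ev.label for ev in protocol],
    )


def run_duration_trials(
    specs: list[PairSpec] | None = None,
    n_trials: int = 10,
    *,
    mechanism: str = "lowfreq",
    base_seed: int = 0,
    duration_s: float = 25.0,
) -> list[dict]:
    """Initiation trials across pairs; one row per trial.

    Row keys: pair seeds, trial seed, ``elicited`` flag, and (when a
    discharge was detected) ``onset_s`` / ``offset_s`` / ``duration_s`` /
    ``dominant_frequency_hz`` plus the mechanism's window ``t0_s`` and
    estimated onset.
    """
    specs = specs if specs is not None else reference_pair_specs()
    rows: list[dict] = []
    for p_idx, spec in enumerate(specs):
        full = build_pair(spec)
        for k in range(n_trials):
            ts = trial_seed_for(base_seed, p_idx, k)
            trial = seizure_trial(
                full, ts, mechanism=mechanism, duration_s=duration_s
            )
            ev = trial.discharge
            row = {
                "pair": spec.key(),
                "pair_index": p_idx,
                "trial_seed": ts,
                "mechanism": mechanism,
                "t0_s": trial.t0_s,
                "onset_estimate_s": trial.onset_estimate_s,
                "elicited": ev is not None,
            }
            if ev is not None:
                row.update(
                    onset_s=ev.onset_s,
                    offset_s=ev.offset_s,
                    duration_s=ev.duration_s,
                    dominant_frequency_hz=ev.dominant_frequency_hz,
                )
            rows.append(row)
    return rows


def _suprathreshold_span(full, trial_seed, *, mechanism, duration_s) -> float:
    """Discharge span without maintenance, minimum-duration filter off.

    Without maintenance the response outlives the stimulus only by the
    relaxation time, usually below the detector's 1 s minimum; the twin
    comparison therefore measures the raw suprathreshold span.
    """
    det = DetectorConfig(min_duration_s=0.0)
    trial = seizure_trial(
        full,
        trial_seed,
        mechanism=mechanism,
        with_maintenance=False,
        duration_s=duration_s,
        detector=det,
    )
    ev = trial.discharge
    return ev.duration_s if ev is not None else 0.0


def maintenance_twin(
    full: CouplingMatrix,
    trial_seed: int,
    *,
    mechanism: str = "lowfreq",
    duration_s: float = 25.0,
) -> dict:
    """Deterministic twin comparison: discharge span with vs without maintenance."""
    with_m = seizure_trial(
        full, trial_seed, mechanism=mechanism, duration_s=duration_s
    )
    ev = with_m.discharge
    span_without = _suprathreshold_span(
        full, trial_seed, mechanism=mechanism, duration_s=duration_s
    )
    dur_with = ev.duration_s if ev is not None else 0.0
    ratio = dur_with / span_without if span_without > 0 else float("inf")
    return {
        "duration_with_s": dur_with,
        "span_without_s": span_without,
        "ratio": ratio,
        "elicited": ev is not None,
    }


def hfs_twin(
    full: CouplingMatrix,
    trial_seed: int,
    *,
    mechanism: str = "lowfreq",
    hfs_after_onset_s: float = 4.0,
    duration_s: float = 25.0,
) -> dict:
    """Stimulated vs unstimulated twin; classifies termination success.

    A discharge counts as terminated by the 1 s / 130 Hz train when the
    stimulated run's offset falls before the end of stimulation + 0.5 s
    and earlier than the unstimulated twin's offset.
    """
    twin = seizure_trial(full, trial_seed, mechanism=mechanism, duration_s=duration_s)
    stim = seizure_trial(
        full,
        trial_seed,
        mechanism=mechanism,
        hfs_after_onset_s=hfs_after_onset_s,
        duration_s=duration_s,
    )
    ev_twin = twin.discharge
    ev_stim = stim.discharge
    hfs_start = twin.onset_estimate_s + hfs_after_onset_s
    hfs_end = hfs_start + 1.0
    applicable = ev_twin is not None and ev_twin.offset_s > hfs_start
    terminated = (
        applicable
        and ev_stim is not None
        and ev_stim.offset_s <= hfs_end + 0.5
        and ev_stim.offset_s < ev_twin.offset_s - 1e-9
    )
    return {
        "twin_offset_s": ev_twin.offset_s if ev_twin else None,
        "stim_offset_s": ev_stim.offset_s if ev_stim else None,
        "hfs_window": (hfs_start, hfs_end),
        "applicable": applicable,
        "terminated": bool(terminated),
    }
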