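"""Matrix screening: select circuits with the desired dynamical phenotypes.

Random draws of the structured connectivity produce qualitatively different
dynamics: many networks fall silent, many lock permanently into the
high-amplitude 7–8 Hz collective rhythm, and a minority sustain irregular
broadband activity or sit close to the locking threshold.  Screening
filters candidates the way the original matrix-selection procedure does:

* *surrounding* matrices must generate non-decaying irregular activity
  without a well-established main spectral peak (normal background);
* *focal* matrices must be able to generate a detected spike-and-wave
  discharge in response to the brief intracortical-excitability ramp, with
  the discharge terminating spontaneously within an allowed duration.

A focal matrix alone cannot express the interictal background that
initiation presupposes, so its discharge capability is evaluated with the
candidate embedded in a composed network next to a reference surrounding
matrix (part of the screening criteria).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .connectivity import CouplingMatrix, ProbabilityTable, compose_network, sample_matrix
from .dynamics import IntegrationBlowupError, SimulationConfig, simulate
from .layout import NetworkLayout, Population, Region
from .observables import DetectorConfig, compute_lfp, detect_swd, _moving_rms
from .protocols import initiation_excitability, initiation_lowfreq, maintenance

__all__ = [
    "ScreeningCriteria",
    "ScreeningReport",
    "spectral_prominence",
    "classify_surrounding",
    "classify_focal",
    "screen_batch",
    "screen_pairs",
    "relaxation_time",
]


@dataclass(frozen=True)
class ScreeningCriteria:
    """Thresholds of the matrix-selection procedure.

    ``prominence_threshold`` bounds the ratio of the largest 3–15 Hz
    spectral peak to the total 1–100 Hz power for an acceptable
    *background* (surrounding) matrix; ``min_std`` is the non-decaying
    floor on the cortex LFP.  Focal candidates must elicit a detected
    discharge that ends within ``max_swd_duration_s``.  All decisions are
    made on ``sim_duration_s`` of activity after ``burn_in_s`` of
    discarded transient.
    """

    prominence_threshold: float = 0.25
    min_std: float = 0.5
    max_swd_duration_s: float = 60.0
    sim_duration_s: float = 20.0
    burn_in_s: float = 2.0
    copy_fraction: float = 0.15
    #: pair-level screening: minimum envelope coefficient of variation of
    #: the composed interictal baseline (rules out a steady lock) and
    #: minimum post-entrainment relaxation time (critical slowing marks
    #: discharge-prone circuits)
    min_baseline_cv: float = 0.04
    min_relaxation_s: float = 0.08
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    #: reference surrounding matrix (seed, compose seed) used to embed a
    #: focal candidate for the initiation test
    context_surround_seed: int = 103
    context_compose_seed: int = 203
    ramp_t0_s: float = 8.0


@dataclass
class ScreeningReport:
    """Decision plus the measured statistics for one candidate."""

    accepted: bool
    reason: str
    stats: dict = field(default_factory=dict)


def spectral_prominence(
    channel: np.ndarray,
    f_samp: float,
    peak_band: tuple[float, float] = (3.0, 15.0),
    total_band: tuple[float, float] = (1.0, 100.0),
) -> float:
    """Largest peak power in ``peak_band`` relative to ``total_band`` power.

    Welch estimate with 2 s windows (0.5 Hz resolution).  A well-locked
    7–8 Hz rhythm concentrates most of its power in one bin and scores
    high; broadband irregular activity scores low.
    """
    x = channel - np.mean(channel)
    nper = min(len(x), int(2 * f_samp))
    freqs, pxx = sps.welch(x, fs=f_samp, nperseg=nper, detrend="constant")
    tot = pxx[(freqs >= total_band[0]) & (freqs <= total_band[1])].sum()
    if tot <= 0:
        return 0.0
    sel = (freqs >= peak_band[0]) & (freqs <= peak_band[1])
    return float(pxx[sel].max() / tot)


def _cortex_after_burnin(mat: CouplingMatrix, criteria: ScreeningCriteria, seed: int):
    cfg = SimulationConfig(
        duration_s=criteria.burn_in_s + criteria.sim_duration_s,
        seed=seed,
        record="compartments",
    )
    res = simulate(mat, cfg)
    c = res.population_sum(Population.PY) + res.population_sum(Population.IN)
    i0 = int(criteria.burn_in_s * res.f_samp)
    return c[i0:], res.f_samp


def classify_surrounding(
    C_surround: CouplingMatrix,
    criteria: ScreeningCriteria | None = None,
    seed: int = 0,
) -> ScreeningReport:
    """Accept a surrounding matrix iff it sustains peak-free irregular activity."""
    criteria = criteria or ScreeningCriteria()
    for key in C_surround.layout.counts:
        if key[1] is Region.FOCAL:
            raise ValueError("surrounding candidate contains focal compartments")
    try:
        cortex, fs = _cortex_after_burnin(C_surround, criteria, seed)
    except IntegrationBlowupError as exc:
        return ScreeningReport(False, f"blow-up at step {exc.step}")
    std = float(cortex.std())
    if std < criteria.min_std:
        return ScreeningReport(False, "decaying", {"std": std})
    prom = spectral_prominence(cortex, fs)
    stats = {"std": std, "prominence": prom}
    if prom >= criteria.prominence_threshold:
        return ScreeningReport(False, "dominant spectral peak", stats)
    return ScreeningReport(True, "accepted", stats)


def _context_network(
    C_focal: CouplingMatrix, criteria: ScreeningCriteria
) -> CouplingMatrix:
    """Embed a focal candidate next to the reference surrounding matrix."""
    ms = sample_matrix(
        NetworkLayout.surround_only(),
        tau_steps=C_focal.tau_steps,
        seed=criteria.context_surround_seed,
        copy_fraction=criteria.copy_fraction,
    )
    return compose_network(
        C_focal,
        ms,
        seed=criteria.context_compose_seed,
        copy_fraction=criteria.copy_fraction,
    )


def classify_focal(
    C_focal: CouplingMatrix,
    criteria: ScreeningCriteria | None = None,
    seed: int = 0,
    *,
    with_maintenance: bool = True,
) -> ScreeningReport:
    """Accept a focal matrix iff the excitability ramp elicits a discharge.

    The candidate is embedded in the reference composed network, the
    intracortical excitability ramp is applied after a settled interictal
    baseline, and the cortex LFP is passed to the discharge detector.
    Acceptance requires a detected event starting at or after the ramp
    and ending spontaneously within the allowed duration; the report
    stores onset, offset, duration and dominant frequency.
    """
    criteria = criteria or ScreeningCriteria()
    for key in C_focal.layout.counts:
        if key[1] is Region.SURROUND:
            raise ValueError("focal candidate contains surrounding compartments")
    full = _context_network(C_focal, criteria)
    t0 = criteria.ramp_t0_s
    ramp = initiation_excitability(t0)
    protocol = [ramp]
    if with_maintenance:
        # anchored at the expected onset (end of the ramp), 0.5 s delay
        protocol.append(maintenance(ramp.t_end, delay_s=0.5))
    cfg = SimulationConfig(
        duration_s=criteria.burn_in_s + criteria.sim_duration_s,
        seed=seed,
        record="compartments",
    )
    try:
        res = simulate(full, cfg, protocol=protocol)
    except IntegrationBlowupError as exc:
        return ScreeningReport(False, f"blow-up at step {exc.step}")
    lfp = compute_lfp(res)
    det = replace(criteria.detector, baseline=(criteria.burn_in_s, t0 - 0.5))
    events = [ev for ev in detect_swd(lfp, det) if ev.onset_s >= t0 - det.rms_window_s]
    if not events:
        return ScreeningReport(False, "no discharge elicited", {"n_events": 0})
    ev = events[0]
    stats = {
        "onset_s": ev.onset_s,
        "offset_s": ev.offset_s,
        "duration_s": ev.duration_s,
        "dominant_frequency_hz": ev.dominant_frequency_hz,
    }
    end = cfg.duration_s
    if ev.duration_s > criteria.max_swd_duration_s:
        return ScreeningReport(False, "discharge too long", stats)
    if ev.offset_s >= end - 0.5:
        return ScreeningReport(False, "no spontaneous termination", stats)
    return ScreeningReport(True, "accepted", stats)


def relaxation_time(
    full: CouplingMatrix,
    seed: int = 3,
    *,
    entrain_t0_s: float = 8.0,
    entrain_len_s: float = 1.0,
    settle_factor: float = 1.2,
) -> tuple[float, dict]:
    """Time for the cortex envelope to resettle after 1 s of 8 Hz entrainment.

    Networks close to their synchronization threshold relax slowly
    (critical slowing down); the relaxation time is the screening statistic
    for discharge-prone composed circuits.  Returns ``(relax_s, stats)``.
    """
    ev = initiation_lowfreq(entrain_t0_s, duration_s=entrain_len_s)
    cfg = SimulationConfig(
        duration_s=entrain_t0_s + entrain_len_s + 11.0,
        seed=seed,
        record="compartments",
    )
    res = simulate(full, cfg, protocol=[ev])
    c = res.population_sum(Population.PY) + res.population_sum(Population.IN)
    c = c - c.mean()
    fs = res.f_samp
    rms = _moving_rms(c, int(0.25 * fs))
    base = rms[int(4 * fs) : int((entrain_t0_s - 0.5) * fs)]
    mu = float(base.mean())
    after = rms[int((entrain_t0_s + entrain_len_s + 0.05) * fs) :]
    below = np.nonzero(after < settle_factor * mu)[0]
    relax = float(below[0] / fs) if below.size else float("inf")
    return relax, {"baseline_rms": mu, "baseline_cv": float(base.std() / mu)}


def screen_pairs(
    n_candidates: int,
    criteria: ScreeningCriteria | None = None,
    seed: int = 0,
    *,
    surround_offset: int = 100,
    compose_offset: int = 200,
    tau_cycle: tuple[int, ...] = (9, 10, 11, 12, 13),
) -> tuple[list[dict], list[tuple[int, ScreeningReport]]]:
    """Screen composed focal/surrounding pairs for discharge capability.

    This is the operative selection procedure: subnetworks near the
    reference operating point are silent in isolation, so both the
    interictal-background requirement (sustained, not steadily locked)
    and the discharge requirement are properties of the *composed*
    circuit.  Candidate ``k`` uses focal seed ``seed + k``, surrounding
    seed ``seed + k + surround_offset`` and composition seed ``seed + k
    + compose_offset``, with the conduction delay cycling over
    ``tau_cycle`` — fully deterministic and resumable.

    Stages per candidate: (1) the composed baseline must be non-decaying
    with envelope CV above ``min_baseline_cv``, and the relaxation time
    after 1 s of 8 Hz entrainment must exceed ``min_relaxation_s``
    (critical slowing); (2) the excitability ramp, with the maintenance
    process anchored at its end, must elicit a detected discharge that
    terminates spontaneously within the allowed duration.

    Returns accepted pair descriptors (dicts with the seeds, delay and
    measured statistics) and all per-candidate reports.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    criteria = criteria or ScreeningCriteria()
    accepted: list[dict] = []
    reports: list[tuple[int, ScreeningReport]] = []
    for k in range(n_candidates):
        fseed = seed + k
        sseed = fseed + surround_offset
        cseed = fseed + compose_offset
        tau = tau_cycle[fseed % len(tau_cycle)]
        try:
            mf = sample_matrix(
                NetworkLayout.focal_only(),
                tau_steps=tau,
                seed=fseed,
                copy_fraction=criteria.copy_fraction,
            )
            ms = sample_matrix(
                NetworkLayout.surround_only(),
                tau_steps=tau,
                seed=sseed,
                copy_fraction=criteria.copy_fraction,
            )
            full = compose_network(
                mf, ms, seed=cseed, copy_fraction=criteria.copy_fraction
            )
            relax, stats = relaxation_time(full, seed=3)
        except IntegrationBlowupError as exc:
            reports.append((fseed, ScreeningReport(False, f"blow-up at step {exc.step}")))
            continue
        if stats["baseline_rms"] < criteria.min_std:
            reports.append((fseed, ScreeningReport(False, "decaying", stats)))
            continue
        if stats["baseline_cv"] < criteria.min_baseline_cv:
            reports.append(
                (fseed, ScreeningReport(False, "steady lock (no irregular background)", stats))
            )
            continue
        if relax < criteria.min_relaxation_s:
            stats["relaxation_s"] = relax
            reports.append((fseed, ScreeningReport(False, "fast relaxation", stats)))
            continue
        stats["relaxation_s"] = relax
        rep = classify_focal(
            mf,
            replace(
                criteria,
                context_surround_seed=sseed,
                context_compose_seed=cseed,
            ),
            seed=3,
        )
        rep.stats.update(stats)
        reports.append((fseed, rep))
        if rep.accepted:
            accepted.append(
                {
                    "focal_seed": fseed,
                    "surround_seed": sseed,
                    "compose_seed": cseed,
                    "tau_steps": tau,
                    **rep.stats,
                }
            )
    return accepted, reports


def screen_batch(
    n_candidates: int,
    layout: NetworkLayout,
    probs: ProbabilityTable | None = None,
    criteria: ScreeningCriteria | None = None,
    seed: int = 0,
    *,
    kind: str | None = None,
    tau_cycle: tuple[int, ...] = (9, 10, 11, 12, 13),
) -> tuple[list[CouplingMatrix], list[tuple[int, ScreeningReport]]]:
    """Generate and classify ``n_candidates`` matrices for ``layout``.

    Per-candidate seeds derive deterministically from the master ``seed``;
    the batch is fully reproducible and resumable.  ``kind`` selects the
    classifier ("focal" or "surrounding"; inferred from the layout when
    omitted).  Returns the accepted matrices and a per-candidate report
    list (an empty accepted set is a valid outcome).
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    criteria = criteria or ScreeningCriteria()
    if kind is None:
        regions = {r for (_p, r) in layout.counts}
        kind = "surrounding" if Region.SURROUND in regions else "focal"
    if kind not in ("focal", "surrounding"):
        raise ValueError(f"unknown candidate kind {kind!r}")
    accepted: list[CouplingMatrix] = []
    reports: list[tuple[int, ScreeningReport]] = []
    for k in range(n_candidates):
        cand_seed = int(
            np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)
        )
        tau = tau_cycle[k % len(tau_cycle)]
        mat = sample_matrix(
            layout,
            probs,
            tau_steps=tau,
            seed=cand_seed,
            copy_fraction=criteria.copy_fraction,
        )
        if kind == "surrounding":
            rep = classify_surrounding(mat, criteria, seed=cand_seed)
        else:
            rep = classify_focal(mat, criteria, seed=cand_seed)
        reports.append((cand_seed, rep))
        if rep.accepted:
            accepted.append(mat)
    return accepted, reports
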