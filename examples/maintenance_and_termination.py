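"""Maintenance elongation and stimulation-induced termination, via twins.

The dynamics are deterministic, so a protocoled run and its
reduced-protocol twin are identical up to the first perturbed sample:
differences are attributable purely to the protocol.
"""
from swdnet.experiments import (
    build_pair,
    hfs_twin,
    maintenance_twin,
    reference_pair_specs,
)

full = build_pair(reference_pair_specs()[0])

m = maintenance_twin(full, trial_seed=11)
print(
    f"with maintenance: {m['duration_with_s']:.2f} s | without: "
    f"{m['span_without_s']:.2f} s | ratio {m['ratio']:.1f}"
)
print("The 15% corticothalamic coupling increase sustains the discharge.")

h = hfs_twin(full, trial_seed=11)
print(
    f"\n130 Hz stimulation window {h['hfs_window'][0]:.1f}-{h['hfs_window'][1]:.1f} s; "
    f"unstimulated offset {h['twin_offset_s']:.2f} s, "
    f"stimulated offset {h['stim_offset_s']:.2f} s -> "
    f"{'terminated' if h['terminated'] else 'not terminated'}"
)
print("An earlier stimulated offset inside the window counts as an abortion.")
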