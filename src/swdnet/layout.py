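"""Compartment layout of the two-subnetwork cortico-thalamo-cortical circuit.

The model network is organised into five cell populations — cortical pyramidal
cells (PY), cortical interneurons (IN), thalamocortical relay cells of the VPM
(TC), reticular-thalamic cells (RE) and an external trigeminal input
compartment (NT) — each split (except NT) into a small *focal* subnetwork,
where seizures can be generated, and a larger *surrounding* subnetwork
responsible for normal background activity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Population(str, Enum):
    PY = "PY"
    IN = "IN"
    TC = "TC"
    RE = "RE"
    NT = "NT"


class Region(str, Enum):
    FOCAL = "focal"
    SURROUND = "surrounding"
    EXTERNAL = "external"


#: Populations whose outgoing couplings are excitatory (positive weight).
EXCITATORY = frozenset({Population.PY, Population.TC, Population.NT})
#: Populations whose outgoing couplings are inhibitory (negative weight).
INHIBITORY = frozenset({Population.IN, Population.RE})

#: Default node counts: 40 focal + 160 surrounding PY, 10 + 40 IN,
#: 40 + 80 TC, 40 + 80 RE, and 10 external trigeminal nodes — 500 in total.
DEFAULT_COUNTS: dict[tuple[Population, Region], int] = {
    (Population.PY, Region.FOCAL): 40,
    (Population.IN, Region.FOCAL): 10,
    (Population.TC, Region.FOCAL): 40,
    (Population.RE, Region.FOCAL): 40,
    (Population.PY, Region.SURROUND): 160,
    (Population.IN, Region.SURROUND): 40,
    (Population.TC, Region.SURROUND): 80,
    (Population.RE, Region.SURROUND): 80,
    (Population.NT, Region.EXTERNAL): 10,
}

# Block order used for index assignment (focal block first, then surrounding,
# then the external input, mirroring how sub-matrices are composed).
_BLOCK_ORDER: tuple[tuple[Population, Region], ...] = (
    (Population.PY, Region.FOCAL),
    (Population.IN, Region.FOCAL),
    (Population.TC, Region.FOCAL),
    (Population.RE, Region.FOCAL),
    (Population.PY, Region.SURROUND),
    (Population.IN, Region.SURROUND),
    (Population.TC, Region.SURROUND),
    (Population.RE, Region.SURROUND),
    (Population.NT, Region.EXTERNAL),
)


@dataclass(frozen=True)
class NetworkLayout:
    """Node counts per (population, region) and derived contiguous index ranges.

    Index ranges are half-open ``[start, stop)`` intervals over
    ``[0, n_total)``; every node belongs to exactly one compartment.
    """

    counts: dict[tuple[Population, Region], int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )

    def __post_init__(self) -> None:
        for (pop, region), n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {pop.value}/{region.value}")
            if pop is Population.NT and region is not Region.EXTERNAL:
                raise ValueError("NT nodes must have region 'external'")
            if pop is not Population.NT and region is Region.EXTERNAL:
                raise ValueError(f"{pop.value} cannot be external")

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def ranges(self) -> dict[tuple[Population, Region], range]:
        """Contiguous, non-overlapping index range of each compartment."""
        out: dict[tuple[Population, Region], range] = {}
        start = 0
        for key in _BLOCK_ORDER:
            if key not in self.counts:
                continue
            n = self.counts[key]
            out[key] = range(start, start + n)
            start += n
        # Any non-standard keys (e.g. reduced layouts) appended afterwards.
        for key, n in self.counts.items():
            if key not in out:
                out[key] = range(start, start + n)
                start += n
        return out

    def indices(self, pop: Population, region: Region | None = None) -> list[int]:
        """Node indices of one population, optionally restricted to a region."""
        idx: list[int] = []
        for (p, r), rng in self.ranges().items():
            if p is pop and (region is None or r is region):
                idx.extend(rng)
        return idx

    def population_of(self) -> list[Population]:
        """Per-node population labels (length ``n_total``)."""
        labels: list[Population] = [Population.PY] * self.n_total
        for (p, _r), rng in self.ranges().items():
            for i in rng:
                labels[i] = p
        return labels

    def region_of(self) -> list[Region]:
        """Per-node region labels (length ``n_total``)."""
        labels: list[Region] = [Region.FOCAL] * self.n_total
        for (_p, r), rng in self.ranges().items():
            for i in rng:
                labels[i] = r
        return labels

    @classmethod
    def default(cls) -> "NetworkLayout":
        return cls(dict(DEFAULT_COUNTS))

    @classmethod
    def focal_only(cls, include_nt: bool = True) -> "NetworkLayout":
        """Layout of the focal subnetwork alone (optionally with NT input)."""
        counts = {k: v for k, v in DEFAULT_COUNTS.items() if k[1] is Region.FOCAL}
        if include_nt:
            counts[(Population.NT, Region.EXTERNAL)] = DEFAULT_COUNTS[
                (Population.NT, Region.EXTERNAL)
            ]
        return cls(counts)

    @classmethod
    def surround_only(cls) -> "NetworkLayout":
        """Layout of the surrounding subnetwork alone."""
        counts = {k: v for k, v in DEFAULT_COUNTS.items() if k[1] is Region.SURROUND}
        return cls(counts)
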