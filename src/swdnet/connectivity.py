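"""Random structured connectivity of the cortico-thalamo-cortical network.

Directed couplings between populations are drawn independently per ordered
node pair with a per-pathway probability (focal targets are wired more
densely than surrounding ones).  Only two weights occur: ``+w_exc`` for
edges whose *source* is an excitatory population (PY, TC, NT) and
``-w_inh`` for edges from inhibitory populations (IN, RE) — a Dale-like
sign rule.  A single conduction delay ``tau_steps`` (in integration steps)
is shared by all edges of one matrix.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .layout import EXCITATORY, NetworkLayout, Population, Region

__all__ = [
    "ProbabilityTable",
    "CouplingMatrix",
    "sample_matrix",
    "apply_collaterals",
    "compose_network",
    "save_matrix",
    "load_matrix",
]

P = Population

# Default connection probabilities: {(target_pop, source_pop, target_region): p}.
# Pathways not listed carry probability zero.  Focal targets are coupled four
# times more densely than surrounding ones; the trigeminal input projects only
# to focal TC (relay) cells.
_FOCAL = {
    (P.PY, P.PY): 0.036,
    (P.PY, P.IN): 0.126,
    (P.PY, P.TC): 0.045,
    (P.IN, P.PY): 0.036,
    (P.IN, P.IN): 0.126,
    (P.IN, P.TC): 0.045,
    (P.TC, P.PY): 0.054,
    (P.TC, P.RE): 0.0225,
    (P.TC, P.NT): 0.18,
    (P.RE, P.PY): 0.054,
    (P.RE, P.TC): 0.045,
    (P.RE, P.RE): 0.0225,
}
_SURROUND = {
    (P.PY, P.PY): 0.009,
    (P.PY, P.IN): 0.0315,
    (P.PY, P.TC): 0.0225,
    (P.IN, P.PY): 0.009,
    (P.IN, P.IN): 0.0315,
    (P.IN, P.TC): 0.0225,
    (P.TC, P.PY): 0.0135,
    (P.TC, P.RE): 0.01125,
    (P.RE, P.PY): 0.0135,
    (P.RE, P.TC): 0.0225,
    (P.RE, P.RE): 0.01125,
}

DEFAULT_PROBABILITIES: dict[tuple[Population, Population, Region], float] = {
    **{(t, s, Region.FOCAL): p for (t, s), p in _FOCAL.items()},
    **{(t, s, Region.SURROUND): p for (t, s), p in _SURROUND.items()},
}


@dataclass(frozen=True)
class ProbabilityTable:
    """Connection probabilities keyed by (target pop, source pop, target region)."""

    probs: dict[tuple[Population, Population, Region], float] = field(
        default_factory=lambda: dict(DEFAULT_PROBABILITIES)
    )

    def __post_init__(self) -> None:
        for key, p in self.probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {key} out of [0, 1]: {p}")
            tpop = key[0]
            if tpop is Population.NT and p > 0:
                raise ValueError("NT nodes cannot be coupling targets")

    def get(self, target: Population, source: Population, region: Region) -> float:
        if region is Region.EXTERNAL:
            return 0.0  # external input nodes receive nothing
        return self.probs.get((target, source, region), 0.0)

    @classmethod
    def default(cls) -> "ProbabilityTable":
        return cls(dict(DEFAULT_PROBABILITIES))


@dataclass
class CouplingMatrix:
    """Signed coupling matrix with a shared integer conduction delay.

    ``C[i, j]`` couples source node ``j`` into target node ``i``; the matrix
    entirely determines the network dynamics.
    """

    C: np.ndarray
    tau_steps: int
    layout: NetworkLayout
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        n = self.layout.n_total
        if self.C.shape != (n, n):
            raise ValueError(f"matrix shape {self.C.shape} != layout size {n}")
        if self.tau_steps < 1:
            raise ValueError("tau_steps must be >= 1")
        if np.any(np.diag(self.C) != 0.0):
            raise ValueError("self-couplings must be zero")

    @property
    def n(self) -> int:
        return self.layout.n_total

    def n_edges(self) -> int:
        return int(np.count_nonzero(self.C))

    def copy(self) -> "CouplingMatrix":
        return replace(self, C=self.C.copy(), meta=dict(self.meta))

    def validate_signs(self) -> None:
        """Check the Dale-like rule: column sign fixed by source population."""
        pops = self.layout.population_of()
        for j in range(self.n):
            col = self.C[:, j]
            nz = col[col != 0.0]
            if nz.size == 0:
                continue
            if pops[j] in EXCITATORY:
                if np.any(nz < 0):
                    raise ValueError(f"excitatory source {j} has negative edges")
            elif np.any(nz > 0):
                raise ValueError(f"inhibitory source {j} has positive edges")


def _sign_vector(layout: NetworkLayout) -> np.ndarray:
    """+1 for excitatory source populations, -1 for inhibitory ones."""
    return np.array(
        [1.0 if p in EXCITATORY else -1.0 for p in layout.population_of()]
    )


def sample_matrix(
    layout: NetworkLayout,
    probs: ProbabilityTable | None = None,
    *,
    w_exc: float = 0.1,
    w_inh: float = 0.1,
    tau_steps: int = 10,
    seed: int = 0,
    collaterals: bool = True,
    collateral_rule: str = "mixed",
    copy_fraction: float = 0.5,
) -> CouplingMatrix:
    """Draw a random coupling matrix for ``layout``.

    Each allowed ordered pair (target ``i`` != source ``j``) becomes an edge
    independently with the probability looked up by (target population,
    source population, target region); edge weight is ``+w_exc`` or
    ``-w_inh`` according to the source population.  With
    ``collaterals=True`` (the default generation procedure) every sampled
    edge is completed by its reciprocal edge afterwards.
    """
    if tau_steps < 1:
        raise ValueError("tau_steps must be >= 1")
    if w_exc < 0 or w_inh < 0:
        raise ValueError("weight magnitudes must be nonnegative")
    probs = probs or ProbabilityTable.default()
    rng = np.random.default_rng(seed)
    n = layout.n_total
    C = np.zeros((n, n))
    ranges = layout.ranges()
    for (tpop, tregion), trng in ranges.items():
        if len(trng) == 0:
            continue
        ti = np.asarray(trng)
        for (spop, _sregion), srng in ranges.items():
            if len(srng) == 0:
                continue
            p = probs.get(tpop, spop, tregion)
            if p == 0.0:
                continue
            sj = np.asarray(srng)
            mask = rng.random((ti.size, sj.size)) < p
            w = w_exc if spop in EXCITATORY else -w_inh
            block = np.where(mask, w, 0.0)
            C[np.ix_(ti, sj)] = block
    np.fill_diagonal(C, 0.0)
    mat = CouplingMatrix(
        C,
        tau_steps,
        layout,
        meta={"seed": seed, "w_exc": w_exc, "w_inh": w_inh},
    )
    if collaterals:
        mat = apply_collaterals(
            mat, rule=collateral_rule, copy_fraction=copy_fraction, seed=seed
        )
    return mat


def apply_collaterals(
    mat: CouplingMatrix,
    rule: str = "mixed",
    *,
    copy_fraction: float = 0.5,
    seed: int | None = None,
) -> CouplingMatrix:
    """Complete every directed edge with its reciprocal (collateral) edge.

    Three completion rules are available for the reciprocal entry
    ``C[j, i]`` of a sampled edge ``C[i, j]``:

    ``"copy"``
        the literal symmetrization ``C[j, i] := C[i, j]``.  Networks
        completed this way carry enough recurrent excitation to lock into
        the high-amplitude 7–8 Hz collective rhythm of a discharge — and
        they do so permanently, for essentially every random draw.
    ``"dale"``
        the reciprocal takes the sign of its own source population
        (magnitude from the weight table), preserving the Dale-like sign
        rule throughout.  These networks are far less excitable: they
        produce only low-amplitude irregular activity or die out.
    ``"mixed"`` (default)
        each reciprocal edge independently follows the copy rule with
        probability ``copy_fraction`` (drawn reproducibly from ``seed``)
        and the Dale rule otherwise.  At the default ``copy_fraction =
        0.5`` the generated ensemble spans chaotic, intermediate and
        rhythmic dynamics across random draws — the heterogeneity that
        matrix screening presupposes.

    Edges into external-input (NT) nodes are never created.  All rules
    are idempotent at fixed seed.
    """
    if rule not in ("copy", "dale", "mixed"):
        raise ValueError(f"unknown collateral rule {rule!r}")
    if not (0.0 <= copy_fraction <= 1.0):
        raise ValueError("copy_fraction must lie in [0, 1]")
    C = mat.C.copy()
    pops = mat.layout.population_of()
    need = (C != 0.0) & (C.T == 0.0)  # edge i<-j present, reciprocal j<-i absent
    # the reciprocal's target is the original source j; NT nodes receive nothing
    is_nt = np.array([p is Population.NT for p in pops])
    need &= ~is_nt[None, :]
    ii, jj = np.nonzero(need)
    # dale completion: reciprocal edge C[j, i] has source i, sign by pop(i)
    w_exc = float(mat.meta.get("w_exc", np.max(np.abs(C), initial=0.1) or 0.1))
    w_inh = float(mat.meta.get("w_inh", w_exc))
    signs = _sign_vector(mat.layout)
    mag = np.where(signs > 0, w_exc, w_inh)
    dale_vals = signs[ii] * mag[ii]
    copy_vals = C[ii, jj]
    if rule == "copy":
        vals = copy_vals
    elif rule == "dale":
        vals = dale_vals
    else:
        if seed is None:
            seed = int(mat.meta.get("seed", 0))
        # symmetric per-pair choice keyed by the unordered pair so the rule
        # does not depend on edge enumeration order
        rng = np.random.default_rng([seed, 0x5EED])
        pair_pick = rng.random(C.shape) < copy_fraction
        pick = pair_pick[np.minimum(ii, jj), np.maximum(ii, jj)]
        vals = np.where(pick, copy_vals, dale_vals)
    C[jj, ii] = vals
    np.fill_diagonal(C, 0.0)
    out = replace(mat, C=C, meta=dict(mat.meta))
    out.meta["collateral_rule"] = rule
    if rule == "mixed":
        out.meta["copy_fraction"] = copy_fraction
    return out


def compose_network(
    C_focal: CouplingMatrix,
    C_surround: CouplingMatrix,
    probs: ProbabilityTable | None = None,
    *,
    seed: int = 0,
    collaterals: bool = True,
    collateral_rule: str = "mixed",
    copy_fraction: float = 0.5,
) -> CouplingMatrix:
    """Couple a focal and a surrounding sub-matrix into one full network.

    The two matrices occupy diagonal blocks of the composite matrix; the
    cross-blocks between focal and surrounding compartments are sampled
    with the (sparser) surrounding-area probabilities.  Both inputs must
    share the same conduction delay.
    """
    if C_focal.tau_steps != C_surround.tau_steps:
        raise ValueError(
            "focal and surrounding matrices must share tau_steps "
            f"({C_focal.tau_steps} != {C_surround.tau_steps})"
        )
    probs = probs or ProbabilityTable.default()
    full = NetworkLayout.default()
    n = full.n_total
    C = np.zeros((n, n))
    fr = full.ranges()

    def _embed(sub: CouplingMatrix) -> dict[int, int]:
        m: dict[int, int] = {}
        for key, rng in sub.layout.ranges().items():
            frng = fr[key]
            if len(rng) != len(frng):
                raise ValueError(f"compartment {key} size mismatch with default layout")
            for a, b in zip(rng, frng):
                m[a] = b
        idx = np.array([m[i] for i in range(sub.layout.n_total)])
        C[np.ix_(idx, idx)] = sub.C
        return m

    _embed(C_focal)
    _embed(C_surround)

    rng_ = np.random.default_rng(seed)
    pops = full.population_of()
    regions = full.region_of()
    w_exc = float(C_focal.meta.get("w_exc", 0.1))
    w_inh = float(C_focal.meta.get("w_inh", 0.1))
    focal_idx = np.array([r is Region.FOCAL for r in regions])
    surr_idx = np.array([r is Region.SURROUND for r in regions])
    # cross-blocks in both directions, surrounding-area probabilities
    for t_mask, s_mask in ((focal_idx, surr_idx), (surr_idx, focal_idx)):
        ti = np.nonzero(t_mask)[0]
        sj = np.nonzero(s_mask)[0]
        for i in ti:
            p_row = np.array(
                [probs.get(pops[i], pops[j], Region.SURROUND) for j in sj]
            )
            hit = rng_.random(sj.size) < p_row
            if not hit.any():
                continue
            w = np.array(
                [w_exc if pops[j] in EXCITATORY else -w_inh for j in sj[hit]]
            )
            C[i, sj[hit]] = w
    np.fill_diagonal(C, 0.0)
    out = CouplingMatrix(
        C,
        C_focal.tau_steps,
        full,
        meta={
            "seed": seed,
            "w_exc": w_exc,
            "w_inh": w_inh,
            "focal_seed": C_focal.meta.get("seed"),
            "surround_seed": C_surround.meta.get("seed"),
        },
    )
    if collaterals:
        out = apply_collaterals(
            out, rule=collateral_rule, copy_fraction=copy_fraction, seed=seed
        )
    return out


# ---------------------------------------------------------------------------
# plain-text sparse-triplet persistence


def save_matrix(mat: CouplingMatrix, path) -> None:
    """Write a coupling matrix as tab-separated sparse triplets with a header."""
    lines = ["# swdnet coupling matrix v1"]
    counts = " ".join(
        f"{p.value}:{r.value}={n}" for (p, r), n in mat.layout.counts.items()
    )
    lines.append(f"# layout {counts}")
    lines.append(f"# tau_steps {mat.tau_steps}")
    for k in ("seed", "w_exc", "w_inh", "focal_seed", "surround_seed"):
        if mat.meta.get(k) is not None:
            lines.append(f"# {k} {mat.meta[k]}")
    ti, tj = np.nonzero(mat.C)
    for i, j in zip(ti, tj):
        lines.append(f"{i}\t{j}\t{float(mat.C[i, j])!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def load_matrix(path) -> CouplingMatrix:
    """Read a matrix written by :func:`save_matrix` (lossless round-trip)."""
    if hasattr(path, "read"):
        fh = io.StringIO(path.read())
    else:
        fh = open(path)
    counts: dict[tuple[Population, Region], int] = {}
    tau_steps = None
    meta: dict = {}
    triplets: list[tuple[int, int, float]] = []
    with fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("layout"):
                    for tok in body.split()[1:]:
                        key, val = tok.split("=")
                        pop_s, reg_s = key.split(":")
                        counts[(Population(pop_s), Region(reg_s))] = int(val)
                elif body.startswith("tau_steps"):
                    tau_steps = int(body.split()[1])
                else:
                    parts = body.split()
                    if len(parts) == 2 and parts[0] in (
                        "seed",
                        "w_exc",
                        "w_inh",
                        "focal_seed",
                        "surround_seed",
                    ):
                        v: float | int
                        try:
                            v = int(parts[1])
                        except ValueError:
                            v = float(parts[1])
                        meta[parts[0]] = v
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {ln}: expected 'i<TAB>j<TAB>weight'")
            try:
                i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {ln}: {exc}") from None
            if i == j and w != 0.0:
                raise ValueError(f"line {ln}: nonzero self-coupling {i}->{i}")
            triplets.append((i, j, w))
    if not counts or tau_steps is None:
        raise ValueError("missing layout/tau_steps header")
    layout = NetworkLayout(counts)
    n = layout.n_total
    C = np.zeros((n, n))
    for i, j, w in triplets:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"index ({i}, {j}) outside declared size {n}")
        C[i, j] = w
    return CouplingMatrix(C, tau_steps, layout, meta=meta)
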