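"""Null-model reference ensembles: random-orientation Hilbert curves, freely
jointed chains, and confined random walks.

These generators provide self-contained ensembles with known statistics
against which the heterogeneity of realistic chromatin models can be
calibrated:

* *orientation-random approximate 3D Hilbert curves* — a space-filling
  fractal model of compact chromatin packing; replica-to-replica variability
  comes from applying a fresh random cube symmetry (axis permutation with
  independent sign flips) to the order-1 template at every recursion depth;
* *freely jointed chains* (FJC) — the ideal polymer; its relative
  conformational heterogeneity tends to ``1/sqrt(3) ~= 0.58`` in the
  long-chain limit;
* *sphere-confined random walks* — an FJC constrained to a spherical volume,
  emulating the heterogeneity-suppressing effect of nuclear confinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import CellConformation, ConformationEnsemble

__all__ = [
    "ReferenceEnsembleSpec",
    "hilbert_curve_points",
    "random_cube_symmetry",
    "generate_hilbert_replica",
    "generate_fjc_replica",
    "generate_confined_walk_ensemble",
    "generate_reference_ensemble",
    "analytic_fjc_relative_ch",
    "coarse_grain",
]

# Canonical order-1 template: the 8 octant centres in Gray-code order, and the
# signed-permutation transform each child applies to the previous level
# (classic recursive construction of the 3D Hilbert curve).
_TEMPLATE_OFFSETS = 0.5 * np.array(
    [
        [1, 1, 1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, 1, 1],
        [-1, -1, 1],
        [-1, -1, -1],
        [1, -1, -1],
        [1, -1, 1],
    ],
    dtype=float,
)
_CHILD_TRANSFORMS = [
    np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float),
    np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float),
    np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float),
    np.array([[-1, 0, 0], [0, 1, 0], [0, 0, -1]], dtype=float),
    np.array([[-1, 0, 0], [0, 1, 0], [0, 0, -1]], dtype=float),
    np.array([[0, -1, 0], [0, 0, -1], [1, 0, 0]], dtype=float),
    np.array([[0, -1, 0], [0, 0, -1], [1, 0, 0]], dtype=float),
    np.array([[0, 0, 1], [-1, 0, 0], [0, -1, 0]], dtype=float),
]


@dataclass
class ReferenceEnsembleSpec:
    """Parameters of a reference ensemble.

    ``p`` is the Hilbert recursion depth (8**p points); ``n_segments`` the
    FJC segment count; ``segment_length`` the physical step; and
    ``segment_genomic_size`` the genomic content assigned to one retained
    segment (10 kb by default, so 2048 beads span ~20 Mb).
    """

    kind: str = "fjc"
    n_replicas: int = 18
    p: int = 4
    n_segments: int = 2047
    segment_length: float = 1.0
    segment_genomic_size: int = 10_000
    coarse_grain_factor: int = 2
    confinement_radius: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("hilbert", "fjc", "confined_walk"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.p < 1:
            raise ValueError("recursion depth p must be >= 1")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be > 0")


def random_cube_symmetry(rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over the 48 signed axis permutations of the cube."""
    perm = rng.permutation(3)
    signs = rng.choice([-1.0, 1.0], size=3)
    S = np.zeros((3, 3))
    for i in range(3):
        S[i, perm[i]] = signs[i]
    return S


def hilbert_curve_points(p: int, syms: list[np.ndarray] | None = None) -> np.ndarray:
    """Points of the depth-``p`` 3D Hilbert curve in the unit cube.

    With ``syms=None`` (identity at every depth) the canonical curve is
    produced: 8**p points on the ``2**p`` grid, consecutive points exactly one
    fine-lattice unit apart.  Supplying a cube symmetry per depth reorients
    the order-1 template at that depth before descending into its children,
    which yields distinct approximately-continuous space-filling paths
    (occasional non-unit steps appear at block boundaries).
    """
    if p < 1:
        raise ValueError("recursion depth p must be >= 1")
    if syms is None:
        syms = [np.eye(3)] * p
    if len(syms) != p:
        raise ValueError(f"need one symmetry per depth, got {len(syms)} for p={p}")
    n = 8**p
    idx = np.arange(n)
    digits = []
    x = idx.copy()
    for _ in range(p):
        digits.append(x % 8)
        x //= 8
    digits = digits[::-1]  # most-significant digit first
    pts = np.zeros((n, 3))
    orient = np.tile(np.eye(3), (n, 1, 1))
    scale = 1.0
    for d in range(p):
        S = syms[d]
        k = digits[d]
        offs = _TEMPLATE_OFFSETS @ S.T  # row i = S @ offset_i
        pts += scale * 0.5 * np.einsum("nij,nj->ni", orient, offs[k])
        SP = np.stack([S @ T for T in _CHILD_TRANSFORMS])
        orient = np.einsum("nij,njk->nik", orient, SP[k])
        scale *= 0.5
    return pts + 0.5  # shift from [-0.5, 0.5]^3 into the unit cube


def coarse_grain(points: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th point starting from the first."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return points[::factor]


def generate_hilbert_replica(
    spec: ReferenceEnsembleSpec,
    rng: np.random.Generator,
    cell_id: str = "hilbert0",
    random_orientation: bool = True,
) -> CellConformation:
    """One orientation-random Hilbert replica, coarse-grained and annotated.

    The full curve has ``8**spec.p`` points; coarse-graining by
    ``spec.coarse_grain_factor`` keeps every factor-th bead, and each
    retained segment is assigned ``spec.segment_genomic_size`` bp.
    """
    syms = (
        [random_cube_symmetry(rng) for _ in range(spec.p)]
        if random_orientation
        else None
    )
    pts = hilbert_curve_points(spec.p, syms)
    pts = coarse_grain(pts, spec.coarse_grain_factor) * (2**spec.p)
    # positions scaled to fine-lattice units so the retained step is O(1)
    L = len(pts)
    return CellConformation(
        cell_id=cell_id,
        positions=pts,
        radii=np.zeros(L),
        genomic_sizes=np.full(L, spec.segment_genomic_size),
    )


def generate_fjc_replica(
    spec: ReferenceEnsembleSpec,
    rng: np.random.Generator,
    cell_id: str = "fjc0",
) -> CellConformation:
    """A freely jointed chain: cumulative sum of i.i.d. uniform unit steps."""
    steps = rng.normal(size=(spec.n_segments, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    pos = np.vstack([np.zeros(3), np.cumsum(spec.segment_length * steps, axis=0)])
    L = spec.n_segments + 1
    return CellConformation(
        cell_id=cell_id,
        positions=pos,
        radii=np.zeros(L),
        genomic_sizes=np.full(L, spec.segment_genomic_size),
    )


def generate_confined_walk_replica(
    spec: ReferenceEnsembleSpec,
    rng: np.random.Generator,
    cell_id: str = "walk0",
) -> CellConformation:
    """FJC steps rejected until the bead stays inside a sphere."""
    R = spec.confinement_radius
    if R <= spec.segment_length:
        raise ValueError("confinement radius must exceed the segment length")
    pos = np.zeros((spec.n_segments + 1, 3))
    for i in range(1, spec.n_segments + 1):
        while True:
            step = rng.normal(size=3)
            step *= spec.segment_length / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if np.dot(cand, cand) <= R * R:
                pos[i] = cand
                break
    L = spec.n_segments + 1
    return CellConformation(
        cell_id=cell_id,
        positions=pos,
        radii=np.zeros(L),
        genomic_sizes=np.full(L, spec.segment_genomic_size),
    )


def generate_confined_walk_ensemble(
    spec: ReferenceEnsembleSpec, radius: float | None = None
) -> ConformationEnsemble:
    if radius is not None:
        spec = ReferenceEnsembleSpec(**{**spec.__dict__, "confinement_radius": radius})
    return generate_reference_ensemble(
        ReferenceEnsembleSpec(**{**spec.__dict__, "kind": "confined_walk"})
    )


def generate_reference_ensemble(spec: ReferenceEnsembleSpec) -> ConformationEnsemble:
    """Generate ``spec.n_replicas`` cells of the requested kind (seeded)."""
    rng = np.random.default_rng(spec.seed)
    cells = []
    for r in range(spec.n_replicas):
        cid = f"{spec.kind}{r}"
        if spec.kind == "hilbert":
            cells.append(generate_hilbert_replica(spec, rng, cid))
        elif spec.kind == "fjc":
            cells.append(generate_fjc_replica(spec, rng, cid))
        else:
            cells.append(generate_confined_walk_replica(spec, rng, cid))
    return ConformationEnsemble(
        cells=cells,
        length_unit="arbitrary",
        avg_bead_genomic_size=spec.segment_genomic_size,
        metadata={"kind": spec.kind, "seed": spec.seed},
    )


def analytic_fjc_relative_ch() -> float:
    """Long-chain relative conformational heterogeneity of an ideal FJC.

    With mean end-to-end distance ``Rs = l * sqrt(s)`` and standard deviation
    ``Sigma = l * sqrt(s / 3)``, the ratio ``Sigma / Rs = 1 / sqrt(3)`` is
    independent of both the segment length and the separation.
    """
    return 1.0 / np.sqrt(3.0)
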