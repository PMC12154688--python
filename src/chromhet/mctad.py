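"""Lattice-path model of chromatin folding inside TADs (the MC-TAD algorithm).

A TAD is modelled as a cube of ``N x N x N`` equal cubic bins (one bin per
Hi-C-resolution unit of chromatin).  A chromatin conformation is a path over
bin centres built from axis-aligned unit segments that traverses ``N^3 - 1``
segments inside the first cube, crosses into the face-adjacent neighbour cube
(the next TAD along the genome), and traverses ``N^3 - 1`` further segments
there.  The spread of such paths yields the intra-TAD end-to-end distance
width sigma used for resolution up-conversion.

Two permissibility conventions are implemented (``PathRules.edge_policy``):

``"unique"`` (default)
    No lattice segment is traversed twice; bin-centre revisits (self-contacts
    at a point) are allowed.  This convention reproduces the single-cube path
    census (384 at N=2) and the sigma values 0.31 / 0.33 / 0.34 for
    N = 2, 3, 4.

``"no_backtrack"``
    Only an immediate reversal onto the segment just laid is forbidden, and
    the first segment inside the second cube must turn off the inter-cube
    axis.  This convention reproduces the two-cube path census (98,304 at
    N=2).  The two published censuses are not reproducible under any single
    convention we could construct; see the methods note.

Paths are directed and deduplicated by their canonical encoding — the
sequence of global bin indices — so a path and its reversal are distinct.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PathRules",
    "TadLattice",
    "LatticePathSet",
    "SigmaResult",
    "generate_paths",
    "enumerate_paths_exhaustive",
    "is_valid_path",
    "path_coords",
    "compute_sigma",
    "estimate_sigma_streaming",
    "sigma_to_microns",
]

SCOPES = ("single_cube", "two_cubes")


@dataclass(frozen=True)
class PathRules:
    """Permissibility rules for lattice paths.

    The start-face constraint — the starting face of the path in the first
    cube may not coincide with the starting face in the second cube unless
    the start bin lies on an edge of the cube — is realized here in two
    optional forms, because its precise operational meaning is
    under-determined:

    ``entry_turn``: the first segment inside the second cube must not
    continue straight along the inter-cube axis.  Resolved automatically: on
    for the ``no_backtrack`` census convention (where it is required to
    reproduce the published two-cube census), off otherwise.

    ``start_face_rule``: the first-cube path may not *start* at a bin lying
    solely on the exit face (off by default: under the edge-unique convention
    this exclusion shifts sigma away from the published 0.31/0.33/0.34
    values, which arbitrate the reading; at N=2 every bin is on an edge and
    the rule never bites either way).
    """

    edge_policy: str = "unique"
    start_face_rule: bool = False
    entry_turn: bool | None = None

    def __post_init__(self) -> None:
        if self.edge_policy not in ("unique", "no_backtrack"):
            raise ValueError(f"unknown edge_policy {self.edge_policy!r}")

    @property
    def entry_turn_resolved(self) -> bool:
        if self.entry_turn is None:
            return self.edge_policy == "no_backtrack"
        return self.entry_turn

    @classmethod
    def edge_unique(cls) -> "PathRules":
        return cls(edge_policy="unique")

    @classmethod
    def no_backtrack(cls) -> "PathRules":
        return cls(edge_policy="no_backtrack")


class TadLattice:
    """Bin lattice of one TAD cube plus its neighbour along ``+x``.

    Bins are unit cubes indexed ``(i, j, k)``, 0-based.  Global bin ids are
    ``local`` for the first cube and ``N^3 + local`` for the second; the
    second cube is the first translated by ``N`` bins along the adjoining
    axis.  Coordinates returned by :meth:`coords` are bin centres in
    arbitrary units where the *TAD cube side is 1* (bin side ``1/N``).
    """

    def __init__(self, n_side: int):
        if n_side < 2:
            raise ValueError(f"n_side must be >= 2, got {n_side}")
        self.n_side = n_side
        N = n_side
        self.n_bins = N**3
        self.bins = [(i, j, k) for i in range(N) for j in range(N) for k in range(N)]
        self._index = {b: n for n, b in enumerate(self.bins)}
        self.neighbors: list[tuple[int, ...]] = []
        for b in self.bins:
            lst = []
            for d in range(3):
                for s in (-1, 1):
                    c = list(b)
                    c[d] += s
                    c = tuple(c)
                    if c in self._index:
                        lst.append(self._index[c])
            self.neighbors.append(tuple(lst))
        # bins on the exit face (local x == N-1) and their mirror entries
        self.exit_face = tuple(
            n for n, b in enumerate(self.bins) if b[0] == N - 1
        )
        self.entry_of_exit = {
            n: self._index[(0, b[1], b[2])] for n, b in enumerate(self.bins)
            if b[0] == N - 1
        }
        # starts forbidden by the start-face rule: solely on the exit face
        def n_faces(b):
            return sum(1 for d in range(3) for v in (0, N - 1) if b[d] == v)

        self.exit_face_only = frozenset(
            n for n, b in enumerate(self.bins)
            if b[0] == N - 1 and n_faces(b) == 1
        )
        # local moves that continue straight along +x (for the entry-turn rule)
        self.plus_x_of = {}
        for n, b in enumerate(self.bins):
            c = (b[0] + 1, b[1], b[2])
            if c in self._index:
                self.plus_x_of[n] = self._index[c]

    def coords(self, global_ids: np.ndarray) -> np.ndarray:
        """Bin-centre coordinates (a.u., cube side 1) for global bin ids."""
        g = np.asarray(global_ids)
        local = g % self.n_bins
        cube = g // self.n_bins
        xyz = np.array(self.bins, dtype=float)[local]
        xyz[..., 0] += cube * self.n_side
        return (xyz + 0.5) / self.n_side


@dataclass
class LatticePathSet:
    """Deduplicated collection of permissible paths."""

    n_side: int
    scope: str
    rules: PathRules
    paths: set = field(default_factory=set)
    converged: bool = False
    attempts_since_new: int = 0
    total_attempts: int = 0
    seed: int | None = None
    exhaustive: bool = False

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    def path_array(self) -> np.ndarray:
        return np.array(sorted(self.paths), dtype=np.int64)


@dataclass
class SigmaResult:
    """Spread of TAD-contour-length subchain end-to-end distances."""

    n_side: int
    sigma_au: float
    n_subchains: int
    sigma_um: float | None = None
    mean_au: float | None = None
    converged: bool = True
    run_sigmas: tuple[float, ...] | None = None


def _allowed_start(lattice: TadLattice, start: int, scope: str,
                   rules: PathRules) -> bool:
    if scope == "two_cubes" and rules.start_face_rule:
        return start not in lattice.exit_face_only
    return True


def _grow_random(lattice: TadLattice, rng: random.Random, scope: str,
                 rules: PathRules) -> tuple[int, ...] | None:
    """One stochastic growth attempt; None when the attempt is rejected."""
    N = lattice.n_side
    L = lattice.n_bins - 1
    nb = lattice.neighbors
    unique = rules.edge_policy == "unique"
    start = rng.randrange(lattice.n_bins)
    if not _allowed_start(lattice, start, scope, rules):
        return None
    path = [start]
    used: set[int] = set()
    cur = start
    prev = -1
    for _ in range(L):
        if unique:
            cands = [x for x in nb[cur]
                     if (cur * 4096 + x if cur < x else x * 4096 + cur) not in used]
        else:
            cands = [x for x in nb[cur] if x != prev]
        if not cands:
            return None
        nxt = cands[rng.randrange(len(cands))] if len(cands) > 1 else cands[0]
        if unique:
            used.add(cur * 4096 + nxt if cur < nxt else nxt * 4096 + cur)
        path.append(nxt)
        prev = cur
        cur = nxt
    # the first-cube stage must finish on the exit face so the chain can
    # continue into the neighbouring TAD
    if lattice.bins[cur][0] != N - 1:
        return None
    if scope == "single_cube":
        return tuple(path)
    entry = lattice.entry_of_exit[cur]
    path2 = [entry]
    used2: set[int] = set()
    prev = -2  # the crossing segment leaves the second cube; never a candidate
    cur2 = entry
    first = True
    for _ in range(L):
        if unique:
            cands = [x for x in nb[cur2]
                     if (cur2 * 4096 + x if cur2 < x else x * 4096 + cur2)
                     not in used2]
        else:
            cands = [x for x in nb[cur2] if x != prev]
        if first and rules.entry_turn_resolved:
            straight = lattice.plus_x_of.get(cur2)
            cands = [x for x in cands if x != straight]
        if not cands:
            return None
        nxt = cands[rng.randrange(len(cands))] if len(cands) > 1 else cands[0]
        if unique:
            used2.add(cur2 * 4096 + nxt if cur2 < nxt else nxt * 4096 + cur2)
        path2.append(nxt)
        prev = cur2
        cur2 = nxt
        first = False
    nb3 = lattice.n_bins
    return tuple(path) + tuple(x + nb3 for x in path2)


def generate_paths(
    n_side: int,
    scope: str = "single_cube",
    seed: int | None = None,
    convergence_patience: int = 50_000,
    rules: PathRules | None = None,
    max_attempts: int | None = None,
) -> LatticePathSet:
    """Stochastically grow permissible paths until no new unique path appears.

    Convergence is declared after ``convergence_patience`` consecutive growth
    attempts (successful or rejected) yield no new unique path.  The returned
    set is reproducible from ``seed``; at convergence for small ``n_side`` it
    equals the exhaustive enumeration.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if convergence_patience < 1:
        raise ValueError("convergence_patience must be >= 1")
    rules = rules or PathRules()
    lattice = TadLattice(n_side)
    rng = random.Random(seed)
    out = LatticePathSet(n_side=n_side, scope=scope, rules=rules, seed=seed)
    since_new = 0
    attempts = 0
    while since_new < convergence_patience:
        if max_attempts is not None and attempts >= max_attempts:
            break
        attempts += 1
        p = _grow_random(lattice, rng, scope, rules)
        if p is not None and p not in out.paths:
            out.paths.add(p)
            since_new = 0
        else:
            since_new += 1
    out.converged = since_new >= convergence_patience
    out.attempts_since_new = since_new
    out.total_attempts = attempts
    return out


def enumerate_paths_exhaustive(
    n_side: int,
    scope: str = "single_cube",
    rules: PathRules | None = None,
    max_paths: int = 5_000_000,
) -> LatticePathSet:
    """Complete depth-first enumeration under the same permissibility rules.

    Deterministic; serves as the oracle for the stochastic generator.  Raises
    ``RuntimeError`` when the enumeration exceeds ``max_paths`` (resource
    guard for lattices too large to enumerate).
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    rules = rules or PathRules()
    lattice = TadLattice(n_side)
    N = n_side
    L = lattice.n_bins - 1
    nb = lattice.neighbors
    unique = rules.edge_policy == "unique"
    out = LatticePathSet(n_side=n_side, scope=scope, rules=rules,
                         exhaustive=True, converged=True)

    def candidates(cur, prev, used, first_in_cube2=False):
        if unique:
            cands = [x for x in nb[cur]
                     if (cur * 4096 + x if cur < x else x * 4096 + cur)
                     not in used]
        else:
            cands = [x for x in nb[cur] if x != prev]
        if first_in_cube2 and rules.entry_turn_resolved:
            straight = lattice.plus_x_of.get(cur)
            cands = [x for x in cands if x != straight]
        return cands

    def dfs2(path2, used2, prev):
        if len(path2) - 1 == L:
            full = base + tuple(x + lattice.n_bins for x in path2)
            out.paths.add(full)
            if len(out.paths) > max_paths:
                raise RuntimeError(
                    f"enumeration exceeded max_paths={max_paths}"
                )
            return
        cur = path2[-1]
        for x in candidates(cur, prev, used2, first_in_cube2=(len(path2) == 1)):
            if unique:
                key = cur * 4096 + x if cur < x else x * 4096 + cur
                used2.add(key)
            path2.append(x)
            dfs2(path2, used2, cur)
            path2.pop()
            if unique:
                used2.discard(key)

    base: tuple[int, ...] = ()

    def dfs1(path, used, prev):
        nonlocal base
        if len(path) - 1 == L:
            if lattice.bins[path[-1]][0] != N - 1:
                return
            if scope == "single_cube":
                out.paths.add(tuple(path))
                if len(out.paths) > max_paths:
                    raise RuntimeError(
                        f"enumeration exceeded max_paths={max_paths}"
                    )
            else:
                base = tuple(path)
                entry = lattice.entry_of_exit[path[-1]]
                dfs2([entry], set(), -2)
            return
        cur = path[-1]
        for x in candidates(cur, prev, used):
            if unique:
                key = cur * 4096 + x if cur < x else x * 4096 + cur
                used.add(key)
            path.append(x)
            dfs1(path, used, cur)
            path.pop()
            if unique:
                used.discard(key)

    for start in range(lattice.n_bins):
        if not _allowed_start(lattice, start, scope, rules):
            continue
        dfs1([start], set(), -1)
    return out


def is_valid_path(
    path: tuple[int, ...],
    n_side: int,
    scope: str = "single_cube",
    rules: PathRules | None = None,
) -> bool:
    """Standalone permissibility check for a canonically encoded path."""
    rules = rules or PathRules()
    lattice = TadLattice(n_side)
    nbins = lattice.n_bins
    L = nbins - 1
    want = nbins if scope == "single_cube" else 2 * nbins
    if len(path) != want:
        return False
    cubes = [g // nbins for g in path]
    if scope == "single_cube":
        if any(c != 0 for c in cubes):
            return False
    else:
        if cubes != [0] * nbins + [1] * nbins:
            return False
    # start-face rule
    if scope == "two_cubes" and rules.start_face_rule:
        if path[0] in lattice.exit_face_only:
            return False
    locals_ = [g % nbins for g in path]
    # segments: unit axis moves; crossing is the mirror step
    used = set()
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        la, lb = locals_[i], locals_[i + 1]
        if cubes[i] != cubes[i + 1]:  # the crossing segment
            if i != L:  # only after N^3 - 1 segments inside the first cube
                return False
            if lattice.entry_of_exit.get(la) != lb:
                return False
            continue
        if lb not in lattice.neighbors[la]:
            return False
        if rules.edge_policy == "unique":
            key = (cubes[i], min(la, lb), max(la, lb))
            if key in used:
                return False
            used.add(key)
        else:
            if i >= 1 and path[i + 1] == path[i - 1]:
                return False
    # first-cube stage must end on the exit face
    if lattice.bins[locals_[L]][0] != n_side - 1 and scope == "single_cube":
        return False
    if scope == "two_cubes":
        if lattice.bins[locals_[L]][0] != n_side - 1:
            return False
        if rules.entry_turn_resolved and len(path) > nbins + 1:
            entry_local = locals_[nbins]
            nxt_local = locals_[nbins + 1]
            if lattice.plus_x_of.get(entry_local) == nxt_local:
                return False
    return True


def path_coords(path: tuple[int, ...], n_side: int) -> np.ndarray:
    """Node coordinates of a path in a.u. (TAD cube side = 1)."""
    return TadLattice(n_side).coords(np.asarray(path))


def compute_sigma(
    paths: LatticePathSet, tad_genomic_size: int = 118_000
) -> SigmaResult:
    """Width sigma of TAD-contour-length subchain distances over a path set.

    For every path, Euclidean distances are taken between node pairs whose
    contour separation is one TAD (``N^3`` segments, so the endpoints straddle
    the two cubes), over all offsets; sigma is the population standard
    deviation of the pooled distances in a.u. (cube side 1).
    ``tad_genomic_size`` is carried for unit bookkeeping only.
    """
    if paths.scope != "two_cubes":
        raise ValueError("sigma is defined over two-cube path sets")
    if not paths.paths:
        raise ValueError("empty path set")
    lattice = TadLattice(paths.n_side)
    sep = paths.n_side**3
    arr = lattice.coords(paths.path_array())
    diffs = arr[:, sep:, :] - arr[:, :-sep, :]
    d = np.sqrt(np.einsum("pij,pij->pi", diffs, diffs)).ravel()
    return SigmaResult(
        n_side=paths.n_side,
        sigma_au=float(d.std(ddof=0)),
        mean_au=float(d.mean()),
        n_subchains=d.size,
    )


# ---------------------------------------------------------------------------
# streaming sigma for lattices too large to enumerate
# ---------------------------------------------------------------------------


def _smc_sigma_run(
    n_side: int, population: int, seed: int, rules: PathRules
) -> tuple[float, float, int]:
    """One sequential-importance-sampling run with systematic resampling.

    Walkers grow two-cube paths step by step carrying Rosenbluth weights
    (product of the number of allowed moves), which makes the weighted
    population an unbiased sample of the *uniform* distribution over
    permissible paths; resampling at low effective sample size keeps the
    weights from degenerating.
    """
    lattice = TadLattice(n_side)
    N = n_side
    L = lattice.n_bins - 1
    nb = lattice.neighbors
    unique = rules.edge_policy == "unique"
    rng = np.random.default_rng(seed)
    pyrng = random.Random(int(rng.integers(2**31)))
    M = population

    starts = []
    while len(starts) < M:
        s = pyrng.randrange(lattice.n_bins)
        if _allowed_start(lattice, s, "two_cubes", rules):
            starts.append(s)
    paths = [[s] for s in starts]
    useds: list[set[int]] = [set() for _ in range(M)]
    prevs = [-1] * M
    logw = np.zeros(M)
    alive = np.ones(M, dtype=bool)
    stage2: list[list[int] | None] = [None] * M

    def resample():
        nonlocal paths, useds, prevs, logw, alive, stage2
        if not alive.any():
            raise RuntimeError("all walkers died; increase population")
        w = np.where(alive, np.exp(logw - logw[alive].max()), 0.0)
        wn = w / w.sum()
        ess = 1.0 / np.sum(wn**2)
        if ess > M / 2:
            return
        pos = (rng.random() + np.arange(M)) / M
        ids = np.searchsorted(np.cumsum(wn), pos)
        paths = [list(paths[j]) for j in ids]
        useds = [set(useds[j]) for j in ids]
        prevs = [prevs[j] for j in ids]
        stage2 = [None if stage2[j] is None else list(stage2[j]) for j in ids]
        alive = alive[ids].copy()
        logw = np.zeros(M)

    def step(i: int, in_cube2: bool, first: bool) -> bool:
        p = stage2[i] if in_cube2 else paths[i]
        cur = p[-1]
        if unique:
            u = useds[i]
            cands = [x for x in nb[cur]
                     if (cur * 4096 + x if cur < x else x * 4096 + cur) not in u]
        else:
            cands = [x for x in nb[cur] if x != prevs[i]]
        if in_cube2 and first and rules.entry_turn_resolved:
            straight = lattice.plus_x_of.get(cur)
            cands = [x for x in cands if x != straight]
        n = len(cands)
        if n == 0:
            return False
        logw[i] += math.log(n)
        x = cands[pyrng.randrange(n)] if n > 1 else cands[0]
        if unique:
            useds[i].add(cur * 4096 + x if cur < x else x * 4096 + cur)
        prevs[i] = cur
        p.append(x)
        return True

    for _ in range(L):
        for i in range(M):
            if alive[i] and not step(i, False, False):
                alive[i] = False
        resample()
    for i in range(M):
        if not alive[i]:
            continue
        if lattice.bins[paths[i][-1]][0] != N - 1:
            alive[i] = False
            continue
        stage2[i] = [lattice.entry_of_exit[paths[i][-1]]]
        useds[i] = set()
        prevs[i] = -2
    resample()
    first = True
    for _ in range(L):
        for i in range(M):
            if alive[i] and not step(i, True, first):
                alive[i] = False
        resample()
        first = False

    w = np.where(alive, np.exp(logw - logw[alive].max()), 0.0)
    sep = N**3
    coords = (np.array(lattice.bins, dtype=float) + 0.5) / N
    ds, ws = [], []
    n_sub = 0
    for i in range(M):
        if not alive[i]:
            continue
        c1 = coords[paths[i]]
        c2 = coords[stage2[i]].copy()
        c2[:, 0] += 1.0
        arr = np.vstack([c1, c2])
        diffs = arr[sep:] - arr[:-sep]
        d = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
        ds.append(d)
        ws.append(np.full(d.size, w[i]))
        n_sub += d.size
    dd = np.concatenate(ds)
    ww = np.concatenate(ws)
    mean = float(np.average(dd, weights=ww))
    var = float(np.average((dd - mean) ** 2, weights=ww))
    return math.sqrt(var), mean, n_sub


def estimate_sigma_streaming(
    n_side: int,
    seed: int | None = None,
    rules: PathRules | None = None,
    population: int = 8000,
    tol: float = 0.005,
    max_rounds: int = 4,
    n_runs: int = 2,
    tad_genomic_size: int = 118_000,
) -> SigmaResult:
    """Streaming sigma estimate for lattices too large to enumerate.

    ``n_runs`` independent sampling runs are compared; convergence is
    declared when their sigma estimates all agree within ``tol`` (the
    population doubles each round otherwise).  The reported sigma averages
    the runs; the per-run values are kept for uncertainty estimates.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 independent runs")
    rules = rules or PathRules()
    master = np.random.default_rng(seed)
    M = population
    last = None
    for _ in range(max_rounds):
        sigs, means, ns = [], [], []
        for _ in range(n_runs):
            s, m, n = _smc_sigma_run(
                n_side, M, int(master.integers(2**31)), rules)
            sigs.append(s)
            means.append(m)
            ns.append(n)
        last = SigmaResult(
            n_side=n_side,
            sigma_au=float(np.mean(sigs)),
            mean_au=float(np.mean(means)),
            n_subchains=int(np.sum(ns)),
            converged=(max(sigs) - min(sigs)) < tol,
            run_sigmas=tuple(sigs),
        )
        if last.converged:
            return last
        M *= 2
    return last


def sigma_to_microns(
    sigma_au: float | None = None,
    c_conv: float | None = None,
    direct_sigma_um: float | None = None,
) -> float:
    """Convert a dimensionless sigma (a.u., cube side 1) to microns.

    Exactly one of ``c_conv`` (microns per a.u., i.e. the physical TAD
    diameter) or ``direct_sigma_um`` (an externally supplied physical value,
    passed through) must be given.
    """
    if (c_conv is None) == (direct_sigma_um is None):
        raise ValueError("supply exactly one of c_conv or direct_sigma_um")
    if direct_sigma_um is not None:
        if direct_sigma_um < 0:
            raise ValueError("sigma must be >= 0")
        return float(direct_sigma_um)
    if sigma_au is None:
        raise ValueError("sigma_au required with c_conv")
    return float(c_conv) * float(sigma_au)
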