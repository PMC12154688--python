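"""Rs(s) distance curves and the conformational-heterogeneity metrics.

For one cell, ``Rs(s)`` is the Euclidean distance between bead centres,
averaged over every bead pair separated by ``s`` beads along the chain.
Separation is counted in beads of equal genomic size and converted to bp with
the ensemble's average bead genomic size.

Across an ensemble of ``n`` cells, the *conformational heterogeneity*
``C.H.(s)`` is the population standard deviation (divisor ``n``) of the
per-cell ``Rs(s)`` values.  The dimensionless variant divides each cell's
curve by the ensemble mean first::

    relative Rs(k)(s) = Rs(k)(s) / mean_k Rs(k)(s)
    relative C.H.(s)  = population sd over k of relative Rs(k)(s)

Relative C.H. is scale invariant and therefore comparable across models
expressed in different length units.  Error bars come from recomputing the
metric on independently resampled ensembles (sample sd across resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import CellConformation, ConformationEnsemble

__all__ = [
    "SeparationGrid",
    "RsProfile",
    "HeterogeneityProfile",
    "compute_rs_profile",
    "compute_rs_profiles",
    "compute_ch",
    "compute_relative_ch",
    "aggregate_resamples",
    "fit_scaling_exponent",
    "write_heterogeneity_tsv",
    "write_rs_matrix_tsv",
]


@dataclass
class SeparationGrid:
    """Genomic separations at which Rs is evaluated.

    ``separations_beads`` are strictly increasing integers in units of beads
    of equal genomic size; ``bp_per_bead`` converts them to bp.
    """

    separations_beads: np.ndarray
    bp_per_bead: int

    def __post_init__(self) -> None:
        s = np.asarray(self.separations_beads, dtype=np.int64)
        if s.size == 0 or np.any(s < 1) or np.any(np.diff(s) <= 0):
            raise ValueError("separations must be strictly increasing and >= 1")
        self.separations_beads = s

    @classmethod
    def full(cls, n_beads: int, bp_per_bead: int) -> "SeparationGrid":
        """All integer separations 1 .. L-1."""
        return cls(np.arange(1, n_beads), bp_per_bead)

    @classmethod
    def for_ensemble(cls, ensemble: ConformationEnsemble) -> "SeparationGrid":
        return cls.full(ensemble.n_beads, ensemble.avg_bead_genomic_size)

    @property
    def separations_bp(self) -> np.ndarray:
        return self.separations_beads * self.bp_per_bead

    def __len__(self) -> int:
        return len(self.separations_beads)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SeparationGrid)
            and self.bp_per_bead == other.bp_per_bead
            and np.array_equal(self.separations_beads, other.separations_beads)
        )


@dataclass
class RsProfile:
    """Per-cell mean spatial distance at each grid separation."""

    cell_id: str
    grid: SeparationGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("values must match the grid length")


@dataclass
class HeterogeneityProfile:
    """Ensemble heterogeneity curves on a common separation grid."""

    grid: SeparationGrid
    mean_rs: np.ndarray
    ch: np.ndarray
    relative_rs: np.ndarray | None  # (n_cells, n_s)
    relative_ch: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    resample_mean: np.ndarray | None = None
    resample_sd: np.ndarray | None = None


def compute_rs_profile(
    cell: CellConformation, grid: SeparationGrid
) -> RsProfile:
    """Average distance between bead centres for each separation on the grid.

    For separation ``s`` all ``L - s`` index pairs ``(i, i + s)`` contribute;
    at ``s = L - 1`` exactly one pair remains.  Bead radii are carried by the
    containers but do not enter the distance.
    """
    L = cell.n_beads
    smax = int(grid.separations_beads[-1])
    if smax >= L:
        raise ValueError(
            f"grid separation {smax} out of range for {L} beads (max {L - 1})"
        )
    pos = cell.positions
    vals = np.empty(len(grid))
    for j, s in enumerate(grid.separations_beads):
        d = pos[s:] - pos[:-s]
        vals[j] = np.mean(np.sqrt(np.einsum("ij,ij->i", d, d)))
    return RsProfile(cell.cell_id, grid, vals)


def compute_rs_profiles(
    ensemble: ConformationEnsemble, grid: SeparationGrid | None = None
) -> list[RsProfile]:
    if grid is None:
        grid = SeparationGrid.for_ensemble(ensemble)
    return [compute_rs_profile(c, grid) for c in ensemble.cells]


def _stack(profiles: list[RsProfile]) -> np.ndarray:
    if len(profiles) < 2:
        raise ValueError("heterogeneity metrics need at least 2 cells")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if p.grid != grid:
            raise ValueError("profiles are on mismatched separation grids")
    return np.vstack([p.values for p in profiles])


def compute_ch(profiles: list[RsProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Mean Rs curve and conformational heterogeneity C.H.(s).

    C.H. is the population standard deviation (divisor ``n``) of the per-cell
    Rs values at each separation; zero for an ensemble of identical cells.
    """
    m = _stack(profiles)
    return m.mean(axis=0), m.std(axis=0, ddof=0)


def compute_relative_ch(profiles: list[RsProfile]) -> HeterogeneityProfile:
    """Relative Rs curves and the dimensionless relative C.H.(s).

    Separations where the ensemble-mean distance vanishes (coincident beads
    in every cell) are undefined and reported as NaN, never zero-filled.
    """
    m = _stack(profiles)
    mean_rs = m.mean(axis=0)
    ch = m.std(axis=0, ddof=0)
    ok = mean_rs > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(ok, m / mean_rs, np.nan)
    rel_ch = np.full(len(mean_rs), np.nan)
    rel_ch[ok] = rel[:, ok].std(axis=0, ddof=0)
    return HeterogeneityProfile(
        grid=profiles[0].grid,
        mean_rs=mean_rs,
        ch=ch,
        relative_rs=rel,
        relative_ch=rel_ch,
        cell_ids=[p.cell_id for p in profiles],
    )


def aggregate_resamples(
    resamples: list[HeterogeneityProfile],
) -> HeterogeneityProfile:
    """Across-resample mean and sd of relative C.H. — the reported error bars.

    The across-resample spread uses the sample standard deviation (divisor
    ``n - 1``), the standard uncertainty estimator for a handful of resamples.
    """
    if len(resamples) < 2:
        raise ValueError("need at least 2 resampled profiles")
    grid = resamples[0].grid
    for r in resamples[1:]:
        if r.grid != grid:
            raise ValueError("resampled profiles are on mismatched grids")
    rc = np.vstack([r.relative_ch for r in resamples])
    mean_rs = np.vstack([r.mean_rs for r in resamples]).mean(axis=0)
    ch = np.vstack([r.ch for r in resamples]).mean(axis=0)
    return HeterogeneityProfile(
        grid=grid,
        mean_rs=mean_rs,
        ch=ch,
        relative_rs=None,
        relative_ch=rc.mean(axis=0),
        resample_mean=rc.mean(axis=0),
        resample_sd=rc.std(axis=0, ddof=1),
    )


def fit_scaling_exponent(
    profiles: list[RsProfile] | RsProfile,
    fit_range: tuple[int, int] = (2, 400),
) -> tuple[float, float]:
    """Power-law exponent of Rs ∝ s^alpha from a log-log least-squares fit.

    The slope of ``log Rs`` versus ``log s`` is fitted per replica over
    ``fit_range`` (in beads, inclusive); the mean and sample sd across
    replicas are returned (sd is NaN for a single replica).
    """
    if isinstance(profiles, RsProfile):
        profiles = [profiles]
    lo, hi = fit_range
    alphas = []
    for p in profiles:
        s = p.grid.separations_beads
        mask = (s >= lo) & (s <= hi) & (p.values > 0)
        if mask.sum() < 3:
            raise ValueError(
                f"cell {p.cell_id!r}: fewer than 3 usable grid points in "
                f"fit range {fit_range}"
            )
        slope = np.polyfit(np.log(s[mask]), np.log(p.values[mask]), 1)[0]
        alphas.append(slope)
    alphas = np.asarray(alphas)
    sd = alphas.std(ddof=1) if len(alphas) > 1 else float("nan")
    return float(alphas.mean()), float(sd)


def write_heterogeneity_tsv(profile: HeterogeneityProfile, path: str) -> str:
    df = pd.DataFrame(
        {
            "s_beads": profile.grid.separations_beads,
            "s_bp": profile.grid.separations_bp,
            "mean_rs": profile.mean_rs,
            "ch": profile.ch,
            "relative_ch": profile.relative_ch,
            "resample_mean": (
                profile.resample_mean
                if profile.resample_mean is not None
                else np.full(len(profile.grid), np.nan)
            ),
            "resample_sd": (
                profile.resample_sd
                if profile.resample_sd is not None
                else np.full(len(profile.grid), np.nan)
            ),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_rs_matrix_tsv(profiles: list[RsProfile], path: str) -> str:
    """Per-cell Rs matrix: one row per cell, one column per separation."""
    grid = profiles[0].grid
    df = pd.DataFrame(
        np.vstack([p.values for p in profiles]),
        index=[p.cell_id for p in profiles],
        columns=[str(int(s)) for s in grid.separations_beads],
    )
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path
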