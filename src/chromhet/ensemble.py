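"""Single-cell chromatin conformation ensembles: containers, validation and I/O.

A *cell conformation* is one cell's chromatin chain as an ordered sequence of
beads (3D centre position, radius, genomic content in bp).  An *ensemble* is a
set of such conformations sharing the same bead schema, e.g. the 18-20 model
nuclei produced by a chromatin simulation, each treated as one "single cell".

Two text formats are supported:

* the native TSV schema — header lines ``#unit=<micron|arbitrary>`` and
  ``#avg_bead_genomic_size_bp=<int>`` followed by the columns
  ``cell_id  chain_id  bead_index  x  y  z  radius  genomic_size_bp``;
* multi-frame XYZ (coordinates only, one frame per cell) with a sidecar TSV
  supplying radii and genomic sizes.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "CellConformation",
    "ConformationEnsemble",
    "TrajectorySet",
    "read_ensemble",
    "write_ensemble",
    "merge_homolog_chains",
    "segment_boundaries",
    "sample_trajectory_snapshots",
]

LENGTH_UNITS = ("micron", "arbitrary")


class SchemaError(ValueError):
    """Raised when an input file or container violates the ensemble schema."""


@dataclass
class CellConformation:
    """Ordered bead chain of a single cell.

    Parameters
    ----------
    cell_id:
        Identifier of the cell (nucleus / replica / snapshot).
    positions:
        ``(L, 3)`` float array of bead centre coordinates, genomic order.
    radii:
        ``(L,)`` bead radii, same length unit as the positions.
    genomic_sizes:
        ``(L,)`` genomic content of each bead in bp.
    chain_id:
        Chain label; a single chain per conformation after preprocessing.
    """

    cell_id: str
    positions: np.ndarray
    radii: np.ndarray
    genomic_sizes: np.ndarray
    chain_id: str = "0"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.genomic_sizes = np.asarray(self.genomic_sizes, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise SchemaError(
                f"cell {self.cell_id!r}: positions must be (L, 3), "
                f"got {self.positions.shape}"
            )
        L = self.positions.shape[0]
        if L < 2:
            raise SchemaError(f"cell {self.cell_id!r}: need at least 2 beads, got {L}")
        if self.radii.shape != (L,) or self.genomic_sizes.shape != (L,):
            raise SchemaError(
                f"cell {self.cell_id!r}: radii/genomic_sizes must match bead count {L}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise SchemaError(f"cell {self.cell_id!r}: non-finite coordinates")
        if np.any(self.radii < 0) or not np.all(np.isfinite(self.radii)):
            raise SchemaError(f"cell {self.cell_id!r}: radii must be finite and >= 0")
        if np.any(self.genomic_sizes <= 0):
            raise SchemaError(f"cell {self.cell_id!r}: genomic sizes must be > 0")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass
class ConformationEnsemble:
    """A set of single-cell conformations sharing one bead/genomic schema."""

    cells: list[CellConformation]
    length_unit: str = "arbitrary"
    avg_bead_genomic_size: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_unit not in LENGTH_UNITS:
            raise SchemaError(
                f"length_unit must be one of {LENGTH_UNITS}, got {self.length_unit!r}"
            )
        if not self.cells:
            raise SchemaError("ensemble has no cells")
        L = self.cells[0].n_beads
        gsz = self.cells[0].genomic_sizes
        for c in self.cells:
            if c.n_beads != L:
                raise SchemaError(
                    f"cell {c.cell_id!r} has {c.n_beads} beads, expected {L}"
                )
            if not np.array_equal(c.genomic_sizes, gsz):
                raise SchemaError(
                    f"cell {c.cell_id!r}: per-index genomic sizes differ from "
                    f"cell {self.cells[0].cell_id!r}"
                )
        if not self.avg_bead_genomic_size:
            self.avg_bead_genomic_size = int(round(float(np.mean(gsz))))

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_beads(self) -> int:
        return self.cells[0].n_beads


@dataclass
class TrajectorySet:
    """Ordered snapshot sequences from which single-cell ensembles are resampled.

    Each trajectory is split into ``n_segments`` equal segments; the snapshots
    sitting at the segment boundaries (``n_segments`` of them, endpoints
    included) are the candidates from which one snapshot per trajectory is
    drawn for each resampled ensemble.
    """

    trajectories: list[list[CellConformation]]
    n_segments: int = 50
    n_resamples: int = 10
    seed: int | None = None
    length_unit: str = "arbitrary"
    avg_bead_genomic_size: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise SchemaError("n_segments must be >= 2")
        for t, traj in enumerate(self.trajectories):
            if len(traj) < self.n_segments:
                raise SchemaError(
                    f"trajectory {t} has {len(traj)} snapshots, fewer than "
                    f"n_segments={self.n_segments}"
                )


def segment_boundaries(n_snapshots: int, n_segments: int) -> np.ndarray:
    """Snapshot indices of the segment boundaries, endpoints included.

    For ``T`` snapshots and ``m`` segments the boundaries are the snapshots at
    ``round(j * (T - 1) / (m - 1))`` for ``j = 0 .. m-1``.
    """
    if n_snapshots < n_segments:
        raise SchemaError(
            f"{n_snapshots} snapshots cannot host {n_segments} segment boundaries"
        )
    j = np.arange(n_segments)
    return np.rint(j * (n_snapshots - 1) / (n_segments - 1)).astype(int)


def sample_trajectory_snapshots(traj: TrajectorySet) -> list[ConformationEnsemble]:
    """Draw ``n_resamples`` single-cell ensembles from trajectory boundaries.

    Each resampled ensemble holds exactly one boundary snapshot per
    trajectory, drawn uniformly and independently; the whole procedure is
    reproducible from ``traj.seed``.
    """
    rng = np.random.default_rng(traj.seed)
    out: list[ConformationEnsemble] = []
    bounds = [
        segment_boundaries(len(t), traj.n_segments) for t in traj.trajectories
    ]
    for r in range(traj.n_resamples):
        cells = []
        for t, trajectory in enumerate(traj.trajectories):
            snap = trajectory[bounds[t][rng.integers(traj.n_segments)]]
            cells.append(
                CellConformation(
                    cell_id=f"traj{t}",
                    positions=snap.positions.copy(),
                    radii=snap.radii.copy(),
                    genomic_sizes=snap.genomic_sizes.copy(),
                    chain_id=snap.chain_id,
                )
            )
        out.append(
            ConformationEnsemble(
                cells=cells,
                length_unit=traj.length_unit,
                avg_bead_genomic_size=traj.avg_bead_genomic_size,
                metadata={"resample_index": r, "seed": traj.seed},
            )
        )
    return out


def merge_homolog_chains(
    chain_a: CellConformation, chain_b: CellConformation
) -> CellConformation:
    """Collapse two paired homologous chains into a single chain.

    Bead ``i`` of the merged chain sits at the centre of mass of the paired
    beads (unweighted midpoint: the paired beads carry equal genomic content),
    and keeps the radius of the initial beads of the pair (the mean of the two
    radii, which equals either one for equal-radius pairs).
    """
    if chain_a.n_beads != chain_b.n_beads:
        raise SchemaError(
            f"homolog chains have unequal lengths: {chain_a.n_beads} vs "
            f"{chain_b.n_beads} (cells {chain_a.cell_id!r}, {chain_b.cell_id!r})"
        )
    return CellConformation(
        cell_id=chain_a.cell_id,
        positions=0.5 * (chain_a.positions + chain_b.positions),
        radii=0.5 * (chain_a.radii + chain_b.radii),
        genomic_sizes=chain_a.genomic_sizes.copy(),
        chain_id=f"{chain_a.chain_id}+{chain_b.chain_id}",
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "cell_id",
    "chain_id",
    "bead_index",
    "x",
    "y",
    "z",
    "radius",
    "genomic_size_bp",
]


def _parse_headers(path: str) -> dict:
    headers: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].strip().partition("=")
                headers[key.strip()] = val.strip()
    return headers


def _ensemble_from_frame(
    df: pd.DataFrame, unit: str, avg_size: int, metadata: dict
) -> ConformationEnsemble:
    cells = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("bead_index")
        idx = grp["bead_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise SchemaError(
                f"cell {cell_id!r}: bead_index must be 0..L-1 without gaps"
            )
        chain_ids = grp["chain_id"].unique()
        if len(chain_ids) != 1:
            raise SchemaError(f"cell {cell_id!r}: multiple chain_ids {chain_ids}")
        cells.append(
            CellConformation(
                cell_id=str(cell_id),
                positions=grp[["x", "y", "z"]].to_numpy(float),
                radii=grp["radius"].to_numpy(float),
                genomic_sizes=grp["genomic_size_bp"].to_numpy(),
                chain_id=str(chain_ids[0]),
            )
        )
    return ConformationEnsemble(
        cells=cells,
        length_unit=unit,
        avg_bead_genomic_size=avg_size,
        metadata=metadata,
    )


def _read_tsv(path: str, adapter: dict | None = None) -> ConformationEnsemble:
    headers = _parse_headers(path)
    adapter = adapter or {}
    colmap = adapter.get("columns", {})
    unit = adapter.get("unit", headers.get("unit"))
    avg = adapter.get("avg_bead_genomic_size_bp",
                      headers.get("avg_bead_genomic_size_bp"))
    if unit is None:
        raise SchemaError(f"{path}: missing '#unit=' header")
    if avg is None:
        raise SchemaError(f"{path}: missing '#avg_bead_genomic_size_bp=' header")
    avg_size = int(avg)
    try:
        df = pd.read_csv(path, sep=adapter.get("sep", "\t"), comment="#")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise SchemaError(f"{path}: malformed TSV ({exc})") from exc
    if colmap:
        df = df.rename(columns={v: k for k, v in colmap.items()})
    for col, default in (("chain_id", "0"),):
        if col not in df.columns:
            df[col] = default
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df[_COLUMNS].isna().any().any():
        bad = int(df[df[_COLUMNS].isna().any(axis=1)].index[0])
        raise SchemaError(f"{path}: malformed row {bad}")
    meta = {k: v for k, v in headers.items() if k not in (
        "unit", "avg_bead_genomic_size_bp")}
    return _ensemble_from_frame(df, unit, avg_size, meta)


def _read_xyz(path: str, sidecar: str) -> ConformationEnsemble:
    frames: list[tuple[str, np.ndarray]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise SchemaError(f"{path}: expected atom count at line {i + 1}") from exc
        comment = lines[i + 1].strip()
        cell_id = comment or f"frame{len(frames)}"
        rows = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise SchemaError(f"{path}: malformed XYZ row at line {i + 3 + j}")
            rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append((cell_id, np.array(rows)))
        i += 2 + n
    if sidecar is None:
        raise SchemaError("XYZ input requires a sidecar TSV with radii/genomic sizes")
    headers = _parse_headers(sidecar)
    if "unit" not in headers or "avg_bead_genomic_size_bp" not in headers:
        raise SchemaError(f"{sidecar}: sidecar needs '#unit=' and "
                          "'#avg_bead_genomic_size_bp=' headers")
    side = pd.read_csv(sidecar, sep="\t", comment="#")
    for col in ("bead_index", "radius", "genomic_size_bp"):
        if col not in side.columns:
            raise SchemaError(f"{sidecar}: missing column {col!r}")
    side = side.sort_values("bead_index")
    radii = side["radius"].to_numpy(float)
    gsz = side["genomic_size_bp"].to_numpy()
    cells = []
    for cell_id, pos in frames:
        if len(pos) != len(radii):
            raise SchemaError(
                f"cell {cell_id!r}: {len(pos)} beads but sidecar describes {len(radii)}"
            )
        cells.append(CellConformation(cell_id, pos, radii.copy(), gsz.copy()))
    return ConformationEnsemble(
        cells=cells,
        length_unit=headers["unit"],
        avg_bead_genomic_size=int(headers["avg_bead_genomic_size_bp"]),
    )


def read_ensemble(
    path: str,
    format: str | None = None,
    sidecar: str | None = None,
    adapter: dict | None = None,
) -> ConformationEnsemble:
    """Read a conformation ensemble from the native TSV or XYZ format.

    ``format`` is inferred from the file suffix when omitted.  XYZ input
    carries coordinates only and requires ``sidecar`` (TSV with columns
    ``bead_index, radius, genomic_size_bp`` plus the unit headers).

    ``adapter`` maps externally deposited tabular layouts onto the native
    schema without rewriting the files: ``{"columns": {<native>: <found>},
    "sep": ..., "unit": ..., "avg_bead_genomic_size_bp": ...}``; values given
    in the adapter take precedence over file headers.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "xyz" if path.lower().endswith(".xyz") else "tsv"
    if format == "tsv":
        return _read_tsv(path, adapter)
    if format == "xyz":
        return _read_xyz(path, sidecar)
    raise ValueError(f"unknown format {format!r}")


def write_ensemble(
    ensemble: ConformationEnsemble, path: str, format: str = "tsv"
) -> str:
    """Write an ensemble; ``read_ensemble(write_ensemble(e))`` reproduces ``e``."""
    if format == "tsv":
        buf = io.StringIO()
        buf.write(f"#unit={ensemble.length_unit}\n")
        buf.write(f"#avg_bead_genomic_size_bp={ensemble.avg_bead_genomic_size}\n")
        buf.write("\t".join(_COLUMNS) + "\n")
        for cell in ensemble.cells:
            for i in range(cell.n_beads):
                x, y, z = cell.positions[i]
                buf.write(
                    f"{cell.cell_id}\t{cell.chain_id}\t{i}\t"
                    f"{x:.10g}\t{y:.10g}\t{z:.10g}\t"
                    f"{cell.radii[i]:.10g}\t{cell.genomic_sizes[i]}\n"
                )
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
        return path
    if format == "xyz":
        with open(path, "w") as fh:
            for cell in ensemble.cells:
                fh.write(f"{cell.n_beads}\n{cell.cell_id}\n")
                for i in range(cell.n_beads):
                    x, y, z = cell.positions[i]
                    fh.write(f"C {x:.10g} {y:.10g} {z:.10g}\n")
        return path
    raise ValueError(f"unknown format {format!r}")
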