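"""End-to-end heterogeneity analysis and two-ensemble comparison workflows."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from .ensemble import ConformationEnsemble, read_ensemble
from .metrics import (
    HeterogeneityProfile,
    SeparationGrid,
    aggregate_resamples,
    compute_relative_ch,
    compute_rs_profiles,
    write_heterogeneity_tsv,
    write_rs_matrix_tsv,
)
from .upconvert import UpconversionSpec, upconvert_profiles

__all__ = ["RunConfig", "load_config", "run_heterogeneity", "compare_ensembles"]

DEFAULT_LANDMARKS_BP = (118_000, 1_000_000, 10_000_000)


def _pkg_version() -> str:
    try:
        return version("chromhet")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunConfig:
    """Configuration of one heterogeneity run.

    ``input_path`` may be None when ``ensemble`` is supplied directly.
    ``n_resamples``/``resample_size`` control optional bootstrap resampling of
    cells (with replacement) used for error bars when no trajectory data is
    available; ``seed`` makes every random stage reproducible.
    """

    input_path: str | None = None
    input_format: str | None = None
    sidecar: str | None = None
    ensemble: ConformationEnsemble | None = None
    label: str = "ensemble"
    n_resamples: int = 0
    resample_size: int | None = None
    seed: int | None = None
    upconversion: UpconversionSpec | None = None
    output_dir: str | None = None
    make_plots: bool = False
    landmarks_bp: tuple[int, ...] = DEFAULT_LANDMARKS_BP
    fit_range: tuple[int, int] = (2, 400)

    def load(self) -> ConformationEnsemble:
        if self.ensemble is not None:
            return self.ensemble
        if self.input_path is None:
            raise ValueError("RunConfig needs input_path or ensemble")
        return read_ensemble(self.input_path, self.input_format, self.sidecar)


def load_config(path: str) -> RunConfig:
    """Build a RunConfig from a YAML key-value file.

    Recognised keys mirror the RunConfig fields (``input_path``, ``label``,
    ``n_resamples``, ``seed``, ``output_dir``, ``make_plots``,
    ``landmarks_bp``, ``fit_range``) plus an optional ``upconversion``
    mapping with ``source_resolution_bp``, ``target_resolution_bp``,
    ``sigma_um``, ``mu`` and ``seed``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    up = raw.pop("upconversion", None)
    for key in ("landmarks_bp", "fit_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if up is not None:
        cfg.upconversion = UpconversionSpec(**up)
    return cfg


def _profiles_for(ensemble: ConformationEnsemble, config: RunConfig):
    grid = SeparationGrid.for_ensemble(ensemble)
    profiles = compute_rs_profiles(ensemble, grid)
    if config.upconversion is not None:
        rng = np.random.default_rng(
            config.upconversion.seed if config.upconversion.seed is not None
            else config.seed
        )
        profiles = upconvert_profiles(profiles, config.upconversion, rng)
    return grid, profiles


def _resampled_heterogeneity(
    profiles, config: RunConfig
) -> HeterogeneityProfile:
    het = compute_relative_ch(profiles)
    if config.n_resamples and config.n_resamples >= 2:
        rng = np.random.default_rng(config.seed)
        size = config.resample_size or len(profiles)
        reps = []
        for _ in range(config.n_resamples):
            ids = rng.integers(len(profiles), size=size)
            reps.append(compute_relative_ch([profiles[i] for i in ids]))
        agg = aggregate_resamples(reps)
        het.resample_mean = agg.resample_mean
        het.resample_sd = agg.resample_sd
    return het


def run_heterogeneity(config: RunConfig) -> dict:
    """Full pipeline: Rs profiles, heterogeneity curves, TSV outputs, manifest.

    Returns a bundle with the ensemble, profiles, the heterogeneity profile
    and the paths of any files written.
    """
    try:
        ensemble = config.load()
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc
    try:
        grid, profiles = _profiles_for(ensemble, config)
    except Exception as exc:
        raise RuntimeError(f"[rs] {exc}") from exc
    try:
        het = _resampled_heterogeneity(profiles, config)
    except Exception as exc:
        raise RuntimeError(f"[heterogeneity] {exc}") from exc

    outputs: dict[str, str] = {}
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        base = os.path.join(config.output_dir, config.label)
        outputs["rs_tsv"] = write_rs_matrix_tsv(profiles, base + ".rs.tsv")
        outputs["heterogeneity_tsv"] = write_heterogeneity_tsv(
            het, base + ".heterogeneity.tsv"
        )
        manifest = {
            "label": config.label,
            "input_path": config.input_path,
            "n_cells": ensemble.n_cells,
            "n_beads": ensemble.n_beads,
            "length_unit": ensemble.length_unit,
            "avg_bead_genomic_size_bp": ensemble.avg_bead_genomic_size,
            "seed": config.seed,
            "n_resamples": config.n_resamples,
            "upconversion": (
                None
                if config.upconversion is None
                else {
                    "source_resolution_bp": config.upconversion.source_resolution_bp,
                    "target_resolution_bp": config.upconversion.target_resolution_bp,
                    "sigma_um": config.upconversion.sigma_um,
                    "mu": config.upconversion.mu,
                    "seed": config.upconversion.seed,
                }
            ),
            "chromhet_version": _pkg_version(),
        }
        mpath = base + ".manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        outputs["manifest"] = mpath
        if config.make_plots:
            from .plotting import plot_heterogeneity

            outputs["plot"] = plot_heterogeneity(
                profiles, het, base + ".heterogeneity.png"
            )
    return {
        "ensemble": ensemble,
        "grid": grid,
        "profiles": profiles,
        "heterogeneity": het,
        "outputs": outputs,
    }


def _landmark_rows(het: HeterogeneityProfile, landmarks_bp) -> pd.DataFrame:
    s_bp = het.grid.separations_bp
    rows = []
    for lm in landmarks_bp:
        i = int(np.argmin(np.abs(s_bp - lm)))
        rows.append(
            {
                "landmark_bp": lm,
                "s_bp": int(s_bp[i]),
                "relative_ch": float(het.relative_ch[i]),
                "resample_sd": (
                    float(het.resample_sd[i]) if het.resample_sd is not None
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def compare_ensembles(config_a: RunConfig, config_b: RunConfig) -> dict:
    """Relative C.H. curves of two ensembles, their difference and landmarks.

    The grids must be comparable (same separations in bp).  Returns a bundle
    with the per-separation table and the landmark summary (defaults: TAD
    scale 118 kb, 1 Mb and 10 Mb).
    """
    res_a = run_heterogeneity(config_a)
    res_b = run_heterogeneity(config_b)
    het_a: HeterogeneityProfile = res_a["heterogeneity"]
    het_b: HeterogeneityProfile = res_b["heterogeneity"]
    if not np.array_equal(
        het_a.grid.separations_bp, het_b.grid.separations_bp
    ):
        raise ValueError("ensembles are on incomparable separation grids")
    diff = het_a.relative_ch - het_b.relative_ch
    diff_sd = None
    if het_a.resample_sd is not None and het_b.resample_sd is not None:
        diff_sd = np.sqrt(het_a.resample_sd**2 + het_b.resample_sd**2)
    table = pd.DataFrame(
        {
            "s_beads": het_a.grid.separations_beads,
            "s_bp": het_a.grid.separations_bp,
            f"relative_ch_{config_a.label}": het_a.relative_ch,
            f"relative_ch_{config_b.label}": het_b.relative_ch,
            "difference": diff,
            "difference_sd": (
                diff_sd if diff_sd is not None
                else np.full(len(het_a.grid), np.nan)
            ),
        }
    )
    landmarks = config_a.landmarks_bp
    lm_a = _landmark_rows(het_a, landmarks).rename(
        columns={"relative_ch": f"relative_ch_{config_a.label}",
                 "resample_sd": f"sd_{config_a.label}"}
    )
    lm_b = _landmark_rows(het_b, landmarks)[["landmark_bp", "relative_ch",
                                             "resample_sd"]].rename(
        columns={"relative_ch": f"relative_ch_{config_b.label}",
                 "resample_sd": f"sd_{config_b.label}"}
    )
    lm = lm_a.merge(lm_b, on="landmark_bp")
    lm["difference"] = (
        lm[f"relative_ch_{config_a.label}"] - lm[f"relative_ch_{config_b.label}"]
    )
    return {
        "a": res_a,
        "b": res_b,
        "table": table,
        "landmarks": lm,
    }
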