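"""Synthetic datasets with the statistical structure of the imaging assays.

The original measurements are quantitative-microscopy readouts of locally
UV-damaged nuclei: bulk accumulation / FLIP / EdU time courses averaged
over tens to hundreds of cells, and per-cell paired two-channel intensity
measurements.  No raw imaging data are redistributable, so every pipeline
stage here consumes synthetic tables generated from the model itself with
matched noise structure:

* bulk curves — model time courses plus Gaussian replicate noise, reported
  as mean, empirical SD and replicate count per time point;
* EdU replicate curves — first-order accumulation curves with additive
  Gaussian noise;
* paired two-channel measurements — a lognormal true signal observed
  through two channels with independent multiplicative lognormal errors.

All generators are bit-reproducible for a fixed seed, and their CSV output
round-trips losslessly through :func:`read_dataset` / :func:`write_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import DATASET_COLUMNS
from .model import FACTORS, ParameterSet, flip_curve, simulate
from .population import lognormal_mean_cv

__all__ = [
    "NoiseSpec",
    "generate_bulk_dataset",
    "generate_edu_curves",
    "generate_paired_measurements",
    "read_dataset",
    "write_dataset",
]

#: default bleach start for simulated FLIP curves (minutes after damage)
DEFAULT_FLIP_START = 15.0


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise model for bulk curves.

    ``kind="relative"`` scales the noise SD with the signal (``sd`` is the
    relative magnitude); ``"absolute"`` applies a constant SD.  Each time
    point receives ``n_replicates`` independent Gaussian draws; the table
    records their mean and empirical SD.
    """

    kind: str = "relative"
    sd: float = 0.05
    n_replicates: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _noisy_rows(
    rng: np.random.Generator,
    observable: str,
    factor: str,
    times: np.ndarray,
    curve: np.ndarray,
    noise: NoiseSpec,
    flip_start: float | None = None,
) -> list[dict]:
    rows = []
    for t, mu in zip(times, curve):
        scale = noise.sd * (abs(mu) if noise.kind == "relative" else 1.0)
        if noise.sd == 0:
            mean, sd = mu, 0.0
        else:
            reps = mu + rng.normal(0.0, max(scale, 1e-300), size=noise.n_replicates)
            mean = float(reps.mean())
            sd = float(reps.std(ddof=1)) if noise.n_replicates > 1 else 0.0
        row = dict(
            observable=observable, factor=factor, time_min=float(t),
            value=mean, sd=sd, n=noise.n_replicates,
        )
        if flip_start is not None:
            row["flip_start"] = flip_start
        rows.append(row)
    return rows


def generate_bulk_dataset(
    params: ParameterSet,
    noise: NoiseSpec | None = None,
    acc_times: Sequence[float] | None = None,
    include_edu: bool = True,
    include_flip: bool = True,
    flip_times: Sequence[float] | None = None,
    flip_start: float = DEFAULT_FLIP_START,
) -> pd.DataFrame:
    """Bulk experiment table: accumulation (all factors), EdU and FLIP.

    Default grids: accumulation and EdU on 0–240 min at 10-min steps; FLIP
    offsets 0–5 min at 5-s steps from ``flip_start``.  With ``noise.sd=0``
    the values equal the model curves exactly.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    times = np.asarray(
        acc_times if acc_times is not None else np.arange(0.0, 241.0, 10.0), float
    )
    grid = np.unique(np.concatenate([[0.0], times]))
    sel = np.searchsorted(grid, times)
    traj = simulate(params, grid)
    rows: list[dict] = []
    for f in FACTORS:
        rows += _noisy_rows(rng, "accumulation", f, times, traj.accumulation(f)[sel], noise)
    if include_edu:
        rows += _noisy_rows(rng, "edu", "", times, traj.edu[sel], noise)
    if include_flip:
        offs = np.asarray(
            flip_times if flip_times is not None else np.arange(0.0, 5.01, 5.0 / 60.0),
            float,
        )
        for f in FACTORS:
            curve = flip_curve(params, flip_start, offs, f)
            rows += _noisy_rows(rng, "flip", f, offs, curve, noise, flip_start=flip_start)
    table = pd.DataFrame(rows)
    return table


def generate_edu_curves(
    lam: float,
    edu_max: float,
    times: Sequence[float],
    noise: NoiseSpec,
) -> pd.DataFrame:
    """Replicate table of noisy first-order EdU curves.

    ``lam`` is per hour and ``times`` in hours.  Returns one row per
    (replicate, time) with columns ``replicate``, ``time_h``, ``value``.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    t = np.asarray(times, float)
    rng = np.random.default_rng(noise.seed)
    clean = edu_max * (1.0 - np.exp(-lam * t))
    rows = []
    for rep in range(noise.n_replicates):
        scale = noise.sd * (np.abs(clean) if noise.kind == "relative" else 1.0)
        vals = clean + (rng.normal(0.0, 1.0, size=t.size) * scale if noise.sd > 0 else 0.0)
        rows.append(pd.DataFrame({"replicate": rep, "time_h": t, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def generate_paired_measurements(
    n: int,
    signal_cv: float,
    relative_error: float,
    seed: int,
    mean: float = 1.0,
) -> pd.DataFrame:
    """Paired two-channel measurements of a lognormal true signal.

    Each channel observes the common signal through independent
    multiplicative lognormal noise with the given per-channel relative
    error (CV of the noise factor).  Columns: ``truth``, ``channel_a``,
    ``channel_b``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if signal_cv < 0 or relative_error < 0:
        raise ValueError("CVs must be >= 0")
    rng = np.random.default_rng(seed)
    truth = lognormal_mean_cv(rng, mean, signal_cv, n)
    noise_a = lognormal_mean_cv(rng, 1.0, relative_error, n)
    noise_b = lognormal_mean_cv(rng, 1.0, relative_error, n)
    return pd.DataFrame(
        {"truth": truth, "channel_a": truth * noise_a, "channel_b": truth * noise_b}
    )


def write_dataset(table: pd.DataFrame, path) -> None:
    """Write a dataset table to CSV (lossless round-trip with read_dataset)."""
    table.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV written by :func:`write_dataset`."""
    table = pd.read_csv(path, keep_default_na=False)
    if "factor" in table.columns:
        table["factor"] = table["factor"].astype(str)
    return table
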