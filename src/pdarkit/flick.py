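"""Live/dead cell counting metrics for kinetic death assays.

Plate-reader death assays report a dead-cell fluorescence signal over time,
plus total-cell anchors obtained by detergent lysis of a parallel plate at
T0 and of the assay plate at endpoint.  From these, live-cell numbers over
time are inferred and the four standard response metrics computed:

* **LF** (lethal fraction): ``dead / (live + dead)``
* **FV** (fractional viability): ``live / (live + dead)`` = 1 − LF
* **RV** (relative viability): treated live count over untreated live count
* **GR** (growth-rate metric): normalized ratio of treated to untreated
  population growth rates, anchored at T0; 1 = unaffected growth, 0 = full
  arrest, negative = net shrinkage.

Zero-denominator metrics are returned as NaN (flagged-missing) and propagate
through downstream tables; they are never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticTrajectory",
    "FlickAnchors",
    "lethal_fraction",
    "fractional_viability",
    "relative_viability",
    "growth_rate_gr",
    "flick_to_trajectory",
    "metric_table",
    "read_trajectories",
    "write_trajectories",
]

#: Columns of the long-format trajectory table.
TRAJECTORY_COLUMNS = ["condition_id", "genotype", "drug", "dose_uM", "time_h", "live", "dead"]


@dataclass
class KineticTrajectory:
    """Time-stamped live and dead cell counts for one well/condition.

    Counts are real-valued (fluorescence-derived), not integers.  Times are
    hours and must be strictly increasing.
    """

    condition_id: str
    genotype: str
    drug: str
    dose: float
    times: np.ndarray
    live: np.ndarray
    dead: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.live = np.asarray(self.live, dtype=float)
        self.dead = np.asarray(self.dead, dtype=float)
        if not (len(self.times) == len(self.live) == len(self.dead)):
            raise ValueError("times, live and dead must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.live < 0) or np.any(self.dead < 0):
            raise ValueError("cell counts must be non-negative")

    @property
    def lethal_fraction(self) -> np.ndarray:
        return lethal_fraction(self.live, self.dead)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": self.condition_id,
                "genotype": self.genotype,
                "drug": self.drug,
                "dose_uM": self.dose,
                "time_h": self.times,
                "live": self.live,
                "dead": self.dead,
            }
        )


@dataclass
class FlickAnchors:
    """Dead-cell signal kinetics plus the two lysis anchors.

    ``total_t0``/``total_end`` are cell counts from the lysed T0 plate and
    the endpoint lysis; ``lysed_signal_end`` is the fluorescence of the fully
    lysed endpoint well, which calibrates fluorescence to cell number.
    """

    dead_signal: np.ndarray
    total_t0: float
    total_end: float
    lysed_signal_end: float

    def __post_init__(self) -> None:
        self.dead_signal = np.asarray(self.dead_signal, dtype=float)
        if self.total_t0 <= 0 or self.total_end <= 0 or self.lysed_signal_end <= 0:
            raise ValueError("lysis anchors must be positive")


def lethal_fraction(live, dead):
    """Fraction of the population that is dead: ``dead / (live + dead)``.

    Returns NaN where ``live + dead == 0``.
    """
    live = np.asarray(live, dtype=float)
    dead = np.asarray(dead, dtype=float)
    if np.any(live < 0) or np.any(dead < 0):
        raise ValueError("counts must be non-negative")
    total = live + dead
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, dead / np.where(total > 0, total, 1.0), np.nan)
    return out if out.ndim else float(out)


def fractional_viability(live, dead):
    """Fraction of the population that is alive; complement of the lethal fraction."""
    live = np.asarray(live, dtype=float)
    dead = np.asarray(dead, dtype=float)
    if np.any(live < 0) or np.any(dead < 0):
        raise ValueError("counts must be non-negative")
    total = live + dead
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > 0, live / np.where(total > 0, total, 1.0), np.nan)
    return out if out.ndim else float(out)


def relative_viability(live_treated, live_untreated):
    """Conventional relative viability: treated live count over untreated live count.

    NaN where the untreated count is zero.
    """
    live_treated = np.asarray(live_treated, dtype=float)
    live_untreated = np.asarray(live_untreated, dtype=float)
    if np.any(live_treated < 0) or np.any(live_untreated < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            live_untreated > 0,
            live_treated / np.where(live_untreated > 0, live_untreated, 1.0),
            np.nan,
        )
    return out if out.ndim else float(out)


def growth_rate_gr(live_treated, live_untreated, live_t0):
    """Growth-rate metric GR.

    ``GR = 2 ** ( log2(live_treated / live_t0) / log2(live_untreated / live_t0) ) − 1``

    GR equals 1 when the treated population grows like the untreated one, 0
    when it is static, and is negative when it shrinks below its T0 size.
    NaN (flagged-missing) where the untreated population did not change from
    T0 (zero denominator).  All counts must be strictly positive.
    """
    live_treated = np.asarray(live_treated, dtype=float)
    live_untreated = np.asarray(live_untreated, dtype=float)
    live_t0 = np.asarray(live_t0, dtype=float)
    if np.any(live_treated <= 0) or np.any(live_untreated <= 0) or np.any(live_t0 <= 0):
        raise ValueError("GR requires strictly positive counts")
    num = np.log2(live_treated / live_t0)
    den = np.log2(live_untreated / live_t0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, np.exp2(num / np.where(den != 0, den, 1.0)) - 1.0, np.nan)
    return out if out.ndim else float(out)


def flick_to_trajectory(
    anchors: FlickAnchors,
    times,
    condition_id: str = "",
    genotype: str = "WT",
    drug: str = "",
    dose: float = 0.0,
    interpolation: str = "geometric",
) -> KineticTrajectory:
    """Convert dead-cell signal plus lysis anchors into a live/dead trajectory.

    Dead counts are the dead-cell signal scaled by ``total_end /
    lysed_signal_end``.  The total population at interior times is
    interpolated between the T0 and endpoint lysis anchors — geometrically
    (log-linear, consistent with exponential growth) by default, or linearly
    with ``interpolation="linear"``.  Live counts are total minus dead,
    clamped at zero (with a warning) if the dead count ever exceeds the
    interpolated total.
    """
    times = np.asarray(times, dtype=float)
    if len(times) != len(anchors.dead_signal):
        raise ValueError("dead_signal must be sampled at the given times")
    if times[0] != 0:
        raise ValueError("trajectory times must start at 0 (the T0 anchor)")
    t_end = times[-1]
    dead = anchors.dead_signal * (anchors.total_end / anchors.lysed_signal_end)
    if interpolation == "geometric":
        total = anchors.total_t0 * (anchors.total_end / anchors.total_t0) ** (times / t_end)
    elif interpolation == "linear":
        total = anchors.total_t0 + (anchors.total_end - anchors.total_t0) * times / t_end
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    live = total - dead
    if np.any(live < 0):
        warnings.warn("dead count exceeds interpolated total; clamping live cells to 0")
        live = np.clip(live, 0.0, None)
    return KineticTrajectory(condition_id, genotype, drug, dose, times, live, dead)


def metric_table(df: pd.DataFrame, untreated_drug: str = "untreated") -> pd.DataFrame:
    """Add LF/FV/RV/GR columns to a long-format trajectory table.

    RV and GR compare each condition at each timepoint against the
    untreated row of the same genotype and timepoint (``drug ==
    untreated_drug``); the T0 anchor for GR is the untreated live count at
    the earliest timepoint.  Rows without a matching untreated reference get
    NaN for RV and GR.
    """
    df = df.copy()
    df["LF"] = lethal_fraction(df["live"].to_numpy(), df["dead"].to_numpy())
    df["FV"] = fractional_viability(df["live"].to_numpy(), df["dead"].to_numpy())
    rv = np.full(len(df), np.nan)
    gr = np.full(len(df), np.nan)
    for genotype, sub in df.groupby("genotype"):
        unt = sub[sub["drug"] == untreated_drug]
        if unt.empty:
            continue
        unt_by_time = unt.groupby("time_h")["live"].mean()
        t0 = unt_by_time.index.min()
        live_t0 = unt_by_time.loc[t0]
        for idx, row in sub.iterrows():
            t = row["time_h"]
            if t not in unt_by_time.index:
                continue
            live_unt = unt_by_time.loc[t]
            if live_unt > 0:
                rv[df.index.get_loc(idx)] = row["live"] / live_unt
            if row["live"] > 0 and live_unt > 0 and live_t0 > 0 and t != t0:
                gr[df.index.get_loc(idx)] = growth_rate_gr(row["live"], live_unt, live_t0)
    df["RV"] = rv
    df["GR"] = gr
    return df


def read_trajectories(path) -> list[KineticTrajectory]:
    """Read a long-format trajectory CSV/TSV into per-condition trajectories."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    out = []
    for cid, sub in df.groupby("condition_id", sort=False):
        sub = sub.sort_values("time_h")
        out.append(
            KineticTrajectory(
                condition_id=str(cid),
                genotype=str(sub["genotype"].iloc[0]),
                drug=str(sub["drug"].iloc[0]),
                dose=float(sub["dose_uM"].iloc[0]),
                times=sub["time_h"].to_numpy(),
                live=sub["live"].to_numpy(),
                dead=sub["dead"].to_numpy(),
            )
        )
    return out


def write_trajectories(trajectories, path) -> None:
    """Write trajectories as a long-format CSV."""
    pd.concat([t.to_frame() for t in trajectories], ignore_index=True).to_csv(path, index=False)
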