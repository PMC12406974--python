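"""GRADE: growth-rate inference adjusted for death.

Net population growth conflates proliferation and death: a drug that kills
half the cells and one that halves the division rate can produce the same
endpoint count.  GRADE deconvolves the two by forward-simulating every
pairwise combination of candidate proliferation rates (doubling time τ) and
death fractions (DR) under the model

    live(t) = C0 · 2^(t/τ) · (1 − DR)
    dead(t) = C0 · 2^(t/τ) · DR

computing the fractional viability FV and growth-rate metric GR of each
simulated pair, and returning the (τ, DR) cell whose simulated (FV, GR)
best matches the observed pair.  The default grid is 500 × 500 with τ
log-spaced on [8, 200] h and DR linear on [0, 0.999].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flick import fractional_viability, growth_rate_gr

__all__ = ["GradeGrid", "GradeResult", "grade_forward", "build_grid", "infer_grade"]


def grade_forward(c0: float, t: float, tau: float, dr: float):
    """Forward model: live and dead counts after ``t`` hours.

    ``tau`` is the doubling time (hours) and ``dr`` the death fraction in
    [0, 1).  The dead count is the fraction ``dr`` of the total population
    ``c0 · 2^(t/tau)``.
    """
    if c0 <= 0:
        raise ValueError("initial cell number must be positive")
    if t < 0 or tau <= 0:
        raise ValueError("t must be non-negative and tau positive")
    dr_arr = np.asarray(dr, dtype=float)
    if np.any(dr_arr < 0) or np.any(dr_arr >= 1):
        raise ValueError("death fraction must lie in [0, 1)")
    total = c0 * np.exp2(np.asarray(t, dtype=float) / np.asarray(tau, dtype=float))
    live = total * (1.0 - dr_arr)
    dead = total * dr_arr
    if np.ndim(live) == 0:
        return float(live), float(dead)
    return live, dead


@dataclass
class GradeGrid:
    """Precomputed (τ, DR) → (FV, GR) lookup."""

    taus: np.ndarray
    drs: np.ndarray
    fv_table: np.ndarray  # shape (n_tau, n_dr)
    gr_table: np.ndarray
    t: float
    c0: float
    untreated_tau: float


@dataclass
class GradeResult:
    """Inferred proliferation/death rate pair for one observation."""

    tau_hat: float
    dr_hat: float
    matched_fv: float
    matched_gr: float
    distance: float
    i_tau: int
    i_dr: int


def build_grid(
    c0: float,
    t: float,
    untreated_tau: float,
    tau_range: tuple[float, float] = (8.0, 200.0),
    dr_range: tuple[float, float] = (0.0, 0.999),
    n_tau: int = 500,
    n_dr: int = 500,
    taus=None,
    drs=None,
) -> GradeGrid:
    """Simulate all pairwise (τ, DR) combinations and tabulate (FV, GR).

    τ values are log-spaced and DR values linear unless explicit axes are
    given.  GR uses ``live_untreated = c0 · 2^(t/untreated_tau)`` and
    ``live_t0 = c0``.
    """
    if t <= 0:
        raise ValueError("assay length must be positive (GR undefined at t=0)")
    if untreated_tau <= 0:
        raise ValueError("untreated doubling time must be positive")
    taus = (
        np.geomspace(tau_range[0], tau_range[1], n_tau)
        if taus is None
        else np.asarray(taus, dtype=float)
    )
    drs = (
        np.linspace(dr_range[0], dr_range[1], n_dr)
        if drs is None
        else np.asarray(drs, dtype=float)
    )
    total = c0 * np.exp2(t / taus)[:, None]  # (n_tau, 1)
    live = total * (1.0 - drs[None, :])
    dead = total * drs[None, :]
    fv = fractional_viability(live, dead)
    live_unt = c0 * 2.0 ** (t / untreated_tau)
    # GR needs strictly positive live counts; DR=1 never occurs (dr < 1).
    gr = growth_rate_gr(live, live_unt, c0)
    return GradeGrid(taus=taus, drs=drs, fv_table=fv, gr_table=gr, t=t, c0=c0,
                     untreated_tau=untreated_tau)


def infer_grade(fv_obs: float, gr_obs: float, grid: GradeGrid) -> GradeResult:
    """Find the grid cell whose simulated (FV, GR) best matches an observation.

    Distance is Euclidean after scaling each axis by its grid range (GR
    spans roughly [−1, 1] while FV spans [0, 1]).  Ties break to the
    smaller DR index, then the smaller τ index, for reproducibility.
    """
    if not (np.isfinite(fv_obs) and np.isfinite(gr_obs)):
        raise ValueError("observed FV and GR must be finite")
    fv_obs = float(np.clip(fv_obs, 0.0, 1.0))
    fv_scale = max(np.ptp(grid.fv_table), 1e-12)
    gr_scale = max(np.ptp(grid.gr_table), 1e-12)
    d2 = ((grid.fv_table - fv_obs) / fv_scale) ** 2 + (
        (grid.gr_table - gr_obs) / gr_scale
    ) ** 2
    # argmin over flattened (i_dr, i_tau) order so DR index breaks ties first.
    flat = np.argmin(d2.T)  # transposed: row = dr index, col = tau index
    i_dr, i_tau = divmod(int(flat), d2.shape[0])
    return GradeResult(
        tau_hat=float(grid.taus[i_tau]),
        dr_hat=float(grid.drs[i_dr]),
        matched_fv=float(grid.fv_table[i_tau, i_dr]),
        matched_gr=float(grid.gr_table[i_tau, i_dr]),
        distance=float(np.sqrt(d2[i_tau, i_dr])),
        i_tau=i_tau,
        i_dr=i_dr,
    )
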