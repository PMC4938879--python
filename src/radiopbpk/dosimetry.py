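"""Cumulated activity and mean absorbed dose.

The kinetic output of the model — an organ time-activity curve A(t) [Bq] —
feeds dosimetry through its time integral (the cumulated activity, Bq·s).
The mean absorbed dose to a target tissue of mass M [kg] is then

    dose = k * A_int * sum_i x_i * E_i * f_i / M   [Gy]

with, per radiation type i, yield ``x_i`` per nuclear transition, mean
energy ``E_i`` [MeV] and absorbed fraction ``f_i``; ``k`` converts units
[Gy·kg·Bq⁻¹·s⁻¹·MeV⁻¹].  No nuclide emission table is bundled: the
radiation spectrum and ``k`` are user inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RadiationSpec", "time_activity_integral", "mean_absorbed_dose"]


@dataclass(frozen=True)
class RadiationSpec:
    """Radiation spectrum entering the absorbed-dose formula.

    yields_, energies_mev, absorbed_fractions are parallel per-radiation
    arrays; k is the unit-conversion constant [Gy·kg·Bq⁻¹·s⁻¹·MeV⁻¹].
    """

    yields_: tuple[float, ...]
    energies_mev: tuple[float, ...]
    absorbed_fractions: tuple[float, ...]
    k: float

    def __post_init__(self) -> None:
        if not len(self.yields_) == len(self.energies_mev) == len(
            self.absorbed_fractions
        ):
            raise ValueError("radiation arrays must have equal length")
        if any(x < 0 for x in self.yields_):
            raise ValueError("yields must be >= 0")
        if any(e < 0 for e in self.energies_mev):
            raise ValueError("energies must be >= 0")
        if any(not 0 <= f <= 1 for f in self.absorbed_fractions):
            raise ValueError("absorbed fractions must be in [0, 1]")
        if not self.k > 0:
            raise ValueError("k must be > 0")

    @property
    def energy_per_transition_mev(self) -> float:
        """sum_i x_i E_i f_i [MeV per nuclear transition]."""
        return float(
            np.sum(
                np.array(self.yields_)
                * np.array(self.energies_mev)
                * np.array(self.absorbed_fractions)
            )
        )


def time_activity_integral(
    time_min: np.ndarray,
    activity_bq: np.ndarray,
    tail: str = "none",
    tail_points: int = 3,
) -> float:
    """Cumulated activity [Bq·s] of one organ curve.

    Trapezoidal integration over the sampled span (time in minutes,
    converted to seconds).  With ``tail="mono_exponential"`` the curve is
    extrapolated beyond the last sample by ``A(t_end)/lambda``, with the
    decay rate taken from a log-linear fit to the last ``tail_points``
    positive samples; a non-decaying terminal segment is an error, since
    the extrapolated integral would diverge.
    """
    t = np.asarray(time_min, dtype=float)
    a = np.asarray(activity_bq, dtype=float)
    if t.ndim != 1 or t.shape != a.shape or t.size < 2:
        raise ValueError("need matching 1-D arrays with at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.any(a < 0):
        raise ValueError("activities must be >= 0")

    integral = float(np.trapezoid(a, t)) * 60.0  # Bq·min -> Bq·s

    if tail == "none":
        return integral
    if tail != "mono_exponential":
        raise ValueError(f"unknown tail mode {tail!r}")
    if tail_points < 2:
        raise ValueError("tail fit needs at least 2 points")
    pos = a > 0
    idx = np.nonzero(pos)[0]
    if idx.size < tail_points:
        raise ValueError("not enough positive samples for the tail fit")
    sel = idx[-tail_points:]
    slope, _ = np.polyfit(t[sel], np.log(a[sel]), 1)
    if slope >= 0:
        raise ValueError(
            f"terminal segment is not decaying (log-slope {slope:g} >= 0); "
            "cannot extrapolate a mono-exponential tail"
        )
    lam = -slope  # 1/min
    return integral + float(a[-1]) / lam * 60.0


def mean_absorbed_dose(
    cumulated_activity_bq_s: float,
    radiation: RadiationSpec,
    target_mass_kg: float,
) -> float:
    """Mean absorbed dose [Gy] to a target of mass ``target_mass_kg``."""
    if not target_mass_kg > 0:
        raise ValueError(f"target mass must be > 0, got {target_mass_kg}")
    if cumulated_activity_bq_s < 0:
        raise ValueError("cumulated activity must be >= 0")
    return (
        radiation.k
        * cumulated_activity_bq_s
        * radiation.energy_per_transition_mev
        / target_mass_kg
    )
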