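"""Stress-relaxation analysis of unconfined-compression tests on cartilage.

A cylindrical cartilage plug is compressed to a fixed strain (ramp) and held
while the stress decays (hold).  The decay is summarised by a two-branch
piecewise exponential

    sigma(t) = A1 * exp(-t / tau1) + B1   for t <  t_split
    sigma(t) = A2 * exp(-t / tau2) + B2   for t >= t_split

with t = 0 at the start of the hold and t_split = 100 s by default, fitted by
least squares subject to three constraints: the model equals the peak stress
at t = 0, reproduces the measured equilibrium stress over the final window of
the hold, and the two branches are continuous at t_split.  tau1 characterises
the fast (fluid-pressurisation) phase, tau2 the slow (matrix) phase.

The fitting surface follows the statsmodels idiom:

    model = PiecewiseRelaxationModel(curve)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class LoadingProtocol:
    """Unconfined-compression stress-relaxation protocol.

    Defaults mirror the standard protocol: 0.01 N preload, ramp at 10 um/s to
    15 % strain, 900 s hold.  Geometry is per specimen.
    """

    sample_diameter_mm: float
    sample_thickness_mm: float
    preload_N: float = 0.01
    target_strain: float = 0.15
    ramp_rate_um_s: float = 10.0
    hold_duration_s: float = 900.0

    def __post_init__(self):
        if not (0.0 < self.target_strain < 1.0):
            raise ValueError("target_strain must lie in (0, 1)")
        for name in ("sample_diameter_mm", "sample_thickness_mm",
                     "ramp_rate_um_s", "hold_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cross_section_mm2(self) -> float:
        return math.pi * (self.sample_diameter_mm / 2.0) ** 2


@dataclass
class RelaxationCurve:
    """Stress during the hold phase, with t = 0 at the end of the ramp.

    ``stress_kPa`` is force over the unloaded cross-section; ``applied_strain``
    is platen displacement over unloaded thickness.  The ramp, when recorded,
    is retained in ``ramp_time_s`` / ``ramp_stress_kPa`` but is never fitted.
    """

    time_s: np.ndarray
    stress_kPa: np.ndarray
    applied_strain: float
    protocol: LoadingProtocol
    ramp_time_s: np.ndarray | None = None
    ramp_stress_kPa: np.ndarray | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.stress_kPa = np.asarray(self.stress_kPa, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.stress_kPa.shape:
            raise ValueError("time and stress must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.stress_kPa)):
            raise ValueError("stress contains non-finite values")
        if not (0.0 < self.applied_strain < 1.0):
            raise ValueError("applied_strain must lie in (0, 1)")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def compute_stress_strain(
    time_s: Sequence[float],
    force_N: Sequence[float],
    displacement_um: Sequence[float],
    protocol: LoadingProtocol,
) -> RelaxationCurve:
    """Convert a force-displacement record into a :class:`RelaxationCurve`.

    Stress is force over the unloaded cross-sectional area (kPa); strain is
    platen displacement over the unloaded thickness.  The end of the ramp is
    taken at the stress maximum; the hold is re-timed so the peak sits at
    t = 0.  Samples before the peak are kept as the (unfitted) ramp.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(force_N, dtype=float)
    d = np.asarray(displacement_um, dtype=float)
    if not (t.shape == f.shape == d.shape) or t.ndim != 1:
        raise ValueError("time, force and displacement must be 1-D and equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("record time must be strictly increasing")

    # N / mm^2 = MPa -> kPa
    stress = f / protocol.cross_section_mm2 * 1000.0
    strain = d / 1000.0 / protocol.sample_thickness_mm

    i_peak = int(np.argmax(stress))
    applied = float(strain[i_peak:].mean())
    return RelaxationCurve(
        time_s=t[i_peak:] - t[i_peak],
        stress_kPa=stress[i_peak:],
        applied_strain=applied,
        protocol=protocol,
        ramp_time_s=t[:i_peak] - t[i_peak],
        ramp_stress_kPa=stress[:i_peak],
    )


@dataclass(frozen=True)
class ModulusResult:
    """Peak and equilibrium stress and strain-normalised moduli (kPa)."""

    E_peak_kPa: float
    E_eq_kPa: float
    sigma_peak_kPa: float
    sigma_eq_kPa: float


def extract_moduli(curve: RelaxationCurve, eq_window_s: float = 100.0) -> ModulusResult:
    """Peak stress (record maximum) and equilibrium stress (mean over the
    final ``eq_window_s`` of the hold), each divided by the applied strain."""
    if eq_window_s <= 0:
        raise ValueError("eq_window_s must be positive")
    if eq_window_s > curve.duration_s:
        raise ValueError(
            f"eq_window_s={eq_window_s} exceeds the hold duration "
            f"({curve.duration_s:.1f} s)"
        )
    sigma_peak = float(curve.stress_kPa.max())
    t_end = curve.time_s[-1]
    in_window = curve.time_s >= t_end - eq_window_s
    sigma_eq = float(curve.stress_kPa[in_window].mean())
    eps = curve.applied_strain
    return ModulusResult(
        E_peak_kPa=sigma_peak / eps,
        E_eq_kPa=sigma_eq / eps,
        sigma_peak_kPa=sigma_peak,
        sigma_eq_kPa=sigma_eq,
    )


class FitConvergenceError(RuntimeError):
    """Raised when the constrained fit fails; carries the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class PiecewiseRelaxationResults:
    """Fitted two-branch relaxation parameters with diagnostics.

    Satisfies, by construction of the reparameterised solver:
    ``A1 + B1 == sigma_peak``; model mean over the final equilibrium window
    equals ``sigma_eq``; the branches agree at ``t_split``.
    """

    A1_kPa: float
    tau1_s: float
    B1_kPa: float
    A2_kPa: float
    tau2_s: float
    B2_kPa: float
    t_split_s: float
    rmse_kPa: float
    sigma_peak_kPa: float
    sigma_eq_kPa: float
    eq_window_s: float
    n_obs: int
    continuity_residual_kPa: float = field(default=0.0)
    peak_residual_kPa: float = field(default=0.0)

    def predict(self, time_s) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        fast = self.A1_kPa * np.exp(-t / self.tau1_s) + self.B1_kPa
        slow = self.A2_kPa * np.exp(-t / self.tau2_s) + self.B2_kPa
        return np.where(t < self.t_split_s, fast, slow)

    @property
    def params(self) -> dict:
        return {
            "A1_kPa": self.A1_kPa, "tau1_s": self.tau1_s, "B1_kPa": self.B1_kPa,
            "A2_kPa": self.A2_kPa, "tau2_s": self.tau2_s, "B2_kPa": self.B2_kPa,
        }

    def summary(self) -> str:
        lines = [
            "Piecewise stress-relaxation fit",
            "=" * 47,
            f"{'n obs':<28}{self.n_obs:>19d}",
            f"{'branch split t_split [s]':<28}{self.t_split_s:>19.1f}",
            f"{'RMSE [kPa]':<28}{self.rmse_kPa:>19.4g}",
            "-" * 47,
            f"{'fast phase A1 [kPa]':<28}{self.A1_kPa:>19.4g}",
            f"{'fast phase tau1 [s]':<28}{self.tau1_s:>19.4g}",
            f"{'fast phase B1 [kPa]':<28}{self.B1_kPa:>19.4g}",
            f"{'slow phase A2 [kPa]':<28}{self.A2_kPa:>19.4g}",
            f"{'slow phase tau2 [s]':<28}{self.tau2_s:>19.4g}",
            f"{'slow phase B2 [kPa]':<28}{self.B2_kPa:>19.4g}",
            "-" * 47,
            f"{'peak stress [kPa]':<28}{self.sigma_peak_kPa:>19.4g}",
            f"{'equilibrium stress [kPa]':<28}{self.sigma_eq_kPa:>19.4g}",
            f"{'continuity residual [kPa]':<28}{self.continuity_residual_kPa:>19.2g}",
        ]
        return "\n".join(lines)


class PiecewiseRelaxationModel:
    """Constrained piecewise-exponential model of a stress-relaxation hold.

    The three constraints (peak match, equilibrium match, branch continuity)
    are eliminated by reparameterisation, leaving free parameters
    ``(A1, tau1, tau2)``: ``B1 = sigma_peak - A1``; given ``tau2``, ``A2`` and
    ``B2`` are the unique solution of branch continuity at ``t_split``
    together with the model's mean over the final equilibrium window equalling
    the measured ``sigma_eq``.  Bounded least squares minimises the RMSE, with
    multi-start over log-spaced time-constant initialisations.

    Parameters
    ----------
    curve : RelaxationCurve
        Hold-phase record, t = 0 at the end of the ramp.
    t_split_s : float
        Fast/slow branch split (100 s by default).
    eq_window_s : float
        Window at the end of the hold defining the equilibrium stress.
    """

    def __init__(self, curve: RelaxationCurve, t_split_s: float = 100.0,
                 eq_window_s: float = 100.0):
        if curve.duration_s <= t_split_s:
            raise ValueError(
                f"hold duration ({curve.duration_s:.1f} s) must exceed "
                f"t_split ({t_split_s} s)"
            )
        n_fast = int(np.sum(curve.time_s < t_split_s))
        n_slow = curve.time_s.size - n_fast
        if min(n_fast, n_slow) < 10:
            raise ValueError("need at least 10 samples per branch")
        self.curve = curve
        self.t_split_s = float(t_split_s)
        self.eq_window_s = float(eq_window_s)
        mod = extract_moduli(curve, eq_window_s)
        self.sigma_peak = mod.sigma_peak_kPa
        self.sigma_eq = mod.sigma_eq_kPa
        t_end = curve.time_s[-1]
        self._t_win = curve.time_s[curve.time_s >= t_end - eq_window_s]

    # -- constraint elimination -------------------------------------------
    def _slow_branch(self, sigma_split: float, tau2: float) -> tuple[float, float]:
        """(A2, B2) from continuity at t_split and the equilibrium-window mean."""
        e_split = math.exp(-self.t_split_s / tau2)
        w_eq = float(np.mean(np.exp(-self._t_win / tau2)))
        denom = e_split - w_eq
        if abs(denom) < 1e-300:
            return 0.0, self.sigma_eq
        A2 = (sigma_split - self.sigma_eq) / denom
        B2 = sigma_split - A2 * e_split
        return A2, B2

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        A1, tau1, tau2 = theta
        B1 = self.sigma_peak - A1
        t = self.curve.time_s
        sigma_split = A1 * math.exp(-self.t_split_s / tau1) + B1
        A2, B2 = self._slow_branch(sigma_split, tau2)
        fast = A1 * np.exp(-t / tau1) + B1
        slow = A2 * np.exp(-t / tau2) + B2
        return np.where(t < self.t_split_s, fast, slow)

    def fit(self, n_starts: int = 5) -> PiecewiseRelaxationResults:
        """Fit by bounded least squares with multi-start initialisation."""
        y = self.curve.stress_kPa
        amp0 = max(self.sigma_peak - self.sigma_eq, 1e-12)
        hold = self.curve.duration_s
        lo = [0.0, 1e-3, 1e-3]
        hi = [10.0 * max(self.sigma_peak, 1e-12), 10.0 * hold, 100.0 * hold]

        tau1_grid = np.geomspace(1.0, self.t_split_s, n_starts)
        best = None
        for tau1_0 in tau1_grid:
            x0 = np.clip([amp0, tau1_0, 8.0 * tau1_0], lo, hi)
            try:
                sol = least_squares(
                    lambda th: self._predict(th) - y,
                    x0=x0, bounds=(lo, hi), method="trf", xtol=1e-14,
                    ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitConvergenceError("all multi-start fits failed", best=None)

        A1, tau1, tau2 = best.x
        B1 = self.sigma_peak - A1
        sigma_split = A1 * math.exp(-self.t_split_s / tau1) + B1
        A2, B2 = self._slow_branch(sigma_split, tau2)
        resid = self._predict(best.x) - y
        rmse = float(np.sqrt(np.mean(resid**2)))
        cont = abs(
            (A1 * math.exp(-self.t_split_s / tau1) + B1)
            - (A2 * math.exp(-self.t_split_s / tau2) + B2)
        )
        res = PiecewiseRelaxationResults(
            A1_kPa=float(A1), tau1_s=float(tau1), B1_kPa=float(B1),
            A2_kPa=float(A2), tau2_s=float(tau2), B2_kPa=float(B2),
            t_split_s=self.t_split_s, rmse_kPa=rmse,
            sigma_peak_kPa=self.sigma_peak, sigma_eq_kPa=self.sigma_eq,
            eq_window_s=self.eq_window_s, n_obs=y.size,
            continuity_residual_kPa=float(cont),
            peak_residual_kPa=float(abs(A1 + B1 - self.sigma_peak)),
        )
        if not best.success:
            raise FitConvergenceError(
                f"least squares did not converge: {best.message}", best=res
            )
        return res


def fit_piecewise(curve: RelaxationCurve, t_split_s: float = 100.0,
                  eq_window_s: float = 100.0) -> PiecewiseRelaxationResults:
    """Functional wrapper around :class:`PiecewiseRelaxationModel`."""
    return PiecewiseRelaxationModel(curve, t_split_s, eq_window_s).fit()


def compare_relaxation_rates(fits_by_group: dict[str, list[PiecewiseRelaxationResults]]):
    """Summarise tau1/tau2 per group and test for group differences.

    Returns a dict with per-group means/SDs of both time constants and, for
    each constant, a group comparison (ANOVA + Tukey) delegated to
    :func:`osteounit.allometry.group_compare`.
    """
    from . import allometry

    for name, fits in fits_by_group.items():
        if len(fits) < 2:
            raise ValueError(f"group {name!r} needs at least 2 fits")
    summary = {
        name: {
            "n": len(fits),
            "tau1_mean_s": float(np.mean([f.tau1_s for f in fits])),
            "tau1_sd_s": float(np.std([f.tau1_s for f in fits], ddof=1)),
            "tau2_mean_s": float(np.mean([f.tau2_s for f in fits])),
            "tau2_sd_s": float(np.std([f.tau2_s for f in fits], ddof=1)),
        }
        for name, fits in fits_by_group.items()
    }
    labels = [g for g, fits in fits_by_group.items() for _ in fits]
    tau1 = [f.tau1_s for fits in fits_by_group.values() for f in fits]
    tau2 = [f.tau2_s for fits in fits_by_group.values() for f in fits]
    comparisons = {
        "tau1": allometry.group_compare(tau1, labels, design="tukey"),
        "tau2": allometry.group_compare(tau2, labels, design="tukey"),
    }
    return {"groups": summary, "comparisons": comparisons}
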