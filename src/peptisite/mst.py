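"""Microscale-thermophoresis (MST) trace evaluation and one-site isotherm
fitting.

The temperature-jump readout is the ratio of the mean fluorescence in the
window 0.5-1.5 s after the IR laser is switched on to the mean over the
last second before it; ΔF_norm of a capillary is that ratio minus the
ligand-free baseline's.

The binding model is the one-binding-site isotherm *with ligand depletion*:
at a labelled-protein concentration P comparable to K_d (here P = 25 nM
against K_d of order 100 nM) the free-ligand approximation is biased, so
the bound fraction is the root of the quadratic mass balance

    fb(c) = [(P + c + K_d) - sqrt((P + c + K_d)^2 - 4 P c)] / (2 P)

which tends to the familiar hyperbola c/(c + K_d) as P -> 0. The pure
hyperbola remains available behind a flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass(frozen=True)
class MSTTrace:
    """One capillary: fluorescence vs time with the laser-on instant."""

    times: np.ndarray            # s, strictly increasing
    fluorescence: np.ndarray     # arbitrary units, > 0
    laser_on_time: float         # s
    ligand_conc: float           # nM

    def __post_init__(self):
        times = np.asarray(self.times, float)
        fluo = np.asarray(self.fluorescence, float)
        if times.ndim != 1 or times.shape != fluo.shape:
            raise ValueError("times and fluorescence must be equal-length 1-D")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(fluo <= 0):
            raise ValueError("fluorescence must be > 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fluorescence", fluo)


@dataclass
class Isotherm:
    """(concentration, ΔF_norm, replicate) points at fixed protein conc."""

    points: pd.DataFrame         # conc_nM, delta_fnorm, replicate
    protein_conc: float          # nM

    def __post_init__(self):
        required = {"conc_nM", "delta_fnorm", "replicate"}
        if not required <= set(self.points.columns):
            raise ValueError(f"isotherm needs columns {sorted(required)}")
        if (self.points.conc_nM < 0).any():
            raise ValueError("concentrations must be >= 0")


@dataclass
class FitResult:
    kd: float                    # nM
    kd_se: float                 # nM
    amplitude: float
    amplitude_se: float
    offset: float
    converged: bool
    no_binding_flag: bool
    model: str = "depletion"


def _fnorm(trace: MSTTrace) -> float:
    t, f, on = trace.times, trace.fluorescence, trace.laser_on_time
    hot = (t > on + 0.5) & (t <= on + 1.5)
    cold = (t >= on - 1.0) & (t <= on)
    if not hot.any() or not cold.any():
        raise ValueError(
            "trace does not cover the evaluation windows "
            "[laser_on - 1 s, laser_on] and (laser_on + 0.5 s, laser_on + 1.5 s]")
    return float(f[hot].mean() / f[cold].mean())


def delta_fnorm_from_trace(trace: MSTTrace, baseline_trace: MSTTrace) -> float:
    """Temperature-jump ΔF_norm of a capillary against the c = 0 baseline."""
    return _fnorm(trace) - _fnorm(baseline_trace)


def fraction_bound(conc, kd: float, protein_conc: float):
    """Bound fraction of the labelled protein under the depletion model.

    Vectorised over ``conc``. Below a degenerate protein concentration of
    1e-6 nM the hyperbolic limit c/(c + K_d) is used directly.
    """
    conc = np.asarray(conc, dtype=float)
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if protein_conc < 0 or np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    if protein_conc < 1e-6:
        out = conc / (conc + kd)
    else:
        p = protein_conc
        s = p + conc + kd
        disc = np.maximum(s * s - 4.0 * p * conc, 0.0)
        out = (s - np.sqrt(disc)) / (2.0 * p)
    return out if out.ndim else float(out)


def fit_isotherm(iso: Isotherm, model: str = "depletion") -> FitResult:
    """Nonlinear least-squares fit of ΔF_norm(c) = offset + amplitude * fb(c).

    K_d is fitted on a log scale with a multistart over a decade-spaced grid
    between the smallest and largest non-zero concentrations; the standard
    errors come from the residual-covariance Jacobian approximation. The
    ``no_binding_flag`` is set when the amplitude is indistinguishable from
    zero (|amplitude| < 2 SE) — the behaviour of the denatured negative
    control.
    """
    if model not in ("depletion", "hyperbolic"):
        raise ValueError("model must be 'depletion' or 'hyperbolic'")
    df = iso.points
    conc = df.conc_nM.to_numpy(float)
    y = df.delta_fnorm.to_numpy(float)
    if np.unique(conc).size < 5:
        raise ValueError("isotherm needs >= 5 distinct concentrations")
    p_fixed = iso.protein_conc if model == "depletion" else 0.0

    def fb(c, kd):
        return fraction_bound(c, kd, p_fixed)

    def residuals(theta):
        log_kd, amplitude, offset = theta
        return offset + amplitude * fb(conc, np.exp(log_kd)) - y

    nonzero = conc[conc > 0]
    lo, hi = nonzero.min(), nonzero.max()
    kd_grid = 10.0 ** np.arange(np.floor(np.log10(lo)),
                                np.ceil(np.log10(hi)) + 1)
    y_top = y[conc >= hi].mean()
    y_bot = y[conc <= lo].mean()
    best = None
    for kd0 in kd_grid:
        theta0 = np.array([np.log(kd0), y_top - y_bot, y_bot])
        try:
            res = least_squares(residuals, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        return FitResult(kd=float("nan"), kd_se=float("nan"), amplitude=0.0,
                         amplitude_se=float("nan"), offset=float(np.mean(y)),
                         converged=False, no_binding_flag=True, model=model)

    log_kd, amplitude, offset = best.x
    kd = float(np.exp(log_kd))
    dofree = max(conc.size - 3, 1)
    s2 = 2.0 * best.cost / dofree
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se_logkd, se_amp = np.sqrt(np.abs(np.diag(cov)))[:2]
    except np.linalg.LinAlgError:
        se_logkd, se_amp = float("inf"), float("inf")
    kd_se = kd * float(se_logkd)        # delta method on the log scale
    no_binding = bool(abs(amplitude) < 2.0 * se_amp)
    return FitResult(kd=kd, kd_se=kd_se, amplitude=float(amplitude),
                     amplitude_se=float(se_amp), offset=float(offset),
                     converged=True, no_binding_flag=no_binding, model=model)


def fit_replicates(iso: Isotherm, model: str = "depletion"
                   ) -> tuple[list[FitResult], float, float]:
    """Per-replicate fits; returns (fits, mean K_d, sd K_d) to mirror
    reporting binding constants as mean ± sd over independent replicates."""
    fits = []
    for rep, sub in iso.points.groupby("replicate"):
        fits.append(fit_isotherm(Isotherm(points=sub.reset_index(drop=True),
                                          protein_conc=iso.protein_conc),
                                 model=model))
    kds = np.array([f.kd for f in fits if f.converged and not f.no_binding_flag])
    if kds.size == 0:
        return fits, float("nan"), float("nan")
    return fits, float(kds.mean()), float(kds.std(ddof=1) if kds.size > 1 else 0.0)
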