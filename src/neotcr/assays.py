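"""Functional-assay quantification.

Covers the downstream readouts used to characterize candidate TCRs:

* impedance-based specific cytolysis from normalized Cell Indexes,
* structural avidity: one-phase exponential decay fit of multimer
  dissociation traces (k_off and t1/2 = ln2 / k_off),
* functional avidity: four-parameter logistic (4PL) dose-response fit
  and EC50,
* cytokine panel log2 ratios with an additive floor,
* theoretical monoisotopic m/z of unmodified peptides for MS inclusion
  lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

# Monoisotopic residue masses (Da), standard unmodified amino acids.
RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}
WATER_MONO = 18.0105646863
PROTON_MASS = 1.007276466622


class FitError(RuntimeError):
    """Nonlinear fit failed or produced an inadmissible parameter."""


# ---------------------------------------------------------------------------
# cytolysis


@dataclass
class CytolysisMeasurement:
    """Normalized Cell Index of a TCR condition vs the non-transduced control."""

    ci_x: float
    ci_non_transduced: float
    timepoint_h: float | None = None


@dataclass
class CytolysisResult:
    percent: float
    outgrowth: bool  # negative cytolysis: target outgrew the control


def specific_cytolysis(m: CytolysisMeasurement) -> CytolysisResult:
    """Specific cytolysis [%] = 100 - (CI_x / CI_non-transduced * 100).

    Negative values (target outgrowth in the TCR condition) are returned
    as-is with ``outgrowth=True``.
    """
    if m.ci_non_transduced <= 0:
        raise ValueError("CI of the non-transduced control must be positive")
    if m.ci_x < 0:
        raise ValueError("CI_x must be nonnegative")
    pct = 100.0 * (1.0 - m.ci_x / m.ci_non_transduced)
    return CytolysisResult(percent=pct, outgrowth=pct < 0)


# ---------------------------------------------------------------------------
# k_off


@dataclass
class DecayTrace:
    """Multimer-dissociation time course (time in seconds, signal ratio)."""

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size < 5:
            raise ValueError("decay trace needs at least 5 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.signal < 0):
            raise ValueError("signal must be nonnegative")


@dataclass
class DecayFit:
    """One-phase exponential decay fit: signal(t) = plateau + amplitude*exp(-k t)."""

    k: float           # per second
    plateau: float
    amplitude: float
    rss: float

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.k


def fit_koff(trace: DecayTrace, with_plateau: bool = True) -> DecayFit:
    """Nonlinear least-squares one-phase decay fit of a dissociation trace.

    Initialization: plateau = min(signal), amplitude = max - min, and k
    from a log-linear regression of the plateau-subtracted signal.
    """
    t, y = trace.time, trace.signal
    if np.ptp(y) == 0:
        raise FitError("signal is constant; no decay to fit")
    p_init = float(y.min())
    a_init = float(y.max() - y.min())
    resid = y - p_init
    pos = resid > a_init * 1e-6
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        k_init = max(-slope, 1e-6)
    else:
        k_init = 1.0 / max(t[-1] - t[0], 1e-9)

    if with_plateau:
        def model(t, plateau, amplitude, k):
            return plateau + amplitude * np.exp(-k * t)
        p0 = [p_init, a_init, k_init]
        bounds = ([0.0, 1e-12, 1e-12], [np.inf, np.inf, np.inf])
    else:
        def model(t, amplitude, k):
            return amplitude * np.exp(-k * t)
        p0 = [a_init + p_init, k_init]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000,
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except RuntimeError as err:
        raise FitError(f"one-phase decay fit did not converge: {err}") from err
    if with_plateau:
        plateau, amplitude, k = popt
    else:
        (amplitude, k), plateau = popt, 0.0
    if k <= 0:
        raise FitError(f"fitted rate k={k!r} is not positive")
    rss = float(np.sum((y - model(t, *popt)) ** 2))
    return DecayFit(k=float(k), plateau=float(plateau),
                    amplitude=float(amplitude), rss=rss)


# ---------------------------------------------------------------------------
# EC50


@dataclass
class DoseResponseCurve:
    """Dose-response readout: molar concentrations and responses."""

    concentrations: np.ndarray  # molar, > 0
    responses: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.unique(self.concentrations).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class FourPLFit:
    """Four-parameter logistic fit; EC50 in molar.

    Canonicalized so ``bottom <= top`` (hill > 0 means response rises
    with concentration).  ``degenerate`` flags a flat curve where no EC50
    exists; ``extrapolated`` flags an EC50 outside the tested range.
    """

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    degenerate: bool = False
    extrapolated: bool = False


def _four_pl(logc, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def fit_ec50(curve: DoseResponseCurve) -> FourPLFit:
    """4PL fit on log10 concentration; flat curves return a degenerate flag."""
    logc = np.log10(curve.concentrations)
    y = curve.responses
    span = float(np.ptp(y))
    if span == 0 or span < 1e-9 * max(1.0, abs(float(np.mean(y)))):
        return FourPLFit(bottom=float(y.mean()), top=float(y.mean()),
                         ec50=float("nan"), hill=float("nan"),
                         rss=float(np.sum((y - y.mean()) ** 2)),
                         degenerate=True)
    p0 = [float(y.min()), float(y.max()), float(np.median(logc)), 1.0]
    try:
        popt, _ = curve_fit(_four_pl, logc, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"4PL fit did not converge: {err}") from err
    bottom, top, log_ec50, hill = popt
    if hill < 0:  # equivalent parameterization with roles swapped
        bottom, top, hill = top, bottom, -hill
    if bottom > top:
        bottom, top = top, bottom
    ec50 = 10.0 ** log_ec50
    rss = float(np.sum((y - _four_pl(logc, *popt)) ** 2))
    extrapolated = not (
        curve.concentrations.min() <= ec50 <= curve.concentrations.max())
    return FourPLFit(bottom=float(bottom), top=float(top), ec50=float(ec50),
                     hill=float(hill), rss=rss, extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# cytokines


def cytokine_log2_ratio(
    panel_num: dict, panel_den: dict, floor: float = 1.0,
) -> dict:
    """Per-analyte log2((num + floor) / (den + floor)) over shared analytes.

    ``floor`` is an additive concentration floor (pg/mL), typically the
    assay's lower detection limit, so zero readings stay finite.
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    shared = [a for a in panel_num if a in panel_den]
    if not shared:
        raise ValueError("panels share no analytes")
    out = {}
    for analyte in shared:
        num, den = panel_num[analyte], panel_den[analyte]
        if num < 0 or den < 0:
            raise ValueError(f"negative concentration for {analyte!r}")
        out[analyte] = math.log2((num + floor) / (den + floor))
    return out


# ---------------------------------------------------------------------------
# peptide m/z


@dataclass
class PeptideIon:
    sequence: str
    charge: int
    mz: float


def peptide_mz(sequence: str, charge: int) -> PeptideIon:
    """Theoretical monoisotopic m/z of an unmodified peptide ion.

    mz = (sum of residue masses + water + charge * proton) / charge,
    reported to 4 decimal places.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    total = WATER_MONO
    for pos, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue {aa!r} at position {pos}") from None
    mz = (total + charge * PROTON_MASS) / charge
    return PeptideIon(sequence=sequence, charge=charge, mz=round(mz, 4))
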