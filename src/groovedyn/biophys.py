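"""Binding, kinetics, stability and 19F NMR analysis.

Implements the quantitative layer over surface plasmon resonance (1:1
steady-state isotherm, single-exponential dissociation, kon from koff/KD),
differential scanning fluorimetry (bi-Gaussian fit of the melt derivative),
fluorescence-anisotropy dissociation (single or biphasic), the pKa-shift
electrostatic destabilization formula, Lorentzian line-shape deconvolution
of 1D spectra, and chemical-exchange saturation-transfer (CEST) exchange
graphs.

The pKa energetics follow

    ddG0 = -2.303 R T (pKa_bound - pKa_free),  R = 1.987 cal/K/mol

reported in kcal/mol with positive values meaning destabilization of the
bound state (pKa shifted down on binding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls
from scipy.signal import find_peaks

__all__ = [
    "R_CAL",
    "ddg_from_pka",
    "kon_from_koff_kd",
    "KineticsResult",
    "fit_dissociation",
    "fit_steady_state",
    "fit_melt_bigaussian",
    "Spectrum1D",
    "LorentzianComponent",
    "lorentzian",
    "fit_lorentzian_mixture",
    "CESTResult",
    "cest_summary",
]

#: gas constant in cal / (K mol)
R_CAL = 1.987


# ---------------------------------------------------------------------------
# Closed-form energetics / kinetics
# ---------------------------------------------------------------------------

def ddg_from_pka(pka_bound: float, pka_free: float,
                 T: float = 298.15) -> float:
    """Electrostatic (de)stabilization from a binding-induced pKa shift.

    Returns -2.303 R T (pKa_bound - pKa_free) in kcal/mol: positive
    (destabilizing) when burial suppresses protonation, i.e. the bound pKa
    falls below the free pKa.
    """
    ddg_cal = -2.303 * R_CAL * T * (pka_bound - pka_free)
    return ddg_cal / 1000.0


def kon_from_koff_kd(koff: float, KD: float) -> float:
    """Association rate kon = koff / KD (s^-1 over M gives M^-1 s^-1)."""
    if KD <= 0:
        raise ZeroDivisionError("KD must be positive")
    return koff / KD


# ---------------------------------------------------------------------------
# Exponential dissociation
# ---------------------------------------------------------------------------

@dataclass
class KineticsResult:
    """Rates with amplitudes and standard errors from a kinetic fit."""

    koff: tuple  # one rate per phase, s^-1, fastest first
    amplitudes: tuple
    offset: float
    stderr: dict
    residual_norm: float
    KD: float | None = None
    kon: float | None = None
    warnings: list = field(default_factory=list)


def _mono(t, A, k, c):
    return A * np.exp(-k * t) + c


def _bi(t, A1, k1, A2, k2, c):
    return A1 * np.exp(-k1 * t) + A2 * np.exp(-k2 * t) + c


def fit_dissociation(time, signal, n_phases: int = 1) -> KineticsResult:
    """Least-squares fit of a single or biphasic exponential decay.

    Used for SPR dissociation phases and anisotropy dissociation curves.
    Requires >= 10 points spanning at least one nominal half-life. A signal
    that is not predominantly decaying is fitted anyway but flagged with a
    quality warning in the result.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(t) < 10:
        raise ValueError("need at least 10 points for a dissociation fit")
    warns = []
    drop = y[0] - y[-1]
    if drop <= 0 or np.mean(np.diff(y) > 0) > 0.6:
        warns.append("signal is not monotone-dominant decay; "
                     "fit quality suspect")
    span = t[-1] - t[0]
    k0 = np.log(2) / max(span / 2.0, 1e-12)
    amp0 = max(drop, abs(y).max(), 1e-12)
    if n_phases == 1:
        p0 = [amp0, k0, y[-1]]
        popt, pcov = curve_fit(_mono, t, y, p0=p0, maxfev=20000)
        fitted = _mono(t, *popt)
        rates = (abs(popt[1]),)
        amps = (popt[0],)
        offset = popt[2]
        names = ["amplitude", "koff", "offset"]
    elif n_phases == 2:
        p0 = [amp0 / 2, k0 * 5, amp0 / 2, k0 / 5, y[-1]]
        popt, pcov = curve_fit(_bi, t, y, p0=p0, maxfev=50000)
        fitted = _bi(t, *popt)
        order = np.argsort([-abs(popt[1]), -abs(popt[3])])
        pairs = [(popt[0], abs(popt[1])), (popt[2], abs(popt[3]))]
        pairs = [pairs[i] for i in order]
        amps = tuple(a for a, _ in pairs)
        rates = tuple(k for _, k in pairs)
        offset = popt[4]
        names = ["A1", "k1", "A2", "k2", "offset"]
    else:
        raise ValueError("n_phases must be 1 or 2")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return KineticsResult(
        koff=rates, amplitudes=amps, offset=float(offset),
        stderr=dict(zip(names, perr)),
        residual_norm=float(np.linalg.norm(y - fitted)),
        warnings=warns,
    )


def fit_steady_state(conc, response):
    """1:1 steady-state binding fit R = Rmax c / (KD + c).

    Returns ``(KD, Rmax, stderr_dict)``. Warns (without failing) when the
    top concentration is below KD/3, where KD becomes an extrapolation.
    """
    c = np.asarray(conc, dtype=float)
    r = np.asarray(response, dtype=float)
    if len(c) < 5:
        raise ValueError("need at least 5 concentrations")
    model = lambda c, KD, Rmax: Rmax * c / (KD + c)
    p0 = [np.median(c), r.max() * 1.5]
    popt, pcov = curve_fit(model, c, r, p0=p0, maxfev=20000,
                           bounds=([0, 0], [np.inf, np.inf]))
    KD, Rmax = popt
    if c.max() < KD / 3:
        warnings.warn("top concentration < KD/3: KD is an extrapolation",
                      stacklevel=2)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return float(KD), float(Rmax), {"KD": perr[0], "Rmax": perr[1]}


def fit_melt_bigaussian(temperature, derivative):
    """Bi-Gaussian fit of a thermal-melt first-derivative curve.

    Fits dRatio/dT as a sum of two Gaussians and returns
    ``(Tm1, Tm2, params)`` with Tm1 the center of the dominant (larger
    amplitude) transition. Single-transition data converge with a
    negligible second amplitude, flagged in ``params['single_transition']``.
    """
    T = np.asarray(temperature, dtype=float)
    y = np.asarray(derivative, dtype=float)
    if len(T) < 20:
        raise ValueError("need at least 20 points across the transition")
    model = lambda T, a1, m1, s1, a2, m2, s2: (
        a1 * np.exp(-0.5 * ((T - m1) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((T - m2) / s2) ** 2)
    )
    peak = T[np.argmax(y)]
    spanq = (T.max() - T.min()) / 4
    amax = max(y.max(), 1e-12)
    best = None
    for m2 in (peak - spanq, peak + spanq):
        p0 = [amax, peak, spanq / 2, amax / 3, m2, spanq / 2]
        try:
            popt, _ = curve_fit(model, T, y, p0=p0, maxfev=50000)
        except RuntimeError:
            continue
        res = float(np.linalg.norm(y - model(T, *popt)))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise RuntimeError("bi-Gaussian fit did not converge")
    popt, res = best
    (a1, m1, s1, a2, m2, s2) = popt
    if abs(a2) > abs(a1):
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    single = abs(a2) < 0.02 * abs(a1)
    params = {"amplitudes": (a1, a2), "centers": (m1, m2),
              "widths": (abs(s1), abs(s2)), "residual_norm": res,
              "single_transition": bool(single)}
    return float(m1), float(m2), params


# ---------------------------------------------------------------------------
# Lorentzian deconvolution
# ---------------------------------------------------------------------------

@dataclass
class Spectrum1D:
    """1D spectrum on a strictly monotone ppm axis."""

    axis: np.ndarray  # ppm, ascending or descending
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        d = np.diff(self.axis)
        if len(self.axis) != len(self.intensity) or not (
                np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone and match "
                             "intensity length")

    def ascending(self) -> "Spectrum1D":
        if self.axis[0] < self.axis[-1]:
            return self
        return Spectrum1D(self.axis[::-1].copy(),
                          self.intensity[::-1].copy(), dict(self.metadata))


@dataclass
class LorentzianComponent:
    center: float  # ppm
    fwhm: float  # ppm
    area_fraction: float  # of total mixture area
    area: float = 0.0  # absolute, same units as intensity * ppm


def lorentzian(x, center, fwhm, area):
    """Area-normalized Lorentzian line shape."""
    hwhm = fwhm / 2.0
    return (area / np.pi) * hwhm / ((x - center) ** 2 + hwhm ** 2)


def _mixture(x, *params):
    # params: [c1, w1, a1, c2, w2, a2, ...] (+ baseline b0, b1 appended)
    n = (len(params)) // 3
    y = np.zeros_like(x)
    for i in range(n):
        c, w, a = params[3 * i:3 * i + 3]
        y = y + lorentzian(x, c, abs(w), a)
    return y


def _mixture_baseline(x, *params):
    b0, b1 = params[-2:]
    return _mixture(x, *params[:-2]) + b0 + b1 * (x - x.mean())


def fit_lorentzian_mixture(spec: Spectrum1D, n_components: int,
                           baseline: bool = False, n_starts: int = 16,
                           seed: int = 0):
    """Multi-start least-squares deconvolution into Lorentzian components.

    Initializations are seeded from peak picking on the (lightly smoothed)
    spectrum, with randomized perturbations for the remaining starts;
    restarts stop early once a fit reaches the apparent noise floor.
    Components are returned sorted by center with area fractions normalized
    to 1. Raises RuntimeError (reporting the best residual) if no start
    converges.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    sp = spec.ascending()
    x, y = sp.axis, sp.intensity
    rng = np.random.default_rng(seed)
    span = x[-1] - x[0]
    # peak picking for initial centers
    kernel = max(len(y) // 200, 1)
    smooth = np.convolve(y, np.ones(kernel) / kernel, mode="same")
    # prominence-ranked picking keeps noise wiggles on a broad line from
    # shadowing genuinely separate peaks
    pk, props = find_peaks(smooth, prominence=0.02 * smooth.max(),
                           distance=max(len(y) // 20, 1))
    order = np.argsort(props["prominences"])[::-1]
    centers0 = list(x[pk[order][:n_components]])
    while len(centers0) < n_components:
        centers0.append(x[0] + rng.uniform(0.2, 0.8) * span)
    w0 = span / (8.0 * n_components)
    total_area = float(np.trapezoid(np.abs(y), x))
    noise = float(np.std(np.diff(y)) / np.sqrt(2)) + 1e-30
    target = 1.5 * noise * np.sqrt(len(y))
    model = _mixture_baseline if baseline else _mixture
    best_popt, best_res = None, np.inf
    for start in range(n_starts):
        p0 = []
        for c in centers0:
            jitter = 0 if start == 0 else rng.normal(0, 0.05 * span)
            width = w0 * (1 if start == 0 else rng.uniform(0.3, 3.0))
            p0 += [c + jitter, width, total_area / n_components]
        if baseline:
            p0 += [0.0, 0.0]
        try:
            popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        res = float(np.linalg.norm(y - model(x, *popt)))
        if res < best_res:
            best_res, best_popt = res, popt
        if best_res <= target:
            break
    if best_popt is None:
        raise RuntimeError(
            f"Lorentzian mixture fit failed to converge in {n_starts} "
            f"starts (best residual {best_res})"
        )
    comps = []
    for i in range(n_components):
        c, w, a = best_popt[3 * i:3 * i + 3]
        comps.append([float(c), abs(float(w)), float(a)])
    total = sum(abs(a) for _, _, a in comps)
    comps.sort(key=lambda t: t[0])
    return [
        LorentzianComponent(center=c, fwhm=w,
                            area_fraction=abs(a) / total, area=a)
        for c, w, a in comps
    ]


# ---------------------------------------------------------------------------
# CEST
# ---------------------------------------------------------------------------

@dataclass
class CESTResult:
    """Saturation-transfer matrix and derived exchange graph.

    ``reduction[i, j]`` is the fractional intensity loss of observed peak j
    when peak i is irradiated (diagonal ~ 1 for effective self-saturation).
    ``edges`` holds (i, j) pairs, i != j, with reduction >= threshold;
    ``isolated`` lists peaks with no incident edge.
    """

    peaks: list  # LorentzianComponent, sorted by center
    reduction: np.ndarray
    edges: list
    isolated: list
    threshold: float


def _component_amplitudes(spec: Spectrum1D, peaks) -> np.ndarray:
    """Non-negative least-squares amplitudes of fixed component shapes."""
    sp = spec.ascending()
    basis = np.stack([
        lorentzian(sp.axis, p.center, p.fwhm, 1.0) for p in peaks
    ], axis=1)
    amps, _ = nnls(basis, sp.intensity)
    return amps


def cest_summary(spectra: dict, reference: Spectrum1D, peaks,
                 threshold: float = 0.25, guard: float = 0.5) -> CESTResult:
    """Summarize a saturation-transfer series as an exchange graph.

    ``spectra`` maps irradiation ppm -> spectrum acquired with saturation
    at that offset; ``reference`` is the unsaturated control and ``peaks``
    the fitted components of the reference. Peak intensities are estimated
    by linear re-fitting of the fixed reference line shapes, so overlapping
    peaks are handled consistently across the series. An exchange edge is
    drawn when irradiating one peak reduces another by at least
    ``threshold`` (fractional). Irradiation offsets closer than ``guard``
    ppm to a peak other than the intended target trigger a contamination
    warning since direct saturation vanishes outside +/- 0.5 ppm.
    """
    peaks = sorted(peaks, key=lambda p: p.center)
    ref_amp = _component_amplitudes(reference, peaks)
    if np.any(ref_amp <= 0):
        raise ValueError("reference intensities must be positive for all "
                         "peaks")
    centers = np.array([p.center for p in peaks])
    n = len(peaks)
    reduction = np.full((n, n), np.nan)
    for offset, spec in spectra.items():
        dist = np.abs(centers - offset)
        target = int(np.argmin(dist))
        near = np.nonzero(dist <= guard)[0]
        if any(i != target for i in near):
            warnings.warn(
                f"irradiation at {offset} ppm lies within {guard} ppm of a "
                "non-target peak: direct-saturation contamination likely",
                stacklevel=2,
            )
        amp = _component_amplitudes(spec, peaks)
        reduction[target] = np.clip(1.0 - amp / ref_amp, 0.0, 1.0)
    edges = [
        (i, j)
        for i in range(n) for j in range(n)
        if i != j and np.isfinite(reduction[i, j])
        and reduction[i, j] >= threshold
    ]
    connected = {i for e in edges for i in e}
    isolated = [i for i in range(n) if i not in connected]
    return CESTResult(peaks=peaks, reduction=reduction, edges=edges,
                      isolated=isolated, threshold=threshold)
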