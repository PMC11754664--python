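"""Time-resolved fluorescence: reconvolution fitting, anisotropy, lifetimes.

Photon-counting decays are modelled as a two-exponential,

    f(t) = A1*exp(-t/tau1) + A2*exp(-t/tau2),

convolved with the measured instrument response function (IRF), with Poisson
weighting.  Several waveforms can be fit globally with lifetimes linked
across them while amplitudes float (the standard linked-reconvolution
workflow).  Steady-state anisotropy uses the polarizer g-factor,

    FA = (Ivv - g*Ivh) / (Ivv + 2*g*Ivh),

and the per-decay summary statistics are the intensity-weighted lifetime
tau = (A1*tau1^2 + A2*tau2^2)/(A1*tau1 + A2*tau2) and the integral
intensity A1*tau1 + A2*tau2.  A titration of either observable against
titrant concentration is reduced to a dissociation constant with the same
Hill machinery used for MST curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding import BindingFitResult, TitrationSeries, fit_binding

__all__ = [
    "DecayWaveform",
    "BiexpFit",
    "PolarizedMeasurement",
    "biexp",
    "convolve_model",
    "fit_decays_global",
    "anisotropy",
    "summarize_lifetime",
    "titration_kd_from_observable",
    "flt_titration_kd",
]


@dataclass(frozen=True)
class DecayWaveform:
    """A photon-counting decay and its IRF on a shared uniform time grid."""

    t_ns: np.ndarray
    counts: np.ndarray
    irf: np.ndarray
    polarization: str = "magic"  # vv | vh | magic
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t_ns, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        r = np.asarray(self.irf, dtype=float)
        for name, arr in (("t_ns", t), ("counts", c), ("irf", r)):
            object.__setattr__(self, name, arr)
        dt = np.diff(t)
        if t.size < 8 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must be uniform with >= 8 samples")
        if c.size != t.size or r.size != t.size:
            raise ValueError("counts/IRF must share the time grid")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        if not np.any(r > 0):
            raise ValueError("IRF is all zero")

    @property
    def dt(self) -> float:
        return float(self.t_ns[1] - self.t_ns[0])


@dataclass(frozen=True)
class BiexpFit:
    """Fitted biexponential parameters (canonical order tau1 < tau2)."""

    a1: float
    a2: float
    tau1_ns: float
    tau2_ns: float
    shift_ns: float = 0.0
    baseline: float = 0.0
    a1_se: float = np.nan
    a2_se: float = np.nan
    tau1_se: float = np.nan
    tau2_se: float = np.nan
    red_chisq: float = np.nan
    flags: tuple[str, ...] = ()

    @property
    def tau_intensity_weighted(self) -> float:
        return summarize_lifetime(self)[0]

    @property
    def integral_intensity(self) -> float:
        return summarize_lifetime(self)[1]


@dataclass(frozen=True)
class PolarizedMeasurement:
    i_vv: float
    i_vh: float
    g_factor: float = 1.03

    def __post_init__(self):
        if self.i_vv < 0 or self.i_vh < 0:
            raise ValueError("intensities must be >= 0")
        if self.g_factor <= 0:
            raise ValueError("g-factor must be > 0")


def biexp(t, a1, a2, tau1, tau2):
    t = np.asarray(t, dtype=float)
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _shift_irf(irf, shift_bins):
    """Sub-bin IRF shift by linear interpolation (zero-padded)."""
    if shift_bins == 0.0:
        return irf
    n = irf.size
    idx = np.arange(n) - shift_bins
    return np.interp(idx, np.arange(n), irf, left=0.0, right=0.0)


def convolve_model(t, a1, a2, tau1, tau2, irf, baseline=0.0, shift_ns=0.0):
    """Causal discrete convolution of a biexponential with a normalized IRF.

    The IRF is normalized to unit sum so that with a delta IRF the model
    equals the biexponential samples exactly; ``shift_ns`` applies a sub-bin
    time shift to the IRF by linear interpolation.
    """
    t = np.asarray(t, dtype=float)
    irf = np.asarray(irf, dtype=float)
    if not np.any(irf > 0):
        raise ValueError("IRF is all zero")
    dt = t[1] - t[0]
    kernel = _shift_irf(irf, shift_ns / dt)
    ksum = kernel.sum()
    if ksum <= 0:
        raise ValueError("shifted IRF has no support on the grid")
    kernel = kernel / ksum
    decay = biexp(t - t[0], a1, a2, tau1, tau2)
    return np.convolve(kernel, decay)[: t.size] + baseline


def fit_decays_global(
    waveforms: list[DecayWaveform],
    link_lifetimes: bool = True,
    tau_init: tuple[float, float] | None = None,
    fit_shift: bool = True,
    fit_baseline: bool = False,
    single_exp_fallback: bool = True,
) -> list[BiexpFit]:
    """Global reconvolution fit of one or more decays.

    Poisson weights (1/sqrt(counts), counts floored at 1).  With
    ``link_lifetimes`` the two lifetimes are shared across all waveforms
    while amplitudes (and optional baselines) float per waveform; the IRF
    time shift is a shared nuisance parameter bounded to +/- 1 bin.  Returns
    one :class:`BiexpFit` per waveform with lifetimes in canonical order.
    """
    if not waveforms:
        raise ValueError("need at least one waveform")
    t0 = waveforms[0].t_ns
    for w in waveforms[1:]:
        if w.t_ns.size != t0.size or not np.allclose(w.t_ns, t0):
            raise ValueError("waveforms in a linked set must share the grid")
    dt = waveforms[0].dt

    if tau_init is None:
        # moment-based guess from the first waveform, relative to the IRF peak
        w = waveforms[0]
        t_irf = w.t_ns[int(np.argmax(w.irf))]
        tail = w.counts.sum()
        tcm = float(np.sum((w.t_ns - t_irf) * w.counts) / tail) if tail > 0 else 1.0
        tcm = max(tcm, 2 * dt)
        tau_init = (0.5 * tcm, 2.0 * tcm)

    params = lmfit.Parameters()
    tmax = float(t0[-1] - t0[0])

    def add_taus(tag):
        params.add(f"tau1{tag}", value=tau_init[0], min=dt / 10, max=tmax)
        params.add(f"tau2{tag}", value=tau_init[1], min=dt / 10, max=5 * tmax)

    if link_lifetimes:
        add_taus("")
    params.add("shift", value=0.0, min=-dt, max=dt, vary=fit_shift)

    for i, w in enumerate(waveforms):
        peak = max(w.counts.max(), 1.0)
        params.add(f"a1_{i}", value=0.6 * peak, min=0.0)
        params.add(f"a2_{i}", value=0.4 * peak, min=0.0)
        if not link_lifetimes:
            add_taus(f"_{i}")
        params.add(f"bl_{i}", value=0.0, vary=fit_baseline, min=0.0)

    weights = [1.0 / np.sqrt(np.maximum(w.counts, 1.0)) for w in waveforms]

    def resid(p):
        out = []
        for i, w in enumerate(waveforms):
            tag = "" if link_lifetimes else f"_{i}"
            m = convolve_model(
                w.t_ns, p[f"a1_{i}"], p[f"a2_{i}"],
                p[f"tau1{tag}"], p[f"tau2{tag}"], w.irf,
                baseline=p[f"bl_{i}"], shift_ns=p["shift"] * 1.0,
            )
            out.append((m - w.counts) * weights[i])
        return np.concatenate(out)

    res = lmfit.minimize(resid, params, method="leastsq",
                         xtol=1e-11, ftol=1e-11, max_nfev=50000)
    if not res.success:
        raise RuntimeError(f"global decay fit did not converge: {res.message}")

    ndata = sum(w.counts.size for w in waveforms)
    red_chisq = float(res.chisqr / max(ndata - res.nvarys, 1))

    def _se(p, name):
        s = p[name].stderr
        return float(s) if s is not None else np.nan

    fits = []
    for i, w in enumerate(waveforms):
        tag = "" if link_lifetimes else f"_{i}"
        p = res.params
        a1, a2 = float(p[f"a1_{i}"].value), float(p[f"a2_{i}"].value)
        t1, t2 = float(p[f"tau1{tag}"].value), float(p[f"tau2{tag}"].value)
        se = {k: _se(p, k) for k in (f"a1_{i}", f"a2_{i}", f"tau1{tag}", f"tau2{tag}")}
        a1se, a2se = se[f"a1_{i}"], se[f"a2_{i}"]
        t1se, t2se = se[f"tau1{tag}"], se[f"tau2{tag}"]
        if t1 > t2:  # canonical order
            a1, a2, t1, t2 = a2, a1, t2, t1
            a1se, a2se, t1se, t2se = a2se, a1se, t2se, t1se
        flags = ()
        if single_exp_fallback and np.isfinite(a2se) and a2 - a2se < 0:
            flags = ("single-exponential",)
        fits.append(BiexpFit(
            a1=a1, a2=a2, tau1_ns=t1, tau2_ns=t2,
            shift_ns=float(p["shift"].value), baseline=float(p[f"bl_{i}"].value),
            a1_se=a1se, a2_se=a2se, tau1_se=t1se, tau2_se=t2se,
            red_chisq=red_chisq, flags=flags,
        ))
    return fits


def anisotropy(meas: PolarizedMeasurement) -> float:
    """Steady-state fluorescence anisotropy with g-factor correction."""
    den = meas.i_vv + 2.0 * meas.g_factor * meas.i_vh
    if den <= 0:
        raise ValueError("zero total intensity")
    return (meas.i_vv - meas.g_factor * meas.i_vh) / den


def summarize_lifetime(fit: BiexpFit) -> tuple[float, float]:
    """(intensity-weighted lifetime, integral intensity A1*tau1 + A2*tau2)."""
    integral = fit.a1 * fit.tau1_ns + fit.a2 * fit.tau2_ns
    if integral <= 0:
        raise ValueError("degenerate decay: A1*tau1 + A2*tau2 <= 0")
    tau_iw = (fit.a1 * fit.tau1_ns**2 + fit.a2 * fit.tau2_ns**2) / integral
    return tau_iw, integral


def titration_kd_from_observable(
    conc_nM, observable, sem=None, modes: int = 1, **fit_kw
) -> BindingFitResult:
    """Hill fit of a titration of FA or lifetime against concentration.

    obs(c) = obs_free + (obs_bound - obs_free) * Hill(c; KD, n); the free
    value maps to the Hill baseline and the bound-minus-free change to the
    amplitude.  Raises if the observable carries no signal change.
    """
    y = np.asarray(observable, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("no signal change across the titration")
    series = TitrationSeries(conc_nM=conc_nM, observable=y, sem=sem)
    return fit_binding(series, modes=modes, **fit_kw)


def flt_titration_kd(conc_nM, decay_sets: list[list[DecayWaveform]] | list[DecayWaveform],
                     **fit_kw) -> BindingFitResult:
    """End-to-end FLT titration: decays -> lifetimes -> Hill fit -> KD.

    ``decay_sets`` holds one waveform per titration point (or a list per
    point, in which case the first is used).  Lifetimes are linked across
    all points in a single global reconvolution fit, each point is reduced
    to its intensity-weighted lifetime, and the lifetime-vs-concentration
    series is fit with the Hill model.
    """
    waveforms = [w[0] if isinstance(w, (list, tuple)) else w for w in decay_sets]
    fits = fit_decays_global(waveforms, link_lifetimes=True)
    taus = [summarize_lifetime(f)[0] for f in fits]
    return titration_kd_from_observable(conc_nM, taus, **fit_kw)
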