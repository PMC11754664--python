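"""Circular-dichroism pH-folding analysis.

Raw ellipticity is converted to mean residue ellipticity (MRE,
deg cm^2 dmol^-1), reduced to a two-state folded fraction via the helix
signal at 222 nm, and the pH dependence of that fraction is fit to a
modified Henderson-Hasselbalch sigmoid with a free Hill slope:

    f_h(pH) = (f_basic + f_acid * 10**(n*(pKa - pH))) / (1 + 10**(n*(pKa - pH)))

so that f_acid is the low-pH plateau, f_basic the high-pH plateau, pKa the
inflection and n the slope there (number of protons in the transition).
An isodichroic point across the pH series supports the two-state reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "EllipticityRecord",
    "PhSeries",
    "PhTransitionFit",
    "compute_mre",
    "fraction_helix",
    "ph_model",
    "fit_ph_transition",
    "find_isodichroic",
]


@dataclass(frozen=True)
class EllipticityRecord:
    """One CD reading.

    wavelength_nm : 190-250 nm
    theta_mdeg    : measured ellipticity, millidegrees
    conc_M        : protein concentration, mol/L
    path_cm       : cuvette path length, cm
    mrm_g_mol     : mean residue molar mass (MW / residue count), g/mol
    n_residues    : number of amino-acid residues
    """

    wavelength_nm: float
    theta_mdeg: float
    conc_M: float
    path_cm: float
    mrm_g_mol: float
    n_residues: int

    def __post_init__(self):
        if not (190.0 <= self.wavelength_nm <= 250.0):
            raise ValueError("wavelength outside far-UV CD range 190-250 nm")
        if self.conc_M <= 0 or self.path_cm <= 0:
            raise ValueError("concentration and path length must be > 0")


@dataclass(frozen=True)
class PhSeries:
    ph: np.ndarray
    value: np.ndarray  # folded fraction or MRE222
    err: np.ndarray | None = None

    def __post_init__(self):
        p = np.asarray(self.ph, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "ph", p)
        object.__setattr__(self, "value", v)
        if self.err is not None:
            object.__setattr__(self, "err", np.asarray(self.err, dtype=float))
        if np.any(np.diff(p) <= 0):
            raise ValueError("pH values must be strictly increasing")


@dataclass(frozen=True)
class PhTransitionFit:
    f_acid: float
    f_basic: float
    pka: float
    hill_n: float
    f_acid_se: float
    f_basic_se: float
    pka_se: float
    hill_n_se: float
    rss: float

    def predict(self, ph):
        return ph_model(ph, self.f_acid, self.f_basic, self.pka, self.hill_n)


def compute_mre(record: EllipticityRecord, as_printed: bool = False) -> float:
    """Mean residue ellipticity in deg cm^2 dmol^-1.

    Standard path-length form: MRE = theta_mdeg / (10 * l_cm * C_M * N_res).
    ``as_printed=True`` evaluates M0*theta/(100*C*lambda) literally (theta in
    degrees), for auditing against sources that typeset the denominator with
    the wavelength in place of the path length.
    """
    if as_printed:
        theta_deg = record.theta_mdeg / 1000.0
        return record.mrm_g_mol * theta_deg / (
            100.0 * record.conc_M * record.wavelength_nm
        )
    return record.theta_mdeg / (
        10.0 * record.path_cm * record.conc_M * record.n_residues
    )


def fraction_helix(mre222, folded_ref: float, unfolded_ref: float) -> np.ndarray:
    """Two-state folded fraction from the 222 nm helix signal.

    f = (MRE - MRE_unfolded) / (MRE_folded - MRE_unfolded).  Values are
    reported as-is (possibly slightly outside [0, 1] from noise), never
    silently clipped.
    """
    if folded_ref == unfolded_ref:
        raise ValueError("folded and unfolded references must differ")
    return (np.asarray(mre222, dtype=float) - unfolded_ref) / (folded_ref - unfolded_ref)


def ph_model(ph, f_acid, f_basic, pka, n):
    x = 10.0 ** (n * (pka - np.asarray(ph, dtype=float)))
    return (f_basic + f_acid * x) / (1.0 + x)


def fit_ph_transition(series: PhSeries, pka_grid=None) -> PhTransitionFit:
    """Nonlinear least squares on the pH sigmoid with multistart over pKa.

    All four parameters (plateaus, pKa, Hill n) are free; n is bounded
    positive so the parameterization is canonical (f_acid = low-pH plateau).
    """
    p_, v = series.ph, series.value
    if p_.size < 6:
        raise ValueError("need >= 6 pH points spanning the transition")
    if pka_grid is None:
        pka_grid = np.arange(4.0, 9.01, 0.5)
    w = None
    if series.err is not None and np.any(series.err > 0):
        e = np.array(series.err)
        e[e <= 0] = e[e > 0].min()
        w = 1.0 / e

    span = v.max() - v.min()
    if span == 0:
        raise RuntimeError("flat series: no transition to fit")

    best = None
    for pka0 in pka_grid:
        params = lmfit.Parameters()
        params.add("f_acid", value=float(v[0]))
        params.add("f_basic", value=float(v[-1]))
        params.add("pka", value=float(pka0), min=p_.min() - 1, max=p_.max() + 1)
        params.add("n", value=1.0, min=1e-3, max=10.0)

        def resid(pp):
            r = ph_model(p_, pp["f_acid"], pp["f_basic"], pp["pka"], pp["n"]) - v
            return r * w if w is not None else r

        try:
            res = lmfit.minimize(resid, params, method="leastsq",
                                 xtol=1e-13, ftol=1e-13, max_nfev=10000)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res

    if best is None:
        raise RuntimeError("pH transition fit failed (no inflection in range?)")
    pka_hat = float(best.params["pka"].value)
    if pka_hat - (p_.min() - 1) < 1e-6 or (p_.max() + 1) - pka_hat < 1e-6:
        raise RuntimeError(
            f"no inflection within the sampled pH range: fitted pKa {pka_hat:.2f} "
            "sits at the search boundary")

    def _se(name):
        s = best.params[name].stderr
        return float(s) if s is not None else np.nan

    return PhTransitionFit(
        f_acid=float(best.params["f_acid"].value),
        f_basic=float(best.params["f_basic"].value),
        pka=float(best.params["pka"].value),
        hill_n=float(best.params["n"].value),
        f_acid_se=_se("f_acid"), f_basic_se=_se("f_basic"),
        pka_se=_se("pka"), hill_n_se=_se("n"),
        rss=float(best.chisqr),
    )


def find_isodichroic(wavelengths, spectra, flat_tol: float = 1e-12):
    """Wavelength where MRE is invariant across a set of spectra.

    ``spectra`` is an (n_spectra, n_wavelengths) array on a common grid; the
    isodichroic point is the wavelength minimizing the across-spectra
    variance.  Returns (wavelength, residual_variance, flag) where flag is
    "degenerate" if the spectra are globally identical and "no-crossing" if
    the minimum variance is not well separated from the typical variance
    (no two-state crossing point).
    """
    wl = np.asarray(wavelengths, dtype=float)
    s = np.asarray(spectra, dtype=float)
    if s.ndim != 2 or s.shape[1] != wl.size:
        raise ValueError("spectra must be (n_spectra, n_wavelengths) on a common grid")
    if s.shape[0] < 3:
        raise ValueError("need >= 3 spectra")
    var = s.var(axis=0)
    i = int(np.argmin(var))
    flag = ""
    if var.max() < flat_tol:
        flag = "degenerate"
    elif var[i] > 0.05 * np.median(var):
        flag = "no-crossing"
    return float(wl[i]), float(var[i]), flag
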