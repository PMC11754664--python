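"""Hill-model analysis of MST dose-response curves.

Microscale thermophoresis reports F_norm, the ratio of fluorescence in the
heated state to the cold state, as a function of titrant (protein)
concentration.  Saturation binding is modelled with one or two additive Hill
terms,

    F(c) = baseline + sum_m  dF_m * c**n_m / (KD_m**n_m + c**n_m),

where KD_m is the dissociation constant of mode m and n_m its Hill
coefficient.  Full-length transposase titrations show a specific (nanomolar)
and a nonspecific (micromolar) mode; the biphasic model is the additive sum
of the two, and the number of modes is selected by small-sample-corrected
AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

__all__ = [
    "TitrationSeries",
    "ModeFit",
    "BindingFitResult",
    "hill",
    "normalize_baseline",
    "fit_binding",
    "select_binding_model",
]


@dataclass(frozen=True)
class TitrationSeries:
    """A dose-response table: titrant concentration vs observable.

    Concentrations are in nM and must be strictly increasing; a leading
    zero-concentration point (no titrant) is allowed and acts as a baseline
    anchor.  ``sem`` holds per-point standard errors of the mean across
    experiment repeats (0 means unweighted).
    """

    conc_nM: np.ndarray
    observable: np.ndarray
    sem: np.ndarray | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.conc_nM, dtype=float)
        y = np.asarray(self.observable, dtype=float)
        object.__setattr__(self, "conc_nM", c)
        object.__setattr__(self, "observable", y)
        if self.sem is not None:
            s = np.asarray(self.sem, dtype=float)
            if np.any(s < 0):
                raise ValueError("SEM values must be >= 0")
            object.__setattr__(self, "sem", s)
        if c.size != y.size:
            raise ValueError("conc and observable length mismatch")
        if c.size < 6:
            raise ValueError("titration needs at least 6 points")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class ModeFit:
    """One Hill mode: dissociation constant, cooperativity and amplitude."""

    kd_nM: float
    hill_n: float
    amplitude: float
    kd_se: float = np.nan
    hill_n_se: float = np.nan
    amplitude_se: float = np.nan


@dataclass(frozen=True)
class BindingFitResult:
    modes: tuple[ModeFit, ...]
    baseline: float
    baseline_se: float
    rss: float
    aicc: float
    npoints: int
    flags: tuple[str, ...] = ()

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def kd_nM(self) -> float:
        """KD of the highest-affinity mode (nM)."""
        return self.modes[0].kd_nM

    def predict(self, conc_nM: np.ndarray) -> np.ndarray:
        c = np.asarray(conc_nM, dtype=float)
        y = np.full_like(c, self.baseline, dtype=float)
        for m in self.modes:
            y += m.amplitude * hill(c, m.kd_nM, m.hill_n)
        return y


def hill(c, kd, n):
    """Fractional saturation c**n / (kd**n + c**n); 0 at c = 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        # formulated via (c/kd)**n for numerical range safety
        ratio = np.where(c > 0, (c / kd) ** n, 0.0)
    return ratio / (1.0 + ratio)


def normalize_baseline(series: TitrationSeries) -> TitrationSeries:
    """Subtract the minimum observable value (per-curve display convention).

    Leaves concentrations and SEMs untouched; KD estimates are invariant to
    this shift because the model carries a free baseline.
    """
    y = series.observable - np.min(series.observable)
    return replace(series, observable=y)


def _model(c, params, n_modes):
    y = np.full(c.shape, params["baseline"], dtype=float)
    for m in range(n_modes):
        kd = np.exp(params[f"log_kd{m}"])
        y = y + params[f"df{m}"] * hill(c, kd, params[f"n{m}"])
    return y


def _weights(series: TitrationSeries) -> np.ndarray:
    if series.sem is None or not np.any(series.sem > 0):
        return np.ones_like(series.observable)
    s = np.array(series.sem, dtype=float)
    pos = s[s > 0]
    s[s <= 0] = pos.min()  # unweightable points get the best available weight
    return 1.0 / s


def _aicc(rss, n, k):
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_binding(
    series: TitrationSeries,
    modes: int = 1,
    fix_n: float | None = None,
    n_bounds: tuple[float, float] = (0.5, 4.0),
    n_starts: int = 7,
) -> BindingFitResult:
    """Weighted least-squares Hill fit with multistart over KD initials.

    Weights are 1/SEM (i.e. 1/SEM**2 in the squared loss) when SEMs are
    available.  KD is optimised on a log scale; ``n_starts`` log-spaced
    initial KD values spanning the concentration range are tried (pairs for
    the biphasic model) and the best converged fit is returned.

    Flags: ``unbounded`` when a fitted KD sits at the edge of the sampled
    concentration range (the data do not constrain it).
    """
    if modes not in (1, 2):
        raise ValueError("modes must be 1 or 2")
    if modes == 2 and series.conc_nM.size < 10:
        raise ValueError("biphasic fit requires >= 10 points")

    c = series.conc_nM
    y = series.observable
    w = _weights(series)
    cpos = c[c > 0]
    lo, hi = cpos.min(), cpos.max()
    kd_starts = np.exp(np.linspace(np.log(lo), np.log(hi), n_starts))

    if modes == 1:
        start_sets = [(k,) for k in kd_starts]
    else:
        start_sets = [
            (k1, k2) for i, k1 in enumerate(kd_starts) for k2 in kd_starts[i + 2:]
        ]

    amp0 = (y.max() - y.min()) or 1.0
    sign = 1.0 if y[np.argmax(c)] >= y[np.argmin(c)] else -1.0

    best = None
    for starts in start_sets:
        p = lmfit.Parameters()
        p.add("baseline", value=float(y[0]))
        for m, k0 in enumerate(starts):
            p.add(f"log_kd{m}", value=np.log(k0),
                  min=np.log(lo) - np.log(1e3), max=np.log(hi) + np.log(1e3))
            p.add(f"df{m}", value=sign * amp0 / modes)
            if fix_n is not None:
                p.add(f"n{m}", value=fix_n, vary=False)
            else:
                p.add(f"n{m}", value=1.0, min=n_bounds[0], max=n_bounds[1])

        def resid(params, _c=c, _y=y, _w=w):
            return (_model(_c, params, modes) - _y) * _w

        try:
            res = lmfit.minimize(resid, p, method="leastsq",
                                 xtol=1e-12, ftol=1e-12, max_nfev=20000)
        except Exception:
            continue
        if not res.success:
            continue
        if best is None or res.chisqr < best.chisqr - 1e-12 * abs(best.chisqr):
            best = res

    if best is None:
        raise RuntimeError("binding fit failed to converge from any start")

    n_free = best.nvarys
    rss = float(best.chisqr)
    aicc = _aicc(rss, c.size, n_free)

    fitted = []
    for m in range(modes):
        lk = best.params[f"log_kd{m}"]
        kd = float(np.exp(lk.value))
        kd_se = kd * lk.stderr if lk.stderr is not None else np.nan
        nn = best.params[f"n{m}"]
        df = best.params[f"df{m}"]
        fitted.append(ModeFit(
            kd_nM=kd, hill_n=float(nn.value), amplitude=float(df.value),
            kd_se=float(kd_se) if kd_se is not None else np.nan,
            hill_n_se=float(nn.stderr) if nn.stderr else np.nan,
            amplitude_se=float(df.stderr) if df.stderr else np.nan,
        ))
    fitted.sort(key=lambda m: m.kd_nM)

    # a constant (no-binding) model as the identifiability reference
    wmean = np.sum(w**2 * y) / np.sum(w**2)
    rss_const = float(np.sum(((y - wmean) * w) ** 2))
    aicc_const = _aicc(rss_const, c.size, 1)

    flags = []
    if aicc_const <= aicc + 2.0:  # no evidence of a dose response at all
        flags.append("unbounded")
    else:
        for m in fitted:
            if not (lo * 1.05 < m.kd_nM < hi / 1.05):
                flags.append("unbounded")
                break
    bl = best.params["baseline"]
    return BindingFitResult(
        modes=tuple(fitted), baseline=float(bl.value),
        baseline_se=float(bl.stderr) if bl.stderr else np.nan,
        rss=rss, aicc=aicc, npoints=int(c.size), flags=tuple(flags),
    )


def select_binding_model(series: TitrationSeries, **kw) -> tuple[int, BindingFitResult]:
    """Fit mono- and biphasic models; return (mode count, winning fit).

    The biphasic model wins only when its AICc is more than 2 below the
    monophasic AICc (ties resolve to the simpler model).
    """
    fit1 = fit_binding(series, modes=1, **kw)
    try:
        fit2 = fit_binding(series, modes=2, **kw)
    except (ValueError, RuntimeError):
        return 1, fit1
    if fit1.aicc - fit2.aicc > 2.0:
        return 2, fit2
    return 1, fit1
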