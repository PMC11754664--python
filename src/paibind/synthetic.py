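"""Synthetic-data generators for every assay in the pipeline.

Each generator is a pure function of (scenario parameters, seed): a fixed
seed reproduces its output byte-for-byte.  Defaults emulate the study
conditions of the corresponding experiments -- MST titrations with three
replicate curves and Gaussian noise at 2% of the response amplitude, pH
series from 4.5 to 8.5 in 0.5 steps, photon-counting decays with Poisson
noise and a measured (Gaussian) IRF, Stejskal-Tanner gradient attenuation
with 32 increments spanning 2-98% of a 0.53 T/m maximum gradient at a 60 ms
diffusion delay, amide peak lists with localized perturbations, and an
idealized toy protein/B-DNA complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import TitrationSeries, hill
from .cd_folding import PhSeries, ph_model
from .fluorescence import DecayWaveform, convolve_model
from .nmr import GAMMA_1H, GradientAttenuation, PeakList
from .structure import MolecularModel, build_bdna, build_polyala_helix

__all__ = [
    "SimScenario",
    "gen_titration",
    "gen_ph_series",
    "gen_decay_set",
    "gen_flt_titration",
    "gen_gradient_series",
    "gen_peaklists",
    "gen_toy_complex",
    "simulate",
]


@dataclass(frozen=True)
class SimScenario:
    """A named simulation: ground-truth parameters, noise settings, seed."""

    kind: str  # titration | ph_series | decay_set | gradient_series | peaklists | toy_complex
    parameters: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    seed: int = 0

    KINDS = ("titration", "ph_series", "decay_set", "flt_titration",
             "gradient_series", "peaklists", "toy_complex")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")


def gen_titration(scenario: SimScenario) -> TitrationSeries:
    """Mono- or biphasic Hill dose-response with replicate noise.

    parameters: kd_nM (scalar or list per mode), hill_n, amplitude (dF per
    mode), baseline, conc_min_nM, conc_max_nM, n_points (default 16
    log-spaced points).
    noise: sigma (Gaussian SD on the observable; default 2% of the total
    amplitude), replicates (default 3; per-point SEM is computed across
    replicates).
    """
    p = scenario.parameters
    kd = np.atleast_1d(np.asarray(p.get("kd_nM", 25.3), float))
    n_modes = kd.size
    if n_modes not in (1, 2):
        raise ValueError("1 or 2 binding modes supported")
    hill_n = np.broadcast_to(np.atleast_1d(
        np.asarray(p.get("hill_n", 1.0), float)), (n_modes,))
    amp = np.broadcast_to(np.atleast_1d(
        np.asarray(p.get("amplitude", 1.0), float)), (n_modes,))
    if np.any(kd <= 0):
        raise ValueError("KD values must be positive")
    if n_modes == 2 and max(kd) / min(kd) < 5:
        warnings.warn("KD separation < 5-fold: two modes not resolvable")
    baseline = float(p.get("baseline", 0.0))
    cmin = float(p.get("conc_min_nM", 1.0))
    cmax = float(p.get("conc_max_nM", 500.0))
    npts = int(p.get("n_points", 16))
    conc = np.logspace(np.log10(cmin), np.log10(cmax), npts)

    model = baseline + sum(a * hill(conc, k, n)
                           for a, k, n in zip(amp, kd, hill_n))
    reps = int(scenario.noise.get("replicates", 3))
    if reps < 1:
        raise ValueError("replicate count must be >= 1")
    sigma = float(scenario.noise.get("sigma", 0.02 * np.abs(amp).sum()))
    rng = np.random.default_rng(scenario.seed)
    draws = model + sigma * rng.standard_normal((reps, npts))
    mean = draws.mean(axis=0)
    sem = (draws.std(axis=0, ddof=1) / np.sqrt(reps)) if reps > 1 \
        else np.zeros(npts)
    labels = {k: p[k] for k in ("protein", "dna", "ph") if k in p}
    return TitrationSeries(conc_nM=conc, observable=mean, sem=sem, labels=labels)


def gen_ph_series(scenario: SimScenario) -> PhSeries:
    """Two-state sigmoidal pH-folding series.

    parameters: pka (default 5.98), hill_n, f_acid / f_basic plateaus
    (defaults 0.10 / 0.35), ph_min/ph_max/ph_step (defaults 4.5 / 8.5 / 0.5).
    noise: sigma (default 0.02 on the folded fraction).
    """
    p = scenario.parameters
    n = float(p.get("hill_n", 1.0))
    if n == 0:
        raise ValueError("Hill coefficient 0: degenerate transition")
    pka = float(p.get("pka", 5.98))
    f_acid = float(p.get("f_acid", 0.10))
    f_basic = float(p.get("f_basic", 0.35))
    ph = np.arange(float(p.get("ph_min", 4.5)),
                   float(p.get("ph_max", 8.5)) + 1e-9,
                   float(p.get("ph_step", 0.5)))
    if not (ph.min() <= pka <= ph.max()):
        raise ValueError("pKa outside the sampled pH range")
    sigma = float(scenario.noise.get("sigma", 0.02))
    rng = np.random.default_rng(scenario.seed)
    f = ph_model(ph, f_acid, f_basic, pka, n) + sigma * rng.standard_normal(ph.size)
    err = np.full(ph.size, sigma)
    return PhSeries(ph=ph, value=f, err=err)


def gaussian_irf(t_ns: np.ndarray, center_ns: float = 2.0,
                 sigma_ns: float = 0.2) -> np.ndarray:
    g = np.exp(-0.5 * ((t_ns - center_ns) / sigma_ns) ** 2)
    return g / g.sum()


def gen_decay_set(scenario: SimScenario) -> list[DecayWaveform]:
    """Biexponential decays convolved with an IRF, with Poisson noise.

    parameters: amplitudes (list of (A1, A2) pairs, one per waveform, in
    relative units), tau1_ns / tau2_ns, t_max_ns (default 50), dt_ns
    (default 0.05), irf_center_ns / irf_sigma_ns (Gaussian IRF; or
    irf = explicit waveform; 'delta' gives a one-bin kernel), peak_counts
    (default 1e4; scales each waveform so its model maximum equals this).
    noise: poisson (default True).
    """
    p = scenario.parameters
    tau1 = float(p.get("tau1_ns", 1.0))
    tau2 = float(p.get("tau2_ns", 4.0))
    amps = p.get("amplitudes", [(0.6, 0.4)])
    dt = float(p.get("dt_ns", 0.05))
    if dt > tau1 / 5:
        warnings.warn("time grid coarser than tau1/5: decay undersampled")
    t = np.arange(0.0, float(p.get("t_max_ns", 50.0)) + dt / 2, dt)
    irf_spec = p.get("irf", "gaussian")
    if isinstance(irf_spec, str) and irf_spec == "delta":
        irf = np.zeros(t.size)
        irf[0] = 1.0
    elif isinstance(irf_spec, str):
        irf = gaussian_irf(t, float(p.get("irf_center_ns", 2.0)),
                           float(p.get("irf_sigma_ns", 0.2)))
    else:
        irf = np.asarray(irf_spec, float)
    peak = p.get("peak_counts", 1.0e4)
    poisson = bool(scenario.noise.get("poisson", True))
    rng = np.random.default_rng(scenario.seed)

    waveforms = []
    for a1, a2 in amps:
        m = convolve_model(t, a1, a2, tau1, tau2, irf)
        if peak is not None:
            m = m * (peak / m.max())
        counts = rng.poisson(m).astype(float) if poisson else m
        waveforms.append(DecayWaveform(
            t_ns=t, counts=counts, irf=irf,
            meta={"tau1_ns": tau1, "tau2_ns": tau2, "a1": a1, "a2": a2}))
    return waveforms


def gen_flt_titration(scenario: SimScenario):
    """Fluorescence-lifetime titration: one decay per titrant concentration.

    The bound fraction at each concentration follows a Hill curve
    (parameters: kd_nM default 29.4, hill_n, conc_min_nM/conc_max_nM/
    n_points default 1-1000 nM in 12 log-spaced points) and mixes the free
    and bound amplitude pairs linearly: A = (1-f)*A_free + f*A_bound.  The
    default amplitude pairs (free (0.8, 0.3), bound (0.2, 0.45) at tau1 = 1,
    tau2 = 4 ns) conserve the integral intensity A1*tau1 + A2*tau2 across
    the titration, so the intensity-weighted lifetime is linear in bound
    fraction.  Returns (conc_nM, list of DecayWaveform).
    """
    p = dict(scenario.parameters)
    kd = float(p.get("kd_nM", 29.4))
    n = float(p.get("hill_n", 1.0))
    conc = np.logspace(np.log10(float(p.get("conc_min_nM", 1.0))),
                       np.log10(float(p.get("conc_max_nM", 1000.0))),
                       int(p.get("n_points", 12)))
    a_free = np.asarray(p.get("free_amps", (0.8, 0.3)), float)
    a_bound = np.asarray(p.get("bound_amps", (0.2, 0.45)), float)
    f = hill(conc, kd, n)
    amps = [tuple((1 - fi) * a_free + fi * a_bound) for fi in f]
    sub = SimScenario(kind="decay_set",
                      parameters={**p, "amplitudes": amps},
                      noise=scenario.noise, seed=scenario.seed)
    return conc, gen_decay_set(sub)


def gen_gradient_series(scenario: SimScenario) -> GradientAttenuation:
    """Stejskal-Tanner attenuation I(g) = I0 exp(-D (gamma g delta)^2 (Delta - delta/3)).

    parameters: d_m2_s (default 1.86e-10), i0, g_max_T_m (default 0.53),
    g_frac_min/max (default 0.02/0.98), n_increments (default 32),
    big_delta_s (default 0.060), little_delta_s (default 0.004 -- recorded
    in the output so fits never assume it).
    noise: sigma_frac (Gaussian SD as a fraction of I0; default 0.01).
    """
    p = scenario.parameters
    d = float(p.get("d_m2_s", 1.86e-10))
    if d <= 0:
        raise ValueError("diffusion coefficient must be > 0")
    i0 = float(p.get("i0", 1.0))
    g = np.linspace(float(p.get("g_frac_min", 0.02)),
                    float(p.get("g_frac_max", 0.98)),
                    int(p.get("n_increments", 32))) * float(p.get("g_max_T_m", 0.53))
    big_delta = float(p.get("big_delta_s", 0.060))
    little_delta = float(p.get("little_delta_s", 0.004))
    b = (GAMMA_1H * g * little_delta) ** 2 * (big_delta - little_delta / 3.0)
    signal = i0 * np.exp(-d * b)
    if signal[-1] / i0 > 0.9:
        warnings.warn("attenuation at max gradient < 10%: D not measurable")
    sigma = float(scenario.noise.get("sigma_frac", 0.01)) * i0
    rng = np.random.default_rng(scenario.seed)
    intensity = signal + sigma * rng.standard_normal(g.size)
    return GradientAttenuation(
        g_T_m=g, intensity=intensity, big_delta_s=big_delta,
        little_delta_s=little_delta, gamma=GAMMA_1H,
        meta={"d_true_m2_s": d, "i0_true": i0, "sigma": sigma},
    )


def gen_peaklists(scenario: SimScenario) -> tuple[PeakList, PeakList]:
    """Free and DNA-bound amide peak lists with localized perturbations.

    parameters: residues (list of residue numbers, default 1..55),
    interface (dict residue -> (dH shift, dN shift) in ppm, or residue list
    with default shifts 0.10/0.50), drop_probability (bound peaks missing
    at random, emulating exchange broadening; default 0).
    noise: jitter_ppm (Gaussian SD applied to 1H of all bound peaks; the
    15N jitter is 5x larger, matching the CSP weighting scale; default 0.003).
    """
    p = scenario.parameters
    residues = list(p.get("residues", range(1, 56)))
    if len(residues) != len(set(residues)):
        raise ValueError("duplicate residue numbers")
    interface = p.get("interface", {})
    if not isinstance(interface, dict):
        interface = {int(r): (0.10, 0.50) for r in interface}
    rng = np.random.default_rng(scenario.seed)
    jitter = float(scenario.noise.get("jitter_ppm", 0.003))
    drop_p = float(p.get("drop_probability", 0.0))

    d_h = 7.5 + 2.0 * rng.random(len(residues))
    d_n = 108.0 + 24.0 * rng.random(len(residues))
    free = pd.DataFrame({"residue": residues, "aa": "ALA",
                         "dH_ppm": d_h, "dN_ppm": d_n})
    bound = free.copy()
    for k, r in enumerate(residues):
        if r in interface:
            dh, dn = interface[r]
            bound.loc[k, "dH_ppm"] += dh
            bound.loc[k, "dN_ppm"] += dn
        else:
            bound.loc[k, "dH_ppm"] += jitter * rng.standard_normal()
            bound.loc[k, "dN_ppm"] += 5.0 * jitter * rng.standard_normal()
    keep = rng.random(len(residues)) >= drop_p
    bound = bound[keep].reset_index(drop=True)
    return PeakList(free), PeakList(bound)


def gen_toy_complex(scenario: SimScenario) -> MolecularModel:
    """Idealized B-DNA duplex plus a poly-alanine helix at a stated pose.

    parameters: sequence (ACGT string, default 10 bp), n_residues (default
    12), protein_offset (xyz, default [12, 0, 15] relative to the DNA
    origin).  Deterministic: no noise.
    """
    p = scenario.parameters
    seq = str(p.get("sequence", "ACGTACGTAC"))
    n_res = int(p.get("n_residues", 12))
    offset = np.asarray(p.get("protein_offset", [12.0, 0.0, 15.0]), float)
    dna = build_bdna(seq)
    prot = build_polyala_helix(n_res, origin=offset)
    return MolecularModel(
        serial=np.concatenate([prot.serial, dna.serial + prot.serial.max()]),
        name=np.concatenate([prot.name, dna.name]),
        element=np.concatenate([prot.element, dna.element]),
        resnum=np.concatenate([prot.resnum, dna.resnum]),
        resname=np.concatenate([prot.resname, dna.resname]),
        chain=np.concatenate([prot.chain, dna.chain]),
        coords=np.vstack([prot.coords, dna.coords]),
        chain_roles={**prot.chain_roles, **dna.chain_roles},
    )


_DISPATCH = {
    "titration": gen_titration,
    "ph_series": gen_ph_series,
    "decay_set": gen_decay_set,
    "flt_titration": gen_flt_titration,
    "gradient_series": gen_gradient_series,
    "peaklists": gen_peaklists,
    "toy_complex": gen_toy_complex,
}


def simulate(scenario: SimScenario):
    """Dispatch a scenario to its generator."""
    return _DISPATCH[scenario.kind](scenario)
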