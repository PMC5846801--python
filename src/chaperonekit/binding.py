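"""Binding and stability analysis: single-site ITC fitting, thermofluor
melting-temperature estimation, complex-occupancy quantitation and
dose-equivalence interpolation.

The ITC model is the standard single-site (Wiseman) isotherm for a
perfusion cell: after each injection the effective cell concentrations
follow the displacement-dilution bookkeeping, the bound concentration is
the smaller root of the binding quadratic, and the differential heat per
injection carries the displaced-volume correction.  Thermodynamic
self-consistency (dG = dH - T dS = -RT ln Ka) holds by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy.signal import savgol_filter

__all__ = [
    "ITCThermogram",
    "ITCFit",
    "MeltCurve",
    "TmResult",
    "WeakBindingWarning",
    "fit_itc_single_site",
    "normalize_melt",
    "tm_estimate",
    "complex_occupancy",
    "equivalent_dose",
]

R_KCAL = 1.987204258640832e-3  # gas constant, kcal / (mol K)


class WeakBindingWarning(UserWarning):
    """Raised when the Wiseman c-value puts the titration outside the
    reliably fittable regime (c < 1 weak, c > 1000 too tight)."""


@dataclass
class ITCThermogram:
    """Injection schedule and measured heats for one titration."""

    cell_volume_ml: float
    cell_conc: float          # M, macromolecule in the cell
    syringe_conc: float       # M, titrant
    injection_volumes_ul: np.ndarray
    heats_ucal: np.ndarray
    temperature_K: float = 293.15

    def __post_init__(self) -> None:
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.injection_volumes_ul.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats must have equal length")
        if np.any(self.injection_volumes_ul <= 0) or self.cell_volume_ml <= 0:
            raise ValueError("volumes must be > 0")

    @property
    def molar_ratios(self) -> np.ndarray:
        """Cumulative titrant:macromolecule molar ratio after each injection."""
        v0 = self.cell_volume_ml * 1e-3
        dv = np.cumsum(self.injection_volumes_ul) * 1e-6
        mt = self.cell_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
        xt = self.syringe_conc * (dv / v0) * (1 - dv / (2 * v0))
        return xt / mt


@dataclass
class ITCFit:
    n: float
    Ka: float                 # M^-1
    dH: float                 # kcal/mol
    dS: float                 # cal/(mol K)
    dG: float                 # kcal/mol
    q_dilution: float         # ucal per injection, fitted offset
    stderr: dict = field(default_factory=dict)
    residual_rms: float = 0.0
    c_value: float = 0.0
    reliable: bool = True

    @property
    def Kd(self) -> float:
        return 1.0 / self.Ka


@dataclass
class MeltCurve:
    T: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.T.shape != self.F.shape:
            raise ValueError("T and F must have equal length")


@dataclass
class TmResult:
    Tm: float
    method: str
    amplitude: float = np.nan
    width: float = np.nan
    basal_offset: float = np.nan


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def _model_heats(params: lmfit.Parameters, tg: ITCThermogram) -> np.ndarray:
    from .syndata import wiseman_heats  # local import to avoid cycle at module load

    n = params["n"].value
    ka = 10.0 ** params["log10_Ka"].value
    dh = params["dH"].value
    q0 = params["q_dil"].value
    return wiseman_heats(n, 1.0 / ka, dh, tg.cell_conc, tg.syringe_conc,
                         tg.cell_volume_ml, tg.injection_volumes_ul) + q0


def fit_itc_single_site(
    thermogram: ITCThermogram,
    discard_first: bool = True,
    init: dict | str = "auto",
    float_dilution: bool = True,
) -> ITCFit:
    """Fit per-injection heats to the single-site isotherm.

    The first-injection heat is excluded by default (small pre-injection
    convention) and a constant heat-of-dilution offset is floated.
    Parameters are (n, Ka, dH); dS is derived from dG = -RT ln Ka and
    dH at the run temperature.  A Wiseman c-value (n Ka [cell]) below 1
    or above 1000 triggers :class:`WeakBindingWarning` and marks the fit
    unreliable.
    """
    tg = thermogram
    use = np.ones(tg.heats_ucal.size, dtype=bool)
    if discard_first:
        use[0] = False
    if use.sum() < 8:
        raise ValueError("need at least 8 usable injections")
    heats = tg.heats_ucal

    params = lmfit.Parameters()
    if init == "auto":
        # total heat / total moles injected approximates dH; half-saturation
        # near molar ratio 1 motivates n ~ 1 and Kd ~ cell concentration / 10.
        mol_per_inj = tg.syringe_conc * tg.injection_volumes_ul * 1e-6
        early = heats[1:4].sum() / mol_per_inj[1:4].sum() / 1e9  # kcal/mol
        dh0 = early if abs(early) > 1e-3 else -5.0
        n0, ka0 = 1.0, 10.0 / tg.cell_conc
    else:
        n0 = init.get("n", 1.0)
        ka0 = init.get("Ka", 1.0 / init.get("Kd", tg.cell_conc))
        dh0 = init.get("dH", -5.0)
    params.add("n", value=n0, min=0.05, max=10.0)
    params.add("log10_Ka", value=np.log10(ka0), min=0.0, max=12.0)
    params.add("dH", value=dh0, min=-100.0, max=100.0)
    params.add("q_dil", value=0.0, vary=float_dilution, min=-50.0, max=50.0)

    def resid(p):
        return (_model_heats(p, tg) - heats)[use]

    # Pre-fit signal check: a titration whose heat dynamic range is
    # comparable to its injection-to-injection noise carries no isotherm
    # information (the weak-binding / low-c signature).
    q_used = heats[use]
    noise_est = float(np.median(np.abs(np.diff(q_used))) / np.sqrt(2) + 1e-12)
    signal_range = float(q_used.max() - q_used.min())
    signal_starved = signal_range < 15.0 * noise_est
    raw_sat = float(np.mean(np.abs(heats[-3:])) /
                    max(np.mean(np.abs(heats[1:4])), 1e-12))
    weak_suspect = signal_starved or raw_sat > 0.4

    result = lmfit.minimize(resid, params, method="leastsq")
    if not result.success:
        # Levenberg-Marquardt occasionally stops on error-bar estimation for
        # degenerate (information-poor) data; the trust-region backend is
        # more forgiving and the reliability checks below flag such fits.
        result = lmfit.minimize(resid, params, method="least_squares")
    if not result.success and not weak_suspect:
        raise ValueError(f"ITC fit did not converge: {result.message}")
    pv = result.params
    n = pv["n"].value
    ka = 10.0 ** pv["log10_Ka"].value
    dh = pv["dH"].value
    T = tg.temperature_K
    dg = -R_KCAL * T * np.log(ka)
    ds = (dh - dg) / T * 1e3  # cal/(mol K)
    c_value = n * ka * tg.cell_conc
    reliable = True
    # Data-driven saturation check: in the low-c (weak-binding) regime the
    # per-injection heats never decay toward the dilution baseline, so the
    # isotherm carries no curvature and (n, Ka, dH) are unidentifiable even
    # when the optimizer converges to some degenerate combination.
    q_net = np.abs(heats - pv["q_dil"].value)
    sat_ratio = float(np.mean(q_net[-3:]) / max(np.mean(q_net[1:4]), 1e-12))
    if signal_starved:
        warnings.warn(
            f"heat dynamic range ({signal_range:.2g} ucal) is within the "
            f"injection noise ({noise_est:.2g} ucal): low-c, weak-binding "
            "regime — the single-site fit is unreliable (Kd likely at or "
            "beyond the mM scale)",
            WeakBindingWarning, stacklevel=2)
        reliable = False
    elif sat_ratio > 0.4:
        warnings.warn(
            f"no saturation within the titration (final/initial heat ratio "
            f"{sat_ratio:.2f}): low-c, weak-binding regime — the single-site "
            "fit is unreliable (Kd likely at or beyond the mM scale)",
            WeakBindingWarning, stacklevel=2)
        reliable = False
    elif c_value < 1.0:
        warnings.warn(
            f"Wiseman c-value {c_value:.3g} < 1: binding too weak for a "
            "reliable single-site fit (Kd likely at or beyond the mM scale)",
            WeakBindingWarning, stacklevel=2)
        reliable = False
    elif c_value > 1000.0:
        warnings.warn(
            f"Wiseman c-value {c_value:.3g} > 1000: titration too tight to "
            "constrain Ka", WeakBindingWarning, stacklevel=2)
        reliable = False
    stderr = {}
    for name in ("n", "log10_Ka", "dH", "q_dil"):
        stderr[name] = pv[name].stderr
    return ITCFit(n=n, Ka=ka, dH=dh, dS=ds, dG=dg,
                  q_dilution=pv["q_dil"].value, stderr=stderr,
                  residual_rms=float(np.sqrt(np.mean(result.residual**2))),
                  c_value=float(c_value), reliable=reliable)


# ---------------------------------------------------------------------------
# Thermofluor
# ---------------------------------------------------------------------------

def _boltzmann(T, f_pre, f_post, tm, width):
    return f_pre + (f_post - f_pre) / (1.0 + np.exp(-(T - tm) / width))


def _require_transition(curve: MeltCurve) -> None:
    F = curve.F
    rng = float(F.max() - F.min())
    noise = float(np.std(np.diff(F)) / np.sqrt(2)) if F.size > 3 else 0.0
    if rng == 0 or (noise > 0 and rng < 10 * noise):
        raise ValueError("no transition: melt curve has no usable dynamic range")


def normalize_melt(curves: list[MeltCurve], basal_T: float = 20.0) -> list[tuple[MeltCurve, float]]:
    """Min-max normalize melt curves between fitted pre/post baselines.

    Each curve is mapped onto [0, 1] between the fitted folded and
    unfolded plateaus; the returned basal offset is the normalized
    fluorescence at ``basal_T`` (elevated values flag hydrophobic
    exposure already present at low temperature).  Affine transforms of
    a curve normalize to identical output.
    """
    out = []
    for c in curves:
        _require_transition(c)
        fit = _fit_boltzmann(c)
        pre, post = fit["f_pre"], fit["f_post"]
        F_norm = (c.F - pre) / (post - pre)
        basal = float(np.interp(basal_T, c.T, F_norm)) if c.T[0] <= basal_T <= c.T[-1] else np.nan
        out.append((MeltCurve(T=c.T.copy(), F=F_norm), basal))
    return out


def _fit_boltzmann(curve: MeltCurve) -> dict:
    T, F = curve.T, curve.F
    model = lmfit.Model(_boltzmann)
    span = T[-1] - T[0]
    tm0 = float(T[np.argmax(np.gradient(savgol_filter(F, min(5, len(F) // 2 * 2 - 1), 2), T))])
    params = model.make_params(f_pre=float(F[:3].mean()), f_post=float(F[-3:].mean()),
                               tm=tm0, width=span / 30)
    params["width"].min = 1e-3
    params["tm"].min, params["tm"].max = T[0], T[-1]
    res = model.fit(F, params, T=T)
    return {k: float(v.value) for k, v in res.params.items()}


def tm_estimate(curve: MeltCurve, method: str = "derivative",
                smooth_window: int = 7) -> TmResult:
    """Apparent melting temperature as the inflection of the transition.

    ``derivative``: maximum of the Savitzky-Golay-smoothed dF/dT with a
    parabolic sub-grid refinement.  ``sigmoid``: midpoint of a Boltzmann
    fit.  For a symmetric noiseless sigmoid both agree to grid
    resolution.  A flat curve raises ``ValueError``.
    """
    _require_transition(curve)
    T, F = curve.T, curve.F
    if method == "sigmoid":
        fit = _fit_boltzmann(curve)
        return TmResult(Tm=fit["tm"], method="sigmoid",
                        amplitude=fit["f_post"] - fit["f_pre"], width=fit["width"])
    if method != "derivative":
        raise ValueError(f"unknown method {method!r}")
    win = min(smooth_window, F.size - 1)
    if win % 2 == 0:
        win -= 1
    Fs = savgol_filter(F, win, polyorder=2) if win >= 3 else F
    dF = np.gradient(Fs, T)
    i = int(np.argmax(dF))
    if 0 < i < dF.size - 1:
        denom = dF[i - 1] - 2 * dF[i] + dF[i + 1]
        delta = 0.5 * (dF[i - 1] - dF[i + 1]) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        tm = float(T[i] + delta * (T[min(i + 1, T.size - 1)] - T[i]))
    else:
        tm = float(T[i])
    return TmResult(Tm=tm, method="derivative", amplitude=float(F.max() - F.min()))


# ---------------------------------------------------------------------------
# Occupancy and dose equivalence
# ---------------------------------------------------------------------------

def complex_occupancy(
    lanes,
    complex_species: tuple[str, ...] = ("complex",),
    free_species: tuple[str, ...] = ("free",),
    standard_curve: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Percent of the kinase pool incorporated in complex bands.

    ``occupancy = 100 * complex / (complex + free)``; invariant to
    exposure scaling.  With ``standard_curve = (signal, concentration)``
    the band signals are first converted to concentrations by log-linear
    interpolation (ELISA-style standards).
    """
    df = lanes
    def total(names):
        m = df["species"].isin(names)
        vals = df.loc[m, "intensity"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"no bands found for species {names}")
        if standard_curve is not None:
            sig, conc = standard_curve
            vals = np.exp(np.interp(np.log(vals), np.log(sig), np.log(conc)))
        return float(vals.sum())

    cx, fr = total(complex_species), total(free_species)
    if cx + fr <= 0:
        raise ValueError("zero total band intensity")
    return 100.0 * cx / (cx + fr)


def equivalent_dose(
    dose_a: np.ndarray,
    response_a: np.ndarray,
    dose_b: np.ndarray,
    response_b: np.ndarray,
    at_dose_a: float,
) -> float:
    """Dose on curve B achieving the same normalized response as
    ``at_dose_a`` on curve A (monotone interpolation).

    Both responses must be monotone non-increasing in dose; the matched
    level must lie within both curves' ranges.
    """
    da, ra = np.asarray(dose_a, float), np.asarray(response_a, float)
    db, rb = np.asarray(dose_b, float), np.asarray(response_b, float)
    for r, name in ((ra, "A"), (rb, "B")):
        if np.any(np.diff(r) > 1e-12):
            raise ValueError(f"response curve {name} is not monotone decreasing")
    if not da[0] <= at_dose_a <= da[-1]:
        raise ValueError("query dose outside curve A's range")
    level = float(np.interp(at_dose_a, da, ra))
    if not rb.min() <= level <= rb.max():
        raise ValueError("matched response level outside curve B's range")
    # invert monotone-decreasing curve b
    return float(np.interp(level, rb[::-1], db[::-1]))
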