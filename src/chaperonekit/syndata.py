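"""Synthetic data generators with known ground truth.

Every input data type consumed by the analysis stages (peptide-level HDX
uptake tables, ITC thermograms, thermofluor melt curves, SAXS curves and
SEC-SAXS frame matrices, 2D amide peak lists, densitometry lane tables)
can be generated here from explicit ground-truth parameters, so each
analysis operation is testable by parameter recovery without any external
downloads.

Conventions
-----------
* Amide exchange follows two-state EX2 kinetics with a single base
  intrinsic rate ``k_int`` (default 1 s^-1 at 22 degC) modulated per
  residue by a protection factor PF >= 1: ``k_ex = k_int / PF``.
  Relative deuteration is plateau-normalized (100 % = full exchange at
  the buffer deuterium fraction), matching the relative-values-only
  reporting of bottom-up HDX-MS without back-exchange correction.
* On-ice incubation slows exchange roughly tenfold
  (:data:`ICE_SLOWDOWN`); the 3 s on-ice point is therefore equivalent
  to 0.3 s at 22 degC.
* All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .binding import ITCThermogram, MeltCurve
from .saxs import SAXSCurve, sphere_intensity, two_sphere_intensity

__all__ = [
    "ICE_SLOWDOWN",
    "D2O_FRACTION",
    "ExchangeModel",
    "GroundTruth",
    "default_ground_truth",
    "synthetic_construct_sequence",
    "segmented_peptide_map",
    "simulate_hdx_pair",
    "simulate_itc",
    "simulate_melt_curve",
    "simulate_saxs",
    "simulate_secsaxs_frames",
    "make_base_peaklist",
    "simulate_titration_peaklists",
    "simulate_lane_table",
]

#: Slowdown of amide exchange for incubation on ice relative to 22 degC.
ICE_SLOWDOWN = 10.0

#: Deuterium fraction of the labelling buffer (75.4 % v/v D2O).
D2O_FRACTION = 0.754

# FGFR3 kinase-domain construct span in full-length numbering.
CONSTRUCT_START = 455
CONSTRUCT_END = 768


@dataclass
class ExchangeModel:
    """Per-residue amide exchange kinetics.

    k_int
        intrinsic exchange rate (s^-1) at 22 degC.
    PF
        protection factor (>= 1); observed rate is ``k_int / PF``.
    f_D2O
        deuterium fraction of the exchange buffer (0 < f <= 1).
    temp_factor
        rate multiplier for non-22 degC incubations (e.g. 0.1 on ice).
    """

    residue_index: int
    k_int: float = 1.0
    PF: float = 1.0
    f_D2O: float = D2O_FRACTION
    temp_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.k_int <= 0:
            raise ValueError("k_int must be > 0")
        if self.PF < 1:
            raise ValueError("protection factor must be >= 1")
        if not 0 < self.f_D2O <= 1:
            raise ValueError("f_D2O must be in (0, 1]")

    @property
    def k_ex(self) -> float:
        """Observed exchange rate (s^-1) at 22 degC."""
        return self.k_int / self.PF

    def deuterium_fraction(self, t: float) -> float:
        """Deuterium occupancy of this amide after ``t`` seconds."""
        return self.f_D2O * -np.expm1(-self.k_ex * self.temp_factor * t)


@dataclass
class GroundTruth:
    """Registry of true parameters used by the generators.

    Downstream fits are expected to recover these within the tolerances
    stated by the corresponding analysis module.
    """

    #: residue -> (PF_free, PF_bound)
    hdx: dict[int, tuple[float, float]] = field(default_factory=dict)
    #: (n, Kd in M, dH in kcal/mol)
    itc: tuple[float, float, float] = (1.0, 1.8e-6, -9.2)
    #: (Tm degC, transition width degC, pre-slope, post-slope)
    melt: tuple[float, float, float, float] = (55.0, 2.0, 0.0, 0.0)
    #: shape descriptor: ("sphere", (R,)) or ("two_sphere", (R1, R2, separation)), nm
    saxs_shape: tuple[str, tuple[float, ...]] = ("sphere", (3.0,))
    saxs_I0: float = 1.0
    #: dilution-series concentrations, mg/mL
    saxs_concentrations: tuple[float, ...] = (4.2, 2.1, 1.1)
    #: (Kd M, kinase concentration M)
    titration: tuple[float, float] = (1.8e-6, 100e-6)
    #: residue -> CSP (ppm) applied at full saturation
    csp: dict[int, tuple[float, float]] = field(default_factory=dict)
    #: residue -> exchange-broadening factor in [0, 1] (1 = no broadening)
    broadening: dict[int, float] = field(default_factory=dict)
    #: residues whose random-coil peaks sharpen/intensify on binding
    sharp_residues: tuple[int, ...] = ()
    #: species -> true fraction (sums to 1) for densitometry lanes
    lanes: dict[str, float] = field(default_factory=lambda: {"complex": 0.145, "free": 0.855})

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["hdx"] = {str(k): v for k, v in self.hdx.items()}
        d["csp"] = {str(k): v for k, v in self.csp.items()}
        d["broadening"] = {str(k): v for k, v in self.broadening.items()}
        return d


# ---------------------------------------------------------------------------
# HDX
# ---------------------------------------------------------------------------

#: Regions of the kinase C-lobe protected on co-chaperone binding
#: (full-length numbering, 1-based inclusive).
PROTECTED_BLOCKS = ((592, 602), (611, 628), (670, 684), (732, 752))

#: N-lobe regions that become more exchanging (deprotected) on binding.
DEPROTECTED_BLOCKS = ((464, 492), (500, 535))


def default_ground_truth() -> GroundTruth:
    """Ground truth emulating a strong-client kinase/Cdc37 pair.

    The HDX profile has a baseline protection factor of 200 in both
    states, C-lobe blocks that gain protection on binding and N-lobe
    blocks that lose it, mirroring the remodelling signature of a
    kinase/co-chaperone binary complex.
    """
    hdx: dict[int, tuple[float, float]] = {}
    for r in range(CONSTRUCT_START, CONSTRUCT_END + 1):
        hdx[r] = (200.0, 200.0)
    for lo, hi in PROTECTED_BLOCKS:
        for r in range(lo, hi + 1):
            hdx[r] = (50.0, 5000.0)
    for lo, hi in DEPROTECTED_BLOCKS:
        for r in range(lo, hi + 1):
            hdx[r] = (2000.0, 50.0)

    # CSPs for the lobe-interface allosteric network, applied at saturation.
    csp = {556: (0.06, 0.8), 536: (0.08, 0.9), 532: (0.05, 0.6),
           529: (0.07, 0.8), 525: (0.04, 0.5)}
    # Intermediate-timescale exchange attenuates the whole spectrum well
    # beyond the stoichiometric expectation; the N-lobe beta-strand set is
    # broadened beyond detection in the complex.
    broadening = {r: 0.15 for r in range(CONSTRUCT_START, CONSTRUCT_END + 1)}
    broadening.update({r: 0.0 for r in range(495, 516)})
    sharp = tuple(range(456, 468))
    for r in sharp:
        broadening[r] = 1.0
    return GroundTruth(hdx=hdx, csp=csp, broadening=broadening, sharp_residues=sharp)


def synthetic_construct_sequence(seed: int = 0, prolines: bool = False) -> str:
    """Deterministic synthetic kinase-domain sequence (residues 455-768).

    Glycines are placed at 481, 533, 549 and 574 so the default NMR
    reference-peak set is always available.  By default the sequence is
    proline-free, keeping every backbone amide observable; pass
    ``prolines=True`` to sprinkle ~4 % prolines for exercising the
    exchangeable-amide exclusion rules.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))
    n = CONSTRUCT_END - CONSTRUCT_START + 1
    seq = rng.choice(alphabet, size=n)
    if prolines:
        n_pro = max(1, n // 25)
        pos = rng.choice(np.arange(2, n - 1), size=n_pro, replace=False)
        seq[pos] = "P"
    for ref in (481, 533, 549, 574):
        seq[ref - CONSTRUCT_START] = "G"
    return "".join(seq)


def segmented_peptide_map(
    sequence: str,
    blocks: tuple[tuple[int, int], ...] = PROTECTED_BLOCKS + DEPROTECTED_BLOCKS,
    start: int = CONSTRUCT_START,
    length: int = 10,
    stride: int = 4,
) -> list[tuple[int, int, str]]:
    """Tile the construct with peptides whose exchangeable spans do not
    straddle block boundaries.

    Bottom-up HDX cannot attribute uptake within a peptide; a peptide
    mixing residues from two regions smears the difference signal across
    both.  Here peptide boundaries are aligned with the designed
    protection blocks (a peptide may begin one residue *before* a block,
    because a peptide's first residue is not exchange-observable), so a
    residue-level consolidation of the peptide-level signal is
    well-posed.  Real pepsin maps do not guarantee this; see the methods
    documentation for what that implies.
    """
    end = start + len(sequence) - 1
    # Segment boundaries: construct split at block edges.
    edges = sorted({start, end + 1, *(lo for lo, _ in blocks), *(hi + 1 for _, hi in blocks)})
    peptides: list[tuple[int, int, str]] = []
    for seg_lo, seg_hi_excl in zip(edges[:-1], edges[1:]):
        seg_hi = seg_hi_excl - 1
        # Peptide (p0, p1) has exchangeable span (p0+1 .. p1); require that
        # span inside [seg_lo, seg_hi] => p0 >= seg_lo - 1, p1 <= seg_hi.
        p0_min = max(start, seg_lo - 1)
        p0 = p0_min
        while True:
            p1 = min(p0 + length - 1, seg_hi)
            if p1 - p0 >= 2:  # at least two exchangeable residues
                peptides.append((p0, p1, sequence[p0 - start: p1 - start + 1]))
            if p1 >= seg_hi:
                break
            p0 += stride
            if p0 > seg_hi - 2:
                p0 = max(p0_min, seg_hi - length + 1)
    # Deduplicate while keeping order.
    seen: set[tuple[int, int]] = set()
    out = []
    for p in peptides:
        if (p[0], p[1]) not in seen:
            seen.add((p[0], p[1]))
            out.append(p)
    return out


def _peptide_exchangeable(start: int, end: int, sequence: str) -> list[int]:
    """Exchange-observable residues of a peptide: all but the first
    residue and prolines (standard bottom-up HDX convention)."""
    residues = []
    for i, (r, aa) in enumerate(zip(range(start, end + 1), sequence)):
        if i == 0 or aa == "P":
            continue
        residues.append(r)
    return residues


def simulate_hdx_pair(
    profiles: dict[int, tuple[float, float]],
    peptide_map: list[tuple[int, int, str]],
    timepoints: tuple[float, ...] = (0.3, 3.0, 30.0, 300.0),
    replicates: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
    k_int: float = 1.0,
    f_D2O: float = D2O_FRACTION,
    normalize_to_d2o: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate matched free/bound peptide uptake tables.

    Per-residue deuterium fraction at time ``t`` is
    ``f_D2O * (1 - exp(-(k_int / PF) * t))``; peptide relative
    deuteration averages this over the exchange-observable residues
    (first residue and prolines excluded) and, with
    ``normalize_to_d2o``, is expressed as percent of the f_D2O plateau.
    Gaussian noise of ``noise_sd`` (percentage points) is added per
    replicate.

    Returns two DataFrames (free, bound) with the uptake-CSV columns
    ``peptide_id,start,end,sequence,state,timepoint_s,replicate,
    deuteration_pct,score``.
    """
    if not peptide_map:
        raise ValueError("peptide map is empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    lo, hi = min(profiles), max(profiles)
    rng = np.random.default_rng(seed)
    tables = {"free": [], "bound": []}
    for pid, (start, end, sequence) in enumerate(peptide_map):
        if start < lo or end > hi:
            raise ValueError(f"peptide {start}-{end} outside profile range {lo}-{hi}")
        exch = _peptide_exchangeable(start, end, sequence)
        if not exch:
            warnings.warn(
                f"peptide {start}-{end} has no exchangeable amides; excluded",
                stacklevel=2,
            )
            continue
        for state_idx, state in enumerate(("free", "bound")):
            pfs = np.array([profiles[r][state_idx] for r in exch])
            for t in timepoints:
                frac = np.mean(-np.expm1(-(k_int / pfs) * t))
                d = 100.0 * frac if normalize_to_d2o else 100.0 * f_D2O * frac
                for rep in range(1, replicates + 1):
                    tables[state].append(
                        (f"pep{pid:03d}", start, end, sequence, state, t, rep,
                         d + rng.normal(0.0, noise_sd), 50.0)
                    )
    cols = ["peptide_id", "start", "end", "sequence", "state", "timepoint_s",
            "replicate", "deuteration_pct", "score"]
    free = pd.DataFrame(tables["free"], columns=cols)
    bound = pd.DataFrame(tables["bound"], columns=cols)
    return free, bound


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def wiseman_heats(
    n: float,
    kd: float,
    dh: float,
    cell_conc: float,
    syringe_conc: float,
    cell_volume_ml: float,
    injection_volumes_ul: np.ndarray,
) -> np.ndarray:
    """Noise-free per-injection heats (ucal) for a single-site isotherm.

    Uses the standard perfusion-cell displacement bookkeeping: after a
    cumulative injected volume dV the effective cell concentrations are
    ``Mt = M0 (1 - dV/2V0) / (1 + dV/2V0)`` and
    ``Xt = X0 (dV/V0)(1 - dV/2V0)``.  The bound concentration is the
    smaller root of ``B^2 - B(n Mt + Xt + Kd) + n Mt Xt = 0`` and the
    differential heat carries the displaced-volume correction.
    """
    v0 = cell_volume_ml * 1e-3  # L
    inj = np.asarray(injection_volumes_ul, dtype=float) * 1e-6  # L
    if np.any(inj <= 0):
        raise ValueError("injection volumes must be > 0")
    if inj.sum() > v0:
        raise ValueError("total injected volume exceeds cell volume")
    dv = np.cumsum(inj)
    mt = cell_conc * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
    xt = syringe_conc * (dv / v0) * (1 - dv / (2 * v0))
    b = n * mt + xt + kd
    bound = 0.5 * (b - np.sqrt(b * b - 4 * n * mt * xt))
    q = dh * v0 * bound * 1e9  # kcal/mol * mol -> ucal
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q + (inj / v0) * (q + q_prev) / 2 - q_prev
    return dq


def simulate_itc(
    truth: tuple[float, float, float] = (1.0, 1.8e-6, -9.2),
    cell_conc: float = 16.9e-6,
    syringe_conc: float = 211.7e-6,
    cell_volume_ml: float = 1.458,
    injection_volumes_ul: tuple[float, ...] | None = None,
    noise_sd_ucal: float = 0.0,
    temperature_K: float = 293.15,
    seed: int = 0,
) -> ITCThermogram:
    """Simulate a single-site titration thermogram.

    Defaults reproduce the reference titration geometry: 1.458 mL cell,
    16.9 uM macromolecule, 211.7 uM titrant, 20 injections of 15 uL with
    a 3 uL first injection.
    """
    n, kd, dh = truth
    if cell_conc <= 0 or syringe_conc <= 0:
        raise ValueError("concentrations must be > 0")
    if injection_volumes_ul is None:
        injection_volumes_ul = (3.0,) + (15.0,) * 19
    inj = np.asarray(injection_volumes_ul, dtype=float)
    heats = wiseman_heats(n, kd, dh, cell_conc, syringe_conc, cell_volume_ml, inj)
    if noise_sd_ucal > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd_ucal, size=heats.size)
    return ITCThermogram(
        cell_volume_ml=cell_volume_ml,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes_ul=inj,
        heats_ucal=heats,
        temperature_K=temperature_K,
    )


# ---------------------------------------------------------------------------
# Thermofluor
# ---------------------------------------------------------------------------

def simulate_melt_curve(
    truth: tuple[float, float, float, float] = (55.0, 2.0, 0.0, 0.0),
    T_grid: np.ndarray | None = None,
    amplitude: float = 1.0,
    basal: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """Two-state thermofluor melt: linear baselines joined by a logistic
    transition whose noiseless inflection equals the true Tm.

    The default grid is 10-90 degC in 1 degC steps.
    """
    tm, width, pre_slope, post_slope = truth
    if T_grid is None:
        T_grid = np.arange(10.0, 91.0, 1.0)
    T = np.asarray(T_grid, dtype=float)
    if T.ndim != 1 or T.size < 3 or np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    theta = 1.0 / (1.0 + np.exp(-(T - tm) / width))
    pre = basal + pre_slope * (T - T[0])
    post = basal + amplitude + post_slope * (T - T[0])
    F = pre + (post - pre) * theta
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F + rng.normal(0.0, noise_sd, size=F.size)
    return MeltCurve(T=T, F=F)


# ---------------------------------------------------------------------------
# SAXS
# ---------------------------------------------------------------------------

def _form_factor(shape: str, params: tuple[float, ...], s: np.ndarray, I0: float) -> np.ndarray:
    if shape == "sphere":
        (r,) = params
        return sphere_intensity(s, r, I0)
    if shape == "two_sphere":
        r1, r2, sep = params
        return two_sphere_intensity(s, r1, r2, sep, I0)
    raise ValueError(f"unknown shape {shape!r}")


def simulate_saxs(
    shape: str = "sphere",
    params: tuple[float, ...] = (3.0,),
    I0: float = 1.0,
    s_grid: np.ndarray | None = None,
    concentrations: tuple[float, ...] | None = None,
    noise_scale: float = 0.0,
    noise_floor: float = 1e-4,
    structure_factor_b: float = 0.0,
    structure_factor_s0: float = 0.3,
    seed: int = 0,
) -> list[SAXSCurve]:
    """Simulate SAXS curves for a sphere or two-sphere body.

    With ``concentrations`` given, the measured intensity for a sample at
    concentration c (mg/mL) is ``c * I_form(s) * S(s, c)`` where
    ``S = 1 - b c exp(-(s/s0)^2)`` emulates a repulsive interparticle
    structure factor linear in concentration, so an I/c-vs-c
    extrapolation recovers the ideal form factor.  Errors follow
    ``sigma = noise_scale * (sqrt(I) + floor)``; Gaussian noise with
    that sigma is added when ``noise_scale > 0``.
    """
    if s_grid is None:
        s_grid = np.arange(0.025, 5.0, 0.01)
    s = np.asarray(s_grid, dtype=float)
    if np.any(s <= 0) or np.any(np.diff(s) <= 0):
        raise ValueError("s grid must be positive and ascending")
    form = _form_factor(shape, params, s, I0)
    rng = np.random.default_rng(seed)
    curves = []
    for c in (concentrations if concentrations is not None else [None]):
        if c is None:
            ideal = form.copy()
        else:
            sf = 1.0 - structure_factor_b * c * np.exp(-((s / structure_factor_s0) ** 2))
            ideal = c * form * sf
        sigma = noise_scale * (np.sqrt(np.abs(ideal)) + noise_floor)
        if noise_scale > 0:
            I = ideal + rng.normal(0.0, 1.0, size=s.size) * sigma
        else:
            I = ideal
            sigma = np.full_like(I, noise_floor * max(I0, 1.0))
        curves.append(SAXSCurve(s=s, I=I, sigma=sigma, concentration=c))
    return curves


def simulate_secsaxs_frames(
    components: list[SAXSCurve],
    mixing: np.ndarray,
    noise_scale: float = 0.0,
    noise_floor: float = 1e-4,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mix component curves into a SEC-SAXS frame matrix.

    ``mixing`` is (n_frames, n_components), non-negative.  Returns the
    frame intensity matrix and the matching per-bin sigma matrix used
    for error weighting downstream.
    """
    mixing = np.asarray(mixing, dtype=float)
    if np.any(mixing < 0):
        raise ValueError("mixing matrix must be non-negative")
    if mixing.shape[1] != len(components):
        raise ValueError("mixing columns must match number of components")
    comp = np.vstack([c.I for c in components])
    frames = mixing @ comp
    sigmas = noise_scale * (np.sqrt(np.abs(frames)) + noise_floor)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, 1.0, size=frames.shape) * sigmas
        frames = np.clip(frames, 0.0, None)
    else:
        sigmas = np.full_like(frames, noise_floor)
    return frames, sigmas


# ---------------------------------------------------------------------------
# NMR peak lists
# ---------------------------------------------------------------------------

def make_base_peaklist(
    sequence: str | None = None,
    start: int = CONSTRUCT_START,
    snr: float = 30.0,
    sharp_residues: tuple[int, ...] = (),
    sharp_height_frac: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Assigned 2D amide peak list for a synthetic construct.

    One peak per non-proline residue with realistic shift ranges
    (1H 6.5-10 ppm, 15N 103-130 ppm), log-normal heights and a common
    signal-to-noise ratio.  Residues in ``sharp_residues`` start with a
    reduced height (``sharp_height_frac`` of the median) and a 1H shift
    inside the random-coil window, emulating transiently unfolded
    termini.
    """
    if sequence is None:
        sequence = synthetic_construct_sequence()
    rng = np.random.default_rng(seed)
    rows = []
    median_h = 100.0
    for i, aa in enumerate(sequence):
        if aa == "P":
            continue
        res = start + i
        if res in sharp_residues:
            dh = rng.uniform(7.95, 8.55)
            dn = rng.uniform(118.0, 124.0)
            h = median_h * sharp_height_frac * rng.uniform(0.8, 1.2)
        else:
            dh = rng.uniform(6.5, 10.0)
            dn = rng.uniform(103.0, 130.0)
            h = median_h * rng.lognormal(0.0, 0.3)
        rows.append((f"{aa}{res}", dh, dn, h, snr))
    return pd.DataFrame(rows, columns=["assignment", "dH_ppm", "dN_ppm", "height", "snr"])


def _free_fraction(ratio: float, kd: float, p0: float) -> float:
    """Free-kinase fraction from single-site equilibrium at ligand:kinase
    molar ratio ``ratio`` and kinase concentration ``p0``."""
    l0 = ratio * p0
    b = p0 + l0 + kd
    bound = 0.5 * (b - np.sqrt(b * b - 4 * p0 * l0))
    return 1.0 - bound / p0


def simulate_titration_peaklists(
    base: pd.DataFrame,
    truth: GroundTruth,
    ratios: tuple[float, ...] = (0.25, 0.5),
    sharp_gain: float = 6.0,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Peak lists across a co-chaperone titration.

    For each ligand:kinase molar ratio the free fraction follows the
    single-site equilibrium at the truth (Kd, kinase concentration).
    Peak heights scale as ``f_free * beta_r ** f_bound`` where the
    residue-specific broadening factor ``beta_r`` (1 = stoichiometric
    attenuation only, 0 = broadened beyond detection in the complex)
    models intermediate-timescale exchange.  CSPs are applied in
    proportion to the bound fraction, and designated sharp random-coil
    peaks intensify linearly with the molar ratio.
    """
    if any(r < 0 for r in ratios):
        raise ValueError("molar ratios must be >= 0")
    kd, p0 = truth.titration
    out = []
    for ratio in ratios:
        df = base.copy()
        f_free = _free_fraction(ratio, kd, p0)
        f_bound = 1.0 - f_free
        res_numbers = df["assignment"].str.extract(r"(\d+)$")[0].astype(float)
        beta = res_numbers.map(lambda r: truth.broadening.get(int(r), 1.0)).to_numpy()
        # beta ** f_bound with 0**0 == 1: ratio 0 is an exact identity,
        # while beta == 0 wipes the peak out at any bound fraction.
        scale = f_free * np.power(beta, f_bound)
        df["height"] = df["height"] * scale
        for res, (ddh, ddn) in truth.csp.items():
            m = res_numbers == res
            df.loc[m, "dH_ppm"] += ddh * f_bound
            df.loc[m, "dN_ppm"] += ddn * f_bound
        sharp_mask = res_numbers.isin(truth.sharp_residues).to_numpy()
        df.loc[sharp_mask, "height"] = base.loc[sharp_mask, "height"] * (1.0 + sharp_gain * ratio)
        out.append(df)
    return out


# ---------------------------------------------------------------------------
# Densitometry lanes
# ---------------------------------------------------------------------------

def simulate_lane_table(
    truth: dict[str, float] | None = None,
    exposure_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Band-intensity table for complex-occupancy quantitation.

    Band intensity is proportional to species fraction times exposure;
    the occupancy estimator applied to noiseless output returns the true
    fraction exactly (and is invariant to the exposure scale).
    """
    if truth is None:
        truth = {"complex": 0.145, "free": 0.855}
    total = sum(truth.values())
    if not np.isclose(total, 1.0):
        raise ValueError("species fractions must sum to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for species, frac in truth.items():
        inten = frac * exposure_scale
        if noise_sd > 0:
            inten = max(0.0, inten + rng.normal(0.0, noise_sd * exposure_scale))
        rows.append(("lane1", species, inten))
    return pd.DataFrame(rows, columns=["lane", "species", "intensity"])
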