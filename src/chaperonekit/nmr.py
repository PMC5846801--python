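"""Peak-list-level NMR analyses.

Works on assigned 2D amide (1H-15N) peak lists: combined chemical-shift
perturbations, titration intensity attenuation, reference-peak height
normalization, simulated signal-to-noise confidence thresholds for
selective-unlabelling classification, and detection of emergent sharp
peaks in the random-coil region.

Peak lists are DataFrames with columns
``assignment, dH_ppm, dN_ppm, height, snr``; assignments are
residue-type + number strings (``G481``) or empty for unassigned peaks.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "CSP_N_WEIGHT",
    "DEFAULT_REF_RESIDUES",
    "DEFAULT_SNR_CLASSES",
    "RC_WINDOW_H",
    "match_peaks",
    "combined_csp",
    "normalize_heights",
    "intensity_ratio_profile",
    "simulate_ratio_thresholds",
    "classify_unlabelled",
    "detect_sharp_peaks",
]

#: Nitrogen weight in the combined amide shift: Dd = sqrt((0.2 DdN)^2 + DdH^2).
CSP_N_WEIGHT = 0.2

#: Glycine reference peaks used to put spectra on a common height scale.
DEFAULT_REF_RESIDUES = ("G481", "G533", "G549", "G574")

#: Signal-to-noise classes for which confidence thresholds are simulated.
DEFAULT_SNR_CLASSES = (30.0, 20.0, 10.0, 8.0)

#: Random-coil 1H chemical-shift window (ppm).
RC_WINDOW_H = (7.9, 8.6)

_RES_RE = re.compile(r"([A-Za-z]+)?(\d+)$")


def residue_number(assignment) -> float:
    """Residue number from an assignment string, NaN if unassigned."""
    if not isinstance(assignment, str):
        return np.nan
    m = _RES_RE.match(assignment.strip())
    return float(m.group(2)) if m else np.nan


def match_peaks(
    a: pd.DataFrame,
    b: pd.DataFrame,
    tol_H: float = 0.05,
    tol_N: float = 0.5,
) -> tuple[pd.DataFrame, pd.Index, pd.Index]:
    """Pair peaks between two lists.

    Peaks sharing an assignment are paired by identity.  Unassigned
    peaks are paired greedily by normalized distance within a
    (tol_H, tol_N) box, each peak used at most once; equidistant
    candidates resolve to the lower residue number (then lower row
    index).  Returns (pairs, unmatched_a, unmatched_b).
    """
    if a.empty or b.empty:
        raise ValueError("both peak lists must be non-empty")
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []

    bmap: dict[str, int] = {}
    for j, asg in b["assignment"].items():
        if isinstance(asg, str) and asg:
            bmap.setdefault(asg, j)
    for i, asg in a["assignment"].items():
        if isinstance(asg, str) and asg and asg in bmap:
            j = bmap[asg]
            rows.append((i, j))
            used_a.add(i)
            used_b.add(j)

    free_a = [i for i in a.index if i not in used_a]
    free_b = [j for j in b.index if j not in used_b]
    cands = []
    for i in free_a:
        dh = np.abs(b.loc[free_b, "dH_ppm"].to_numpy() - a.at[i, "dH_ppm"])
        dn = np.abs(b.loc[free_b, "dN_ppm"].to_numpy() - a.at[i, "dN_ppm"])
        inside = (dh <= tol_H) & (dn <= tol_N)
        dist = np.sqrt((dh / tol_H) ** 2 + (dn / tol_N) ** 2)
        for j, ok, d in zip(free_b, inside, dist):
            if ok:
                tie = residue_number(b.at[j, "assignment"])
                cands.append((d, np.inf if np.isnan(tie) else tie, i, j))
    for d, _, i, j in sorted(cands, key=lambda t: (t[0], t[1], t[2], t[3])):
        if i in used_a or j in used_b:
            continue
        rows.append((i, j))
        used_a.add(i)
        used_b.add(j)

    pairs = pd.DataFrame(
        {
            "assignment": [a.at[i, "assignment"] or b.at[j, "assignment"] for i, j in rows],
            "dH_a": [a.at[i, "dH_ppm"] for i, _ in rows],
            "dN_a": [a.at[i, "dN_ppm"] for i, _ in rows],
            "height_a": [a.at[i, "height"] for i, _ in rows],
            "dH_b": [b.at[j, "dH_ppm"] for _, j in rows],
            "dN_b": [b.at[j, "dN_ppm"] for _, j in rows],
            "height_b": [b.at[j, "height"] for _, j in rows],
            "snr_a": [a.at[i, "snr"] for i, _ in rows],
            "snr_b": [b.at[j, "snr"] for _, j in rows],
            "index_a": [i for i, _ in rows],
            "index_b": [j for _, j in rows],
        }
    )
    unmatched_a = a.index.difference(list(used_a))
    unmatched_b = b.index.difference(list(used_b))
    return pairs, unmatched_a, unmatched_b


def combined_csp(pairs: pd.DataFrame, weight_N: float = CSP_N_WEIGHT) -> pd.DataFrame:
    """Combined amide chemical-shift perturbation per paired peak:
    ``csp = sqrt((weight_N * DdN)^2 + DdH^2)`` (ppm)."""
    ddh = pairs["dH_b"] - pairs["dH_a"]
    ddn = pairs["dN_b"] - pairs["dN_a"]
    out = pd.DataFrame({
        "assignment": pairs["assignment"],
        "residue": pairs["assignment"].map(residue_number),
        "delta_dH": ddh,
        "delta_dN": ddn,
        "csp": np.sqrt((weight_N * ddn) ** 2 + ddh**2),
    })
    return out


def normalize_heights(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    ref_residues: tuple[str, ...] = DEFAULT_REF_RESIDUES,
) -> tuple[float, pd.DataFrame]:
    """Scale sample peak heights onto the reference spectrum's scale.

    The scale factor is the mean over the reference residues of
    (reference height / sample height); after multiplication the
    reference-peak ratios average to 1.  Missing reference residues
    raise an error naming them.
    """
    s_idx = sample.set_index("assignment")
    r_idx = reference.set_index("assignment")
    ratios = []
    for res in ref_residues:
        if res not in s_idx.index:
            raise ValueError(f"reference residue {res} missing from sample peak list")
        if res not in r_idx.index:
            raise ValueError(f"reference residue {res} missing from reference peak list")
        ratios.append(float(r_idx.at[res, "height"]) / float(s_idx.at[res, "height"]))
    scale = float(np.mean(ratios))
    out = sample.copy()
    out["height"] = out["height"] * scale
    return scale, out


def intensity_ratio_profile(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    molar_ratio: float | None = None,
    kd: float | None = None,
    conc: float | None = None,
    attenuation_margin: float = 0.2,
    tol_H: float = 0.05,
    tol_N: float = 0.5,
) -> pd.DataFrame:
    """Per-residue height ratio sample / reference.

    1 means equivalent intensities, 0 a peak absent from the sample
    (completely unlabelled, or broadened beyond detection).  With a
    molar ratio, Kd and concentration, the expected residual free-state
    intensity from the single-site equilibrium is attached and peaks
    attenuated below ``expected * (1 - margin)`` are flagged (evidence
    of exchange broadening beyond simple stoichiometry).
    """
    pairs, _, ref_only = match_peaks(sample, reference, tol_H, tol_N)
    recs = pd.DataFrame({
        "assignment": pairs["assignment"],
        "residue": pairs["assignment"].map(residue_number),
        "ratio": pairs["height_a"] / pairs["height_b"],
        "snr": pairs["snr_a"],
    })
    # reference peaks with no sample counterpart: completely attenuated
    missing = reference.reset_index(drop=True).loc[ref_only]
    if not missing.empty:
        recs = pd.concat([recs, pd.DataFrame({
            "assignment": missing["assignment"],
            "residue": missing["assignment"].map(residue_number),
            "ratio": 0.0,
            "snr": 0.0,
        })], ignore_index=True)
    if molar_ratio is not None and kd is not None and conc is not None:
        l0 = molar_ratio * conc
        bsum = conc + l0 + kd
        bound = 0.5 * (bsum - np.sqrt(bsum * bsum - 4 * conc * l0))
        expected = 1.0 - bound / conc
        recs["expected_free_fraction"] = expected
        recs["attenuated"] = recs["ratio"] < expected * (1.0 - attenuation_margin)
    return recs.reset_index(drop=True)


def simulate_ratio_thresholds(
    snr_levels: tuple[float, ...] = DEFAULT_SNR_CLASSES,
    n_sim: int = 100_000,
    seed: int = 0,
    true_height: float = 100.0,
) -> dict[float, float]:
    """Confidence thresholds for peak-height ratios at given S/N levels.

    For each S/N, two peak heights are drawn as Normal(A, A/snr), their
    ratio formed ``n_sim`` times, and the threshold taken as
    mean - 3 * sd.  Ratios below the threshold are confidently below
    parity (e.g. successfully unlabelled residues).  Results are
    scale-free in A and deterministic under a fixed seed.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for stable thresholds")
    out: dict[float, float] = {}
    rng = np.random.default_rng(seed)
    for snr in snr_levels:
        if snr <= 0:
            raise ValueError("snr must be > 0")
        a = true_height + rng.normal(0.0, true_height / snr, n_sim)
        b = true_height + rng.normal(0.0, true_height / snr, n_sim)
        ratio = a / b
        out[snr] = float(ratio.mean() - 3.0 * ratio.std())
    return out


def classify_unlabelled(
    ratios: pd.DataFrame,
    thresholds: dict[float, float],
) -> pd.DataFrame:
    """Call residues unlabelled when their height ratio falls below the
    confidence threshold of their S/N class.

    Each record's S/N maps to the nearest configured class *rounding
    down* (an S/N of 25 is judged against the 20 threshold); values
    below the lowest class use the lowest class.
    """
    classes = np.array(sorted(thresholds), dtype=float)
    out = ratios.copy()

    def snr_class(snr: float) -> float:
        below = classes[classes <= snr]
        return float(below[-1]) if below.size else float(classes[0])

    out["snr_class"] = out["snr"].map(snr_class)
    out["threshold"] = out["snr_class"].map(lambda c: thresholds[c])
    out["call"] = np.where(out["ratio"] < out["threshold"], "unlabelled", "labelled")
    return out


def detect_sharp_peaks(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    rc_window_H: tuple[float, float] = RC_WINDOW_H,
    height_quantile: float = 0.5,
    tol_H: float = 0.05,
    tol_N: float = 0.5,
) -> pd.DataFrame:
    """Emergent sharp peaks in the random-coil region.

    Returns sample peaks whose 1H shift lies inside ``rc_window_H``,
    whose height exceeds the given quantile of matched-peak heights and
    which have no reference counterpart within tolerance, or whose
    reference counterpart is at least 2x weaker (intensification).
    Ranked by height, rank 1 = most intense.
    """
    pairs, unmatched_a, _ = match_peaks(sample, reference, tol_H, tol_N)
    if pairs.empty:
        cutoff = 0.0
    else:
        cutoff = float(np.quantile(pairs["height_a"], height_quantile))
    lo, hi = rc_window_H
    cands = []
    matched_by_a = dict(zip(pairs["index_a"], pairs["height_b"]))
    for i, row in sample.reset_index(drop=True).iterrows():
        if not lo <= row["dH_ppm"] <= hi:
            continue
        if row["height"] <= cutoff:
            continue
        ref_h = matched_by_a.get(i)
        if ref_h is not None and row["height"] < 2.0 * ref_h:
            continue  # present and not notably intensified
        cands.append((row["assignment"], row["dH_ppm"], row["dN_ppm"], row["height"]))
    out = pd.DataFrame(cands, columns=["assignment", "dH_ppm", "dN_ppm", "height"])
    out = out.sort_values("height", ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
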