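"""Differential HDX-MS analysis.

Operates on peptide-level relative-deuteration tables (long format, one
row per replicate measurement) and produces free-vs-complex difference
maps, significance classes, a residue-level consolidation and protected
/ deprotected interval lists.

Sign convention: the stored difference is ``delta_D = bound - free``,
so *negative* values mean protection (slower exchange in the complex)
and positive values deprotection.  Reports can flip to the
free-minus-complex convention at the presentation layer.

Time points are stored as 22 degC-equivalent seconds; a 3 s on-ice
labelling pulse (exchange ~tenfold slower) is ingested as 0.3 s.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_THRESHOLD_PCT",
    "qc_filter",
    "uptake_stats",
    "differential_uptake",
    "select_max_difference",
    "classify",
    "consolidate_residues",
    "extract_intervals",
]

#: Significance threshold on |delta_D| in percentage points: a peptide
#: changes significantly when its uptake difference exceeds 5 %.
DEFAULT_THRESHOLD_PCT = 5.0

GROUP_KEYS = ["peptide_id", "start", "end", "sequence", "state", "timepoint_s"]


def qc_filter(peptides: pd.DataFrame, min_score: float = 10.0) -> pd.DataFrame:
    """Remove peptides with identification score <= ``min_score``.

    Duplicate ``peptide_id`` entries with differing scores keep the
    max-score instance.  Raises if nothing survives.
    """
    if "score" not in peptides.columns:
        raise ValueError("peptide table lacks a 'score' column")
    kept = peptides[peptides["score"] > min_score].copy()
    removed = len(peptides) - len(kept)
    if kept.empty:
        raise ValueError(f"score filter (<= {min_score}) removed all peptides")
    # keep only rows belonging to the max-score instance of each peptide_id
    max_score = kept.groupby("peptide_id")["score"].transform("max")
    kept = kept[kept["score"] == max_score]
    if removed:
        warnings.warn(f"score filter removed {removed} rows", stacklevel=2)
    return kept


def uptake_stats(replicate_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of relative deuteration per
    (peptide, state, time point) group.

    Groups with a single replicate get sd = NaN with a warning.
    """
    g = replicate_table.groupby(GROUP_KEYS, as_index=False)["deuteration_pct"]
    out = g.agg(mean_D="mean", sd_D=lambda v: v.std(ddof=1), n="count")
    if (out["n"] == 1).any():
        warnings.warn(
            f"{int((out['n'] == 1).sum())} groups have a single replicate; "
            "sd undefined", stacklevel=2)
    return out


def differential_uptake(
    free: pd.DataFrame,
    bound: pd.DataFrame,
    timepoint: float | None = None,
) -> pd.DataFrame:
    """Per-peptide uptake difference ``delta_D = bound - free``.

    Inputs are replicate tables or the output of :func:`uptake_stats`;
    peptides present in only one state are dropped with a warning.
    ``sd_pooled = sqrt(sd_free^2 + sd_bound^2)``.
    """
    def prep(df):
        if "mean_D" not in df.columns:
            df = uptake_stats(df)
        if timepoint is not None:
            df = df[np.isclose(df["timepoint_s"], timepoint)]
        return df

    f, b = prep(free), prep(bound)
    merged = f.merge(b, on=["peptide_id", "start", "end", "sequence", "timepoint_s"],
                     suffixes=("_free", "_bound"))
    if merged.empty:
        raise ValueError("no common peptides between free and bound datasets")
    n_drop = max(len(f), len(b)) - len(merged)
    if n_drop:
        warnings.warn(f"{n_drop} peptide/timepoint groups unmatched between states",
                      stacklevel=2)
    out = merged[["peptide_id", "start", "end", "sequence", "timepoint_s"]].copy()
    out["delta_D"] = merged["mean_D_bound"] - merged["mean_D_free"]
    out["sd_pooled"] = np.sqrt(merged["sd_D_free"] ** 2 + merged["sd_D_bound"] ** 2)
    out["significant"] = False
    out["direction"] = "no-change"
    return out


def select_max_difference(records: pd.DataFrame) -> pd.DataFrame:
    """Per peptide, keep the time point with the largest |delta_D|
    (ties broken by the earliest time point)."""
    df = records.copy()
    df["_absd"] = df["delta_D"].abs()
    df = df.sort_values(["peptide_id", "_absd", "timepoint_s"],
                        ascending=[True, False, True], kind="mergesort")
    out = df.groupby("peptide_id", as_index=False).head(1).drop(columns="_absd")
    return out.sort_values("start").reset_index(drop=True)


def classify(records: pd.DataFrame,
             threshold_pct: float = DEFAULT_THRESHOLD_PCT,
             replicate_aware: bool = False,
             sd_multiple: float = 2.0) -> pd.DataFrame:
    """Mark significant differences and assign a direction.

    Significant iff ``|delta_D| > threshold_pct`` (strict: a change of
    exactly the threshold is not significant).  With
    ``replicate_aware`` the difference must additionally exceed
    ``sd_multiple * sd_pooled``.  Direction is ``protected`` for
    negative delta_D (bound exchanges less), ``deprotected`` for
    positive, else ``no-change``.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be > 0")
    out = records.copy()
    sig = out["delta_D"].abs() > threshold_pct
    if replicate_aware:
        sig &= out["delta_D"].abs() > sd_multiple * out["sd_pooled"].fillna(0.0)
    out["significant"] = sig
    out["direction"] = np.where(~sig, "no-change",
                                np.where(out["delta_D"] < 0, "protected", "deprotected"))
    return out


def _exchangeable(start: int, end: int, sequence: str) -> list[int]:
    return [r for i, (r, aa) in enumerate(zip(range(start, end + 1), sequence))
            if i > 0 and aa != "P"]


def consolidate_residues(
    classified: pd.DataFrame,
    construct_range: tuple[int, int],
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Collapse peptide-level differences onto residues.

    Each residue's consolidated delta_D is the weighted mean over the
    peptides whose exchange-observable span (first residue and prolines
    excluded) covers it, weighting each peptide by 1 / N_exch so that
    shorter, higher-resolution peptides dominate.  The residue class is
    re-derived from the consolidated delta_D with the same threshold;
    residues covered by no peptide are 'no-coverage'.

    Returns a DataFrame with one row per residue of the construct:
    ``residue, delta_D, n_peptides, cls``.
    """
    lo, hi = construct_range
    acc = {r: [0.0, 0.0, 0] for r in range(lo, hi + 1)}  # wsum, w, count
    for row in classified.itertuples():
        exch = _exchangeable(row.start, row.end, row.sequence)
        if not exch:
            continue
        w = 1.0 / len(exch)
        for r in exch:
            if lo <= r <= hi:
                a = acc[r]
                a[0] += w * row.delta_D
                a[1] += w
                a[2] += 1
    rows = []
    for r in range(lo, hi + 1):
        wsum, w, n = acc[r]
        if n == 0:
            rows.append((r, np.nan, 0, "no-coverage"))
            continue
        d = wsum / w
        if abs(d) > threshold_pct:
            cls = "protected" if d < 0 else "deprotected"
        else:
            cls = "no-change"
        rows.append((r, d, n, cls))
    return pd.DataFrame(rows, columns=["residue", "delta_D", "n_peptides", "cls"])


def extract_intervals(
    residue_map: pd.DataFrame,
    cls: str,
    min_len: int = 3,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residues of class ``cls`` with length
    >= ``min_len``, as 1-based inclusive (start, end) pairs."""
    valid = {"protected", "deprotected", "no-change", "no-coverage"}
    if cls not in valid:
        raise ValueError(f"unknown class {cls!r}")
    residues = residue_map.loc[residue_map["cls"] == cls, "residue"].to_numpy()
    if residues.size == 0:
        return []
    residues = np.sort(residues)
    breaks = np.where(np.diff(residues) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [residues.size - 1]])
    return [(int(residues[a]), int(residues[b]))
            for a, b in zip(starts, ends)
            if residues[b] - residues[a] + 1 >= min_len]
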