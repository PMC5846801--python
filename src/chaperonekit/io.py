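"""Readers and writers for the plain-text formats the pipeline consumes.

All formats round-trip losslessly and validate strictly, reporting the
offending line number on malformed input:

* uptake CSV — ``peptide_id,start,end,sequence,state,timepoint_s,
  replicate,deuteration_pct,score`` with an optional ``condition``
  column (``ice`` rows are converted to 22 degC-equivalent seconds by
  dividing by the tenfold on-ice slowdown);
* peak-list CSV — ``assignment,dH_ppm,dN_ppm,height,snr``;
* 3-column whitespace ``.dat`` (s nm^-1, I, sigma), tolerant of leading
  header/comment lines (the de facto SASBDB/ATSAS exchange layout);
* ITC CSV — ``injection,volume_uL,heat_ucal`` preceded by ``#``
  metadata lines for the cell geometry;
* melt CSV — ``temperature_C,fluorescence``;
* restraint text as written by
  :meth:`chaperonekit.saxs.ContactRestraintSet.to_text`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import ITCThermogram, MeltCurve
from .saxs import SAXSCurve

__all__ = [
    "effective_timepoint",
    "read_uptake_csv", "write_uptake_csv",
    "read_peaklist_csv", "write_peaklist_csv",
    "read_dat", "write_dat",
    "read_itc_csv", "write_itc_csv",
    "read_melt_csv", "write_melt_csv",
    "write_ground_truth", "read_ground_truth",
]

UPTAKE_COLUMNS = ["peptide_id", "start", "end", "sequence", "state",
                  "timepoint_s", "replicate", "deuteration_pct", "score"]
PEAKLIST_COLUMNS = ["assignment", "dH_ppm", "dN_ppm", "height", "snr"]

from .syndata import ICE_SLOWDOWN  # noqa: E402  (single source for the factor)


def effective_timepoint(timepoint_s: float, condition: str = "22C") -> float:
    """22 degC-equivalent labelling time.

    A pulse on ice exchanges ~tenfold slower, so a 3 s on-ice point is
    equivalent to exactly 0.3 s at 22 degC.
    """
    cond = condition.strip().lower()
    if cond in ("ice", "0c", "on-ice", "on_ice"):
        return timepoint_s / ICE_SLOWDOWN
    if cond in ("22c", "rt", "ambient", ""):
        return timepoint_s
    raise ValueError(f"unknown incubation condition {condition!r}")


def read_uptake_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing uptake columns {missing}")
    bad = df[(df["deuteration_pct"] < -5) | (df["deuteration_pct"] > 105)]
    if not bad.empty:
        # +2 for header line and 1-based numbering
        raise ValueError(
            f"{path}: deuteration out of range at line {int(bad.index[0]) + 2}")
    if (df["start"] > df["end"]).any():
        row = df.index[df["start"] > df["end"]][0]
        raise ValueError(f"{path}: start > end at line {int(row) + 2}")
    if "condition" in df.columns:
        df["timepoint_s"] = [
            effective_timepoint(t, c)
            for t, c in zip(df["timepoint_s"], df["condition"].fillna("22C"))
        ]
        df = df.drop(columns=["condition"])
    return df


def write_uptake_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in UPTAKE_COLUMNS if c in df.columns])


def read_peaklist_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PEAKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing peak-list columns {missing}")
    if (df["height"] < 0).any():
        row = df.index[df["height"] < 0][0]
        raise ValueError(f"{path}: negative height at line {int(row) + 2}")
    return df


def write_peaklist_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PEAKLIST_COLUMNS)


def read_dat(path, concentration: float | None = None) -> SAXSCurve:
    """Read a 3-column (s, I, sigma) text file.

    Leading lines that do not parse as three floats are kept as header
    comments; once data rows begin, an unparsable line is an error
    naming the line number.
    """
    header: list[str] = []
    s, I, sig = [], [], []
    in_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                if in_data:
                    break  # trailing blank ends the data block
                continue
            parts = stripped.split()
            try:
                vals = [float(p) for p in parts[:3]]
                if len(vals) != 3:
                    raise ValueError
            except ValueError:
                if in_data:
                    raise ValueError(f"{path}: malformed data row at line {lineno}") from None
                header.append(stripped)
                continue
            in_data = True
            s.append(vals[0])
            I.append(vals[1])
            sig.append(vals[2])
    if not s:
        raise ValueError(f"{path}: no data rows found")
    return SAXSCurve(np.array(s), np.array(I), np.array(sig),
                     concentration=concentration, header=header)


def write_dat(curve: SAXSCurve, path) -> None:
    with open(path, "w") as fh:
        for h in curve.header:
            fh.write(h if h.startswith("#") else f"# {h}")
            fh.write("\n")
        if curve.concentration is not None:
            fh.write(f"# concentration_mg_ml: {curve.concentration}\n")
        sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.s)
        for row in zip(curve.s, curve.I, sig):
            fh.write("%.8e %.8e %.8e\n" % row)


def read_itc_csv(path) -> ITCThermogram:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = float(val)
            data_start = i + 1
        else:
            break
    df = pd.read_csv(path, skiprows=data_start, float_precision="round_trip")
    for col in ("injection", "volume_uL", "heat_ucal"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing ITC column {col}")
    required = ("cell_volume_mL", "cell_conc_M", "syringe_conc_M")
    for key in required:
        if key not in meta:
            raise ValueError(f"{path}: missing metadata line '# {key}=...'")
    return ITCThermogram(
        cell_volume_ml=meta["cell_volume_mL"],
        cell_conc=meta["cell_conc_M"],
        syringe_conc=meta["syringe_conc_M"],
        injection_volumes_ul=df["volume_uL"].to_numpy(),
        heats_ucal=df["heat_ucal"].to_numpy(),
        temperature_K=meta.get("temperature_K", 293.15),
    )


def write_itc_csv(tg: ITCThermogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_mL={tg.cell_volume_ml}\n")
        fh.write(f"# cell_conc_M={tg.cell_conc}\n")
        fh.write(f"# syringe_conc_M={tg.syringe_conc}\n")
        fh.write(f"# temperature_K={tg.temperature_K}\n")
        fh.write("injection,volume_uL,heat_ucal\n")
        for i, (v, q) in enumerate(zip(tg.injection_volumes_ul, tg.heats_ucal), 1):
            fh.write(f"{i},{float(v)!r},{float(q)!r}\n")


def read_melt_csv(path) -> MeltCurve:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    for col in ("temperature_C", "fluorescence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing melt column {col}")
    return MeltCurve(T=df["temperature_C"].to_numpy(), F=df["fluorescence"].to_numpy())


def write_melt_csv(curve: MeltCurve, path, plate_meta: str | None = None) -> None:
    with open(path, "w") as fh:
        if plate_meta:
            fh.write(f"# {plate_meta}\n")
        fh.write("temperature_C,fluorescence\n")
        for t, f in zip(curve.T, curve.F):
            fh.write(f"{float(t)!r},{float(f)!r}\n")


def write_ground_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2, sort_keys=True))


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
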