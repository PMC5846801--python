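"""Mapping residue-level HDX classes onto structure coordinates.

Writes the consolidated protection class into the B-factor column of a
PDB file so the map can be rendered in any molecular viewer:

* protected residues carry ``-|delta_D|`` (more negative = stronger
  protection),
* deprotected residues ``+|delta_D|``,
* no-change residues 0,
* residues without peptide coverage the sentinel value
  :data:`NO_COVERAGE_BFACTOR`.

Construct and PDB numbering are reconciled with an explicit integer
offset per chain (``pdb_resnum = construct_resnum + offset``).
"""

from __future__ import annotations

import warnings

import gemmi
import pandas as pd

__all__ = ["NO_COVERAGE_BFACTOR", "map_classes_to_structure"]

NO_COVERAGE_BFACTOR = 999.0


def map_classes_to_structure(
    residue_map: pd.DataFrame,
    pdb_path,
    out_path,
    chain: str = "A",
    numbering_offset: int = 0,
    max_unmapped_frac: float = 0.20,
) -> dict:
    """Annotate a PDB chain with HDX classes via the B-factor column.

    ``residue_map`` is the per-residue consolidation (columns
    ``residue, delta_D, cls``).  Residues of the chain that have no
    entry in the map are logged and counted; more than
    ``max_unmapped_frac`` unmappable residues is an error.  Returns a
    summary dict with per-class counts.
    """
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    model = st[0]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise ValueError(f"chain {chain!r} not found in {pdb_path}")

    codes = {}
    for row in residue_map.itertuples():
        if row.cls == "protected":
            b = -abs(row.delta_D)
        elif row.cls == "deprotected":
            b = abs(row.delta_D)
        elif row.cls == "no-change":
            b = 0.0
        else:
            b = NO_COVERAGE_BFACTOR
        codes[int(row.residue) + numbering_offset] = (b, row.cls)

    counts = {"protected": 0, "deprotected": 0, "no-change": 0,
              "no-coverage": 0, "unmapped": 0}
    n_res = 0
    for res in target:
        n_res += 1
        num = res.seqid.num
        if num in codes:
            b, cls = codes[num]
            counts[cls] += 1
        else:
            b = NO_COVERAGE_BFACTOR
            counts["unmapped"] += 1
        for atom in res:
            atom.b_iso = b
    if n_res == 0:
        raise ValueError(f"chain {chain!r} has no residues")
    frac = counts["unmapped"] / n_res
    if frac > max_unmapped_frac:
        raise ValueError(
            f"{counts['unmapped']}/{n_res} residues unmappable "
            f"({100 * frac:.0f} % > {100 * max_unmapped_frac:.0f} %)")
    if counts["unmapped"]:
        warnings.warn(f"{counts['unmapped']} chain residues had no class entry",
                      stacklevel=2)
    st.write_pdb(str(out_path))
    counts["n_residues"] = n_res
    return counts
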