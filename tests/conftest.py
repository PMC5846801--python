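import gemmi
import numpy as np
import pandas as pd
import pytest

from chaperonekit import syndata


@pytest.fixture(scope="session")
def truth():
    return syndata.default_ground_truth()


@pytest.fixture(scope="session")
def sequence():
    return syndata.synthetic_construct_sequence()


@pytest.fixture(scope="session")
def peptide_map(sequence):
    return syndata.segmented_peptide_map(sequence)


@pytest.fixture(scope="session")
def designed_classes():
    """residue -> designed HDX class for the default ground truth."""
    out = {}
    for lo, hi in syndata.PROTECTED_BLOCKS:
        out.update({r: "protected" for r in range(lo, hi + 1)})
    for lo, hi in syndata.DEPROTECTED_BLOCKS:
        out.update({r: "deprotected" for r in range(lo, hi + 1)})
    return out


@pytest.fixture()
def ca_trace_pdb(tmp_path):
    """Minimal CA-trace PDB for the kinase construct, written on demand."""
    st = gemmi.Structure()
    st.name = "synthetic kinase trace"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, res_num in enumerate(range(syndata.CONSTRUCT_START, syndata.CONSTRUCT_END + 1)):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(res_num, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(i * 1.5, 0.0, 0.0)
        atom.occ = 1.0
        atom.b_iso = 20.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    path = tmp_path / "trace.pdb"
    st.write_pdb(str(path))
    return path


def hdx_residue_map(free, bound, timepoints=(0.3, 3.0, 30.0, 300.0),
                    construct_range=(455, 768)):
    """Shared helper: full differential-HDX chain to a residue map."""
    from chaperonekit import hdx

    records = pd.concat(
        [hdx.differential_uptake(free, bound, timepoint=t) for t in timepoints],
        ignore_index=True)
    best = hdx.classify(hdx.select_max_difference(records))
    return hdx.consolidate_residues(best, construct_range)
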