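# chaperonekit

Quantitative analysis of how strongly a protein kinase is recognized by
the Hsp90/Cdc37 chaperone system, and of the structural remodelling the
co-chaperone induces.  Destabilized kinase variants — for example
disease-linked point mutants of a receptor tyrosine kinase domain —
become "stronger clients": they bind the kinase-specific co-chaperone
Cdc37 more tightly, melt at lower temperature, and are handed on to
Hsp90 for protection and refolding.  Characterizing this requires a
battery of orthogonal solution methods, each with its own quantitative
pipeline.  `chaperonekit` implements those pipelines as one tested
package for structural biologists working with HDX-MS, NMR, SAXS, ITC
and thermal-shift data on protein-protein complexes:

* **Differential HDX-MS** — peptide-level relative deuteration
  statistics, free-vs-complex difference maps (ΔD = D_bound − D_free),
  the |ΔD| > 5 % significance rule with max-time-point selection,
  residue-level consolidation, and extraction of protected /
  deprotected intervals that feed contact restraints for rigid-body
  modelling.
* **NMR peak-list analyses** — combined amide chemical-shift
  perturbations Δδ = √((0.2·Δδ₁₅N)² + Δδ₁H²), titration intensity
  ratios against the single-site expectation, reference-peak height
  normalization, Monte-Carlo confidence thresholds (mean − 3σ of
  simulated height ratios at S/N 30/20/10/8) for selective-unlabelling
  calls, and detection of emergent sharp random-coil peaks.
* **Primary SAXS** — Guinier fit (s·Rg ≤ 1.3 window, with curvature
  correction), regularized indirect Fourier transform to P(r) and
  D_max, Porod-invariant particle volume V = 2π²I(0)/Q, molecular mass
  against a 66 kDa reference, zero-concentration extrapolation of
  dilution series, and error-weighted NMF deconvolution of SEC-SAXS
  frame matrices with Rg-based component selection.
* **Binding & stability** — single-site (Wiseman) ITC fitting with
  displacement-dilution bookkeeping and low-c reliability diagnostics,
  thermofluor T_m by smoothed-derivative inflection or Boltzmann fit,
  complex-occupancy quantitation from band densitometry, and
  dose-equivalence interpolation between inhibition curves.
* **Synthetic data** — every input type can be generated from known
  ground truth (two-state HDX kinetics with per-residue protection
  factors, Wiseman thermograms, sigmoid melts, sphere/two-body
  scattering, titration peak lists, lane tables), so each analysis
  stage is testable by parameter recovery.

## Worked example

Generate a synthetic bundle (HDX uptake tables, ITC thermogram, melt
curve, SAXS dilution series, peak lists, lane table plus a ground-truth
sidecar), then analyze it:

```bash
chaperonekit synth --out demo --seed 0
chaperonekit hdx --free demo/hdx_free.csv --bound demo/hdx_bound.csv --out demo/diff.csv
chaperonekit itc demo/itc.csv --out demo/itc_fit.json
chaperonekit melt demo/melt.csv
```

which prints

```
protected: 592-602, 611-628, 670-684, 732-752
deprotected: 464-492, 500-535
{
  "n": 1.0061545191015513,
  "Kd_M": 2.1299040904375187e-06,
  "dH_kcal_mol": -9.488244833052022,
  ...
}
Tm = 55.14 C (derivative)
```

The HDX stage recovers exactly the protection blocks designed into the
ground truth: four C-lobe intervals that gain protection on
co-chaperone binding (the candidate interaction surface) and the
N-lobe stretches that become *more* exchanging (remodelling).  The ITC
fit recovers the designed K_d = 1.8 µM (here 2.1 µM from one noisy
thermogram) and 1:1 stoichiometry, and the melt analysis returns the
designed T_m of 55 °C to within the 1 °C grid.  The same stages run on real uptake CSVs, `.dat` curves and
thermogram tables with the formats described in the module docstrings
(`chaperonekit.io`).

The library surface mirrors the CLI, e.g.:

```python
from chaperonekit import saxs, syndata

curve = syndata.simulate_saxs("sphere", (3.0,), 1.0)[0]
g = saxs.guinier_fit(curve)          # g.Rg ~ 2.324 nm, g.I0 ~ 1.0
pr = saxs.ift_pr(curve, Dmax=6.0)    # P(r) with real-space Rg and I(0)
```

## Restraint file format

`saxs.build_contact_restraints` writes a fixed-column text table, one
restraint per line:

```
# molecule  start  end  target
kinase        607   624  contact cochaperone
cochaperone     4    28  contact kinase or other-domain-of-cochaperone
```

columns: molecule name, 1-based inclusive interval, target clause —
directly consumable as input for rigid-body modelling runs.
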