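# editquant

Quantitative readouts of genome-editing outcomes from three complementary
bench assays, plus ground-truth simulators for all of them.

When a programmable nuclease (a TALEN pair or an RNA-guided FokI nuclease)
cuts a genomic locus, the double-strand break is repaired either by
non-homologous end joining (NHEJ), leaving indels, or by homology-directed
repair (HDR) from a template. `editquant` implements the downstream
quantification:

- **`editquant.melt`** — quantitative high-resolution melting analysis
  (HRMA). Melt profiles are windowed and normalized to [0, 1], the control
  profile is subtracted from each test profile, and the *difference curve
  area* DCA = ∫ |F_test(T) − F_control(T)| dT is calibrated against known
  mutant percentages with a second-order polynomial standard curve,
  DCA = a·p² + b·p + c, inverted analytically to estimate the mutant
  fraction p of an unknown sample.
- **`editquant.taqman`** — efficiency-corrected relative quantification.
  Amplification efficiency E = 10^(−1/slope) from a dilution series, then
  the Pfaffl ratio E_target^ΔCq_target / E_ref^ΔCq_ref (ΔCq = control −
  sample) with delta-method uncertainties; anchored on the unedited control
  the ratio reads as the remnant wild-type fraction.
- **`editquant.repair`** — partition of repair into pathway frequencies
  from a probe panel: N = (Ec−Eb)/Ec (NHEJ), HN = (Ec−Ed_hom)/Ec (NHEJ+HDR),
  HDR_a = (HN−N)/Ec, HDR_t = (Ec−Ed_het)/Ec (true HDR, via a heterologous
  probe lost only on donor integration), %HDR_t = 100·HDR_t/HN.
- **`editquant.ngs`** — amplicon deep-sequencing indel classification:
  primer-anchored target extraction (both strands), Levenshtein edit
  distance to the wild-type segment, and a stringency cutoff that absorbs
  sequencing-error background; per-locus mutation percentages, unique indel
  sets and size spectra.
- **`editquant.synthetic`** — simulators with known truth: logistic
  two-state melt curves and mixtures, Cq tables from the exponential
  amplification law, and amplicon read sets with injected indels and
  substitution error.
- **`editquant.workbench`** — staged end-to-end runs with a JSON manifest,
  and reproduction of the packaged reference calibration/probe-panel data.

## Worked example

`examples/` contains one short script per capability. For instance:

```sh
$ python examples/repair_partition.py
          condition    N   HN  HDR_a  HDR_t  pct_HDR_t flags
pSQT1313-F8S2 Cl.10 0.68 1.00   0.32   0.44  44.000000
pSQT1313-F8S2 Cl.11 0.51 0.96   0.45   0.41  42.708333

pSQT1313-F8S2 Cl.10: 44.00 % of combined repair is true HDR
pSQT1313-F8S2 Cl.11: 42.71 % of combined repair is true HDR
```

Reading: for clone 10, 68 % of target sites were repaired by NHEJ when only
a backbone plasmid was present; with a donor template, all detectable targets
(HN = 1.00) were modified, and the heterologous probe attributes a 0.44
frequency to genuine donor integration — so 44 % of the combined repair went
through the HDR pathway.

```sh
$ python examples/hrma_standard_curve.py
nominal   0.0 %  ->  DCA 0.000
nominal  50.0 %  ->  DCA 0.750
...
standard curve r^2 = 1.0000 (...)
unknown sample: DCA 0.525 -> estimated 35.0 % mutant (true 35.0 %)
```

The DCA grows monotonically with the mutant share of the template; inverting
the fitted standard curve recovers an unknown mix's composition.

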