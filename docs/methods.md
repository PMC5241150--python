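# Methods

This note documents the models behind each module, the defaults and why they
were chosen, what the simulators do and do not emulate, and the numerical
conventions at the edges.

## Quantitative HRMA (`editquant.melt`)

**Model.** A melt profile is raw fluorescence F(T) on a uniform temperature
grid (the acquisition convention modelled throughout is 70–95 °C in 0.2 °C
steps, 126 points). Within a user-chosen analysis window [T_low, T_high] the
profile is normalized as

    F̃(T) = (F(T) − F(T_high)) / max_T (F(T) − F(T_high)),

so the post-melt baseline is 0 and the pre-melt maximum is 1. Normalization
is invariant under positive affine transforms of F, which is what makes
profiles from wells with different absolute dye signal comparable. The
difference curve of a test sample against a control is Δ(T) = F̃_test −
F̃_control, and its area

    DCA = ∫ |Δ(T)| dT   (trapezoidal rule, normalized-RFU·°C)

is the quantitative statistic. The absolute value makes DCA non-negative
regardless of the direction of the Tm shift; no sign convention is imposed.

**Calibration.** Mixes of mutant (or a Tm-matched surrogate) and wild-type
PCR product at known percentages p give calibration pairs (p, DCA). The
standard curve is a least-squares degree-2 polynomial. The default
orientation fits DCA = a·p² + b·p + c — the orientation in which such
calibrations are plotted — and estimation inverts the quadratic
analytically, taking the real root closest to [0, 100] (exact tie → smaller
root; no real root → out-of-calibration error). The alternative orientation
(p as a quadratic in DCA, estimation by direct evaluation) is available via
`orientation="pct-from-dca"`; on the packaged reference series both
orientations reproduce the published per-row estimates to within ~1.3
percentage points, and the choice is a convention, not a substantive
difference. Estimates are never clamped: values slightly outside [0, 100]
are legitimate measurement noise (the reference data include a 104.8 %
estimate) and are returned with an `out_of_range` flag.

**Windows and replicates.** The analysis window is an assay-level choice
supplied by the user; `suggest_window` offers a starting point by finding
where the pooled |dF/dT| drops below 1 % of its maximum on either side of
the transition. Replicate handling follows the bench protocol the module
models (≥ 4 replicates per condition): difference curves are computed per
test replicate against the *mean* control profile, and the replicate-mean
DCA feeds estimation, with the SD reported. Curves on grids that differ by
less than half a step (equal step sizes) are interpolated onto the control
grid; anything larger is an error, to avoid silently comparing different
runs.

## Efficiency-corrected qPCR (`editquant.taqman`)

Amplification efficiency comes from a dilution series: the regression of
mean Cq on log10 relative input has slope −1/log10(E), so E = 10^(−1/slope)
(E = 2 ⇔ slope −3.3219). Relative quantities use the efficiency-corrected
ratio E_t^ΔCq_t / E_r^ΔCq_r with ΔCq = Cq(control) − Cq(sample); the sign
convention makes an unedited control 1 and edited samples read directly as
remnant wild-type fraction. The ratio is invariant under any constant shift
of all Cq values and reduces to 2^(−ΔΔCq) when both efficiencies are 2.

The SD attached to a ratio is a first-order delta-method propagation of the
replicate Cq SDs, treating the four mean Cqs as independent:

    sd(ratio) = ratio · sqrt( ln(E_t)²·(sd²_t,sample + sd²_t,control)
                            + ln(E_r)²·(sd²_r,sample + sd²_r,control) ).

Instrument software computes its own (undocumented) uncertainty; only point
estimates are comparable across implementations. Replicates aggregate by
arithmetic mean of Cq within sample × target; wells with no Cq (failed
amplification) are dropped.

## Repair partition (`editquant.repair`)

The four-panel algebra is stated in the module docstring. Two conventions
deserve note. First, the apparent-HDR formula divides the already-normalized
difference HN − N by Ec a second time; because panels are anchored at
Ec = 1 this is numerically inert, and the formula is implemented in that
published form (a `strict=True` mode computes HN − N). Second, out-of-range
results — negative frequencies, HN < N — are *flagged*, never clipped:
replicate noise genuinely produces them (the heterologous probe shows a
small non-significant negative-looking shift under backbone-only
conditions), and clipping would bias panel averages. %HDR_t is undefined
when HN = 0; it is reported as `None` with a flag, or raised if the caller
sets `pct_required=True`.

## Amplicon indel classification (`editquant.ngs`)

**Extraction.** A read (or its reverse complement — the first orientation
with a valid anchor pair wins) must contain an exact match of the sense
primer followed downstream by the antisense primer's binding site (the
reverse complement of the antisense primer as ordered). The segment between
the anchors, primers excluded, is the extracted target. Exact matching keeps
extraction deterministic; an opt-in `max_mismatch` allows Hamming-distance
substitutions inside primers for lower-quality data. With multiple anchor
occurrences the first sense anchor and first subsequent antisense anchor are
used, with a logged warning.

**Scoring.** The extracted segment is compared to the wild-type target by
Levenshtein edit distance (unit-cost substitutions/insertions/deletions;
`N` matches only `N`), computed by the classic dynamic program with the row
recurrence vectorized (the insertion propagation is a prefix-minimum in
shifted coordinates). Calls: distance < stringency → `wildtype`; otherwise
`deletion`/`insertion` by the sign of size_delta = len(segment) −
len(wild type), or `complex` when size_delta = 0. The strict inequality
means stringency 3 tolerates up to two changes as sequencing background.
`complex` reads count toward the mutation percentage but are excluded from
both indel size spectra, which bin |size_delta| at 1 bp. Unique indel sets
deduplicate on the identical extracted string (not on inferred coordinates,
which are not unique under edit-distance scoring). FASTQ quality scores are
ignored — classification is sequence-only. Internally all coordinates are
0-based half-open; reported sizes are positive bp.

Background correction is a plain difference of mutation percentages between
a test sample and a control at the same locus and stringency; negative
results are flagged, not floored.

## Simulators (`editquant.synthetic`)

**Melt.** Two-state melting as a falling logistic F(T) = f_low +
(f_high − f_low)/(1 + exp((T − tm)/width)), with additive Gaussian noise.
Mixtures are pointwise convex combinations of the two homoduplex curves.
Defaults: wild-type Tm 78.5 °C, mutant Tm shifted −1.5 °C (the magnitude a
~10-bp deletion produces in a ~150-bp amplicon), width 0.5 °C, plateaus
1000/50 RFU — these produce DCA magnitudes of order 0–1.5, matching the
reference calibration series. **Not modelled:** heteroduplex melting.
Authentic mutant/wild-type mixes can form heteroduplexes on reannealing,
which skews real profiles; the convex-combination model corresponds to the
surrogate-product mixing protocol. Passing round-trip tests therefore
demonstrate correctness of the *analysis*, not absence of heteroduplex bias
in real mixes.

**Reads.** Each read is sense primer + allele segment + antisense binding
site, with per-base substitution error and random strand. Error is
substitution-only at a uniform rate so stringency behaviour is analytically
predictable; platform indel errors (homopolymer artifacts) are deliberately
excluded, which is why per-locus background differences seen on real
single-molecule data will not appear in simulation. The default
per_base_error = 0.006 is chosen so that a ~107-nt target accumulates ≥ 3
substitutions (a false mutant call at stringency 3) in ≈ 3 % of reads,
matching the observed read-level background at such loci.

**Cq.** Cq = baseline − log(template)/log(E) + Gaussian replicate noise;
zero-template wells emit no Cq. Draw order is documented per generator;
fixed seeds reproduce outputs bitwise.

## Problem sizes and numerical choices

The test and acceptance workloads use the sizes a desk check needs, chosen
once: 11-point calibration series (matching the reference design), 4 melt
replicates per condition, read sets of 400–10,000 with binomial-interval
assertions, 8 qPCR wells per sample × target at 0.05-cycle replicate SD
(budgeting the delta-method relative SD of a ratio at ≈ 2.5 %, comfortably
inside the 5 % recovery checks), and a 10⁴-pair exhaustive-recursion oracle
for edit distance on strings ≤ 8 nt. Grid-uniformity tolerance is 1e-6 °C;
quadratic inversion treats |a| < 1e-14 as linear. Reference comparisons of
the repair table are made after rounding to the 2-decimal scale on which the
published values are printed.

## Known limitations

- HRMA estimation assumes the calibration mixes and test samples share melt
  behaviour; surrogate-product curves can differ systematically from
  authentic mutant mixes (the packaged series show exactly this: for a given
  nominal percentage the authentic series' DCA runs slightly higher).
- The dilution-series efficiency fit uses ordinary least squares on level
  means; heteroscedastic Cq noise across dilution levels is not weighted.
- Primer-anchored extraction discards reads with any error inside a primer
  when matching is exact, which deflates `with_target` (visible in the
  simulated example at 0.6 % per-base error) but leaves the mutation
  percentage essentially unbiased since the loss is allele-agnostic.
- The classifier reports net size changes only; a deletion plus nearby
  insertion of equal length is called `complex`, not resolved into events.
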