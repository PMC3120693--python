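# Methods

## The delayed SSA engine

The engine extends Gillespie's stochastic simulation algorithm with a
time-ordered waiting list for delayed products.  Each iteration draws a
candidate reaction and waiting time by a standard SSA step; if the earliest
queued release precedes the candidate, time jumps to the release instead and
the candidate is discarded (valid because the exponential clock is
memoryless).  Conventions fixed where the algorithm sketch is silent:

* a tie between the candidate time and the head release is resolved in
  favour of the release;
* equal release times are served first-in-first-out by insertion order
  (determinism);
* when the total propensity is zero but the list is non-empty, time jumps
  straight to the next release — required for a promoter that is
  sequestered mid-delay; with an empty list the run terminates at `t_stop`;
* propensities use mass-action combinatorics (x, or x(x−1)/2 for a
  second-order homodimerisation); reactions are at most second order;
* when a reaction queues several delayed products, each product entry draws
  its own delay (only one random delay exists in the gene model here, so
  the choice has no effect on it);
* sampled time series record the state immediately *before* each sample
  time (left limit), plus per-species totals still on the waiting list so
  conservation (free + pending) can be audited.

Two execution paths implement the same law: `advance_one_event` is a
single-step reference in plain Python, and the full-trajectory loop is
compiled with numba (one seedable stream per cell, derived from
`SeedSequence((master_seed, cell_index))`, so populations are reproducible
and order-independent).  The paths consume different random streams and are
therefore compared statistically, not event-for-event; both are tested
against analytic results (Poisson stationarity of a zero-delay birth–death
process, the delayed pure-birth mean λ·(t−τ)).

Gamma delays are parameterised by moment matching (shape = (mean/sd)²,
scale = sd²/mean).  The regime of interest has shape ≈ 2.3·10⁻³, far below
one; sampling goes through numpy's gamma generator, which handles
shape < 1 correctly.  About a fifth of the draws underflow to zero — the
true mass below 10⁻³⁰⁰ s at this shape — which is harmless for every
statistic computed here.

## The gene-expression model

Four reactions (see README) with the promoter consumed at initiation and
re-queued with delay τ1, so the promoter is unavailable during open-complex
formation; the transcript's ribosome binding site appears τ2 = 2 s after
initiation, and each translation yields a mature protein τ3 = 420 s later
(τ3 absorbs elongation and GFP maturation).  Induction enters only through
k1: the TetR/aTc equilibrium is not modelled explicitly, matching how the
rates were tuned to the measured means.  Initiations therefore form a
renewal process with mean interval 1/k1 + E[τ1], giving the closed-form
stationary means used as the independent oracle,

    E[RNA] = (1/k1 + E[τ1])⁻¹ / k3,     E[P] = E[RNA] · k2 / k4.

Only the delay's mean enters the means — both variants share them — while
its variance drives the Fano factor, which is the whole point of the
comparison.

Populations are sampled by default at t = 25 000 s (five protein lifetimes,
quasi-steady state) from an empty RNA/protein state.  Three samplers exist:
the numba event loop (default), the Python reference, and an exact direct
sampler that exploits the absence of feedback — initiation times by renewal
draws, transcript lifetimes exponential, translations a Poisson process
over each transcript's clipped lifetime, protein survival by thinning.
The direct sampler draws from exactly the same distribution (verified
against the event loop at 3-combined-SE agreement) and is ~20× faster, so
grid scans use it.

## Calibration and the fit distance

Measured single-cell totals are fluorescence (a.u.); the model counts
molecules.  Because Fano factors scale linearly under multiplication, a
single fluorescence-per-protein factor φ links the two scales.  φ is fitted
by least squares through the origin from the five measured mean GFP levels
against the closed-form model means; the per-condition ratios agree to
CV < 5% (φ ≈ 53 a.u./molecule), which is also the consistency check that
validates the reconstructed reaction scheme — alternatives (e.g. a promoter
that is not sequestered during the open complex) break this constancy.
A per-condition φ would trivially equalise the means and has no physical
reading, so a single global factor is used.

The fit distance is D = Σᵢ (Fano(E)ᵢ − Fano(M)ᵢ)² over the five induction
strengths, computed in fluorescence units (the only scale on which the
measured Fano factors live).  The delay-SD scan simulates the gamma-delay
variant over a grid of candidate SDs (SD 0 means the constant-delay
variant), converts protein counts to fluorescence via φ, and minimises D.

**Observation window for the scan.**  Populations default to 25 000 s, but
the scan uses 50 000 s.  A candidate SD is identifiable only if the window
is long enough to feel the delay distribution's scale (sd²/mean: 8 400 s at
SD 400 but 135 000 s at SD 1600); at 25 000 s the Fano factor is nearly
flat — even non-monotone — across the upper half of the default grid
{0, 25, 50, 100, 200, 400, 800, 1600} s and the fit degenerates.  At
50 000 s the curve is monotone over the grid and synthetic data generated
at SD* = 400 s is recovered at the correct grid point in 20/20 seeded
repetitions (500 cells/condition).  Means are at steady state under either
window, so φ is unaffected.

Default problem sizes: 1 000 cells/condition for fitting runs, matching the
measured populations (88–299 cells) with margin; the trend and recovery
tests run at 500 cells/condition.

## Imaging pipeline

Protein mode: each z-slice is median-filtered with a 2×2 window (lower
median of `input[i:i+2, j:j+2]`, edge-padded — an even window needs a
convention, and the lower median never invents values), then summed into
I_SUM.  The initial mask is a permissive threshold: baseline + 10% of the
way to Otsu's threshold, where the baseline is the image median (with a
near-zero background this reduces to 10% of Otsu).  After opening with a
radius-2 disk, objects with solidity < 0.9 or eccentricity < 0.7 are
treated as cell clusters and split on the extended maxima of their I_SUM
sub-image, assigning pixels to the nearest maximum geodesically (watershed
on −I_SUM).  The h-maxima depth defaults to 2% of the cluster's intensity
range: protein levels span >4× between neighbouring cells, so a depth tied
to the joint range must stay below the dimmest cell's own peak height;
watershed pieces smaller than 85 px (no plausible cell) are folded into the
neighbour sharing the longest boundary.  Border-touching objects and
objects outside 30–5 000 px are removed before any statistics.

Each cell's total intensity is read from its brightest z-slice; if that is
the first or last slice the cell's axial peak may lie outside the acquired
range and the record is flagged (ties prefer the lowest interior slice).
Outlier rules: the ⌊0.025 n⌋ highest-intensity cells are flagged (floor —
conservative), then cells outside 0.5–1.5× the median area (median over the
intensity survivors).  Autofluorescence is fitted by OLS of control-cell
intensity on area (in pixels) and subtracted; negative corrected values are
retained, since clipping would bias means and Fano factors.  Manual
exclusion of poorly segmented cells is modelled as an explicit label list,
never interactively.

RNA mode: cells are segmented by the mean-intensity threshold plus opening.
Isolated hot pixels are despeckled by a targeted 3×3 median replacement (a
blanket median filter shaves ~30% off diffraction-limited peak integrals).
Spot enhancement is a Gaussian-kernel density response: the image minus a
first-pass background map (per-cell medians, ambient outside) smoothed at
the spot scale.  The spot mask is Otsu's threshold on the log response
inside cells, floored at 6 robust SDs of the response measured away from
cells — the floor keeps empty images spot-free, and the log keeps a bright
multi-RNA class from pushing the threshold above dim single-RNA spots.
Spot cores grow into integration regions (within 3.5 px of a core); region
intensities are summed above a per-pixel baseline (cytoplasm level inside
cells, ambient outside, their average on the 1-px mask boundary, whose
position is uncertain by about a pixel).

Counts come from intensity-distribution slicing.  The unit (single-RNA)
intensity, when not supplied, is estimated from per-cell pooled totals by
lattice voting: every total/k is a candidate unit, candidates are scored by
how many totals fall near one of their multiples (Gaussian vote on the
absolute residual), and a small bonus for larger spacings breaks the exact
submultiple degeneracy.  Per-cell RNA is `round(pooled intensity / unit)` —
pooling before rounding is robust to a single spot fragmenting into several
detected cores, which per-spot rounding would each inflate to ≥ 1.

## Synthetic data

The generator emulates: single-cell fluorescence populations whose mean
scales with induction and whose distribution widens super-Poissonianly at
strong induction (counts come from the stochastic model itself);
autofluorescence linear in cell area by construction (slope 12 a.u./px,
intercept 400 a.u.), so the background fit can be checked for exact
recovery; and diffraction-limited spots whose integrated intensity is an
integer multiple of a unit intensity.

Rendering conventions: rods are capsules weighted by projected cylinder
thickness (2√(r²−d²)), so cell centres are brighter than borders — the
property the cluster-splitting step relies on; flat rods would render a
bright seam between touching cells instead.  The axial profile is a
Gaussian over slice index centred on a random interior slice and
renormalised after truncation, making the brightest-slice rule meaningful
and the first/last-slice discard triggerable on demand; the stack-integrated
signal of a cell equals φ·protein + autofluorescence exactly before noise.
Clusters are rendered as end-to-end bent pairs (division chains), the
geometry the solidity rule detects.  Noise is Poisson on pixel intensities
plus Gaussian read noise (σ = 5 a.u. over an ambient of 100, background
CV ≈ 10%) plus rare hot pixels (rate 5·10⁻⁵).

Spot images use a unit intensity of 2 500 a.u. over a cytoplasmic diffuse
level of 40 a.u. — realistic single-molecule contrast for MS2-GFP tagging
(the assay only works because single transcripts are bright); distinct
spots keep ≥ 4 px separation, with closer RNAs rendered as one spot, as
they would appear optically.

What passing the synthetic round trips does *not* show: performance on real
images with uneven illumination, focus drift, debris, non-rod morphologies
or overlapping (not merely touching) cells; the PSF is a Gaussian, not a
measured optical model; and camera gain/offset are not calibrated.  The
round trips validate the algorithmic steps, not the microscope.

## Known limitations

* The model omits RNAp/ribosome pools, cell growth and division, plasmid
  copy-number dynamics and MS2-GFP binding kinetics (scope choices).
* Delay-SD recovery degrades when the candidate scale exceeds the
  observation window (see the scan-window discussion); SDs ≳ 1 600 s would
  need still longer windows.
* The unit-intensity estimator needs the totals to populate more than one
  lattice point; a field where every cell held the same RNA count would be
  resolved only up to that common multiple.
* Fano-factor estimates from a few hundred heavy-tailed cells carry
  10–30% Monte-Carlo error; the fit scan damps this through the grid's
  geometric spacing and, optionally, replicate averaging.
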