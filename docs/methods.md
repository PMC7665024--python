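# Methods

This note documents the models, numerical choices and known limitations of
deerflex in enough detail to reproduce or challenge any of them.

## Forward dipolar model

For an isotropically oriented pair of nitroxide spin labels at distance
*r* (nm), the powder-averaged DEER form-factor kernel is

    K(t, r) = ∫₀¹ cos[(1 − 3u²) · ω_dd(r) · t] du,
    ω_dd(r) = 2π·D / r³,  D = 52.04 MHz·nm³,

with *t* in μs.  D follows from the point-dipole interaction of two free
electrons; exchange coupling, orientation selection and finite
excitation bandwidth are not modeled.  The kernel is evaluated in closed
form through Fresnel integrals, with a fourth-order Taylor series below
x = ω·t = 10⁻⁴ where the closed form loses digits to cancellation; the
combination is accurate to better than 10⁻⁸ everywhere on the supported
grids (the test suite verifies 10⁻⁶ agreement against an independent
million-point Riemann quadrature, evaluated via quadratic-phase
recurrences validated against direct cosine summation).

Measured echoes are modeled as
V(t) = [(1 − λ) + λ·F(t)] · exp(−k·t^(d/3)) + ε(t), with modulation depth
λ ∈ [0, 1], background rate k ≥ 0, background dimensionality d (default 3,
homogeneous excluded volume; adjustable within [2, 3.5] for membrane-like
samples) and i.i.d. Gaussian noise.  Units are fixed — μs, nm, densities
per nm — and never converted implicitly.

Default distance grid: 1.5–8.0 nm at Δr = 0.02 nm.  Round-trip studies in
this package run the inversion on a 0.05 nm grid (the truth is always
simulated on the 0.02 nm grid to avoid inverting on the simulation grid);
0.05 nm is far below every tolerance scored on the results.

## Inversion chain

1. **Background.**  a·exp(−k·t^(d/3)) is least-squares fitted to the trace
   tail (default: t ≥ 0.6·t_max, log-linear initialization, bounded
   refinement); λ = 1 − a clipped to [0, 1].  The trace noise SD is
   estimated from the fit-window residuals.  Because a narrow distribution
   at long distance oscillates through the whole tail window and biases
   this fit, `invert` performs one refinement round: the first-pass
   distribution provides a form-factor estimate, and (λ, k) are refitted
   on the *full* trace with that form factor fixed.  The form-factor
   estimate is restricted to the reliable range r ≤ (2·D·t_max)^(1/3) —
   distances whose dipolar half-period fits in the window — because mass
   beyond it is indistinguishable from background and must be handed back
   to the background term rather than frozen into the model.  Without this
   restriction the refinement converges to a self-consistent wrong λ, and
   the excess appears as a spurious pedestal at the long-distance edge of
   P(r).
2. **Correction.**  s(t) = (V/B − (1 − λ))/λ.  The signal-level noise SD
   is the trace SD divided by λ and multiplied by the rms of 1/B(t): the
   background division amplifies late-time noise, and ignoring that factor
   systematically underestimates σ and pushes later χ² decisions toward
   over-fitting.
3. **Tikhonov.**  p(α) = argmin_{p≥0} ‖K·p·Δr − s‖² + α²‖L₂p‖² with L₂ the
   second-difference operator with zero end rows (free boundaries), solved
   by active-set NNLS on the stacked system — non-negativity inside the
   solver, not by clipping, which would distort the L-curve.  The α path
   is 41 values log-spaced over [10⁻⁴, 10⁴].
4. **α selection (L-curve).**  The corner of (log ρ, log η) is located by
   maximum signed curvature from central finite differences after a
   3-point moving average.  Two numerical safeguards matter on NNLS paths:
   both log axes are rescaled to [0, 1] (log η spans ~13 decades against
   ~1 for log ρ, so raw-axis curvature is meaningless), and near-stationary
   points (< 0.01 rescaled arc length apart) are pruned — runs of
   numerically identical solutions at the path ends otherwise produce
   unbounded spurious curvature.  Ties break toward larger α.  Against a
   brute-force RMSE-oracle scan on simulated traces, the selection lands
   within one decade of the oracle in ≥ 80% of cases; the residual
   mild over-smoothing tendency of the L-curve on smooth solutions is a
   known property of the criterion, which is why the chain does not end
   here.
5. **Maximum entropy.**  Minimize ½‖K·p·Δr − s‖²/σ² + μ·Σ(p·ln(p/m) − p + m)
   over p ≥ 0, prior m = Tikhonov solution floored at 10⁻⁸ per nm.  Inner
   solves use bound-constrained L-BFGS-B with warm starts; a damped
   multiplicative fixed point was tried first and is unconditionally
   unstable whenever the data-term curvature p·H/μ exceeds the damping
   margin, which is the generic situation at realistic noise floors.  μ is
   bisected so the reduced chi-square lands in [0.9, 1.5] (target 1):
   if the prior is already inside the band it is returned unchanged (the
   maximum-entropy answer is the largest admissible μ), otherwise μ
   decreases until first entry into the band's upper part.  Driving χ²/N
   all the way to 1.0 re-fits noise whenever σ is even slightly
   underestimated and measurably degrades mode recovery; landing at the
   conservative edge does not.  If the band is unreachable (prior
   over-fits it, or the data cannot be fit that well at any μ) the closest
   solution is returned and a ConvergenceWarning is issued.

The pipeline is deterministic given trace and configuration, and reports
ρ(α)/η(α) monotonicity, the selected α, λ, k, σ and χ²/N.

## Flexibility metrics

Mode = grid argmax (ties toward smaller r).  FWHM = distance between the
*outermost* crossings of half the global maximum, crossings linearly
interpolated; a distribution still above half-maximum at a grid edge is
clamped with a BoundaryTruncationWarning.  The outermost-crossing
convention is deliberate: broad conformational ensembles are often
multimodal, and a main-peak-only width would understate the spread that
the flexibility argument is about.  Moments and the min-overlap
coefficient ∫min(p_a, p_b)dr complete the report.

## In-silico spin labeling

A deliberately simplified accessible-volume label: candidate spin centres
are drawn uniformly in a spherical shell 5.0–9.0 Å around the labeled
residue's Cα — the typical backbone-to-NO-midpoint offset of a
nitroxide label — restricted to the Cα→Cβ hemisphere when a Cβ exists
(wrong-hemisphere draws are reflected, preserving uniformity), and
rejected within 2.5 Å of any heavy atom outside the labeled residue.
Pairwise distances between two clouds are histogrammed with linear
(mean-preserving) assignment to bracketing grid points and smeared with a
0.1 nm Gaussian.  All rejection logic is exactly reproducible by a naive
double loop, which the tests and the acceptance script exploit.  This
surrogate reproduces the coarse behavior that matters for cross-checking
DEER distances (label offset, excluded-volume sensitivity); it does not
weight conformers, model label dihedral chemistry, or reproduce any
specific rotamer-library program, so agreement at the 1–2 Å level is the
most that should be expected of it.

## Assay metrics

FRET efficiency E = 1 − I/I₀ (donor intensity with/without acceptor);
cytochrome-c release (I − I₀)/(I_max − I₀)·100% between the no-BAX and
activated-BAX controls; FRAP recovery fitted as
f(t) = f₀ + (f_∞ − f₀)(1 − e^(−t/τ)) with D = w²/(4τ) for bleach radius w,
and pore activity D/D₀ against the detergent-disrupted reference
(D₀ = 26.5 μm²/s for 70-kDa, 51.2 μm²/s for 10-kDa fluorescent dextran;
activity approaches 1 when the vesicles are largely disrupted).  The
single-exponential recovery law is a surrogate for the full FRAP theory
(which lives behind an interface so another law can be swapped in);
intensities are assumed background-subtracted scalars, image processing
being upstream of this package.

## Synthetic data: what it emulates and what it does not

`make_scenario` draws two contrasting ensembles.  *Narrow* (rigidified,
"EEE-like"): one Gaussian component, SD ∈ [0.15, 0.25] nm.  *Broad*
(flexible, "WT-like"): 2–3 Gaussian components with overall ensemble SD
drawn in [0.6, 0.9] nm, constructed as one dominant conformation with
heavily overlapping shoulders — a 3-component symmetric-shoulder form
(centre weight 0.40–0.50) or a 2-component one-sided-shoulder form
(dominant weight 0.60–0.70), component SD at 0.85–0.95 of the ensemble SD,
offsets scaled so the mixture SD lands exactly on its drawn target.  Two
properties of this construction are intentional: the ground-truth FWHM
range (≈1.4–2.2 nm, median ≈1.75) brackets the width regime the analysis
must resolve against narrow truths (0.35–0.59 nm), and the hump's maximum
is stable — a dense-grid scan shows the smoothing-induced argmax shift
stays below ~0.04 nm at these parameters, versus ~0.06 nm and beyond for
more separated components, where the most probable distance stops being a
well-defined observable at realistic noise.  Resolved multi-conformer
mixtures with comparable peak heights are deliberately *not* generated:
recovering an argmax that flips between near-equal peaks tests noise, not
the method.  Modes lie in 2.5–5.0 nm, λ ∈ [0.2, 0.4], k ∈ [0.02, 0.1] μs⁻¹,
d = 3.

Traces are simulated at t_max = 4 μs with 256 points (≈16 ns step — a
realistic acquisition; the 4 μs window covers the dipolar half-period of
distances to ≈7.5 nm, which broad ensembles need) and SNR = λ/σ_noise = 30.
The generators are pure functions of their arguments including the seed.

Passing round-trip tests on these data shows the chain recovers what it
simulates: Gaussian-mixture ensembles, ideal stretched-exponential
backgrounds, white Gaussian noise.  Real traces add background-model
error, orientation selection, multispin effects and detector noise
structure, none of which the generator emulates — so synthetic recovery
rates are an upper bound on real-data performance.

The toy structure generator packs ideal poly-Ala helices (1.5 Å rise,
100°/residue, 2.3 Å backbone radius, Cβ 1.53 Å radially outward) on a
hexagonal grid 10 Å apart, with a small seeded coordinate jitter
(0.05 Å) so different seeds give distinct, reproducible fixtures.

`recovery_benchmark` draws paired broad/narrow scenarios, inverts both,
and scores: |mode error| ≤ 0.1 nm per trace, FWHM ranking per pair, and
ρ/η monotonicity of every regularization path.  At its default settings
(50 pairs, SNR 30, 0.05 nm inversion grid) the observed mode-recovery
fraction is 0.91–0.95 across seeds with the ranking correct in every
pair; a full run takes about half a minute.

## Degenerate inputs and tie-breaks

All-zero regularized solutions are returned flagged `is_empty` rather
than raising (batch robustness); statistics on them raise
UndefinedModeError.  Equal-density modes resolve toward smaller r; equal
L-curve curvatures toward larger α.  λ ≤ 0.01 refuses correction
(nothing to invert).  Flat FRAP curves raise FitFailureError with
residual diagnostics rather than returning an unidentifiable τ.  Pair
distances outside the grid are clipped with an OutOfGridWarning and the
histogram renormalized.

## Known limitations

- No uncertainty bands on P(r); no Gaussian-mixture model fitting.
- The background dimensionality is user-set, not estimated.
- The L-curve criterion's over-smoothing bias is mitigated, not removed;
  distances near the grid's long edge rely on the reliable-range
  heuristic in the background refinement.
- The labeler's shell parameters are config-exposed but not calibrated to
  any specific rotamer library.
- Raw experimental traces for the 12/92 double mutants exist only in the
  source study's supplementary material (no public accession), so the
  published-width checks run only when those files are supplied locally
  (see `tests/test_acceptance.py::test_published_widths_from_raw_deer_traces`).
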