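# Methods

`sh2kinetics` models and analyzes the membrane recruitment of SH2 domains to
tyrosine-phosphorylated binding sites, as observed by TIRF and
single-particle-tracking photoactivated localization microscopy (sptPALM).
This note documents the model, the estimators, the numerical choices, and
what the synthetic data do and do not capture.

## The kinetic model

Membrane-bound SH2 abundance obeys the linear balance

    d[mem:SH2]/dt = γ_on(t) − λ_off(t) · [mem:SH2](t)

where γ_on(t) is the apparent on-rate (newly appearing membrane-bound
molecules per unit time) and λ_off(t) the apparent off-rate inferred from
single-molecule dwell times.  Both are *apparent* quantities: when
phosphosites pack into clusters, a dissociated SH2 domain is frequently
recaptured by a neighboring free site before it escapes to the cytosol, so
the observed dwell lengthens (λ_off falls) even though the microscopic
chemistry is unchanged.  The integrating-factor solution

    [mem:SH2](t) = c·e^{−Λ(t)} + e^{−Λ(t)} ∫₀ᵗ γ_on(u) e^{Λ(u)} du,
    Λ(t) = ∫₀ᵗ λ_off(u) du

is evaluated by quadrature (`rebindmodel.analytic_occupancy`) and
cross-validated against adaptive ODE integration
(`rebindmodel.integrate_occupancy`); the two agree to better than 1e-6
relative error on all profiles we test.

Two back-of-envelope diffusion-limited on-rate estimates are provided:
`on_rate_from_kd` (k_on = k_off / K_d; with k_off ≈ 1 s⁻¹ and K_d ≈ 1 µM
this gives ~1e6 M⁻¹s⁻¹) and `smoluchowski_upper_bound` (4πDs/N for N sites
sharing a cluster of size s, converted from µm³/s to M⁻¹s⁻¹).

## The simulator (`simkit`)

The generator produces ground truth for every downstream stage.

**Phosphosite field.**  `n_sites` sites are uniform over a square membrane
patch.  Each activates (is phosphorylated) at an exponential time with mean
`tau_phospho`, so the cumulative activation probability is 1 − e^{−t/τ}.
A clustering quantile per site moves a growing fraction of phosphorylated
sites — `clustered_fraction_max · (1 − e^{−t/tau_cluster})` — from its
dispersed position into one of `cluster_count` disc-shaped clusters of
radius `cluster_radius`.  Cluster membership is assigned round-robin over a
seeded permutation so clusters carry equal expected site numbers; with
Poisson (uniform-random) assignment the dimmest cluster routinely drops
below the intensity threshold used for segmentation, which is a property of
the assignment noise, not of the biology being emulated.  Dephosphorylation
is off by default (binding-site measurements plateau on the timescales
simulated); a first-order decay is config-gated for exploring the early
transient dip.

**Binding dynamics.**  Fixed-step hybrid stepping at `frame_interval/10`
(reaction probabilities 1 − e^{−k·dt} per substep, Brownian displacement
σ = √(2·D_bound·dt) per axis with reflecting boundaries).  Free
phosphorylated sites capture molecules from a well-mixed, non-depleting
cytosolic reservoir at rate `k_on_intrinsic · sh2_concentration` per site
(the measured cytosolic SH2 concentration, ~6.5 µM ≈ 3900 molecules/µm³,
makes depletion negligible).  A bound molecule dissociates at `k_off_true`;
on dissociation, free phosphosites within `rebind_capture_radius` are
offered one Bernoulli trial each (`rebind_probability`, nearest first);
failure returns the molecule to the pool.  Bleaching (`k_bleach`) ends
observability only — ground-truth occupancy is unaffected.  All randomness
flows from one integer seed through named substreams (phospho, binding,
activation, noise), so identical configs reproduce bit-identical logs.

**Rendering.**  sptPALM mode draws a photoactivated subset of molecules as
pixel-integrated Gaussian PSFs (`psf_sigma`) scaled to
`photons_per_molecule`, over `background_photons`, with per-pixel Poisson
shot noise plus Gaussian read noise, written as 16-bit multi-page TIFF with
a JSON sidecar (pixel size, frame interval).  The activation subset is an
*unbiased Bernoulli thinning* whose probability is set so the mean
instantaneous visible density equals `activation_density`.  A hard per-frame
admission cap was rejected deliberately: it vetoes molecules in proportion
to the number of frames they span, i.e. selectively against long dwells, and
measurably inflates the apparent off-rate (~60% in our conditions) — exactly
the estimator artifact this package exists to expose.  Densities above
0.1/µm² trigger a mistracking warning.  `bulk` mode renders *all* bound
molecules in every frame, emulating the conventional-excitation channel used
for recruitment and clustering quantification; cluster segmentation operates
on this channel, because the temporal mean of sparse single-molecule frames
turns individual molecules into spurious bright spots.

**Intrinsic association default.**  `k_on_intrinsic` defaults to
6.4e-5 µm³/s (a per-site pseudo-first-order capture rate of ~0.25 s⁻¹ at the
default SH2 concentration), i.e. a sub-saturating regime in which site
occupancy responds visibly to changes in the apparent off-rate.  At the
diffusion-limited value (~1.7e-3 µm³/s) sites are occupied ~90% of the time
and rebinding-driven modulation is nearly invisible in occupancy — a regime
that answers no question this package asks.

## Estimators

**Detection (`locfit.detect_spots`).**  Matched Gaussian filtering at the
PSF scale; background = median, noise = 1.4826·MAD of the filtered frame;
local maxima above `threshold_snr` noise units are refined by least-squares
2D Gaussian fits (σ fixed to the PSF) in a ±3σ window; detections closer
than one PSF σ are merged keeping the brighter.  SNR is reported on the
filtered image.

**Linking (`locfit.link_trajectories`).**  Greedy mutual-nearest-neighbor
between consecutive frames within `max_displacement`; no gap closing, no
merge/split, ties broken by detection index (output is order-invariant).
The default scan radius is 3·√(4·D·Δt) with D from a pilot MSD pass.  A
2·√(4·D·Δt) radius truncates ~e⁻⁴ ≈ 1.8% of genuine Brownian steps, which
splits tracks and biases λ_off upward by ~0.09 s⁻¹ at 5 Hz — far beyond its
statistical error — while 3σ-equivalent truncation (~1e-4) is negligible and
the radius stays well below nearest-neighbor spacings at sparse-activation
densities.

**Diffusion (`locfit.compute_msd`).**  Time-and-ensemble-averaged MSD over
tracks longer than 4 frames (`min_length = 5`); D from an unweighted linear
fit MSD = 4DΔt + b over the first 4 lags.  The free intercept absorbs the
static localization-error offset; the fit residual norm exposes
non-Brownian (e.g. drift) components.  Per-track D values are available for
distributions.

**Apparent on-rate (`kinetics.estimate_gamma_on`).**  Track starts counted
in windows (default 0.8 min = 48 s) divided by the window length, reported
in events/min with Poisson counting errors.  Tracks present in frame 0 are
pre-existing binding, never recruitment events.  Detection recall < 1 scales
γ_on multiplicatively; comparisons therefore use shapes and time constants
unless recall is measured.

**Apparent off-rate (`kinetics.estimate_lambda_off`).**  Track lengths in
frames are geometric observations of an exponential dwell (memorylessness
makes the frame-sampled distribution exactly geometric with survival
q = e^{−λΔt}), so the MLE is q̂ = S/(S + n_u) with S the survived frame
transitions and n_u the uncensored count; λ = −ln q̂ / Δt.  Tracks reaching
the last frame are right-censored; tracks starting at frame 0 are
left-censored and excluded.  The bleach rate (from config, or an
immobilized-control measurement in real data) is subtracted additively.
Standard errors come from the observed information, optionally from a
trajectory bootstrap.  λ_observed ≤ k_bleach is flagged degenerate rather
than clipped; all-censored data yield a lower-bound-only flag.  A
continuous-time censored MLE (`fit_exponential_dwells`) handles real-valued
dwells.

**Recovery fits (`kinetics.fit_recovery`).**  Nonlinear least squares of
y = A·(1 − e^{−t/τ}), A free by default or pinned to 1; τ initialized at
time-to-half-max / ln 2, bounded in (0, 10·t_max]; R² < 0.5 carries a
poor-fit flag.  τ inherits the unit of the supplied time axis.

**Cluster segmentation (`clusterfield`).**  Pixel intensities are split by
*exact* 1-D two-class k-means — an exhaustive split search over the sorted
intensity histogram with prefix sums (Lloyd iterations from extreme-value
initialization can stall in local optima).  The threshold is the midpoint of
the class means, making the mask invariant to intensity scaling.
8-connected components smaller than one PSF area (π·σ²) are removed.  A
no-structure guard returns an empty mask when the class-mean separation is
below 6 pooled within-class standard deviations: pure noise sits near 3, a
dim diffuse molecule carpet near 4–5, genuine clustered fields above 10.
Trajectories are partitioned by whether their first localization falls on a
mask pixel; the non-cluster rate series is computed as total − cluster,
exactly.  The clustering summary is (mean component area in µm²) × (component
count), from temporal-mean images over sliding windows (default 30–60 s).

**Far-Western analytics (`fwtable`).**  Band tables are normalized per
replicate row to unit maximum over all bands and time points, then replicate
rows are averaged per probe (in that order).  Relative specificity is the
per-band difference of lane-fraction profiles (SH2 − anti-pY), which sums to
zero within each lane by construction.  Probes are clustered by average
linkage on the uncentered correlation Σxy/√(Σx²Σy²), implemented directly
(O(n³), n ≤ dozens of probes) with lexicographic leaf-label tie-breaking so
merge order is deterministic; flat clusters are maximal subtrees whose
merges all exceed the similarity cutoff (default 0.85).  Exports: nested
JSON and Newick with merge similarities as internal labels.

## Numerical choices

- Simulation substeps: frame_interval/10; reaction probabilities use exact
  exponential complements, not first-order Taylor.
- ODE: RK45, rtol 1e-10, atol 1e-12, max step 1/50 of the interval.
- Analytic occupancy: per-step Simpson on a 16× refined grid for both Λ and
  the convolution; the convolution is accumulated in the shifted form
  ∫γ(u)e^{−(Λ(t)−Λ(u))}du, in which every exponent is non-positive, so large
  cumulative off-rates cannot overflow.
- Recovery fit non-convergence returns an explicit failed result; the
  pipeline degrades to non-converged fits on series shorter than 5 points.
- k-means threshold ties cannot occur (the SSE-optimal split is computed
  exhaustively); dendrogram merge ties break lexicographically.

## Study conditions

The canned studies (`studies.py`) fix the conditions used by the test suite
and the reproduction script:

- *Tracking study*: 128×128 px at 0.16 µm/px (20.5 µm field), 5 Hz, 600
  frames, 300 dispersed sites, activation density 0.015/µm², 800
  photons/molecule over 10 background photons, k_off_true = 1 s⁻¹ (the
  measured effective off-rate's order of magnitude), k_bleach = 0.2 s⁻¹,
  D_bound = 0.021 µm²/s (the measured GRB2 value); four movies pooled to
  exceed 3000 trajectories.  The residual λ_off bias from track-splitting at
  these conditions is a few percent.
- *Rebinding-contrast study*: ground-truth event logs (no imaging), 12.8 µm
  field, 200 sites, 240 s, τ_phospho = 25 s, τ_cluster = 70 s, capture
  radius 0.1 µm, rebind probability 0.3; the two arms differ only in
  `clustered_fraction_max` (0.8 vs 0); 20 matched replicates per arm.
- *Imaging scenarios*: `egf-clustered` (220 sites, clustering on) and
  `pv-dispersed` (330 sites, clustering off — phosphatase-inhibition-style:
  more binding sites, no foci), 96×96 px, 4 Hz, 240 s, otherwise identical.

These sizes are the package's chosen operating points; they reproduce the
qualitative orderings (λ_off clustered < dispersed; τ_recruit clustered >
dispersed; cluster-region γ_on rising more slowly than non-cluster γ_on;
dispersed recruitment tracking site creation) at small simulation scale.

## What the synthetic data do not capture

- Binding sites are static between relocation events; in cells the
  receptor (and the whole cluster) diffuses, carrying its bound SH2 domain
  with it.  Bound-molecule motion relative to its site is therefore
  slightly exaggerated here.
- The cytosol is a well-mixed infinite reservoir: no depletion, no 3D
  diffusion gradients, no competition between binding partners or
  compartments.
- Optics: 2D only, single Gaussian PSF, single-exponential bleaching, no
  blinking, no EM-gain noise model.
- Dispersed sites are sparse enough to resolve individually; real
  unclustered phosphosite densities are far higher and blur into a carpet.
- Phosphorylation is one first-order step; no kinase/phosphatase feedback,
  no transient early dip unless the dephosphorylation gate is enabled.

Passing tests therefore demonstrate estimator correctness and the internal
consistency of the rebinding mechanism under these idealized conditions, not
quantitative agreement with any particular cell measurement.

## Known limitations

- The geometric dwell MLE corrects bleaching additively; it does not model
  detection gaps (blinking or missed frames), which appear as extra
  apparent off-rate when recall drops.
- γ_on is recall-biased (multiplicatively) on tracked data.
- The no-structure segmentation guard is a heuristic with a documented
  operating band; images engineered near separation ≈ 6 within-SD will
  flip between empty and non-empty masks.
- Average-linkage clustering is quadratic in memory over probes — fine for
  domain panels, not for thousands of rows.
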