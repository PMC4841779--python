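# sh2kinetics

Simulation and analysis of single-molecule SH2 domain membrane-recruitment
kinetics.

When a receptor tyrosine kinase is activated, SH2 domain-containing
effectors are recruited to phosphotyrosine (pY) sites on the membrane.
Bulk measurements of binding-site abundance (far-Western blotting) and
live-cell imaging of actual membrane binding (TIRF / sptPALM) can disagree
strikingly: recruitment can keep rising long after the binding sites have
plateaued, because phosphosites pack into clusters and a dissociating SH2
domain is recaptured by a neighboring free site before it escapes to the
cytosol.  Rebinding suppresses the *apparent* off-rate λ_off and delays the
approach to maximal binding, even though the microscopic chemistry never
changes.

`sh2kinetics` is for microscopists and modelers who want to study this
regime quantitatively.  It provides:

- **`simkit`** — a ground-truth simulator: phosphosite fields with
  first-order creation and progressive clustering, stochastic SH2
  binding/diffusion/rebinding event logs, and rendered sptPALM/TIRF movies
  (16-bit TIFF) with realistic activation sparsity and camera noise.
- **`locfit`** — single-molecule localization (matched filter + Gaussian
  fits), mutual-nearest-neighbor tracking, and MSD-based diffusion
  estimation.
- **`kinetics`** — the apparent on-rate γ_on(t) (windowed recruitment-event
  counting), the apparent off-rate λ_off (censored dwell-time maximum
  likelihood with photobleaching correction), first-order recovery fits
  y = A·(1 − e^{−t/τ}), and time-series R².
- **`clusterfield`** — cluster segmentation by exact two-class k-means
  intensity thresholding, and partitioning of trajectories into cluster /
  non-cluster groups with group-wise on-rates.
- **`rebindmodel`** — the occupancy balance
  d[mem:SH2]/dt = γ_on(t) − λ_off(t)·[mem:SH2](t), solved both numerically
  and via its integrating-factor solution, plus diffusion-limited on-rate
  estimates (k_off/K_d and the 4πDs/N upper bound).
- **`fwtable`** — far-Western band-table analytics: per-probe max
  normalization, relative-specificity profiles, and average-linkage
  hierarchical clustering on uncentered correlation with a 0.85 similarity
  cutoff.
- **`pipeline` / `sh2kin` CLI** — end-to-end scenario runs
  (simulate → track → kinetics → clusters → model) with seeded, manifested,
  byte-reproducible outputs.

## Worked example

Matched simulations that differ only in whether binding sites cluster,
analyzed on ground-truth event logs:

```python
from sh2kinetics.studies import run_rebind_replicate

for clustered in (False, True):
    r = run_rebind_replicate(seed=1, clustered=clustered)
    print(f"{r['scenario']:9s}  lambda_off = {r['lambda_off_per_s']:.2f}/s   "
          f"tau_recruit = {r['tau_recruit_s']:.0f} s   "
          f"rebinds/event = {r['mean_rebinds']:.2f}")
```

```
dispersed  lambda_off = 0.89/s   tau_recruit = 26 s   rebinds/event = 0.08
clustered  lambda_off = 0.74/s   tau_recruit = 36 s   rebinds/event = 0.27
```

Both arms use the same microscopic constants (k_off = 1 s⁻¹, identical
on-rate, identical site count).  Clustering alone triples the rebinding
frequency, suppresses the apparent off-rate by ~16%, and slows the
approach to maximal membrane binding by ~40% — recruitment lags binding-site
creation without any change in chemistry.

The back-of-envelope diffusion-limited on-rate estimates:

```python
from sh2kinetics.rebindmodel import on_rate_from_kd, smoluchowski_upper_bound

print(f"k_on from k_off/K_d:        {on_rate_from_kd(1.0, 1e-6):.2e} 1/(M s)")
print(f"Smoluchowski upper bound:   {smoluchowski_upper_bound(D=1.0, s=0.1, N=1000):.2e} 1/(M s)")
```

```
k_on from k_off/K_d:        1.00e+06 1/(M s)
Smoluchowski upper bound:   7.57e+05 1/(M s)
```

From the shell, a full rendered scenario (movie, trajectories, rates,
cluster masks, occupancy model and a summary JSON) is one command:

```bash
sh2kin run --scenario egf-clustered --seed 1 --out-dir out/egf
```

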