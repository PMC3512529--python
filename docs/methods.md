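# Methods

## The model

`il2x` implements a deterministic ODE model of IL-2–mediated coupling
between T cells activated in a shared, well-mixed microenvironment (an
interaction volume of 100 µm³, the scale of a cell cluster on an
antigen-presenting cell). The state is (U_i, B_i, I): unbound and bound
IL-2 receptors per cell, and free IL-2 molecules in the volume.

Assumptions, in order of importance:

- **Well-mixed volume.** Secreted IL-2 is instantly available to every
  cell; there is no autocrine privilege and no spatial gradient. Transport
  out of the neighbourhood is lumped into the first-order removal rate
  `d_I`.
- **Effective two-state receptor.** The three IL-2R subunits are collapsed
  into a single receptor species whose synthesis responds to signaling;
  receptor–ligand binding is one-step with rates `k_on`, `k_off`.
- **Signaling in quasi-equilibrium.** Downstream signaling (STAT5
  phosphorylation) is assumed proportional to the bound-receptor count B,
  so the feedback acts directly through B. The Hill coefficient of 2
  reflects the dimeric transcription factor driving receptor expression.
- **Pre-proliferative window.** The model describes the first ~days after
  activation; proliferation and death are outside its scope.

TCR signal strength enters as a single dimensionless parameter m ∈ [0, 1]
scaling both IL-2 secretion (`s·m`) and the feedback amplitude
(`m·g_f·B²/(B²+K_f²)` on top of constitutive synthesis `g_c`).

## Parameters

Fixed unit system: minutes, molecule counts, µm³. `k_on` is declared in
M⁻¹min⁻¹ and converted internally to the per-molecule rate
`k_on_eff = k_on/(N_A·V)`; both values are retained on `MediumParams`.

| parameter | default | units | meaning |
|---|---|---|---|
| g_c | 0.0510204 | molec·min⁻¹ | constitutive IL-2R synthesis |
| a_U | 3.40136·10⁻⁴ | min⁻¹ | unbound-receptor internalization (g_c/a_U = 150) |
| a_B | 3.40136·10⁻⁴ | min⁻¹ | bound-complex internalization (IL-2 consumption) |
| g_f | 6.12245 | molec·min⁻¹ | maximal induced synthesis rate |
| K_f | 800 | molecules | feedback half-saturation; also the commitment cutoff |
| n | 2 | — | Hill coefficient |
| s | 0.670068 | molec·min⁻¹ | maximal IL-2 secretion rate |
| d_I | 4.0 | min⁻¹ | free-IL-2 removal (degradation + transport) |
| k_on | 6.6·10⁸ | M⁻¹min⁻¹ | association (≈1.1·10⁷ M⁻¹s⁻¹) |
| k_off | 4.4898·10⁻⁴ | min⁻¹ | dissociation (K_d ≈ 10 pM with the slow clock) |
| V | 100 (×5 for ensembles) | µm³ | interaction volume |

### How the defaults were chosen

The binding-side constants are literature-scale: `k_on ≈ 10⁷ M⁻¹s⁻¹` and a
low-picomolar affinity for the high-affinity IL-2R, and a removal rate
`d_I` fast enough that free cytokine escaping capture leaves the ~3 µm
neighbourhood within seconds (diffusive escape is in fact sub-second, so
`d_I = 4 min⁻¹` is conservative). The synthesis/turnover side is
*effective*: receptor up-regulation runs through transcription,
translation and trafficking, so its rates are orders of magnitude slower
than the binding events. These slow rates were calibrated jointly against
the quantitative behaviors that characterize this system:

1. resting receptor number `g_c/a_U = 150`;
2. a sharp commitment threshold at half-maximal TCR signal, m_c ≈ 0.5,
   starting from the naive condition `U = g_c/a_U, B = I = 0`;
3. a critical competition window of ≈ 14 h for the pair
   (m₁ = 0.65, m₂ = 1);
4. qualitative pair outcomes: exclusion of the weaker cell at simultaneous
   activation, coexistence of two strong cells, joint (quorum-like)
   commitment of two equal cells slightly below threshold, and coexistence
   when the stronger cell arrives after the window closes;
5. ensemble statistics: a modal benefit of ≈ 1.5× for a strong cell among
   nine uniform-random competitors at short delay, and exclusion of a
   long-delayed strong cell only by groups with mean m ≳ 0.5 containing a
   competitor with m ≳ 0.75.

The calibration exploits an exact structural property: dividing all slow
rates (g_c, a_U, a_B, g_f, s, k_off) by a common factor λ while keeping
k_on, d_I and K_f fixed leaves every steady state and every
molecule-count-based quantity unchanged (free IL-2 scales as I/λ) and
multiplies all slow timescales by λ. Anchors 1, 2, 4, 5 were therefore
tuned first in a fast-clock system, and λ = 14.7 then set the window
length (anchor 3) without disturbing them. The calibrated set ships as
`src/il2x/data/default_params.yaml` and is treated as frozen.

### Threshold mechanism and the static bistable window

Under the calibrated regime, near-threshold commitment is limited by IL-2
*capture*: at the threshold, the captured share of the secreted cytokine
just sustains the receptor pool needed to keep capturing it. This is what
makes the collective effects strong (pooling helps sub-threshold
neighbours commit; a committed competitor's receptor pool starves an
igniting one). A consequence worth stating explicitly: the *static*
bistable window of the isolated cell — where low and high fixed-point
branches coexist — lies at m ∈ (≈0.354, ≈0.366), below the *dynamic*
from-rest threshold m_c ≈ 0.5. Between the two, the high branch is the
unique fixed point but is unreachable from the naive initial condition on
any relevant timescale without cooperative help; hysteresis in the strict
sweep sense exists only inside the static window, and is tested there.

## Commitment, labels and indices

- **Commitment:** steady-state B ≥ K_f. The high branch saturates the
  feedback (B ≫ K_f) while the low branch sits near the constitutive
  scale, so K_f separates them robustly. Exposed as an argument wherever
  it is used.
- **Interaction index:** `C_i = (B_i^together − B_i^alone)/B_ref` with
  `B_ref` the single-cell endpoint at m = 1 under the same parameters,
  computed once per map so that C is comparable across the (m₁, m₂) plane.
- **Labels:** |C| < ε = 0.05 is coexistence; C ≥ ε cooperation; C ≤ −ε
  competition, refined to *excluded* when the cell was committed alone but
  not together. ε is 5 % of the maximal response, below the resolution at
  which map structure is interpreted; it is configurable.
- **Ensemble normalization:** the focal cell's no-interaction reference is
  its solo endpoint in the canonical 100 µm³ medium — the same setting as
  the single-cell analysis. (At matched per-cell density the alternative
  choices differ by a few percent.)
- **Exclusion statistics:** a run counts as excluding the focal cell when
  its endpoint B < K_f; the reported composition thresholds are the
  smallest bin centers (bin width 0.05) of competitor mean-m and max-m in
  which any exclusion occurs. These minima are extreme-value statistics
  and move slightly with the number of runs; the shipped protocols use
  1,000 runs (short-delay benefit) and 2,000 runs (long-delay
  composition), which keep the acceptance run within minutes on one CPU.

## Numerics

- **Integrator:** scipy's BDF with rtol 10⁻⁸, atol 10⁻⁶ and an analytic
  Jacobian. The system is stiff (binding equilibrates in ~0.2 min against
  multi-day receptor dynamics). LSODA was rejected after it entered a
  step-size limit cycle (~10⁶ RHS evaluations per leg) near committed
  steady states of pair systems; BDF integrates the same legs in ~10²
  steps. The RHS is kept smooth (no clamping; the Hill term uses |B|ⁿ) so
  the error estimator never sees a kink; negativity beyond 10⁻⁶ relative
  is checked after each leg and raises.
- **Event handling:** cells are absent from the volume before their
  activation time and enter at rest (U = g_c/a_U, B = 0), matching
  transfer-style protocols; a `present-but-unstimulated` switch keeps them
  in the volume with constitutive turnover instead. Integration restarts
  at each entry.
- **Steady state:** legs of 2·10⁴–2·10⁵ min are integrated until the
  maximal relative derivative rate falls below 10⁻⁹ min⁻¹, with a hard cap
  of 10⁶ min (the slow clock needs ~3·10⁵ min for full relaxation);
  endpoints that hit the cap carry a non-converged flag and are excluded
  from maps and distributions.
- **Fixed points:** the three steady-state conditions reduce to one scalar
  equation in B; roots are located by a sign-change scan on 10⁴ log-spaced
  points up to `10·(g_c+g_f)/min(a_U,a_B)` (also capped by the IL-2 supply
  `s_m/a_B`) and polished by bracketed root finding, then classified by
  the eigenvalues of the 3-D Jacobian. Real parts within 10⁻¹⁰ of zero are
  flagged marginal and not counted as stable.
- **Bisections:** the commitment threshold is bisected to 10⁻³ in m after
  a 6-point monotonicity pre-scan (non-monotone outcomes raise with the
  scan attached); the critical window is bisected to 10 min after a
  5-interval pre-scan, with explicit `no_window` / `always_excludes`
  flags. Both are verified against brute-force grid scans in the tests.
- **Seeds:** one top-level seed; per-run generators derive from
  `SeedSequence((seed, run_id))`, so ensembles are reproducible and
  order-invariant.

## The noise model

Initial-receptor noise (`NoiseSpec`) draws the entering cell's U from a
lognormal with the resting mean and a configurable coefficient of
variation. The lognormal is the standard choice for protein-copy-number
variability; since the magnitude of that variability is context-dependent,
no default cv is asserted and the noise path is validated for
reproducibility and scale, not for a specific exclusion probability.

## What the simulations do and do not show

All results are properties of the calibrated deterministic model.
Passing tests show that the implementation reproduces the intended
regime — threshold, window, phase-map structure, ensemble statistics —
not that real T-cell clusters obey these equations: the model omits
spatial structure and synaptic secretion, stochastic reaction noise,
explicit pSTAT5 dynamics, the three-subunit receptor, proliferation, and
any heterogeneity beyond the TCR strength m and (optionally) initial
receptor counts. The control variants (linear feedback, constant induced
synthesis) are hypothetical circuits used to show that the nonlinearity
is what creates the time-dependent competition; their parameters are
matched to the Hill form's scale (slope at K_f, half-saturation output)
rather than calibrated independently.
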