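# Methods

## 1. Branched pathway model

### States (16, all in µM except mRNA in arbitrary concentration units)

| group | species |
|---|---|
| IKK relay | `p105` (fraction intact), `tpl2a` (fraction active) |
| MKK6 arm | `mkk6`, `mkk6_p`, `mkk6_pp` |
| MKK4 arm | `mkk4`, `mkk4_p`, `mkk4_pp` |
| p38 | `p38`, `p38_p`, `p38_pp` |
| NFκB module | `nfkb_ikb` (cytoplasmic complex), `nfkb_c` (free cytoplasmic), `nfkb_n` (nuclear), `ikb` (free IκB), `ikb_mrna` |

Reported activities are baseline-deducted `p38_pp` and `nfkb_n`.

### Inputs

Each stimulus maps to two receptor-proximal activity curves, IKK(t) and
TAK1(t), each a difference of exponentials normalized to its amplitude, with
an optional delayed second phase (used for the LPS/TRIF arm). Curve output
is clipped to [0, 1]; the per-cell `receptor_amplitude` then scales both
curves inside the ODE, so sampled amplitudes act multiplicatively and are
not clipped. Dose acts through `dose/(dose + half_dose)`, normalized to 1 at
the stimulus' reference high dose. `mock` (or dose 0) yields identically
zero inputs and, by construction of the resting equilibrium, identically
zero activity.

Shipped stimulus shapes (amplitude, rise τ, decay τ, all minutes):

| stimulus | IKK | TAK1 | half dose | reference dose |
|---|---|---|---|---|
| TNF  | 0.9, 1.5, 12 | 0.45, 1.5, 10 | 1 | 100 ng/ml |
| LPS  | 0.75, 5, 45 + second phase 0.35 @ 60 | 0.95, 30, 170 | 1 | 100 |
| P3C4 | 1.0, 4, 55 | 0.75, 10, 70 | 1 | 100 |
| CpG  | 0.5, 22, 90 | 0.45, 28, 110 | 30 | 1000 nM |

These are calibrated to the qualitative phenomenology: TNF weak and
transient, LPS biphasic and sustained with the MKK6-pp peak preceding the
MKK4-pp peak, P3C4 intermediate, CpG slow.

### Kinetics

Both MAP2K arms and both p38 steps use distributive two-step phosphorylation
with Hill-Michaelis kinetics, v·act·x^n/(K^n + x^n), and first-order
dephosphorylation per phospho-form. The IKK→Tpl2 relay degrades p105
(releasing/activating Tpl2) with basal p105 resynthesis. The NFκB module is
a reduced 5-state IκBα feedback loop: IKK degrades complexed and free IκB,
free NFκB imports into the nucleus, nuclear NFκB drives IκB mRNA synthesis
(Hill, n = 2), translated IκB recaptures cytoplasmic NFκB and exports
nuclear NFκB. There is no basal complex turnover, so the resting state is an
exact equilibrium (all NFκB complexed, zero free IκB/mRNA) and baselines are
noise-free.

### Key defaults and rationale (µM, 1/min)

- Totals: `p38_tot` 0.4, `MKK4_tot`/`MKK6_tot` 0.2, `NFkB_tot` 0.35 —
  sub-saturating so activity scales near-linearly with totals.
- p38/MKK catalysis: `v_p38_*` 0.5 with `Km` 0.6 and `n` 1 (substrate-linear
  regime); `v_mkk6` 0.22, `v_mkk4` 0.1, `Km` 0.3, `n` 1; slow MKK4
  dephosphorylation (0.03) sustains the late TAK1 branch.
- NFκB module: complex release `k_c_deg` 0.05 (release stays sub-saturating
  over the first half hour), import 1.5, export 4.0, association 8.0,
  `k_tx` 0.02, `k_tl` 0.04, mRNA turnover 0.04, IKK-driven free-IκB
  degradation 0.2. The feedback product `k_tx·k_tl` is deliberately small
  enough that the first ≈30 min of nuclear NFκB are release-dominated; the
  early-interval response therefore reflects the shared receptor amplitude,
  while later intervals are increasingly feedback- (NFκB-module-noise-)
  dominated. This reproduces the qualitative population pattern: early
  p38×NFκB correlations exceed late ones, and denoising the NFκB module
  raises amplitude/total-activity correlations.

`fit_representative` refits selected parameters (default: the three kinase
totals) to stimulus-labeled target trajectories by bounded least squares in
log10 space; this is the supported route for recalibrating the
representative cell.

### Heterogeneity

Ten parameters are lognormally distributed with median equal to the
representative value: p38 module (`p38_tot`, `MKK4_tot`, `MKK6_tot`),
receptor (`receptor_amplitude`), NFκB module (`NFkB_tot`, `k_tx`, `k_tl`,
`k_ikb_deg_ikk`, `k_imp`, `k_exp`). Default shape σ = ln2/Φ⁻¹(0.995) ≈
0.26909 puts 99 % of draws within twofold of the median (acceptance target
t2). Draws use a fixed per-parameter order so denoising one module does not
shift the random streams of the others.

### Numerics

`solve_ivp` LSODA, rtol 1e-6, atol 1e-9, max step 5 min (one frame);
equilibration requires max |dy/dt| < 1e-9 µM/min within 5000 min and
names the worst species on failure. Kinase/NFκB mass conservation on the
stimulated trace is ≈ 1e-14 relative (gate: 1e-6). One cell ≈ 0.2 s; the
shipped 500-cell population ≈ 100 s.

## 2. Units

Microscopy A.U. convert to model µM via multiplicative factors
p38: 0.1096 (= 0.08 µM / 0.73 A.U., the printed calibration) and
nfkb: 0.0383. The nfkb factor is kept as printed even though the quoted
calibration pair (0.30 µM / 7.62 A.U.) gives 0.0394; the discrepancy is
documented rather than silently "fixed".

## 3. Features

Per cell and channel, 12 core features — time to half-max activity, time to
max, max amplitude, max/min derivative (`np.gradient`), first-peak width at
half prominence (`scipy.signal.find_peaks`, rel_height 0.5), total duration
above threshold, total activity (sum of the 16 interval integrals), time to
half total activity, dominant frequency (detrended rFFT over 0–4 h,
excluding the zero bin), number of peaks, early(0–2 h)/late(2–8 h) activity
ratio — plus 16 half-hour trapezoid integrals over 0–8 h. Crossing times are
linearly interpolated; features whose span exceeds the grid are NaN, never
raised. Responder = activity > 3× baseline SD for ≥ 3 consecutive frames
within 60 min; a zero-variance baseline (routine for noise-free simulations)
falls back to an absolute floor of 1e-3.

Preprocessing subtracts each cell's baseline mean and, given ≥ 8 mock
trajectories, a smoothed mock-derived drift curve. Quality filtering drops
cells with missing frames, |activity| > 50, or < 3 baseline frames, and
reports per-rule counts.

## 4. Mutual information

Discrete–continuous k-NN estimator (k = 3): for each cell the distance to
its k-th within-class neighbor defines a radius; the count m of all-class
points strictly inside it (including the query point, the ψ(n+1) convention)
gives MI = ψ(N) − ⟨ψ(N_c)⟩ + ψ(k) − ⟨ψ(m)⟩, reported in bits. Euclidean
distance on z-scored features; NaN/constant columns dropped. Sample-size
bias is removed by computing MI on 12 subsample fractions on an even grid
over 65–90 % (one draw each) and extrapolating MI(n) = a + b/n to the
intercept. Calibration: separated two/four-class Gaussians give
1.000/2.001 bits; independent features give ≈ 0.006 bits.

## 5. Classification

BaggingClassifier over DecisionTreeClassifier(max_leaf_nodes = max_splits+1)
— 30 trees, 20 splits — with stratified 5-fold CV, class balancing by
downsampling, z-scored features; held-out predictions are aggregated into a
confusion matrix, accuracy, and per-class F1. Remaining tree hyperparameters
follow scikit-learn defaults and are echoed in the report. The
shuffled-pairing control permutes one pathway's feature block across all
cells (identity permutations redrawn for n > 5) to test whether joint
pairing carries information beyond the marginals.

## 6. Dose response

Responder fractions per dose (mock plotted at 1/100 of the lowest nonzero
dose) are fit with A = maxA·cⁿ/(halfAⁿ + cⁿ) + intersect under box bounds
HillC ∈ [0.1, 10], halfA ∈ [min, max dose], maxA ∈ [0, 1],
intersect ∈ [0, 0.9], using 5 deterministic multistarts (best residual wins,
ties by start index). A flat response flags `halfA_conc` unidentifiable, and
the p38-vs-NFκB half-max fold difference refuses unidentifiable inputs.

## 7. Correlation structure

Paired p38×NFκB Spearman matrices with pairwise-complete rows; p-values use
the t approximation above n = 30 and a pairings permutation test below;
flagged pairs require p < 0.05 and |CC| > 0.15. Constant columns yield NaN.
The shuffle control permutes one pathway within condition groups.

## 8. Gene model

dm/dt = k_syn·h⁺(NFκB) − k_deg·h⁻(p38)·m with activating/repressing Hill
terms (n = 2; K_d 0.1/0.04 µM); p38 stabilizes the transcript by repressing
degradation — the AND gate. `NFkB_only` fixes the degradation factor at 1,
the exact p38 ≡ 0 limit (bit-for-bit identical there). Populations are
sampled at 0.25/1/3/8 h. Statistics: Fano = var(ddof=1)/mean;
bimodality coefficient (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) with unbiased
skew/kurtosis (normal → 1/3, two-point → 1, uniform → 5/9); two-sided
permutation test for mean differences with p = (1+count)/(n_perm+1),
n_perm ≥ 100.

## 9. I/O, configuration, seeds

Trajectories travel as one long-format CSV (`cell_id, condition, dose,
replicate, time_min, p38_activity, nfkb_activity, units`; baseline frames
at negative times). Counts load from CSV (genes × cells) or MatrixMarket
with optional `<stem>_genes.txt`/`<stem>_cells.txt` sidecars. Pipeline
configuration is YAML with a single global seed; each stage's seed is
SHA-256 of `"<seed>:<stage>"` truncated below 2³¹, and artifacts are stamped
with a 12-hex config hash.

## 10. Generator realism and limits

The simulator reproduces: stimulus-specific kinetic fingerprints, dose
saturation with p38 requiring higher doses than NFκB, lognormal single-cell
heterogeneity with twofold-99 % spread, shared-receptor-noise-driven
early correlations, and module-denoising effects. It does not model:
receptor-level biochemistry (replaced by parametric input curves),
transcriptional bursting or measurement noise in the gene model, cell cycle
or extrinsic temporal drift (drift correction exists but the generator does
not produce drift), and the raw-time-series LSTM classifier (no deep
learning dependency is shipped). Baselines are noise-free, so responder
thresholds rely on the documented SD floor.

## 11. Problem sizes

Single cell ≈ 0.2 s; 500-cell population ≈ 100 s; feature extraction
≈ 2 ms/cell; MI at 2000 cells/class ≈ 1 s; the full test suite ≈ 5 min,
dominated by the two shipped 500-cell populations.
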