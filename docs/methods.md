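# Methods

## Quinone homologue annotation

### Masses and formulas

Monoisotopic masses use the standard atomic values (C 12 exactly,
H 1.00782503, O 15.99491462, N 14.00307401, Na 22.98976928 Da); ion m/z
subtracts one electron mass (0.00054858 Da) per positive charge, so the
[M+H]⁺ delta is +1.00727646 Da. Neutral formulas follow deterministically
from (class, *n*, *m*), where *n* counts isoprene units and *m* chain
double bonds (the "*n*:*m*" notation):

| class | C | H | O |
|---|---|---|---|
| menaquinone (MK) | 11 + 5n | 8n + 8 + 2(n−m) | 2 |
| ubiquinone (UQ) | 9 + 5n | 8n + 10 + 2(n−m) | 4 |
| plastoquinone (PQ) | 8 + 5n | 8n + 8 + 2(n−m) | 2 |
| methyl-plastoquinone | 9 + 5n | 8n + 10 + 2(n−m) | 2 |

Methyl-plastoquinone is plastoquinone plus one ring CH₂ (a methyl
replacing a ring H). Only monoisotopic masses are used; isotope-pattern
scoring is out of scope because accurate mass plus the diagnostic MS²
headgroup fragment (C₁₀H₁₃O₂⁺ at m/z 165.0910 for methyl-PQ vs C₉H₁₁O₂⁺
at 151.0754 for PQ) is what distinguishes the series in practice.

### Matching and tie-breaks

A feature is assigned to the candidate ion with the smallest |Δmmu| within
the tolerance; ties break deterministically by lower *n*, then lower *m*,
then class name, then adduct name. The default tolerance of 2.0 mmu covers
an instrument calibrated to ~1 ppm at m/z < 1000 with margin; it can be
given in ppm instead. The default search space (*n* ∈ [4, 12],
*m* ∈ [n−2, n], all four classes, all three adducts) brackets the
homologue range seen in nitrifier extracts with one margin unit.
Unassigned features are returned flagged, never dropped: decoy and
contaminant peaks must stay visible to the analyst.

Exact-mass-only matching has an intrinsic cross-class trap: e.g. the
[M+Na]⁺ of methyl-PQ *n*:*m* lies only ~2.2 mmu from the [M+H]⁺ of
MK *(n)*:*(m)*, so with a 2 mmu tolerance a ≳3σ mass-error outlier can be
misassigned across classes. The recovery property tested (≥ 99% at
σ = 0.5 mmu) holds within the methyl-PQ space; users screening all classes
at once should treat isolated sub-percent cross-class hits with suspicion.

### Quantification and reporting

Per sample, peak areas of a species' adducts are summed and divided by the
total over all assigned species (×100). This mirrors combined-adduct
extracted-ion-chromatogram quantification; as ionisation response differs
between compounds, the percentages are area shares, not molar fractions.
The report writer keeps two sub-threshold states distinct: `< 0.1`
(detected, below the 0.1% reporting floor) and `n.d.` (never detected).
Values below the floor are included in the 100% normalisation.

### Hydrogenation check

Catalytic hydrogenation saturates the isoprenoid chain (*m* → 0,
+2.01565 Da per double bond). The quinone ring is treated as unreduced:
the check is used to confirm chain unsaturation assignments, and no
ring-reduction product masses are needed for that purpose.

## Surface-confined voltammetry

### Model

State variable: reduced fraction x ∈ [0, 1] of a film with total surface
excess Γ_T (mol cm⁻²) on an electrode of geometric area A (cm²). Sweep
E(t) linear at ν (V s⁻¹). Rates (s⁻¹), with f = F/RT and n electrons
transferred in one concerted step:

    k_red = k_s · exp[−α·n·f·(E−E°′)] · exp[+a_O·(2x−1)]
    k_ox  = k_s · exp[(1−α)·n·f·(E−E°′)] · exp[−a_R·(2x−1)]
    dx/dt = k_red·(1−x) − k_ox·x
    i_F   = −n·F·A·Γ_T·dx/dt        (cathodic negative)

a_O and a_R are Frumkin lateral-interaction parameters of the oxidised and
reduced form (positive = attractive). The interaction corrections are
referenced to the half-converted layer (x = ½), which makes detailed
balance yield the Frumkin equilibrium with a single combined term
G = a_O + a_R and *no* spurious potential offset:

    E = E°′ + (1/(n·f))·[ln((1−x)/x) + G·(2x−1)]

At G = 0 this is the Nernst sigmoid (Langmuir limit) with the classical
reversible-limit closed forms — peak at E°′, FWHM = 3.53·RT/(nF)
(45.3 mV for n = 2 at 298 K), i_p = n²F²νAΓ_T/(4RT), peak charge
Q = nFAΓ_T — which serve as the normative tests of the simulator.
Attractive interactions (G > 0) sharpen the peaks, repulsive broaden them;
G > 2 makes the isotherm multivalued and the equilibrium solver returns
the globally stable branch with a bistability flag. Because the dynamic
corrections act per form, an attractive interaction on the oxidised form
only sharpens the cathodic (film-reduction) sweep at finite k_s,
reproducing the sharp-cathodic/broad-anodic asymmetry seen for microbial
quinone films. The two-electron quinone/quinol transfer is modelled as
one concerted step with n = 2 by default (overridable); a sequential
1e⁻ + 1e⁻ scheme would need two more potentials that the data cannot
separate.

Proton stoichiometry is not modelled: E°′ is the apparent (formal)
potential at the measurement pH (7.0). The Ag|AgCl(sat. KCl) → SHE
conversion adds +199 mV as a fixed constant, without temperature
correction, matching how such measurements are conventionally reported.

### Numerics

The coverage ODE is integrated as u = ln((1−x)/x): the logit resolves both
coverage tails to relative precision, so the reconstructed current — a
near-cancellation of large forward and backward rates when the film is
almost fully converted — does not amplify absolute solver error in x. The
production integrator is a compiled (numba) adaptive TR-BDF2 scheme
(L-stable; a merely A-stable step rings on the stiff quasi-equilibrium
that the film rides between peaks) with step-doubling error control and
local extrapolation, relative tolerance 1e−8 for simulation and 1e−7
inside fits. It is validated in the test suite against scipy's LSODA on
identical problems (agreement ≤ 1e−4 of peak current across kinetic
regimes). Default output grid: one point per 0.5 mV. Initial coverage is
the Frumkin equilibrium at the start potential (the sweep must bracket E°′
by ≥ 0.15 V on both sides so the film starts fully oxidised or reduced).

### Peak metrics and baseline

The capacitive baseline is a per-sweep-leg line estimated by Theil–Sen
regression plus two masked least-squares refinements — robust against a
faradaic wave occupying ~20% of a leg — or on user-chosen flank fractions
when the wave defeats the automatic mask; a constant (median) mode exists
for flat offsets. Peaks are current extrema per sweep direction and must
exceed 5 robust standard deviations (MAD-based) of the leg's current;
pure noise yields "no peak", not an exception. FWHM is interpolated at
half height; peak charge integrates i dt over the leg (surface waves decay
to baseline within a leg that brackets E°′ by 0.15 V).

### Fitting

Free parameters: E°′, log₁₀Γ_T, log₁₀k_s, α, a_O, a_R and a linear
baseline per leg, refined by least squares (lmfit/trust-region-reflective)
on currents normalised by the data's peak current. Auto-initialisation
uses the peak midpoint (E_pc+E_pa)/2 for E°′ and the peak charge for Γ_T.
Bounds: Γ_T ∈ [1e−12, 1e−8] mol cm⁻², k_s ∈ [1e−3, 1e4] s⁻¹, α ∈ [0.3, 0.7],
a ∈ [−2, 2], E°′ inside the sweep window; parameters ending at a bound are
flagged. Robustness against local minima comes from seeded multistart
(default 8 starts, default seed 20250805) over k_s, the interaction
parameters and E°′; starts run sequentially and stop early once the best
RSS has not improved by > 0.1% for two consecutive starts (after at least
three), which typically ends after 3–4 starts without changing the
selected optimum. Fits are deterministic given the seed. Uncertainties
are the usual local (covariance-based) estimates; over seeded noisy
replicates the 95% intervals for E°′ cover the truth ≥ 80% of the time in
the test suite's recovery experiment.

## Synthetic data

The generators produce exactly the inputs the two branches consume, from
known ground truth, bit-reproducibly per seed.

**Feature tables** emit one feature per species and adduct at the
theoretical m/z + Normal(0, σ) mmu (default σ = 0.5 mmu, the scale of a
well-calibrated Orbitrap), with areas = scale × abundance × adduct split.
The adduct split defaults to 80/15/5 for [M+H]⁺/[M+NH₄]⁺/[M+Na]⁺ —
a typical positive-ESI pattern for neutral lipids; true instrument ratios
vary and only the combined-area quantification contract matters, so the
split is configurable and carried in the ground truth. Decoys are drawn
uniformly and rejected within 5 mmu of any candidate. The built-in
nitrifier fixtures encode the published composition of the two isolates;
a "< 0.1" entry is encoded as 0.05%, and the printed percentages are
renormalised to sum to exactly 100 (the largest resulting shift is
0.07 percentage points). What these tables do **not** emulate —
chromatographic peak shape, co-elution, isotope envelopes, in-source
fragmentation, response-factor differences — means a passing round-trip
validates the annotation and quantification arithmetic, not
instrument-level robustness.

**Voltammograms** are the forward model at the study's cell conditions
(20 mV s⁻¹, 0.126 cm², 303 K, two-electron couple, sweep +0.10 → −0.45 V
vs Ag|AgCl at 2 mV spacing, as a digitised instrument file) plus a linear
capacitive ramp and additive Gaussian current noise; the default film
parameters (Γ_T = 1e−10 mol cm⁻², k_s = 5 s⁻¹, a_O = 0.9, a_R = 0)
produce the sharp-cathodic/broad-anodic shape characteristic of adsorbed
quinone films, and noise is specified as SNR at the cathodic peak
(20 in the recovery experiments). Real cell artefacts not emulated:
ohmic drop, nonlinear double-layer charging, multi-couple overlap, film
loss between cycles.

## Problem sizes in the shipped experiments

Closed-form checks run on a 0.2 mV grid (5502 points); recovery
experiments use 20 replicates at SNR 20 (552 points each); the fixture
tables hold 42 true features plus decoys. These sizes make the full suite
and the acceptance script each run in about a minute on one CPU while
leaving the statistics stable across seeds.

## Known limitations

* Annotation is exact-mass only; no retention-time model, no MS² spectrum
  scoring beyond the headgroup-fragment formulas, charge +1 only.
* The voltammetric model is single-couple, surface-confined, pH-implicit;
  no diffusion-controlled contribution, no IR drop, no Pourbaix analysis.
* Which parameters the original instrument-data fits held fixed is
  unknowable from the published record; the recovery experiments therefore
  validate the procedure against synthetic ground truth at the published
  conditions rather than against archived instrument files.
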