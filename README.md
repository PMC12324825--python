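# quinox

Tools for two measurements that together characterise the respiratory
quinones of slow-growing nitrifying bacteria (*Nitrospira*), whose pools
are dominated by **methyl-plastoquinones** — plastoquinone analogues with
one extra ring methyl:

1. **Exact-mass annotation and quantification of quinone homologue series**
   from centroided LC-ESI(+)-HRMS feature tables. Quinone candidates are
   enumerated over class (MK/UQ/PQ/methyl-PQ), isoprenoid chain length *n*,
   chain double-bond count *m* and adduct ([M+H]⁺, [M+NH₄]⁺, [M+Na]⁺);
   features are assigned by mass deviation
   Δmmu = (measured − calculated)·10³ within a tolerance (default 2 mmu),
   and species abundances are percentages of combined-adduct peak area.
2. **Formal redox potentials of surface-adsorbed quinones** from cyclic
   voltammetry. A surface-confined couple O + n e⁻ ⇌ R with lateral
   (Frumkin) interactions is simulated via Butler–Volmer kinetics on the
   reduced fraction *x*:

   d*x*/d*t* = k_s·e^(−αnf(E−E°′))·e^(a_O(2x−1))·(1−x)
             − k_s·e^((1−α)nf(E−E°′))·e^(−a_R(2x−1))·x,  f = F/RT

   with faradaic current i = −nFAΓ_T·dx/dt (cathodic negative). Measured
   voltammograms are fitted by seeded multistart least squares
   (E°′, Γ_T, k_s, α, a_O, a_R plus per-leg linear baselines) and E°′ is
   reported vs Ag|AgCl and vs SHE (+199 mV).

It is aimed at microbial-physiology and bioelectrochemistry labs that
profile quinones from small amounts of biomass.

## Worked example

```sh
quinox demo --outdir demo --seed 20250805
```

generates both synthetic input kinds from known ground truth, runs both
pipelines, and prints:

```
seed	20250805
features_assigned	42/52
species_detected	12
e0_true_vs_she_mV	57.0
e0_fit_vs_she_mV	57.2
e0_recovery_error_mV	0.17
```

42 of 52 features are assigned (the 10 unassigned ones are decoys placed
≥ 5 mmu from every candidate), and the formal potential of the simulated
quinone film (+57 mV vs SHE, the value typical of a methyl-plastoquinone
pool) is recovered within 0.2 mV. `demo/quinone_report.tsv` is a
composition table, e.g.

```
Quinone	Accurate mass (m/z)	AEC	Delta mmu	N_inopinata	N_moscoviensis
Methyl-PQ 8:8	695.577	C49H75O2	0.8	45.2	2.1
Methyl-PQ 9:9	763.639	C54H83O2	0.0	0.6	67.1
Methyl-PQ 10:10	831.701	C59H91O2	0.1	< 0.1	29.2
```

with `n.d.` (never detected) kept distinct from `< 0.1` (detected below
the reporting floor).

Individual steps are available as `quinox annotate`, `quinox redox` and
`quinox simulate`, and as library functions (`annotate_features`,
`simulate_cv`, `fit_cv`, …).

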