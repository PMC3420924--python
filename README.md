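# dimerfes

Free-energy pipeline for assessing the **relative stability of
membrane-receptor dimer interfaces** (GPCR homodimers in particular): biased
sampling over dimerization collective variables, reconstruction of the
potential of mean force, and conversion to dimerization constants, standard
free energies, and kinetic lifetimes.

It is aimed at computational structural biologists who run umbrella-sampling
/ metadynamics studies of protein–protein association in membranes and want
a self-contained, testable implementation of the analysis chain — exercised
end to end on synthetic Langevin dynamics over model potentials with known
ground truth, so every stage can be validated against an exact reference.

## The model

A dimer of protomers *a* and *b* in a membrane is described by three
collective variables (CVs):

* `r` — distance between the centers of mass of the two TM bundles (nm);
* `θa`, `θb` — rotational angles of each protomer: the arccosine of the
  inner product of the normalized in-plane projections of (interface-helix
  COM − bundle COM) and (partner COM − own COM), each in [0, π].

Sampling combines a **harmonic umbrella restraint** on `r`
(k = 2400 kcal/(mol·nm²), ~40–50 windows) with **well-tempered
metadynamics** on (θa, θb) (initial hill height 0.12 kcal/mol, σ_M = 0.035
rad, stride 10 ps, bias factor γ = 15) inside steep repulsive walls that
confine the angles to a region Ω₀.  Analysis then proceeds:

1. **Reweighting** removes the time-dependent metadynamics bias: each frame
   gets weight ∝ exp(+β[V(θ(t), t) − c(t)]), with the running offset c(t)
   evaluated on a grid from the evolving bias.
2. **WHAM** combines the umbrella windows into F(r), offset to zero over a
   monomeric reference range (4.5–4.8 nm for TM4/3-like setups, 5.5–5.9 nm
   for TM1/H8-like ones); errors come from a moving-block bootstrap.
3. **Thermodynamics**: with ‖Ω₀‖ = (maxθ − minθ − σ_M)², the surface
   dimerization constant is

       K_D = (‖Ω₀‖ / (2π)²) · ∫₀^{r_D} 2πr e^{−βF(r)} dr   [µm²]

   and on the mole-fraction scale K_X = (N_L/A)·K_D (lipid surface density
   N_L/A ≈ 1.65×10⁶ µm⁻²), ΔG_X° = −RT ln K_X.
4. **Kinetics**: the long-time 2D Smoluchowski capture rate
   k_on = 4πD_C / [ln(4D_C t/R²) − 2γ_EM], k_off = k_on/K_D, and the dimer
   half-life from the closed-form mass-action decay of an initial dimer
   density [D]₀.

The synthetic-dynamics module integrates overdamped (Brownian) Langevin
dynamics of the CV triplet on configurable model potentials — a dimer well
in r, a flat monomeric region, shallow angular minima — whose exact marginal
F(r) is available by quadrature, which is what makes the whole pipeline
falsifiable.

## Worked example

Desk conversion of a measured dimerization constant (K_D = 7.2 µm² for a
TM1/H8 homodimer) into a standard free energy:

```python
>>> import dimerfes as df
>>> m = df.MembraneSpec(lipid_density=1.65e6, temperature=300.0)
>>> kx = df.k_x(7.2, m)
>>> kx
11880000.0
>>> df.delta_g_x(kx, m)
-9.711685928552924
```

K_X ≈ 1.19×10⁷ means dimers are overwhelmingly favored on the mole-fraction
standard state, and ΔG_X° ≈ −9.7 kcal/mol is the corresponding association
free energy.

A reduced end-to-end run on the shallower TM4/3-like preset potential
(20 windows × 30 000 steps, soft umbrellas; about one second):

```python
>>> cfg = df.PipelineConfig(interface="TM4/3", seed=5, n_windows=20,
...                         n_steps=30_000, n_boot=2, force_constant=600.0,
...                         output_stride=0.4)
>>> res = df.run_pipeline(cfg)
>>> round(res.summary["f_min_kcal_mol"], 2), res.summary["r_min_nm"]
(-5.54, 3.45)
>>> round(res.summary["thermo"]["delta_g_kcal_mol"], 2)
-3.03
```

The dimer well is found at r = 3.45 nm; at this toy problem size the depth
(−5.5 kcal/mol vs the constructed −4.8) and ΔG_X° carry visible sampling
error — the production defaults (`PipelineConfig()`: 48 windows ×
4×10⁵ steps) recover the constructed landscape to a few tenths of a
kcal/mol.  The same pipeline is available from the shell:

```sh
dimerfes run-all --interface "TM1/H8" --seed 17 --outdir out/
dimerfes kinetics --k-d 7.2 --d-c 0.08 --contact-radius 0.002 \
    --timescale 10 --d0 1e-3
```

Each run directory contains the exact config + seed used, per-window
COLVAR/HILLS text files, the referenced F(r) profile with bootstrap errors,
and a machine-readable `summary.json`.

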