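# phrelay

Analysis pipeline for the conformational dynamics behind pH-regulated
Ca²⁺ release in C-type lectin receptors.

Endocytic lectins such as langerin bind pathogens through a Ca²⁺-dependent
carbohydrate site and must release both when the endosome acidifies from
pH 7 to ~6. The Ca²⁺-coordinating aspartate/glutamate side chains are not
themselves titratable in that range, so the pH signal has to travel from a
solvent-exposed sensor histidine through the protein's hydrogen-bond
network into the buried binding pocket. `phrelay` packages the
computational chain used to dissect such a relay mechanism, for people
working with MD ensembles of pH-sensitive metal-binding proteins:

- **Featurization** (`phrelay.features`): distances, group-minimum
  distances, geometric hydrogen bonds (donor–acceptor ≤ 0.35 nm,
  H–donor–acceptor angle ≤ 30°, both configurable), Cα RMSF, fitted RMSD
  series, and replica-mean histograms with percentile-bootstrap bands
  (replicas resampled, 1000 samples, 95% by default).
- **Projections** (`phrelay.reduce`): joint PCA across protonation
  ensembles (eigendecomposition of the pooled covariance) and tICA,
  solving C(τ) v = λ C(0) v with symmetrized lagged covariances; free-energy
  surfaces F = −kT ln p on 2D projections and ensemble difference
  densities.
- **Clustering** (`phrelay.cluster`): density-based common-nearest-neighbor
  (CNN) clustering — points a, b join when they are mutual r-neighbors
  sharing at least n_c neighbors — with an O(n²) reference implementation
  for exactness checks.
- **Core-set Markov models** (`phrelay.msm`): milestoning assignment
  (frames between cores inherit the last visited core), sliding-window
  transition counts, reversible estimation by count symmetrization, and
  the implied-timescale lag test t_i = −τ/ln λ_{i+1}.
- **Steered-MD rupture statistics** (`phrelay.rupture`): smoothed-maximum
  rupture detection with a sustained-drop acceptance rule, and notched-box
  cohort summaries (notch 1.57·IQR/√n, outliers beyond 1.5 IQR).
- **Unfolding kinetics** (`phrelay.kinetics`): event classification from
  RMSD or hydrogen-bond persistence, survival curves, and the
  right-censored exponential MLE k̂ = n_events/Σt with t₁/₂ = ln 2/k̂.
- **Ensemble pKa** (`phrelay.pka`): parsing of PROPKA 3.1 summaries,
  including coupled carboxyl–carboxyl (protonated dyad) alternatives a/b,
  and per-residue distribution statistics.
- **ITC thermodynamics** (`phrelay.thermo`): ΔG = RT ln K_d (K_d in mol/l,
  R = 8.314 J/(K·mol)), pH sensitivities ΔΔG = ΔG_pH6 − ΔG_pH7, and the
  one-set-of-sites isotherm fit with the Wiseman c-value diagnostic
  (c = n·[cell]/K_d, low-c warning below 5).
- **Synthetic ground truth** (`phrelay.synthetic`): overdamped Langevin
  samplers with a fine-grid transfer-operator oracle, planted rupture
  traces, censored exponential unfolding times, one-site thermograms, a
  hydrogen-bond toy trajectory, and pKa record generators — every output
  ships with its planted truth, so each stage is testable end to end.

## Worked example

Converting measured Ca²⁺ dissociation constants to binding free energies
and pH sensitivities (the bundled table holds published ITC values for
wildtype langerin and two point mutants at pH 6 and 7, T = 300 K):

```python
>>> from phrelay import thermo
>>> print(thermo.free_energy_table().to_string(index=False))
      variant  ph kd_um  dg_kj_mol  dg_err_kj_mol  ddg_kj_mol
           WT 6.0 800.0      -17.8       0.467662         5.1
           WT 7.0 105.0      -22.9       0.356314         5.1
        H294A 6.0 125.0      -22.4       0.099768         3.2
        H294A 7.0  35.0      -25.6       1.068943         3.2
        E261D 6.0 742.0      -18.0       0.473965         4.8
        E261D 7.0 108.0      -22.8       0.254039         4.8
WT-remeasured 6.0 802.0      -17.8       0.466496         4.9
WT-remeasured 7.0 113.0      -22.7       0.309016         4.9
```

A K_d of 105 μM corresponds to ΔG = −22.9 kJ/mol; the wildtype loses
5.1 kJ/mol of Ca²⁺ affinity between pH 7 and pH 6, and removing the
sensor histidine (H294A) cuts that sensitivity to 3.2 kJ/mol — the
residual pointing to a second, carboxyl-dyad sensor.

Fitting unfolding kinetics with right-censoring:

```python
>>> import numpy as np
>>> from phrelay import synthetic, kinetics
>>> data, truth = synthetic.generate_unfolding_times(
...     k_per_ns=np.log(2) / 93.0, t_max_ns=220.0, n=60, seed=5)
>>> fit = kinetics.fit_exponential(data)
>>> round(fit.half_life_ns, 1), round(fit.sigma_half_life_ns, 1)
(82.9, 11.5)
```

Sixty 220 ns trajectories with a planted 93 ns half-life give
t₁/₂ = 82.9 ± 11.5 ns from the censored MLE — the truth sits inside the
1σ interval, as it should for most seeds.

A complete miniature study — two protonation-state ensembles, 40 pulling
traces per condition, 60 unfolding records per condition, pKa fixtures
and the measurement table — is generated and analyzed by the CLI:

```sh
phrelay demo --outdir study --seed 0
phrelay run --config study/config.yaml
```

which writes free-energy, rupture, kinetics, pKa and implied-timescale
tables plus provenance (config hash, seed, version) under
`study/results/`.

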