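# fieldlab

Forward modeling of transcranial direct current stimulation (tDCS) electric
fields on layered-sphere volume-conductor head phantoms.

## The problem

tDCS delivers a weak direct current (typically 1–2 mA) to the brain through
scalp electrodes. The current does not stay under the electrodes: how much
reaches a given cortical or subcortical region — motor cortex, prefrontal
cortex, insula, cingulate, thalamus, brainstem — depends on the electrode
montage and on the conductivity structure of the head (skin, fat, skull,
CSF, gray and white matter). Forward models answer the planning question a
clinician or researcher actually has: *for this montage, where does the
current go, how strong is it, and how focal is it?*

`fieldlab` implements the full forward-modeling chain on a synthetic head:

1. **Phantom** — a labeled multi-layer sphere (white 58, gray 72, CSF 76,
   skull 83, fat 85, skin 92 mm by default) with geometric stand-ins for
   the regions of interest, in place of an individually segmented MRI.
2. **Montage** — 10-10/10-20 electrode positions from the proportional-arc
   construction; 5 × 7 cm sponge pads and 12 mm high-definition disks
   stamped onto the scalp. Five named montages are built in: `M1-SO`,
   `DLPFC`, `Cz-Oz`, `HD-4x1`, `HD-2x2`.
3. **Solver** — the quasi-static continuity equation ∇·(σ∇V) = 0 on the
   voxel lattice (7-point finite volume, harmonic-mean face conductances),
   with equipotential electrodes, insulated outer surfaces, and the
   potential rescaled so the delivered current is exactly the requested
   total (1 mA by default). Fields follow as E = −∇V and J = σE.
4. **Analysis** — robust (99.9th-percentile) and absolute peaks per region,
   focal volume (brain volume above half the robust peak), depth profiles,
   and montage comparison tables including the deep/superficial peak ratio.
5. **Oracle** — an analytic N-layer-sphere solution (Legendre series with
   per-layer transfer matrices) for point current electrodes, used to
   validate the voxel solver end to end.

Tissue conductivities (S/m): skin 0.465, fat 0.025, skull 0.01, CSF 1.65,
gray 0.276, white 0.126, saline sponge/gel 1.4, electrode 5.99 × 10⁷; air
is treated as insulating.

## Worked example

```bash
python examples/03_solve_m1so.py
```

```
solved 411151 unknowns in 675 CG iterations, residual 9.7e-09, delivered 1.0000 mA
brain peak |E|: robust 0.186 V/m, max 0.213 V/m

per-ROI robust peak |E| (V/m) and |J| (A/m^2):
  PFC        E 0.2126   J 0.05867
  M1         E 0.1516   J 0.04184
  S1         E 0.1116   J 0.03080
  occipital  E 0.1016   J 0.02804
  insula_L   E 0.1211   J 0.03343
  insula_R   E 0.0911   J 0.02513
  cingulate  E 0.1876   J 0.05177
  thalamus   E 0.1061   J 0.01336
  brainstem  E 0.0806   J 0.01560
```

This is the classic motor-cortex/supraorbital montage at 1 mA on the 2 mm
phantom. The brain peak sits well below 1 V/m — the sub-threshold regime
characteristic of tDCS — and the largest peak is prefrontal rather than
under the motor-cortex anode, the well-known spread of conventional pad
montages. Deep structures (insula, cingulate, thalamus, brainstem) receive
a substantial fraction of the superficial peak. Running
`examples/05_compare_montages.py` shows the high-definition montages
reversing that picture: focal volumes shrink by almost an order of
magnitude (HD-2x2 < HD-4x1 ≪ M1-SO) and the deep/superficial peak ratio
drops from ≈0.9 to ≈0.5.

The other examples build the phantom (`01`), print the 10-10 geometry
(`02`), and validate the solver against the analytic sphere (`04`).

A thin CLI wraps the same pipeline:

```bash
fieldlab run --config run.yaml          # phantom -> montage -> solve -> reports
fieldlab compare out1 out2 ... --out comparison.csv
fieldlab validate-sphere --voxel 2
```

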