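# Canonical seven-layer skin optical model for dual-wavelength (590/780 nm)
# diffuse-reflectance simulation.
#
# Units: thickness d in mm (.inf marks the semi-infinite basal layer),
# absorption/scattering coefficients in 1/mm.  Cb is the volume fraction of
# blood at baseline perfusion.  mua is tabulated per wavelength for three
# perfusion states: 0.1x baseline (hypoperfusion), 1.0x (baseline) and
# 3.0x (hyperemia).  mus and g are taken independent of wavelength and of
# the blood fraction; the basal muscle layer is held fixed at all
# perfusion states.
version: 1
n_above: 1.0
layers:
  - name: stratum_corneum
    d: 0.02
    Cb: 0.0
    mus: 100.0
    g: 0.86
    n: 1.5
    mua:
      590: {0.1: 0.025, 1.0: 0.025, 3.0: 0.025}
      780: {0.1: 0.025, 1.0: 0.025, 3.0: 0.025}
  - name: vital_epidermis
    d: 0.08
    Cb: 0.0
    mus: 45.0
    g: 0.80
    n: 1.34
    mua:
      590: {0.1: 0.982, 1.0: 0.982, 3.0: 0.982}
      780: {0.1: 0.338, 1.0: 0.339, 3.0: 0.338}
  - name: upper_vascular_plexus
    d: 0.1
    Cb: 0.20
    mus: 35.0
    g: 0.95
    n: 1.39
    mua:
      590: {0.1: 0.050, 1.0: 0.233, 3.0: 0.471}
      780: {0.1: 0.026, 1.0: 0.030, 3.0: 0.035}
  - name: reticular_dermis
    d: 1.5
    Cb: 0.04
    mus: 25.0
    g: 0.80
    n: 1.40
    mua:
      590: {0.1: 0.029, 1.0: 0.067, 3.0: 0.141}
      780: {0.1: 0.025, 1.0: 0.026, 3.0: 0.028}
  - name: deep_vascular_plexus
    d: 0.2
    Cb: 0.10
    mus: 30.0
    g: 0.95
    n: 1.38
    mua:
      590: {0.1: 0.036, 1.0: 0.129, 3.0: 0.285}
      780: {0.1: 0.025, 1.0: 0.027, 3.0: 0.031}
  - name: subcutaneous_fat
    d: 1.0
    Cb: 0.05
    mus: 5.0
    g: 0.75
    n: 1.44
    mua:
      590: {0.1: 0.031, 1.0: 0.077, 3.0: 0.167}
      780: {0.1: 0.025, 1.0: 0.026, 3.0: 0.028}
  - name: muscle
    d: .inf
    Cb: 0.40
    mus: 53.0
    g: 0.95
    n: 1.37
    mua:
      590: {0.1: 0.442, 1.0: 0.442, 3.0: 0.442}
      780: {0.1: 0.034, 1.0: 0.034, 3.0: 0.034}
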