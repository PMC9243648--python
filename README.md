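# lrbcsim

Monte Carlo modeling of skin diffuse reflectance and estimation of the
cutaneous red-blood-cell pathlength index **L<sub>RBC</sub>** from
dual-wavelength (590/780 nm) reflectometry.

## The problem

Skin perfusion is distributed in two thin, blood-rich horizontal layers
(the upper and deep vascular plexus). An optical probe that illuminates
the skin and collects diffusely reflected light about a millimeter away
probes these layers: at 590 nm hemoglobin absorbs strongly, so the
remitted intensity tracks the local amount of red blood cells, while at
780 nm blood absorption is faint and the remitted intensity is almost
independent of blood content, which makes it a reference for every other
source of light loss. `lrbcsim` is for researchers in tissue optics and
microvascular physiology who want a quantitative, physical-units index of
skin red-blood-cell content — e.g. to track a venous-occlusion challenge,
or to recalibrate transcutaneous fluorescence measurements as local blood
volume drifts.

## The model

Attenuation at wavelength λ, A(λ) = ln[I₀(λ)/Iₑ(λ)], decomposes into
blood, bloodless-tissue and geometry terms. For 550–900 nm the latter two
are nearly wavelength-independent, so the two-wavelength difference
isolates the red-blood-cell term of a modified Beer–Lambert law:

    A(λ₁) − A(λ₂) = L_RBC · [PF(λ₁)·μ_eff,RBC(λ₁) − PF(λ₂)·μ_eff,RBC(λ₂)]

with μ_eff,RBC the effective attenuation coefficient of red blood cells,
PF(λ) a pathlength factor, and L<sub>RBC</sub> the mean pathlength of the
detected light through red blood cells — a length, reported in μm.
Setting PF(590) = 1 and PF(780) = RPF (the differential pathlength
factor, estimated from occlusion traces) gives the working estimator

    L_RBC = [ln(I₀(590)/I₀(780)) + ln(Iₑ(780)/Iₑ(590))]
            / [μ_eff(590) − RPF·μ_eff(780)].

Both wavelengths sit near hemoglobin isosbestic points, so the estimate
is insensitive to oxygen saturation.

The package validates this algebra with a weighted-packet Monte Carlo
simulation of photon transport in a seven-layer skin model (stratum
corneum → muscle, with tabulated thickness, blood fraction, μa, μs, g, n
per layer), tallies diffuse reflectance versus radial exit distance, and
evaluates the estimator on the 0.5–1.2 mm detection annulus. A synthetic
dual-wavelength lock-in reflectometer (1100/1000 Hz carriers, 50
k-samples/s, software quadrature demodulation to 50 samples/s) emulates
the measurement chain so the full experimental pipeline — including RPF
calibration by regression of Δln Vₑ(780) on Δln Vₑ(590) during an
occlusion, scaled by μ_eff(590)/μ_eff(780) = 14.87 — is testable end to
end without hardware.

## Worked example

```python
from lrbcsim import (LrbcConstants, TransportConfig, annulus_intensity,
                     canonical_skin_model, lrbc_from_intensities, run_transport)

config = TransportConfig(n_packets=100_000, seed=1)
ne = {}
for wl in (590, 780):
    result = run_transport(canonical_skin_model(1.0, wl), config)
    ne[wl] = annulus_intensity(result, 0.5, 1.2)
    print(f"{wl} nm: Ne = {ne[wl]:.4f} per incident photon")

lrbc = lrbc_from_intensities(1.0, ne[590], ne[780], LrbcConstants())
print(f"baseline LRBC = {lrbc:.1f} um")
```

prints

```
590 nm: Ne = 0.0866 per incident photon
780 nm: Ne = 0.1530 per incident photon
baseline LRBC = 16.3 um
```

Ne is the diffusely reflected weight per incident photon exiting between
0.5 and 1.2 mm from the illumination axis. More of the strongly absorbed
590 nm light is lost to blood, so Ne(590) < Ne(780); the log of that
contrast divided by the estimator denominator (34.9 mm⁻¹ with the default
constants) gives a baseline red-blood-cell pathlength of ~16 μm, about
what you expect from a single traversal of the upper vascular plexus
(20% blood × 100 μm thickness = 20 μm). Simulating hypoperfused (0.1×)
or hyperemic (3×) skin moves LRBC down or up with blood content.

The same estimator applied to synthetic occlusion recordings:

```sh
lrbcsim synth --shape biphasic --seed 7 --out demod.csv
lrbcsim rpf --demod-csv demod.csv --inflation-time 180
lrbcsim lrbc --demod-csv demod.csv --out series.csv
```

CLI subcommands: `simulate`, `profile`, `lrbc`, `rpf`, `synth`,
`calibrate`, `lrbc-curve`. Every run writes a JSON manifest with the
parameters and seeds needed to reproduce it bit-identically.

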