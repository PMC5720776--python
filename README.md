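# selfgate3d

Retrospective self-gated 3D cardiac MRI for small animals, as a tested,
fully simulated toolkit. It targets the problem of imaging myocardial
infarction in mice — heart rates of 400–550 bpm and respiratory rates of
60–150 breaths/min make external ECG leads and breathing sensors fragile —
by deriving both motion signals from the imaging data itself and
reconstructing motion-consistent cardiac phases from a short (~1.5 min)
undersampled scan.

The package covers the whole chain:

* **trajectory** — golden-angle (180°/φ ≈ 111.246°) stack-of-stars
  sampling with partition-first ordering, so the k-space center line is
  re-acquired every TR × n_partitions = 42 ms;
* **phantom** — a dynamic digital mouse thorax (beating, breathing,
  hyperenhanced infarct sector, multi-coil, noisy) and an exact k-space
  simulator that evaluates every acquired line at its own timestamp;
* **selfgating** — z intensity profiles from the k-space-center samples,
  center-of-mass motion trace, band-pass separation (1.0–2.5 Hz
  respiratory, 6.7–9.2 Hz cardiac), rate-adaptive peak detection, and
  coil-channel selection including a virtual sum-of-squares channel;
* **realign** — six respiratory-amplitude bins with adaptive selection of
  the most populated one, cardiac phase assignment from the mean R–R
  interval, ±30 % arrhythmia cycle rejection, quiescent-phase choice;
* **recon** — slice-decoupled NUFFT reconstruction, by density-compensated
  regridding or by temporal-total-variation compressed sensing,

      argmin λ‖Tρ‖₁  subject to  ‖d − P·F·ρ‖₂² < ε,

  solved with a Bregman-type iteration (F: NUFFT on the radial pattern,
  T: cyclic temporal TV over cardiac phases);
* **quantify** — blood/myocardium contrast-to-noise ratio
  CNR = (μ_cavity − μ_wall)/√(σ²_cavity + σ²_wall), infarct size as
  Area_infarct/(Area_infarct + Area_healthy) via Otsu segmentation inside
  a wall mask, and regression + Bland–Altman agreement statistics.

See `docs/methods.md` for the model, defaults, and numerical choices.

## Worked example

Simulate the protocol-scale acquisition (1600 projections, 10 partitions,
4 coils, 430 bpm / 78 breaths/min, 5 % complex noise), self-gate it, and
realign:

```python
from selfgate3d import (AcquisitionConfig, PhantomSpec, simulate_kspace,
                        extract_gating, realign)

config = AcquisitionConfig(matrix=(128, 128, 10), n_coils=4)
spec = PhantomSpec(grid=(128, 128, 10), seed=1)
kspace = simulate_kspace(spec, config)

gating = extract_gating(kspace)
print(f"heart rate: {gating.heart_rate_bpm:.2f} bpm "
      f"(true {kspace.ground_truth.heart_rate_bpm:.2f})")
print(f"resp rate:  {gating.resp_rate_bpm:.2f} /min (true 78.00)")

assignment = realign(gating)
print(f"{assignment.n_cardiac_phases} cardiac phases, "
      f"{assignment.counts['in_selected_bin']} projections in the "
      f"selected respiratory bin")
```

Output:

```
heart rate: 430.19 bpm (true 430.39)
resp rate:  78.03 /min (true 78.00)
3 cardiac phases, 348 projections in the selected respiratory bin
```

Both rates are recovered within 0.05 % purely from the k-space center —
no ECG, no respiratory sensor. The heartbeat spans only ~3.3 self-gating
profiles, so three cardiac phases result, ~115 spokes each: far below the
in-plane Nyquist count, which is why the compressed-sensing reconstruction
matters. On a matched scaled-down dynamic phantom (3 phases × ~60 spokes
at 64², seed 1) the comparison comes out as:

```
regrid : NRMSE 0.5554   CNR 1.28
cs     : NRMSE 0.5117   CNR 1.47
```

— temporal-TV CS trades streak energy for temporal smoothness, lowering
the reconstruction error and raising the blood–myocardium CNR, the same
ordering reported for in-vivo data.

The same pipeline is scriptable from the shell:

```bash
selfgate3d run --out-dir out --seed 1        # simulate → gate → realign →
                                             # recon (both methods) → quantify
selfgate3d gate --raw out/raw.h5 --plot gating.png
```

which writes the raw HDF5 container, NIfTI cine volumes, CSV reports, and
a JSON manifest that is byte-identical across reruns of the same seed.

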