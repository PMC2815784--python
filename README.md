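# interbeam

Dosimetry toolkit for **interlaced microbeam radiosurgery** — a synchrotron
radiosurgery technique in which arrays of ~50 µm-wide planar kilovoltage
X-ray beams ("microbeams", 50–350 keV, median 107 keV) are cross-fired from
several ports with sub-spacing lateral shifts, so the beams tile the
inter-beam gaps only inside a small target. Normal tissue along each port
sees only a spatially fractionated array, which it tolerates even at
hundreds of Gy; the target receives a quasi-uniform high dose with a lateral
falloff far sharper than conventional radiosurgery. The package is aimed at
medical physicists and beamline scientists who need the planning arithmetic
and Monte Carlo dose distributions behind such irradiations.

## What it computes

* **Spectrum** — a universal synchrotron (wiggler) spectrum filtered through
  Be/C/Al/Cu, with the critical energy calibrated so the filtered median is
  107 keV on the 50–350 keV band.
* **Transport** — numba-accelerated coupled photon–electron Monte Carlo of a
  single rectangular microbeam through cylindrical water phantoms (rat head:
  r = 1.5 cm; human head: r = 8 cm), scoring a 2-D dose grid (1 µm
  transverse resolution in-beam) with per-voxel batch uncertainties.
* **Composition** — exact superposition of the single-beam profile into
  n-beam arrays; peak-to-valley dose ratio
  **PVDR = peak dose / valley dose** at the centermost beam and gap; 90–10 %
  edge penumbra.
* **Interlacing** — multi-port composites: interlaced (ports shifted by
  spacing/n_ports, e.g. 4 ports × 10 beams × 200 µm spacing with 50 µm
  steps) or intersecting (co-registered control, peaks and valleys add);
  plateau dose, homogeneity, and the interlacement enhancement factor
  **Int.EF = D_plateau / D_in-beam − 1**.
* **Planning** — entrance-dose back-planning for a prescribed target dose
  D_t: D_ib = D_t/(1+Int.EF), D_valley = D_ib/PVDR, D_entrance = D_ib/A
  (A = depth attenuation factor).
* **Film** — film-like 2-D dose images (rendering, profile extraction,
  falloff comparison against an externally supplied reference profile).

See `docs/methods.md` for models, assumptions and limitations.

## Worked example

Rat-head geometry: one 50 µm × 2 mm microbeam in the 1.5 cm-radius water
cylinder, superposed into a 10-beam / 200 µm array and interlaced from 4
ports at 200 Gy entrance peak dose per port.

```python
import interbeam as ib
from interbeam import transport as tr
from interbeam.interlace import rat_plan

spec = ib.calibrated_spectrum()                      # 107 keV median
cfg = tr.TransportConfig(n_histories=2_000_000, seed=1)
grid = tr.simulate_single_microbeam(tr.RAT_PHANTOM, tr.MicrobeamSpec(), spec, cfg)

profile = ib.extract_profile(grid, depth_mm=10.0)    # 1 cm depth
array = ib.ArraySpec(n_beams=10, spacing_um=200.0)
res = ib.compute_pvdr(ib.superpose_array(profile, array), array)

plan = rat_plan(entrance_peak_dose_Gy=200.0)         # 4 ports, 50 um steps
inter = ib.build_interlaced_profile(profile, plan)
report = ib.target_report(inter, plan,
                          single_array_inbeam_dose=res.peak_dose * 200.0)

print(f"in-beam dose at 1 cm : {res.peak_dose * 200:6.1f} Gy")
print(f"valley dose at 1 cm  : {res.valley_dose * 200:6.2f} Gy")
print(f"PVDR at 1 cm         : {res.pvdr:6.1f}")
print(f"interlaced plateau   : {report.mean_target_dose:6.1f} Gy "
      f"(width {report.plateau_width_mm:.2f} mm)")
```

Output (a few seconds on one core):

```
in-beam dose at 1 cm :  175.7 Gy
valley dose at 1 cm  :   2.58 Gy
PVDR at 1 cm         :   68.0
interlaced plateau   :  197.7 Gy (width 1.95 mm)
```

A 200 Gy entrance peak per port attenuates to ~176 Gy in-beam at the 1 cm
target depth; tissue between the beams receives only ~2.6 Gy (PVDR ~60–70 at
this history count; the valley estimate carries ~10 % statistical error).
Where the four shifted arrays interlace, the gaps are tiled and the dose
plateaus at ~198 Gy over the 2 mm target — the interlaced target receives
the full prescription while surrounding tissue stays spatially fractionated.

The planning arithmetic is available standalone; for the human-head
planning table (100 Gy to a target at 7.5 cm):

```bash
$ interbeam plan --fixture table1 --row "2x2 mm2" --spacing-um 200
{"field": "2x2 mm2", "spacing_um": 200.0, "inbeam_dose_at_depth_Gy": 88.0,
 "valley_dose_at_depth_Gy": 1.73, "entrance_peak_dose_Gy": 293.0,
 "valley_dose_at_entrance_Gy": 4.13}
```

i.e. delivering a uniform 100 Gy to a 2×2 mm² target at 7.5 cm depth
requires 88 Gy per array in-beam (the interlacement enhancement contributes
the rest) and a ~293 Gy entrance peak dose, while valleys stay below 5 Gy
everywhere.

## Command line

`interbeam` exposes `simulate-kernel`, `compose`, `interlace`, `plan`,
`render`, `fixtures` and `run`. `run` executes the whole chain and writes
TSV/HDF5/TIFF artifacts plus a machine-readable `summary.json`, every file
stamped with the configuration hash:

```bash
interbeam run --preset rat-interlaced --histories 2000000 --seed 1 --out runs/rat
interbeam run --preset human-table1-1x1cm-200-4port --out runs/h1
```

Presets cover the rat interlaced plan, the intersecting control, and the six
human planning-table configurations.

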