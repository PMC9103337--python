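# ovitherm

Non-contact egg freshness assessment by pulse (PT) and pulse-phase (PPT)
thermography.

As a hen egg ages, water and CO₂ escape through the shell and the air
chamber at the dull pole grows; EU marketing rules cap the chamber
height at 6 mm, and at 4 mm (within 9 days of laying) for eggs sold as
"extra fresh".  `ovitherm` measures the chamber without touching the
egg: a brief flash heats the shell by well under 1 °C, an infrared
camera records the cooling transient at 100 Hz, and image processing
extracts the chamber geometry.  The package is aimed at researchers in
food-quality NDT and at anyone building automated egg-grading pipelines
who needs a testable, scriptable reference implementation.

## Method

For every pixel, the cooling transient s₀…s₍N₋₁₎ after the flash is
transformed with a DFT,

    F_k = Σₙ sₙ · exp(−i 2π k n / N),

and the phase arg F₁ (degrees, at the fundamental bin) forms the *phase
image*.  Phase suppresses uneven heating, emissivity variation and
flash reflections, so the chamber edge is crisp there, while the egg
outline is crisp in a single raw frame taken 600 ms after the flash.
The sizing algorithm uses both:

1. segment the egg in the raw frame (Otsu, largest component, fill holes);
2. segment the chamber projection inside the egg in the phase image;
3. crop the phase image to the egg's bounding rectangle, zero the
   background → the *hybrid image*;
4. on rows crossing the chamber, smooth the brightness profile with a
   smoothing spline and mark the perimeter points P1/P2 where the
   profile crosses w_th = b_max/3 (one third of the row maximum);
5. fit an ellipse (≥ 5 points, direct least-squares conic) → semi-axes
   a ≤ b, area A_b = πab (mm² via the calibration scale), volume proxy
   A_b^{3/2}.

The lateral view gives the chamber height c as the mean gap between the
egg's external profile and the internal w_th crossing over the
dull-pole rows.  Camera scale comes from a 10 mm-pitch circular-slot
calibration grid.  Aging analyses (repeatability tables, per-category
means ± σ, normalized A_b/A_b₀ and V_b/V_b₀ series, polynomial
regressions against weight loss with R²) are built on these
measurements.  Everything is exercised on synthetic thermogram phantoms
with exact ground truth — no recorded data is required.

## Worked example

```python
from ovitherm import synth, ppt, sizing

phantom = synth.EggPhantom(chamber_a_mm=6.0, chamber_b_mm=8.0, c_mm=3.0, seed=7)
calib = synth.synthetic_calibration()          # 0.25 mm/px

front, truth = synth.generate_sequence(phantom, view="front")
m = sizing.measure_front(ppt.extract_pt_frame(front), ppt.phase_image(front), calib)
print(f"front view: a = {m.a_mm:.2f} mm, b = {m.b_mm:.2f} mm, "
      f"A_b = {m.A_b_mm2:.1f} mm^2, A_b^1.5 = {m.V_proxy_mm3:.0f} mm^3")

lateral, _ = synth.generate_sequence(phantom, view="lateral")
c_mm, flags = sizing.measure_lateral(ppt.extract_pt_frame(lateral),
                                     ppt.phase_image(lateral), calib)
print(f"lateral view: c = {c_mm:.2f} mm")
print("grade at day 5:", sizing.grade_freshness(c_mm, 5).value)
```

prints

```
front view: a = 6.16 mm, b = 8.26 mm, A_b = 160.0 mm^2, A_b^1.5 = 2023 mm^3
lateral view: c = 3.10 mm
grade at day 5: extra_fresh
```

against ground truth a = 6.00 mm, b = 8.00 mm, A_b = 150.8 mm², c =
3.00 mm: at the default sensor noise (2% of the flash contrast) single
measurements land within a few percent of truth, and repeated
acquisitions of one egg scatter by roughly 1–4% sd — which is what the
technique's repeatability statistics quantify.

The same steps are available from the shell:

```sh
ovitherm synth egg --a-mm 6 --b-mm 8 --seed 7 --out seq.tif --truth truth.json
ovitherm ppt --stack seq.tif --meta seq.json --out phase.tif --preview phase.png
ovitherm size --front seq.tif --front-meta seq.json --calib calib.json --out m.csv
```

plus `calibrate`, `aging`, `synth grid|cohort` and `pipeline` (batch
processing with provenance headers and byte-reproducible outputs).

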