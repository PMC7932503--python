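# bari — brachial artery relaxation index from B-mode cine ultrasound

Arterial walls are viscoelastic: after each systolic pulse the vessel
diameter relaxes back over diastole, and the *rate* of that relaxation is a
candidate imaging biomarker of wall properties — of interest, for example,
when looking for predictors of abdominal aortic aneurysm (AAA) growth
beyond the anteroposterior diameter (APD).  `bari` implements the full
measurement pipeline from a grayscale cine loop of the brachial artery to a
single number, the **brachial artery relaxation index (BARI)**, plus the
cohort statistics used to evaluate such an index, and a ground-truthed
speckle phantom generator so every stage is testable without clinical data.

## The model

A user places a rectangle inside the lumen; an outward, edge-stopping
level-set evolution finds the anterior and posterior wall contours in every
frame, reduced to single-valued traces *y_t(x, t)* and *y_b(x, t)*.  The
diameter surface is

    D(x, t) = |y_b − y_t| · (axial mm/px).

Each cross-section's waveform is split at its peaks and troughs into
systolic dilatation and diastolic relaxation windows.  Dilatation follows a
single exponential rise

    D_d(t) = A_d − B_d · e^{−(t−C_d)/T_d},

while diastolic relaxation needs two timescales (the Zener spring–dashpot
wall model has a sum-of-exponentials step response):

    D_r(t) = A_r + B_R1 · e^{−(t−C_r)/T_R1} + B_R2 · e^{−(t−C_r)/T_R2},

with fast T_R1 < slow T_R2.  Parameters are fitted per window by
Nelder–Mead on the summed squared residuals; poorly fitted windows (large
residual, collapsed timescales, implausible T_R2) are rejected.  **BARI is
the mean of T_R2 over all accepted fits** (all cross-sections, all cycles),
in seconds.  The slow decay happens under minimal driving pressure, so it
is the part most sensitive to intrinsic wall properties.  Cohort-level
helpers compute the annualised growth rate
(ΔAPD/APD_baseline)/(days/365) · 100 %/yr, size-group labels
(small 30–39 mm, moderate 40–55 mm, large >55 mm), rank tests and the
BARI-vs-growth regression.

## Worked example

Everything below is reproducible because the input is a synthetic phantom:
a pulsating two-wall vessel (21 µm pixels, Rayleigh speckle) whose wall
motion follows the forward model above with known parameters — the default
spec programs four cardiac cycles with systolic peaks at 0.5, 1.5, 3.0 and
4.0 s and a true slow constant T_R2 = 1.2 s.

```sh
bari simulate --seed 7 --out loop.dcm --truth truth.json
bari segment --input loop.dcm --roi 60,172,12,52 --out traces.csv
bari diameters --traces traces.csv --out dmap.csv
bari cycles --dmap dmap.csv --out windows.json --stride 4
bari fit --dmap dmap.csv --windows windows.json --out fits.json
bari index --fits fits.json --out bari.json
```

prints, stage by stage:

```
wrote 250-frame phantom loop to loop.dcm
segmented 250 frames (0 failed); QC: usable []
wrote diameter map (40 positions x 250 frames) to dmap.csv
detected 40 cycle windows at 10 cross-sections
fitted 40 windows, 25 accepted
BARI = 1.028921164775876 s from 25 fits
```

Reading the output: all 250 frames segmented and passed quality control
(no intraluminal artefact, traces continuous); 10 cross-sections × 4
cycles gave 40 relaxation windows, of which 25 survived the fit-rejection
rules; their mean slow constant — the BARI — is 1.03 s.  The shortfall
against the programmed 1.2 s illustrates the intrinsic difficulty of
bi-exponential time-constant estimation on windows shorter than the slow
timescale (see `docs/methods.md`); the per-window provenance in
`fits.json` records every parameter, residual and rejection reason.
`bari report --cohort cohort.csv --out report.json` runs the group
comparisons on a participant table.

The same pipeline is available as a library:

```python
from bari import PhantomSpec, analyse_loop, simulate_cine
from bari.phantom import _default_roi

spec = PhantomSpec()
loop, truth = simulate_cine(spec, seed=7)
res = analyse_loop(loop, _default_roi(spec, truth), stride=4)
print(res.result.bari, res.result.n_accepted)
```

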