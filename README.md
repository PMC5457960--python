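# cephpls

PLS path modeling of cephalometric change after surgery-first class III
orthognathic treatment.

## The problem

In the surgery-first approach (SFA) to skeletal class III correction,
mandibular setback surgery precedes orthodontic finishing, and the
occlusion is deliberately left unstable at the postsurgical stage. A
recurring clinical observation is that a larger postsurgical occlusal
vertical dimension (VD — the vertical gap between the upper and lower
first-molar mesial contacts, projected on the Sella-perpendicular
direction) goes with more forward postoperative drift of the mandible,
i.e. less net setback at the end of treatment.

Testing that observation with ordinary multiple regression is
frustrated by collinearity: the distal mandibular segment moves as one
rigid piece, so B point, pogonion, menton and the lower dentition
produce measurements that are almost linear functions of one another.
Partial least squares path modeling (PLS-PM) is the standard
variance-based workaround: observed *manifest variables* (MVs) are
bundled into composite *latent variables* (LVs), and the structural
relations are estimated between composites instead of between collinear
raw columns.

`cephpls` is for biostatisticians and orthodontic researchers who want
that analysis as tested, reusable code: a generic PLS-PM engine, the
cephalometric measurement layer, the specific SFA latent model with its
inner-model search, and synthetic-cohort generators so every stage is
verifiable without access to patient data.

## The model

Measurements are taken on CBCT-generated lateral cephalograms against
two reference lines: the Frankfort horizontal (FH, through porion and
orbitale) and its perpendicular through sella (S-perp). `X^s` denotes
the signed distance of landmark X from the S-perp line (anterior
positive), `X^f` its vertical distance (inferior positive); subscripts
give timepoints T0/T1/T2 (presurgical, postsurgical, posttreatment) or
increments (`X_10 = X(T1) − X(T0)`, `X_20 = X(T2) − X(T0)`). In code
and CSV columns these are written `B_s_10`, `Cp_f_1`, `VD_10`,
`B_s_20`, ...

Four latent variables connect six measurements:

| LV | indicators | mode |
|---|---|---|
| LV_10 (surgical setback) | B_s_10, Me_s_10 | formative |
| LV_1 (postsurgical position) | A_s_1, Cp_f_1 | formative |
| LV_overall | B_s_10, Me_s_10, A_s_1, Cp_f_1, VD_10 | formative |
| LV_setback (final setback) | B_s_20 | reflective |

with inner paths LV_10 → LV_overall and LV_10, LV_overall, LV_1 →
LV_setback. Estimation is the classical alternating PLS algorithm
(centroid/factorial/path schemes, Mode A/Mode B outer updates);
path coefficients are standardised OLS fits among LV scores, and model
quality is summarised by communalities, redundancies, per-equation R²
and the global goodness of fit GoF = √(mean communality × mean R²).

## Worked example

Simulate a 40-patient cohort with the model's shared-indicator wiring
and fit the SFA model:

```python
import cephpls as c

X, truth = c.simulate_sfa_dataset(n=40, seed=7)
res = c.fit_sfa(X)
print(res.path_coefficients["LV_setback"].round(4).to_string())
print("R2:", {k: round(v, 4) for k, v in res.r_squared.items()})
print("VD weight in LV_overall: %.4f"
      % res.outer_weights["LV_overall"]["VD_10"])
```

prints

```
LV_10        -1.0000
LV_overall    1.9177
LV_1          0.0000
R2: {'LV_overall': 0.9501, 'LV_setback': 0.9391}
VD weight in LV_overall: -0.1152
```

Read: the two nearly collinear predictors of the final setback carry
large opposed coefficients (their *difference* is what matters — this
is exactly the ill-conditioned regression PLS-PM is built to survive),
the sink equation explains ~94% of the variance in the final B-point
change, and VD_10 enters the overall composite with a negative weight:
a larger postsurgical VD increase pulls the fitted final-setback score
down, the qualitative relapse effect the model encodes.

The same pipeline runs from the shell:

```bash
cephpls simulate --n 40 --seed 7 --out run/   # synthetic cohort + landmarks
cephpls derive --landmarks run/cohort_landmarks.csv --out run/
cephpls fit --measurements run/measurements.csv --out run/
cephpls search --measurements run/measurements.csv --out run/
cephpls check --out run/                      # audit the published tables
cephpls recover --reps 50 --n 2000 --seed 1 --out run/
```

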