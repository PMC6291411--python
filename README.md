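# mirdose

Internal dosimetry for PET radiopharmaceuticals, from multi-timepoint organ
activity measurements to absorbed doses and effective dose.

When a new tracer — say a ⁶⁸Ga-labelled receptor antagonist — is first given
to humans, medical physicists estimate the radiation burden from a handful of
serial whole-body PET scans. `mirdose` implements that analysis as a
reusable, tested pipeline for anyone doing image-based dosimetry of
diagnostic (and prospectively therapeutic) radiopharmaceuticals:

1. **Quantification** — organ VOI statistics (mean concentration × volume)
   become normalized time-activity curves a(t) = A_organ(t)/A_administered.
2. **Biokinetics** — each washout organ is fitted with a mono-exponential
   a₀·e^(−λ_eff·t) and integrated in closed form to a time-integrated
   activity coefficient (TIAC, or residence time) τ = a₀/λ_eff hours;
   uptake-phase organs (e.g. the gallbladder within a 2-h protocol) fall
   back to trapezoidal integration plus a conservative physical-decay tail.
3. **Special source models** — red marrow from three skeletal sample VOIs
   scaled by the reference marrow mass; colon TIAC partitioned to right
   colon, left colon and rectum by reference segment mass; urinary bladder
   content from a dynamic voiding model (inflow from biologic clearance,
   physical decay, periodic emptying every T_v hours) anchored to the
   measured bladder TIAC.
4. **MIRD dose engine** — absorbed doses D_T = Σ_s τ_s·S(T←s) against an
   explicit S-value kernel (CSV); inverse-mass self-dose rescaling between
   phantom generations; effective dose ED = Σ_T w_T·H_T under selectable
   tissue-weighting schemes (ICRP-103 and ICRP-60 style, shipped as JSON),
   with male/female/reference-person combination.
5. **Reporting** — cohort mean ± SD tables, voiding-interval sweeps with
   integer-percent delta reports, administration-scaled summaries, and
   extrapolation of the measured biokinetics to a therapeutic radionuclide
   (⁶⁸Ga → ¹⁷⁷Lu) by keeping λ_bio fixed and swapping λ_phys.

A synthetic-data module generates complete study-shaped inputs (four scans
at 15/45/70/100 min after ~113 MBq, 5% multiplicative PET noise, toy but
physically plausible S-kernels), so the whole pipeline is testable without
any patient data.

## Worked example

Feeding a published male dose table (shipped with the package) for a
⁶⁸Ga-labelled GRPR antagonist through the delta reporter compares a 0.5-h
with a 1-h urinary voiding cycle:

```python
import mirdose as m
from mirdose.resources import load_reference_doses

ref = load_reference_doses()
deltas = m.delta_table({
    0.5: dict(ref["dose_male_0p5h"].dropna()),
    1.0: dict(ref["dose_male_1h"].dropna()),
})
print(deltas.loc[["urinary_bladder_wall", "prostate", "effective_dose_icrp103"],
                 ["pct_change_raw_1h", "pct_change_1h"]])
ed = ref.loc["effective_dose_icrp103", "dose_male_1h"]
print("ED x 150 MBq =", m.round_sig(m.scale_to_administration(ed, 150.0), 2), "mSv")
```

prints

```
                        pct_change_raw_1h  pct_change_1h
organ
urinary_bladder_wall            60.458453             60
prostate                         9.016393              9
effective_dose_icrp103           6.818182              7
ED x 150 MBq = 2.8 mSv
```

Doubling the voiding interval raises the bladder-wall dose by 60% and the
effective dose by 7%; at that ED (1.88E-02 mSv/MBq) a typical 150-MBq
administration delivers 2.8 mSv — comparable to other ⁶⁸Ga peptides.

The command line drives the same pipeline end to end on synthetic data:

```
mirdose simulate --seed 1 --out study/
mirdose sweep --voi study/voi.csv --study study/study.json \
    --svalues-male study/svalues_male_2_0.csv \
    --svalues-female study/svalues_female_2_0.csv \
    --intervals 0.5,1.0,3.5 --out reports/
```

## Layout

- `src/mirdose/biokinetics.py` — curves, fits, TIACs, radionuclide substitution
- `src/mirdose/source_models.py` — marrow, colon, bladder voiding model
- `src/mirdose/dose_engine.py` — MIRD sums, weighting schemes, effective dose
- `src/mirdose/synthetic_data.py` — study-shaped scenario and toy S-kernels
- `src/mirdose/reporting.py`, `src/mirdose/cli.py` — pipeline driver and CLI
- `src/mirdose/data/` — phantom masses, weighting schemes, aliases,
  published reference dose table
- `docs/methods.md` — models, assumptions, parameter choices, limitations
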