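# riskpipe

**Peritumoral CT radiomics for predicting progression under first-line
pembrolizumab in advanced NSCLC.**

About half of high-PD-L1 advanced non-small-cell lung cancer patients do not
respond to single-agent pembrolizumab, and identifying likely
non-responders *before* treatment would redirect them to alternative
first-line regimens. `riskpipe` implements a complete, tested version of a
pre-treatment CT analysis built for that question: radiomic features from
the lesion core, its edge, and a ~6 mm peritumoral **ring** of surrounding
parenchyma are combined with clinical covariates in a logistic risk model,
and per-slice risk scores are rolled up to patient-level calls by a
frequency-thresholding hierarchy. Predicted risk groups are then compared
on progression-free and overall survival.

The core risk model is a logistic regression over a small signature
(≤5 features, one-in-five rule). Its published form is

    Risk of PD = [1 + exp(−0.282 − 0.509·PackYears + 0.999·NMetSites
                          − 0.816·OD-CentroidDifference_RING
                          + 1.148·RadCentre_RING)]⁻¹

where `OD-CentroidDifference_RING` measures how far the ring's
intensity-weighted centroid is displaced from its geometric centroid and
`RadCentre_RING` measures how far the ring's intensity mass sits toward the
rim. Slice scores become patient calls through three thresholds fitted on
discovery data only: a slice is high-risk when its score ≥ X (published
X = 0.22, the Youden-J cutoff), a lesion is progressive when ≥ Y = 2 of its
≤5 slices are high-risk, and a patient is progressive when ≥ Z = 1 lesion
is.

The study cohort is private, so the package ships a first-class synthetic
cohort generator whose progression signal is planted **only in the
peritumoral ring**; all end-to-end claims are tested as recovery of that
planted structure (see `docs/methods.md` for what this does and does not
demonstrate).

## Worked example

Score a patient with the published calculator (inputs on the [−1, 1]
training scale; `conventional` flips the printed sign convention — see the
methods note), then roll slice scores up to a patient call:

```python
import pandas as pd
from riskpipe.model import eq1_risk
from riskpipe.aggregate import ThresholdSet, classify_hierarchy

risk = eq1_risk(0.4, -0.2, 0.3, -0.5, convention="conventional")
print(f"risk of PD: {risk:.3f}")

scores = pd.DataFrame({
    "patient_id": ["P1"] * 10,
    "lesion_id":  ["L0"] * 5 + ["L1"] * 5,
    "score": [0.31, 0.28, 0.15, 0.10, 0.05,   # lesion L0
              0.18, 0.12, 0.09, 0.07, 0.02],  # lesion L1
})
lesions, patients = classify_hierarchy(scores, ThresholdSet(0.22, 2, 1))
print(lesions.to_string(index=False))
print(patients.to_string(index=False))
```

prints

```
risk of PD: 0.182
patient_id lesion_id  frequency_score  lesion_pd
        P1        L0                2       True
        P1        L1                0      False
patient_id  n_pd_lesions  patient_score  patient_pd
        P1             1              2        True
```

Lesion L0 has two slices at or above the 0.22 cutoff (0.31, 0.28), meeting
the Y = 2 slice-count rule, so it is called progressive; one progressive
lesion meets the Z = 1 rule, so the patient is called high-risk even though
lesion L1 is quiet.

The full pipeline — simulate a cohort, segment, extract 519 features over
three regions, filter, build the six-signature menu (SFS/mRMR/ReliefF ×
with/without clinical), train the nested-CV model, fit thresholds, evaluate
the held-out external split, and compare survival — runs from one call:

```bash
riskpipe run --out runs/demo --seed 1
```

or in Python via `riskpipe.workflow.run_pipeline`. Individual stages are
exposed as `riskpipe simulate | extract | eq1 | optimize-thresholds |
evaluate | survival`.

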