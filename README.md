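# zfpk — zebrafish-embryo fluorescence pharmacokinetics

`zfpk` is a tested, reusable implementation of a fluorescence-based
pharmacokinetic screening analysis for zebrafish embryos (ZFE). The
experimental design it serves compares two administration routes for a
panel of fluorescent compounds — **immersion** in a 10 µM bath versus
**intrayolk (IY) microinjection** at 2 mg/kg — by imaging embryos at fixed
times (0.25, 1, 3, 6, 24, 48, 72, 96, 120 h post exposure) and quantifying
integrated fluorescence intensity (RFU) inside delineated regions: the
whole body (WB), the yolk sac, and the rest of body (RoB = WB − Yolk).

It is aimed at pharmacology and toxicology groups who run (or evaluate)
ZFE uptake assays and need the full chain from images or RFU tables to
exposure statistics and descriptor regressions, with explicit handling of
censored observations.

## The statistics

**AUC.** Tissue exposure per compartment is the linear-trapezoidal area
under the RFU–time curve over a fixed window (default 0.25–72 h):

    AUC = Σᵢ (RFUᵢ + RFUᵢ₊₁)/2 · (tᵢ₊₁ − tᵢ)

summed over consecutive *uncensored* observations. Early post-injection
observations can under-report signal (the injected dye transiently forms
non-fluorescent aggregates at the depot); such points are censored and the
integral starts at the first retained point — no back-extrapolation.

**Relative Exposure (RE).** Absolute RFU values are not comparable across
compounds (quantum yield, camera settings), but within a compound the
ratio cancels the fluorescence scale:

    RE = AUC_immersion / AUC_injection        (per compartment)

**Relative Distribution (RD).** The fraction of injected-compound
exposure reaching non-yolk tissue:

    RD = AUC_RoB / AUC_WB                     (injection route)

**QSPkR.** RE is regressed on molecular descriptors by OLS with centered
polynomial terms (the convention of standard statistics packages):

    RE_WB  ~ β₀ + β₁·LogD + β₂·(LogD − mean)²
    RE_RoB ~ same parabolic form
    RE_Yolk ~ β₀ + β₁·LogD + β₂·TPSA + β₃·MR + β₄·(LogD − mean)(MR − mean)

Because no raw imaging data is deposited for the reference study, the
package ships a synthetic-data generator (`zfpk.synthetic_data`) with
closed-form two-compartment kinetics, a quenching artifact, multiplicative
noise, and a ground-truth manifest, plus a renderer for synthetic embryo
images with exact compartment masks.

## Worked example

Run the pipeline on the packaged reference tables (the seven-dye panel,
AUC values transcribed from the published study, in RFU × 10⁷·h):

```python
from zfpk import load_reference_aucs, summarize_exposure

for s in summarize_exposure(load_reference_aucs()):
    print(f"{s.compound:9s} RE-WB {s.re_wb:5.2f}  RE-RoB {s.re_rob:5.2f}  "
          f"RE-Yolk {s.re_yolk:5.2f}  RD {s.rd:5.2f}")
```

```
S-CY3A    RE-WB  0.15  RE-RoB  0.35  RE-Yolk  0.08  RD  0.24
S-CY5.5A  RE-WB  0.00  RE-RoB  0.00  RE-Yolk  0.00  RD  0.19
S-CY5A    RE-WB  0.00  RE-RoB  0.00  RE-Yolk  0.00  RD  0.18
FAMA      RE-WB  0.04  RE-RoB  0.12  RE-Yolk  0.02  RD  0.25
TAMRA     RE-WB  0.19  RE-RoB  0.25  RE-Yolk  0.17  RD  0.28
R6GA      RE-WB  0.10  RE-RoB  0.39  RE-Yolk  0.00  RD  0.26
CY3A      RE-WB  1.11  RE-RoB  2.00  RE-Yolk  0.93  RD  0.17
```

Reading: only the most lipophilic dye (CY3A, Log D 1.73) achieves
immersion exposure comparable to injection (RE ≈ 1); for the rest,
injection exposes tissue several-fold more. RD between 0.17 and 0.28
means only ~20–30 % of injected-compound exposure reaches non-yolk tissue
within 72 h — the yolk acts as a slow-release depot.

Fitting the descriptor models:

```python
from zfpk import load_reference_descriptors, load_reference_exposure, fit_model
from zfpk.qspkr import ModelSpec, PARABOLIC_TERMS

fit = fit_model(load_reference_descriptors(),
                load_reference_exposure()["re_rob"].to_numpy(),
                ModelSpec("RE_RoB", PARABOLIC_TERMS))
print(fit.equation(), f" RMSE {fit.rmse:.3f}  adj R2 {fit.r2_adj:.3f}")
```

```
RE_RoB = -0.013 + 0.34(logd) + (logd + 0.177)^2 x 0.319  RMSE 0.297  adj R2 0.820
```

The same chain is available from the shell:

```sh
zfpk simulate --descriptors table4.csv --seed 1 --out-dir sim/
zfpk nca --rfu sim/rfu.csv --censor-policy iy_leading_quench --out auc.csv
zfpk exposure --auc auc.csv --out exposure.csv
zfpk qspkr --descriptors table4.csv --exposure exposure.csv --out qspkr.json
```

or end-to-end with `zfpk run --config config.yaml`, which writes
`auc.csv`, `exposure.csv`, `qspkr.json`, `report.md`, and a run log.

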