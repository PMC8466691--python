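# myodti

Muscle diffusion tensor imaging (mDTI) quantification for lower-leg MRI:
per-muscle diffusion metrics by **manual-segmentation-based analysis
(MSB)** and by **volume-based tractography (VBT)**, plus the inter-rater
reliability statistics needed to decide whether segmentations from
different raters — or the two methods themselves — are interchangeable.

mDTI is a surrogate biomarker for muscle injury and neuromuscular disease:
water diffusion in muscle is modelled per voxel as a symmetric tensor
**D**, fitted from the Stejskal–Tanner signal
S_i = S₀·exp(−b_i·g_iᵀDg_i), and summarized by its eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ as

* FA = √(3/2)·√(Σ(λᵢ−MD)²/Σλᵢ²)  (fractional anisotropy)
* MD = (λ₁+λ₂+λ₃)/3        (mean diffusivity, 10⁻³ mm²/s)
* λ₁ (axial) and RD = (λ₂+λ₃)/2  (radial diffusivity)

Because diffusion values differ between muscles, metrics must be extracted
per muscle. MSB superimposes smoothed, one-voxel-eroded muscle masks on the
scalar maps and averages **each voxel once**. VBT runs deterministic
streamline tractography inside the un-eroded muscle volume (max angle 15°,
step 1.5 mm, FA range 0.1–0.6) and samples the maps along the tracts, so a
voxel is weighted by its **tract-visitation count**; it also yields tract
properties — tract density (TD, tracts/cm³), mean tract length (MTL, mm),
muscle volume (Vol, cm³) and mean fiber angle to the craniocaudal axis.
The different weighting is exactly why the two methods agree in homogeneous
muscle but diverge when low-quality rim voxels exist — so the same
segmentation protocol must be used when pooling data.

The package includes:

* robust tensor fitting — weighted least squares with Geman–McClure
  reweighting and residual-based outlier rejection, plus FA/MD/λ/RD/SNR maps
  (`tensor_model`),
* mask post-processing, nearest-neighbour label resampling, voxel-averaged
  extraction and fat-fraction summaries (`msb_extract`),
* muscle-constrained streamline tracking, tract-based sampling and tract
  properties (`vbt_tract`),
* CV, paired t, Pearson r, ICC (absolute agreement and consistency),
  Cronbach's α and Bland–Altman limits of agreement (`reliability_stats`),
* a synthetic pennate-muscle DWI phantom with seven calf compartments,
  two-compartment fat model, Rician noise and simulated raters (`phantom`),
* NIfTI / FSL bval-bvec / TCK / CSV / JSON IO (`io_formats`) and a
  stage-per-subcommand CLI (`cli`).

## Worked example

Simulate one phantom subject at SNR 59 with healthy tissue values, analyze
it with both methods and both simulated raters, and compute inter-rater
reliability of MD:

```python
from myodti import PhantomSpec, simulate_dwi, reliability_report
from myodti.cli import RunConfig, analyze_subject

subject = simulate_dwi(PhantomSpec(seed=7, shape=(48, 48, 24)))
res = analyze_subject(subject, RunConfig(seed=7, shape=(48, 48, 24)), 0)

print(res["snr_mean"])                      # 59.0
print(res["raters"][1]["msb"].head(3))      # per-muscle MSB table
rep = reliability_report(res["raters"][1]["msb"], res["raters"][2]["msb"], "md")
print(rep.icc, rep.cronbach_alpha, rep.mean_diff)
```

Output (abridged; full tables have seven muscles):

```
                 muscle    fa    md  lambda1    rd  n_voxels
     extensor_digitorum 0.191 1.650    2.009 1.471       488
gastrocnemius_lateralis 0.266 1.548    2.029 1.307      1095
 gastrocnemius_medialis 0.172 1.554    1.855 1.403      1320
ICC 1.0  alpha 1.0  mean_diff -4e-05
```

MD and λ₁ land on the 1.5–2.0 ×10⁻³ mm²/s scale and FA around 0.2, the
values typical of healthy calf muscle; the near-unit ICC with a
Bland–Altman mean difference of ~10⁻⁵ says the two simulated raters'
boundary disagreement (Dice ≈ 0.9) barely moves muscle-mean diffusion
metrics. The matching VBT table adds TD ≈ 16 tracts/cm³, MTL 64–80 mm and
per-muscle mean angles within a degree of the configured pennation.

The same pipeline is scriptable from the shell:

```sh
myodti simulate --seed 7 --out subj/
myodti fit-tensor --dwi subj/dwi.nii.gz --bvals subj/bvals --bvecs subj/bvecs \
       --mask subj/labels.nii.gz --sigma subj/sigma.nii.gz --out maps/
myodti extract-msb --maps maps/ --labels subj/labels_rater1.nii.gz --erode 1 \
       --out msb_r1.csv
myodti track-vbt --tensor maps/tensor.nii.gz --labels subj/labels_rater1.nii.gz \
       --out-csv vbt_r1.csv
myodti reliability --a msb_r1.csv --b msb_r2.csv --metric md --out report.json
```

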