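# ctoam — CT-osteoabsorptiometry of the patella

`ctoam` quantifies the spatial distribution of subchondral bone
mineralization on the articular surface of the patella from CT, the way
CT-osteoabsorptiometry (CT-OAM) studies of patellofemoral loading do.
Following Wolff's law, subchondral CT attenuation (in Hounsfield units, HU)
is a surrogate of long-term joint loading history; the package turns a
bilateral pair of patellar CT volumes into a paired, region-resolved
statistical comparison — e.g., operated versus contralateral knees years
after medial patellofemoral ligament (MPFL) reconstruction.

The pipeline:

1. **Segmentation and projection** — bone is thresholded (default 200 HU)
   and reduced to its largest 26-connected component; left patellae are
   mirrored into a standardized right-sided frame; a maximum-intensity
   projection (MIP) along the anterior–posterior axis is computed, windowed
   to 200–1200 HU, and rendered to 8-bit grayscale (linear map onto 0–255,
   round half up — 1000 HU ↦ gray 204).
2. **Regional high-density-area (HDA) fractions** — the tight bounding box
   of the projected bone is cut into four equally wide vertical stripes,
   labelled medial-to-lateral: medial facet (MF), central ridge (CR), medial
   portion of the lateral facet (MLF), lateral portion of the lateral facet
   (LLF).  For a threshold T (primary 1000 HU; 900 and 1100 HU sensitivity),

   HDA_fraction(region) = #\{pixels in region with HU > T\} / #\{pixels with HU > T in all four regions\},

   computed with exact integer counts and rational fractions.  Maxima are
   localized per region and per quadrant, with an explicit indeterminacy
   margin.
3. **Paired statistics** — per-region Wilcoxon signed-rank tests (exact
   2^n enumeration for n ≤ 12, midranks under ties) comparing operated vs.
   contralateral fractions, Holm-corrected, with matched-pairs rank-biserial
   effect sizes r = (R⁺ − R⁻)/(R⁺ + R⁻); a tie-corrected Friedman test
   across the four regions on per-patient fractions averaged over both
   knees, with Bonferroni-corrected pairwise Wilcoxon post-hoc tests;
   Shapiro–Wilk reported as a screen only.  α = 0.05, two-sided.
4. **Synthetic cohort generator** — a stylized half-ellipsoid patella
   phantom (cortical shell, trabecular interior, noisy one-voxel subchondral
   plate whose stripe-wise mean HU encodes the physiological lateral-dominant
   gradient MLF > LLF > CR > MF) with analytic ground-truth HDA fractions,
   exact mirror left/right anatomy, paired knees, and a configurable
   operated-side shift (zero = the null of no side difference).

## Worked example

```python
from ctoam.pipeline import RunConfig, run_pipeline
from ctoam.synthetic_patella import SimulationConfig

summary = run_pipeline(RunConfig(out_dir="demo", seed=42,
                                 simulation=SimulationConfig(seed=42)))
at1000 = summary["per_threshold"]["1000"]
print(at1000["friedman"])          # {'chi2': 27.0, 'df': 3, 'p': 5.89e-06}
print(at1000["region_rank_order"])  # ['MLF', 'LLF', 'CR', 'MF']
for row in at1000["side_comparison"]:
    print(row["region"], round(row["p_adjusted"], 3))
# MF 1.0 / CR 1.0 / MLF 1.0 / LLF 1.0
```

A default nine-patient null cohort reproduces the expected physiological
picture: the interregional Friedman test is highly significant with the
lateral facet stripes dominating (here all nine simulated patients rank the
regions identically, giving the ceiling value χ²(3) = 27), the rank order
MLF > LLF > CR > MF is identical at 900, 1000 and 1100 HU, and no
Holm-adjusted side-to-side comparison is significant (all adjusted p = 1).
`demo/` contains per-patella MIP PNGs, the cohort CSV, per-threshold report
tables (median [IQR] per region as percentages, adjusted p, rank-biserial
r; pairwise post-hoc p), a cross-threshold rank-order table and
`summary.json` with every number in machine-readable form.

The same stages are exposed on the command line:

```bash
ctoam simulate --config sim.yaml --out vols/ --seed 7
ctoam mip --in vols/P01_right_operated.nii.gz --side right --out mips/
ctoam stats --cohort out/cohort.csv --thresholds 900,1000,1100 --out report/
ctoam run --mode simulate --out out/ --seed 7
```

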