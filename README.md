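# traffiq

High-content image scoring of **ATG9A / trans-Golgi-network (TGN) compartmentalization**
for AP-4 deficiency gene-therapy assays.

In AP-4-deficient cells the autophagy cargo protein ATG9A fails to exit the
trans-Golgi network and accumulates there; restoring AP-4 function disperses
it back into the cell periphery. `traffiq` implements the image-analysis
pipeline that turns multi-channel fluorescence fields (nuclear stain,
cell-body marker, TGN marker, ATG9A) into that phenotype's quantitative
readouts:

- **Segmentation by mask overlap** — per-channel intensity cut-offs above the
  local background; a *cell* is a cell-body mask component containing a
  nucleus mask; cargo overlapping the TGN mask is *inside* the TGN, cargo in
  the cell body but off the TGN is *outside*.
- **ATG9A ratio** — per cell, `ratio = F.U. inside TGN / F.U. outside TGN`
  (F.U. = summed fluorescence units). Knockout (KO) cells score high,
  wild-type (WT) cells low.
- **Translocation (percent rescue)** — the unique affine map sending the
  plate's untreated-KO mean ratio to 0 % and its untreated-WT mean to 100 %,
  applied to each well's mean ratio:
  `T = 100 · (r̄_KO − r̄_well) / (r̄_KO − r̄_WT)`.
- **Toxicity QC** — each well's cell count as a Z-score against the plate's
  16 untreated-KO control wells (sample SD); `Z > −3` indicates non-toxicity,
  a well at exactly −3 is flagged toxic.
- **Multi-parametric profiling** — 33 per-cell shape/intensity/TGN features,
  summarized per condition as Z-scores against the untreated-KO wells.
- **Tissue quantification** — perinuclear cargo accumulation (annulus mean
  around each nucleus, normalized to the image background, fold change vs the
  WT group) and calbindin-spheroid counts (objects strictly larger than
  19.904 µm²).

Because the original bioimages are not required, a seeded **synthetic
generator** renders plates and tissue fields with exact ground truth (planted
inside/outside cargo split, cell counts with dose-dependent attrition,
perinuclear enrichment, spheroid areas), so the whole pipeline is testable
end to end.

## Worked example

Score a synthetic plate — 16 KO-untreated + 8 WT-untreated control wells and
3 treated wells at each of six MOIs (multiplicity of infection, vector
genomes per cell), 4 sites per well:

```python
import traffiq as tq

cfg = tq.default_run_config(seed=4, output_dir="demo", wells_per_moi=3, n_sites=4)
potency, wells, cells = tq.run_potency(cfg)
print(potency.to_string(index=False))
```

```
       moi  mean_translocation_pct  sd_translocation_pct  mean_cellcount_z  n_wells  n_cells
    1000.0                0.262341              3.698264          0.061256        3       71
  100000.0                9.555262              9.618083          0.239457        3       73
 1000000.0               25.446598              1.513694         -0.562446        3       64
 2000000.0               35.191098              8.114434         -2.166252        3       46
 4000000.0               55.240955              2.843089         -3.235456        3       34
16000000.0               65.866576             11.207664         -4.482861        3       20
```

Reading the table: translocation rises monotonically with dose — at MOI
2×10⁶ the treated wells have recovered ~35 % of the KO→WT shift in ATG9A
distribution, at 1.6×10⁷ ~66 % — while the cell-count Z-score falls below −3
at the two highest doses, flagging toxicity. The KO control wells' mean
ratio on this plate is 5.77 (mapped to 0 %), the WT controls' 2.44 (mapped to
100 %). Per-cell, per-well and per-MOI CSVs are written under `demo/`, along
with the resolved configuration.

The same pipeline is available from the shell
(`traffiq simulate|segment|potency|profile|tissue`); `traffiq tissue` runs
the tissue branch, e.g. a group planted at 5× perinuclear enrichment is
recovered at fold change 4.17 relative to a WT group planted at 1.2×
(4.166 ≈ 5/1.2).

## Layout

```
src/traffiq/
  synthetic.py     seeded field/plate/tissue generators with ground truth
  segmentation.py  local-background thresholds, cell definition, compartments
  scoring.py       ratio, translocation, Z-score QC, potency table
  profiling.py     33-feature extraction, KO-normalized Z profiles
  tissue.py        perinuclear annuli, background normalization, spheroids
  io.py            TIFF+sidecar I/O, run configs, end-to-end runs
  cli.py           click command group
docs/methods.md    model, parameter and design documentation
```
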