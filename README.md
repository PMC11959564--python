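# spotdist

Feature-anchored distance modeling of spatial gene expression for
Visium-style spot data.

Immune checkpoint therapy works when cytotoxic T cells reach the tumor; it
fails when they are excluded. One way such exclusion shows up in spatial
transcriptomics is as a *distance trend*: the expression of a gene in the
tissue rises or falls with distance to the nearest region that is "high"
for some anchoring feature — a CD8 T-cell program, a cholesterol-synthesis
program. `spotdist` implements that analysis for hexagonal spot arrays
(55 µm spots at ~100 µm center spacing, each capturing a "low-bulk"
admixture of ~10–20 cells), together with the bespoke spot/probe quality
filters such data needs and a synthetic-data generator with known ground
truth so every stage can be verified without any external download.

Intended users: computational biologists analyzing Space-Ranger-style
spatial expression output (Matrix Market counts + spot positions) with
per-spot compartment annotations and gene-set definitions.

## The method

For a gene set *S* (e.g. the packaged 9-gene cholesterol core
`Hmgcs1, Nsdhl, Ch25h, Insig1, Fdps, Sqle, Fdft1, Cyp51, Osbp`) each spot
gets a rank-based Mann–Whitney score: genes are ranked within the spot by
decreasing expression with average ranks on ties, ranks are capped at
`r_max + 1` (default `r_max = 1500`), and

```
U' = Σ_{g∈S} rank_g − n_S(n_S+1)/2,      score = max(0, 1 − U' / (n_S · r_max)).
```

Per tissue section, a spot is **Sig-high** if its score ≥ median + 1.5·SD
of the section's score distribution, **Sig-low** if ≤ the median, and
excluded otherwise. For every Sig-low spot the Euclidean distance *d* to
the nearest Sig-high spot is computed in spot-length units (one unit = the
section's center-to-center spacing). Modeling is restricted to tumor spots
with *d* ≤ 10 spot-lengths; stroma and pathology non-cancer spots are
excluded. For each gene the model

```
log1p(count · 10⁴ / spot_total)  ~  β₀ + β_d · d + sample + adjusted_score
```

is fitted by OLS, where `adjusted_score` is the signature score detrended
against *d* per section (absorbing signature transcripts that diffused out
of the high regions). A negative `β_d` means the gene is expressed
proximal to the feature; positive means distal. A gene is significant when
its Bonferroni-adjusted p-value is < 0.05 **and** its coefficient lies
more than 3 SD from the mean coefficient. Fitting the model separately in
responder (R) and non-responder (NR) tumors, the per-gene difference
`Δ = β_NR − β_R` is screened with a 2·SD outlier rule to find genes whose
spatial relationship to the feature differs with therapy outcome.

Quality control implements four filters: spots lighter than
mean + 1·SD section brightness (too light to be tissue), spots with < 100
detected genes, spots outside hex-connected components of ≥ 200 spots, and
genes whose probe-captured pseudobulk deviates from an OLS fit against
polyA-captured pseudobulk by > 3 residual SD (unspecific probes).

## Worked example

```python
from spotdist import (StudyDesign, PipelineParams, simulate_study, apply_qc,
                      run_group_model, compare_groups)

design = StudyDesign()          # 4 tumors: 2 responders, 2 non-responders
data = simulate_study(design, seed=7)
qc, report = apply_qc(data, PipelineParams())
print(report.to_frame()[["filter", "n_in", "n_removed", "n_retained"]])

for grp in ("R", "NR"):
    m = run_group_model(qc, grp, PipelineParams())["models"]
    print(f"group {grp}: {len(m)} genes tested over {m['n_spots'].iloc[0]} spots, "
          f"{int((m['p_bonf'] < 0.05).sum())} genes with p_bonf < 0.05")
```

prints

```
       filter  n_in  n_removed  n_retained
0  brightness  4356        298        4058
1   min_genes  4356          0        4356
2  contiguity  4058          0        4058
group R: 300 genes tested over 647 spots, 6 genes with p_bonf < 0.05
group NR: 300 genes tested over 725 spots, 6 genes with p_bonf < 0.05
```

The brightness filter removes the light tail of spots (including the 2%
simulated debris); all spots clear the 100-detected-genes rule and the
tissue is one connected component. Within each group, the per-gene fits
recover planted distance trends: the strongest Bonferroni-significant
non-responder genes in this run are

```
       beta_d      se  p_bonf  beta_true
g0035 -0.1569  0.0265  0.0000      -0.08
g0050 -0.1506  0.0270  0.0000      -0.08
g0044 -0.1251  0.0261  0.0006      -0.08
```

i.e. genes planted with negative (proximal) distance coefficients are
estimated negative and significant. `compare_groups` then contrasts the R
and NR coefficient tables gene by gene.

The same pipeline runs from the shell:

```bash
spotdist all --workdir run1 --seed 7      # simulate → qc → score → model → compare
```

Each stage writes its tables plus a manifest (config hash, seed, versions,
input checksums); rerunning with the same seed reproduces every artifact
byte for byte. `spotdist simulate` writes Space-Ranger-style section
directories (`matrix.mtx`, `features.tsv`, `barcodes.tsv`,
`positions.csv`) that `spotdist qc` reads back, so the pipeline consumes
real directory layouts, not in-memory shortcuts.

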