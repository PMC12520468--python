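# dnbtip

Dynamic-network-biomarker (DNB) tipping-point analysis for replicated
time-course expression data.

Many biological state changes — a tumor becoming metastatic, a tissue
crossing into disease — are preceded by a *critical state* in which a
small group of genes starts fluctuating collectively before the
observable transition happens. The DNB framework detects that state
from three signatures of a candidate gene group at each timepoint:

* **SD_in** — the average standard deviation of the group's genes
  across that timepoint's replicates rises sharply;
* **PCC_in** — the average absolute Pearson correlation over all gene
  pairs inside the group rises;
* **PCC_out** — the average absolute correlation between group genes
  and the rest of the transcriptome falls.

These combine into the criticality index

```
CI = size · PCC_in · SD_in / PCC_out
```

whose peak over the sampled timepoints marks the tipping point. `dnbtip`
implements the full analysis around that statistic: differential
expression over baseline contrasts (moderated t, Benjamini–Hochberg),
fuzzy c-means clustering of temporal expression patterns, candidate
module search and tipping-point detection with a permutation null, and
the downstream network steps — first neighbors of the DNB in a
protein–protein interaction graph, intersection with pre-tipping DEGs
and metastasis gene sets, and correlation-network ranking of DNB genes
by their number of high-correlation partners (|r| > 0.8, p < 0.05).

Because real tipping-point datasets are rarely shareable, the package
ships a synthetic-data module that plants a critical transition (a
one-factor covariance burst at a chosen timepoint) with full ground
truth, so every stage can be validated end to end.

## Worked example

```python
from dnbtip import SimulationConfig, simulate_critical_transition, detect_tipping

series, truth = simulate_critical_transition(SimulationConfig(seed=1))
result = detect_tipping(series)
print(result.profile_frame())
```

prints

```
timepoint    sd_in   pcc_in  pcc_out        ci
       W2 0.568555 0.640768 0.638929 11.403797
       W3 0.443557 0.616011 0.635120  8.604199
       W4 1.686574 0.929698 0.641843 48.859318
       W5 0.526334 0.626986 0.634640 10.399709
       W6 0.494393 0.619326 0.633032  9.673752
```

The CI peaks at W4 — the planted transition timepoint — because the
module's replicate-level SD jumps from ~0.5 to ~1.7 and its internal
correlation from the small-sample chance level (~0.64 at n=3) to 0.93.
On this seed the detected 20-gene module contains 19 of the 20 planted
genes. More examples live in `examples/` (differential expression,
temporal patterns, neighbor ranking, the full pipeline); each is a
short script that builds its own input and explains what it prints.

## Command line

The same pipeline is available from the shell:

```
dnbtip simulate --out scratch/demo --seed 1
dnbtip run --config scratch/demo/config.yaml
```

`run` writes DEG tables, cluster assignments, the candidate/CI tables,
the DNB gene list and profile, the neighborhood intersections, ranked
genes and Cytoscape-importable correlation networks into a results
directory, plus a manifest that is byte-identical across reruns with
the same configuration and seed.

## Limitations worth knowing

With three replicates per timepoint, per-timepoint correlations are
extremely noisy (independent gene pairs average |r| ≈ 0.64), which
bounds how reliably a weak transition can be found; `docs/methods.md`
discusses the detector's behavior, its calibration under
no-transition nulls, and the design decisions in detail.
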