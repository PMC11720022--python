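# melanoma-interactome

Tumor–stroma interactome analysis for bulk melanoma transcriptomes: who
is talking to whom across the tumor/stroma boundary, which genes carry
that signaling, and whether they stratify patient survival.

Bulk tumor RNA is a mixture of malignant and stromal cells. Given a
per-sample tumor purity *p_i*, the package deconvolves each gene's bulk
expression into compartment means via the mixing model

    e_bulk[g, i] = p_i · ē_T[g] + (1 − p_i) · ē_S[g]

fit by per-gene non-negative least squares. Ligand–receptor pairs are
then scored with mass-action **Relative Crosstalk (RC)** scores — for the
tumor→stroma axis,

    RC_T,S = ē_L,T ē_R,S / (ē_L,T ē_R,S + ē_L,T ē_R,T + ē_L,S ē_R,S + ē_L,S ē_R,T)

and analogously for tumor→tumor, stroma→tumor, stroma→stroma; the four
scores sum to 1 and the uniform K_D cancels. Top-15 pairs per axis yield
axis gene sets; genes supported by ≥ 2 of 3 evidence sources
(co-expression hubs, cell–cell communication genes, RC crosstalk genes)
form a consensus list; each consensus gene is screened by median-split
Kaplan–Meier / log-rank analysis with BH-FDR adjustment per endpoint
(overall and disease-free survival), and consensus genes are correlated
pairwise (Spearman, rho > 0.8 flagged "strong"). A synthetic-data
generator with planted ground truth (directionally biased pairs, known
compartment profiles, genes with a known hazard effect, evidence sets
with exact overlaps) makes every stage testable end to end with no
downloads. See `docs/methods.md` for the model details and assumptions.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (500 genes × 100 samples, noise σ = 0.1, 5 planted pairs per axis,
5 protective prognostic genes):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_deconvolve.py
python analysis/03_crosstalk.py
python analysis/04_consensus.py
python analysis/05_survival.py
python analysis/06_correlate.py
```

Output (abridged) from a run with seed 1:

```
recovery vs truth: Pearson r = 0.9998 (tumor), 0.9981 (stroma)
axis ts: top-15 holds 5/5 planted pairs, gene-set size 29
consensus (>=2 of 3): 11 genes
endpoint dfs: 11 genes screened, 10 significant at FDR < 0.05
 gene  n_high  n_low  median_high  median_low    p_raw    p_fdr
G0044      50     50    93.440941   17.853821 0.000023 0.000253
```

Reading the numbers: deconvolution recovers the true compartment profiles
almost exactly despite the noise; all 20 planted directional pairs
surface in their axis's top 15; the consensus count equals the designed
overlap (11); and the planted protective genes (G0040–G0044) show the
expected longer median survival in the high-expression arm (93.4 vs 17.9
months for G0044) with small adjusted p-values. Artifacts land under
`results/analysis/`.

The same stages are available as a CLI (`interactome simulate`,
`deconvolve`, `crosstalk`, `axis-genes`, `consensus`, `survival`,
`correlate`, `run-all`) for use on real expression/purity/clinical
tables; `run-all` writes a JSON manifest of every stage artifact, and
`interactome COMMAND --help` documents the file formats.

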