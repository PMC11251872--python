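# dynconn

Dynamic functional brain-network analysis for resting-state BOLD data, plus a
synthetic state-switching multi-group BOLD generator so the entire pipeline is
testable without any acquisition.

The pipeline covers:

- **synthgen** — ground-truth generator: 20 named regions (10 cortical / 10
  subcortical), per-condition covariance-regime libraries (awake-like rich
  coupling vs anesthetic-like suppression), first-order Markov state
  switching, band-limited (0.01–0.10 Hz) correlated signals, mirror-symmetric
  voxel lattices with WM/CSF confounds and motion tables with injected spikes.
- **preprocess** — framewise displacement and frame censoring (0.15 mm
  default, drop or interpolate), linear detrend + WM/CSF/motion nuisance
  regression (global signal deliberately not regressed), hard frequency-domain
  band-pass, mask-normalized Gaussian smoothing (0.7 mm FWHM default).
- **static_fc** — Fisher-z Pearson FC matrices, edge-wise two-sample t-tests
  with Benjamini–Hochberg FDR, FC-matrix similarity over ROI scopes
  (all / cortical / subcortical / cortico-subcortical).
- **dynamic_fc** — sliding-window FC (50 TR / 5 TR default, 89 windows for a
  490-TR series), pooled k-means brain-state clustering with Davies–Bouldin
  model selection, state frequencies, transition probabilities, ANOVA +
  Tukey–Kramer group statistics with Shapiro–Wilk/Bartlett diagnostics.
- **graph_metrics** — sparsity-thresholded (top 20% |z|) binary networks;
  nodal efficiency, clustering coefficient and shortest path per window, with
  per-node coefficient-of-variation summaries.
- **voxel_dynamics** — windowed voxel indices (fALFF, ReHo, VMHC, degree
  centrality, global-signal correlation), voxel- and volume-wise concordance
  (Kendall's W), and FC-architecture stability maps; voxel-wise group tests
  with FDR.
- **pipeline / cli** — end-to-end orchestration with YAML config, provenance
  sidecars, and machine-readable reports.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (window arithmetic,
graph-metric oracle equivalence against networkx, Kendall's W correctness
against a from-definition oracle, planted-state recovery, edge-wise detection
sensitivity/specificity, direction-of-effect checks, exact reductions, and
preprocessing spot checks).

## CLI

```bash
# simulate a synthetic multi-group dataset (TSV series, design.csv, truth JSON)
dynconn simulate --out data/ --seed 42            # add --voxels for NIfTI scans

# validate an input directory against its design table
dynconn validate --input-dir data/

# full run: simulate -> preprocess -> static -> dynamic -> graph
dynconn run-all --input-dir data/ --out out/ --seed 42

# individual stages
dynconn preprocess --input-dir data/ --out out/
dynconn static-fc  --input-dir data/ --out out/
dynconn dynamic-fc --input-dir data/ --out out/
dynconn graph      --input-dir data/ --out out/
dynconn voxel      --input-dir data/ --out out/   # needs simulated voxel scans

dynconn report --out out/
```

All stages accept `--config cfg.yaml` (keys mirror
`dynconn.pipeline.RunConfig`: window width/step, sparsity, band, FD
threshold, k range, alpha, stage toggles, ...), `--seed`, and `--force` to
rerun stages whose inputs are unchanged.

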