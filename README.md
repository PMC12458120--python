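# quantepi

Quantitative differential-epigenomics analysis for chromatin-mark and
methylation studies of drug response, plus hit calling for arrayed
reporter screens.

When ChIP-seq tracks are on an absolute scale (IP-efficiency units, as
produced by sans-spike-in quantitative ChIP), treatment arms can be
compared directly: a peak's *response* is the ratio of its track area
under treatment to its area under vehicle. `quantepi` implements the
peak-level statistics around that idea and the companion analyses a
typical study needs:

- **response** — peak areas, per-pairing log2 fold-changes across the
  full cross of treatment x vehicle replicates, replicate-conserved
  consensus peaks, and replicate-level variance. For a peak with
  treatment area $A_T$ and vehicle area $A_V$, each pairing contributes
  $\log_2\!\frac{A_T + \epsilon}{A_V + \epsilon}$; a replicate's
  response is its mean over vehicle pairings and the peak's response is
  the mean over treatment replicates.
- **diffcall** — fixed-threshold gain/loss calling (acetyl-mark default
  gain $\log_2\mathrm{FC} \ge 0.585 = \log_2 1.5$, loss $\le -1$;
  monomethyl-mark default $\pm 0.5$ with a replicate-variance ceiling of
  1), and narrow/broad peak-shape classes from a two-component Gaussian
  mixture on $\log_{10}$ peak width.
- **chromstate** — overlap enrichment of peak sets against an 18-state
  chromHMM-style annotation, condensation to
  Promoter/Enhancer/Genic/Repressive, and enrichment-bias percentages
  (each state's fold as a share of the summed folds).
- **integrate** — nearest-peak linking of one mark to another within a
  +/- window, k-means (k = 3) stratification of linked regions into
  low/intermediate/high second-mark signal tiers, profile matrices over
  queried coordinates, and a threshold filter for differential
  expression tables (|log2FC| >= 1, FDR <= 0.01).
- **methylation** — per-CpG group delta-beta and DMR calling by the
  contiguity criterion: at least five consecutive same-direction probes
  whose mean |delta-beta| reaches 0.20.
- **screen** — luminescence-per-confluency normalisation, exclusion of
  non-expressed genes (CPM < 100 in every condition) and toxic
  knockdowns (confluency more than 1 SD below the mean), and hit calling
  at Z > 4.
- **simulate** — generators for every input above with planted,
  machine-readable truth (treatment effects, width components, DMR runs,
  screen hits/toxic genes), so the whole pipeline is testable without
  any external data.

## Worked example

Run the end-to-end demo on synthetic data and inspect a response table:

```
$ quantepi demo --seed 3 -o demo_out
INFO quantepi: call: {'n_gain': 40, 'n_loss': 40, 'n_not_significant': 120, ...}
INFO quantepi: dmr: {'n_dmrs': 3, 'n_hyper': 2, 'n_hypo': 1}
INFO quantepi: screen: {'n_hits': 51, 'n_toxic_flagged': 237, 'n_low_expression': 500}

$ quantepi respond --treat demo_out/treat_rep1.bedGraph --treat demo_out/treat_rep2.bedGraph \
    --veh demo_out/veh_rep1.bedGraph --veh demo_out/veh_rep2.bedGraph \
    --peaks demo_out/planted_peaks.bed -o resp.tsv
INFO quantepi: wrote 200 peak responses to resp.tsv

$ quantepi call --responses resp.tsv --mark h3k27ac -o calls.tsv
INFO quantepi: calls: {'not_significant': 121, 'gain': 40, 'loss': 39}
```

The demo plants 200 peaks on a 2 Mb chromosome (20% gains at 2-fold,
20% losses at 0.4-fold, 10% replicate noise); the caller recovers 40
gains and 39-40 losses at the 0.585/-1.0 thresholds. The DMR stage
recovers the planted contiguous-probe runs, and the 18,000-well screen
stage calls the ~50 planted activators at Z > 4 while flagging toxic
wells (the 237 flags are the 100 planted toxic genes plus healthy wells
in the tail of the confluency distribution). Enrichment of the called
gains against the condensed annotation prints per-category folds and
bias percentages that sum to 100.

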