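# refstab

Reference-gene stability evaluation for qPCR cycle-threshold (Ct) data.

Relative quantification by qRT-PCR stands or falls with the reference
("housekeeping") gene used for normalization — and for many sample types,
fecal/intestinal miRNA among them, no validated reference exists. The
standard remedy is an empirical screen: measure a panel of candidates across
samples, score each with three independent stability statistics, and pick
the consensus winner. `refstab` implements that screen end to end:

- **geNorm** — for gene *j*, `M_j = mean_k sd_s(log2 q_js/q_ks)` over partner
  genes *k*, with iterative exclusion of the highest-M gene until two
  remain (those share rank 1); candidates with first-pass `M > 1.5` are
  flagged unstable.
- **NormFinder** (single group) — variance decomposition of
  `y_ij = log2 Q_ij` into sample and gene-noise components; stability
  `rho_i = sqrt(max(0, (k/(k-2))(u_i - mean(u)/(k-1))))` where `u_i` is the
  per-gene variance of sample-centered log quantities.
- **BestKeeper** — per-gene dispersion of raw Ct: SD (mean absolute
  deviation, or classic n−1 SD by flag) and CV = 100·SD/mean, ranked by CV;
  SD > 1 cycle flags instability.
- **Consensus** — per-gene average of the three method ranks, ordered
  ascending (competition ranks, deterministic tie-breaks).
- **Differential expression** — `2^-dCt` levels against the chosen
  normalizer, unpaired Student's t-test between two groups, control-scaled
  means ± SEM, BH q-values.
- **Synthetic data** — a seeded Ct generator with planted per-gene noise,
  shared loading effects and case-group shifts, so every stage is testable
  against ground truth.

All methods consume relative quantities `Q = 2^-(Ct - Ct_min)` (geNorm,
NormFinder) or raw Ct (BestKeeper), as each method's convention dictates.

## Worked example

Simulate a screen-shaped dataset (22 candidates, 5 control + 5 case
samples), rank the candidates, then quantify targets against the default
normalizer:

```
$ refstab simulate --seed 7 --out demo
$ refstab stability --input demo/ct.csv --method all --out demo/stab
$ head -6 demo/stab/consensus.csv
gene,genorm_rank,normfinder_rank,bestkeeper_rank,average,comprehensive_rank
GAPDH,1,6,1,2.667,1
let-7i,1,3,9,4.333,2
mir-1224,3,4,7,4.667,3
16S rRNA,4,7,3,4.667,4
mir-574,5,5,4,4.667,5
```

Each row gives a candidate's rank under the three methods, the arithmetic
mean of those ranks, and the resulting comprehensive rank — here the
planted low-noise genes (GAPDH, let-7i) land on top, i.e. the screen
recovers the simulated truth. Differential expression against the
top-ranked high-abundance candidate:

```
$ refstab de --input demo/ct.csv --metadata demo/samples.csv --out demo/de
$ head -5 demo/de/de.csv
gene,mean_control,sem_control,mean_case,sem_case,fold_change,t,p,q,significant,direction
mir-23a,1.000,0.032,0.272,0.009,0.272,-21.991,0.000,0.000,True,down
GAPDH,1.000,0.021,1.030,0.043,1.030,0.624,0.550,0.889,False,ns
mir-378,1.000,0.031,0.255,0.014,0.255,-21.886,0.000,0.000,True,down
mir-1224,1.000,0.052,0.980,0.043,0.980,-0.302,0.771,0.952,False,ns
```

`mean_case` is scaled so the control mean is 1: mir-23a shows a ~0.27-fold
level in the case group (a planted 2-cycle shift, ≈4-fold down,
p < 0.05 → "down"), while GAPDH and mir-1224 are unchanged ("ns").

The same pipeline runs from the library (`refstab.full_evaluation`,
`refstab.group_compare`, ...), and `refstab consensus --ranks ranks.csv`
aggregates rank columns produced elsewhere. Every output directory carries
a `manifest.json` with the package version, effective config and input
checksums.

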