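# tauseq

Analysis toolkit for the post-transcriptional life of bacterial mRNAs:
time-resolved RNA-decay measurements after transcription arrest, absolute
abundance calibration, statistics of mRNA stability across protein-
localization groups, massively multiplexed signal-peptide fusion-library
design, array-derived FISH probe-pool design, and normalized single-cell
coordinate systems for 3-D localization microscopy.

The package is aimed at researchers studying mRNA turnover and spatial
organisation in rod-shaped bacteria (E. coli in particular), and at anyone
who needs a tested, scriptable implementation of these analysis steps on
their own count tables, sequence sets or localization lists.  Every stage
has a matching synthetic-data generator, so the whole pipeline runs and is
tested end to end without any external data.

## The model at the core

After rifampicin blocks transcription *initiation*, RNA polymerases already
on a gene keep elongating, so the copy number N(t) of an mRNA species stays
at steady state for a delay α before net decay begins:

```
N(t) = Nf + N0                        t ≤ α
N(t) = Nf + N0 · exp(−k (t − α))      t > α
```

N0 + Nf is the initial copy number, Nf a stable baseline, k the first-order
decay rate (1/min) and α (min) the time for the last initiated polymerases
to finish the gene.  Half-lives are τ = ln 2 / k.  The model is fitted by
nonlinear least squares in log space (equal relative weighting of all time
points), and a half-life is *reported* only when the rate error — one
quarter of the 95% confidence interval on k — is strictly less than k/2 and
τ does not exceed the final sampled time point (20 min by default).

Counts become absolute copies per cell in two stages: per-sample scaling by
in-vitro spike-ins of known abundance, then pinning a designated stable RNA
(tmRNA, 597 copies per cell) to a constant at every time point to cancel
extraction-efficiency variation.

## Worked example

Simulate a 40-species rifampicin time course (8 time points, 0–20 min,
Poisson counting noise, four spike-ins), calibrate it, and fit half-lives:

```python
import numpy as np
from tauseq import synthetic as syn, calibration as cal
from tauseq.decay import fit_table

spec = syn.DecaySimSpec(n_species=40, seed=11)
counts, truth = syn.simulate_decay_counts(spec)
rng = np.random.default_rng(11)
counts.loc["tmRNA"] = rng.uniform(4000, 6000, counts.shape[1])

res = cal.calibrate(counts, spec.spikein_copies, drop_spikeins=True)
fits = fit_table(res.calibrated.drop(index="tmRNA"))
print(fits[["k", "alpha", "tau", "pass"]].head(5).round(3))
```

prints

```
                k  alpha    tau   pass
species_id
gene0000    0.485  0.076  1.429   True
gene0001    0.180  3.702  3.844  False
gene0002    0.317  3.100  2.188   True
gene0003    0.179  4.500  3.865  False
gene0004    0.681  3.336  1.017   True
```

35 of the 40 species pass the reporting filter, and among the passers the
median relative half-life error against the simulation ground truth is
7.3%.  `k` is the decay rate in 1/min, `alpha` the transcription-completion
delay in minutes, `tau = ln2/k` the half-life; `pass` marks species whose
rate is determined precisely enough to report (gene0001's wide confidence
interval — its true decay is slow and baseline-dominated — is correctly
rejected).

A statsmodels-style object interface is available for single curves:

```python
from tauseq.decay import DecayModel
fit = DecayModel.from_dataframe(res.calibrated, "gene0002").fit()
print(fit.summary())
```

Other entry points: `tauseq.groupstats` (KS comparisons of half-life
distributions across protein-localization groups), `tauseq.fusion`
(signal-peptide classification, 90-nt barcode encodings, library
assembly), `tauseq.probes` (targeting-region and index-primer screens,
template assembly), `tauseq.geometry` (cell boundary → poles/ribs/
centerline → normalized X, Y, Z → density profiles), and a thin `tauseq`
CLI with `simulate`, `calibrate`, `fit`, `compare`, `design-library` and
`design-probes` subcommands.

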