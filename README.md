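# suldex

Bayesian MCMC estimation of sequence-specific dissociation constants (Kd),
binding energies, and free transcription-factor concentration from paired
pre-bound/bound sequencing counts of short double-stranded DNA ligand pools
— together with a forward simulator of such experiments and a Markov model
of ligand-synthesis frequencies.

## What it does

A ligand pool is sequenced before (`C`, pre-bound counts) and after (`D`,
bound counts) equilibration with a transcription factor. At equilibrium the
fraction of a sequence that is bound follows the hyperbolic isotherm
θ = [TF] / ([TF] + Kd), and the bound-pool frequencies are the pre-bound
frequencies reweighted by θ. Given at least two reference sequences with
known Kd, the package infers posteriors for every other sequence's Kd and
for the free TF concentration by Metropolis–Hastings sampling of a joint
multinomial likelihood over both count vectors.

Three model layers:

- **BBM** (basic binding model): multinomial likelihoods over `C` and `D`
  with free parameters {pre-bound frequencies, non-reference Kds, free TF}.
- **GEM** (generative energy model): adds an additive position-specific
  energy model with per-sequence Gaussian error of scale σ. Individual
  energy terms are switched in/out by reversible-jump MCMC with
  proposal-reallocation refinement; the occupancy ratio between adjacent
  models estimates their Bayes factor.
- **GSM** (generative sequence model): order-m Markov model predicting pool
  counts from polynucleotide frequencies; used for simulation inputs and
  optional frequency smoothing, never silently substituted into a
  likelihood.

Modules: `binding_core` (isotherm math, calibration, Kd↔energy map), `bbm`,
`gem`, `gsm`, `mcmc` (MH engine, tuning, convergence, RJMCMC), `simulator`
(forward simulation + experimental-design presets), `evaluation` (log-Kd
RMSE, CV comparison, energy tables), `io_cli` (TSV/FASTA/JSON formats and
the CLI).

## CLI

```sh
# simulate an experiment from a named preset
suldex simulate --preset leu3_like --tf-free 10 --mean-depth 100 \
    --seed 1 --out-dir runs/sim

# fit the basic binding model
suldex fit-bbm --pre runs/sim/pre_counts.tsv --bound runs/sim/bound_counts.tsv \
    --references runs/sim/references.tsv --out-dir runs/fit \
    --n-generations 100000 --burn-in 10000 --seed 1

# fit the energy model (reversible-jump MCMC)
suldex fit-gem --pre ... --bound ... --references ... \
    --optimal-sequence CCGGTACCGG --out-dir runs/gem

# fit a Markov sequence model to pre-bound counts
suldex fit-gsm --counts runs/sim/pre_counts.tsv --out-dir runs/gsm

# compare a fit against simulation ground truth
suldex evaluate --summary runs/fit/summary.json \
    --truth runs/sim/ground_truth.tsv --out-dir runs/eval
```

Counts are TSV `(sequence, count)`; references are TSV `(sequence, kd_nM)`.
All concentrations are nM; energies are dimensionless (units of RT),
defined relative to the optimal sequence. A YAML config file can supply any
subcommand's defaults via `--config`; explicit flags override. Every
stochastic command is bit-reproducible given the same seed and config, and
every output file carries a config-hash header.

## Notes on priors

Flat priors are used throughout, so the posterior is proportional to the
likelihood on each parameter's sampling scale (log scale for Kd, free TF
and σ; natural scale for energy terms, uniform on [0, w_E]). Fully
unbounded flat log-scale priors would make the posterior improper along the
ridge where the free TF concentration and all non-reference Kds grow
together (reference binding saturates), so the flat support is bounded by
default to a window around the reference Kds (`MCMCConfig.prior_window`),
and a known total-TF concentration can be supplied as a hard upper bound on
free TF.
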