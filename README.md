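# weam — a single-register weighted entropic associative memory

`weam` implements a declarative, distributed model of associative memory in
which the medium is a plain table: an *associative memory register* (AMR)
with `n` columns (the arguments of a discrete function) and `m` rows (its
quantized values). Every object is a function mapping each argument to one
row, and is stored by reinforcing one cell per column. Because traces
overlap on the medium, the stored content is *indeterminate*, and Shannon
entropy plays a functional role: it measures the indeterminacy and counts
the memory's content. The package is for researchers in computational
cognitive modelling who want a small, fully testable implementation of this
memory — its operations, its capacity accounting, and the experiment
protocols used to study it — without any neural-network scaffolding.

## The model

Let `R(a_i, v_j) = w_ij` be the weight table and let a cue be a (possibly
partial) function `f_a`. The three operations are:

- **λ-register** — `Q(a_i, v_j) = R_f(a_i, v_j) + R_a(a_i, v_j)`: every cell
  used by the cue is incremented (a Hebbian-style reinforcement), saturating
  at two-byte cells (`l = 65535`).
- **η-recognition** — a direct logical test, no search: column `i` accepts
  the cue iff its cell is on (`w > 0` and `w ≥ ι·ω_i`, where `ω_i` is the
  mean nonzero weight of the column). The cue is accepted iff at most `ξ`
  columns fail (material implication relaxed by `ξ`) and the mean cue
  weight satisfies `ρ ≥ κ·Ω`. Defaults `ι = κ = ξ = 0` impose no
  constraint beyond direct rejection of unsupported cells.
- **β-retrieval** — constructive, Bayesian recall: for each column, the
  weights define a prior `Ψ_i`, the cue a likelihood `ζ_i` (a normal kernel
  with sd `σ·m` centered at the cue's level), and the output level is
  sampled from `Φ_i ∝ Ψ_i · ζ_i`. With `σ = 0` the memory is reproductive
  (photographic); larger `σ` yields associated and imaged objects. A
  rejected cue retrieves nothing.

Column entropy is the Shannon entropy of `Ψ_i` (an empty column counts 0);
the memory entropy `e` is the column mean; and the number of functions the
register holds — registered plus *emerging* — is `2^{e·n}`. A 256-column
register at unit entropy holding 14,000 registered objects therefore
contains `2^256 − 14,000` emerging objects.

Because real encoders are out of scope, a synthetic domain stands in for
encoder outputs: 10 balanced Gaussian classes in 64 dimensions, split
70/20/10 into train / remember / test corpora, with a linear per-argument
quantizer as the codec and a nearest-centroid classifier as the external
classifier.

## Worked example

```sh
weam demo --out demo_run --seed 0 --size 1000
```

prints

```
fill=0.10 entropy=1.728 precision=100.0 recall=83.0
fill=0.50 entropy=1.776 precision=100.0 recall=100.0
fill=1.00 entropy=1.787 precision=100.0 recall=100.0
demo artifacts in demo_run: sweep.csv, chains.csv, run_config.json
```

Each line is one cell of the fill sweep: a fresh 32-column, 4-row register
is filled with that fraction of the remembered corpus, then every test
object is retrieved (`σ = 0.1`) and classified. At 10 % fill the register
is sparse: cues whose cells are unsupported are rejected directly, so
recall is 83 % while every accepted cue is retrieved and classified
correctly (precision 100 %). As the fill — and the entropy — grows, recall
climbs to 100 % without precision collapsing: the entropy trade-off.
`chains.csv` holds ten association chains (16 rows, `σ = 0.15`): each
retrieval is fed back as the next cue, with the class assigned at each
step; chains stop at the first rejection.

The same pipeline is available as a library (`weam.generate_domain`,
`weam.run_fill_sweep`, `weam.run_chain`, …) and as individual commands
(`generate`, `fit-codec`, `register`, `recognize`, `retrieve`, `chain`,
`sweep`).

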