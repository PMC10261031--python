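# Methods

## The memory model

The memory medium is a single associative memory register (AMR): an
`n × m` table of non-negative integer weights, `n` columns for the
arguments of a discrete function and `m` rows for its quantized values.
An object occupies one cell per column; traces overlap freely, so the
representation is distributed and indeterminate. The model assumes
auto-association on a fixed-size medium (no hetero-associative extension)
and a single register for all classes — storage is unsupervised and
classification is external to the memory.

**Register (λ).** Cell-wise addition of the cue into the table,
saturating at `max_weight` (default 65535, i.e. two-byte cells, with
silent clamping). Partial cues touch only their defined columns.

**Recognition (η).** Column `i` fails when its cue cell has weight 0 or
weight below `ι·ω_i`, where `ω_i` is the column's mean *nonzero* weight
(`ω_i = 0` for an empty column, which then contributes 0 to `Ω`). The cue
is accepted when at most `ξ` columns fail and the mean cue weight `ρ` is
at least `κ·Ω`, `Ω` being the mean of `ω_i` over all `n` columns. Two
interpretation points are deliberate:

- *Zero-weight cells are always off*, even at `ι = 0`: otherwise
  `w ≥ ι·ω_i = 0` would hold vacuously and nothing could ever be
  rejected, destroying the direct-rejection property.
- *Partial cues* are scored over their defined arguments only (the
  divisor of `ρ` and the failing-column count shrink accordingly), while
  `Ω` remains a property of the whole register. The divisor convention is
  an interpretation choice; it makes `ρ` of a partial cue commensurable
  with `κ·Ω`.

**Retrieval (β).** Per column, the prior `Ψ_i` is the normalized weight
column and the likelihood `ζ_i` is a normal density with standard
deviation `σ·m`, evaluated at the integer levels `0…m−1` and
renormalized — the simplest discretization consistent with a level-valued
kernel; no continuity correction is applied. The output level is sampled
from `Φ_i ∝ Ψ_i·ζ_i`. Degenerate cases: at `σ = 0` the kernel is a point
mass, making retrieval reproduce a stored cue exactly; if that point mass
lands on a zero-weight cell (possible only in `ξ`-relaxed columns) the
column falls back to sampling from `Ψ_i`, so retrieval of an accepted cue
is always defined; undefined cue arguments sample from `Ψ_i` alone; a
column with no weight at all stays undefined in the output (the result is
flagged partial). Rejected cues return an undefined result (Python
`None`), never an exception. All sampling flows through an explicit
seeded `numpy` generator; there is no global random state.

**Entropy and capacity.** Column entropy is the Shannon entropy (bits) of
`Ψ_i`, 0 for an empty column; memory entropy `e` is the column mean. The
register holds `2^{e·n}` functions (registered plus emerging); the
package returns this in log space (`capacity_log2`) and provides an exact
big-integer path (`exact_capacity`, `emerging_objects`) for integral
exponents, so quantities like `2^256 − 14000` are computed without
floating-point loss. On a boolean register (weights clamped at 1) the
column entropy reduces to `log2 ν_i` and `2^{e·n} = ∏ν_i`, which the
tests verify against exhaustive enumeration of one-cell-per-column
combinations.

## Codec

A trained encoder/decoder is out of scope; the codec is a per-argument
linear quantizer: bounds are the training corpus min/max (degenerate
arguments widened by 1e-9), levels are equal-width bins
(`floor(m·(x−lo)/(hi−lo))`, clipped so out-of-range values quantize to the
boundary level rather than being rejected), and dequantization returns
bin midpoints, making quantize∘dequantize level-stable. Levels are
0-based throughout.

## Synthetic domain

The generator emulates the geometry of encoder outputs for a 10-class
image corpus: class centroids with coordinates drawn from
`N(0, separation²)` in `n = 64` dimensions and isotropic within-class
noise. Defaults: `separation = 1.0`, `noise_sd = 0.3` — within-class
spread one third of the between-class scale, chosen to mimic
autoencoder-feature clusters that are well separated for a centroid
classifier yet wide enough that one class occupies several quantization
levels per column. Corpus size defaults to 7000 (a tenth of the 70,000
the full-scale setting would use, keeping protocols in seconds), split
70/20/10 into train (codec/classifier fitting), remember (memory
filling) and test (cueing), balanced and disjoint by construction;
partition counts use largest-remainder rounding per class. The classifier
stand-in is nearest-centroid with ties broken toward the lowest class id.
Cue corruption replaces `round(fraction·n)` positions (chosen uniformly
without replacement) with uniform draws on the quantizer's per-argument
range — the feature-space analogue of randomizing half the pixels of an
image cue.

What the generator does *not* emulate: multimodal cluster shapes,
class-dependent covariance, encoder nonlinearity, or the label noise of a
learned classifier. Passing tests on this domain demonstrate the memory's
operating characteristics (direct rejection, the entropy trade-off, chain
degradation), not performance numbers transferable to any real image
corpus.

## Experiment protocols and problem sizes

- **Fill sweep** (entropy trade-off): for each row count and each fill
  fraction (defaults 1, 2, 4, 8, 16, 32, 64, 100 %), a fresh register is
  filled with a balanced random subset of the remembered corpus and every
  test object is retrieved at `σ = 0.1` and classified. Outcomes follow
  the right / wrong / no-response convention: precision
  `= right/(right+wrong)`, recall `= accuracy = right/total`; with no
  responses at all precision is reported as 0 rather than NaN. Raw counts
  are stored next to every percentage so each figure is recomputable.
- **Sigma sweep**: retrieval of every cue at `σ ∈ {0.05, 0.1, 0.2, 0.3,
  0.4, 0.5}`, optionally corrupting cues first, tabulated as class
  preserved / reassigned / rejected.
- **Chains**: recurrent retrieval (`σ = 0.15`, length 6, 16 rows — 4 rows
  leave too little per-column variability for interesting chains); each
  dequantized retrieval becomes the next cue; a chain stops at its first
  rejection.
- **k-fold**: the remember and test pools are rotated through `k`
  balanced folds (round-robin within class) and the fill protocol is
  repeated per fold, reporting mean and sd.

Default problem sizes — 7000-object domain, 700 test cues per sweep cell,
900 chains per condition (30 seeds × 30 cues) — keep every protocol
within seconds on a single CPU while leaving the statistical assertions
(monotone chain degradation, the trade-off shape) comfortable margins.
All sub-seeds derive deterministically from one master seed via
`numpy.random.SeedSequence`.

## Numerical choices

Sampling uses inverse-CDF on the cumulative `Φ_i` with a final clamp to
`m−1` against cumulative-sum round-off. Entropy terms use the
`0·log 0 = 0` convention. Persistence formats are plain text (register:
`meta.json` + `weights.csv` with row 0 = level 0; codec: JSON; corpora:
CSV with a `label` column) and round-trip bit-exactly.

## Known limitations

- The single-register model omits the multi-register class-selection
  mechanism of earlier versions (not needed here by design).
- The linear codec cannot reproduce effects that depend on a learned,
  non-uniform quantization of feature space.
- `ρ`'s divisor for partial cues and the `ζ` discretization are
  documented interpretation choices (above); alternatives (fixed divisor
  `n`, bin-integrated kernels) would change `κ`- and `σ`-sensitive
  results quantitatively but not the model's qualitative behavior.
- Weights saturate rather than rescale; extremely long runs compress the
  high-weight tail of `Ψ_i`.
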