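# Methods

## The model

`petqc` scores long-range chromatin interaction libraries (Hi-C, in situ
Hi-C, ChIA-PET) by a sequencing-saturation argument. A proximity-ligation
library observed as mapped paired-end tags (PETs) defines a contact map:
counts of PETs per 2-D genomic window, i.e. per pair of fixed-size bins
(bin_i ≤ bin_j) on one chromosome. If the interactome readout were
saturated, discarding a random fraction of the PETs would shrink every
window's count *proportionally*; how far individual windows deviate from
proportionality measures how much of the map is sequencing noise rather
than reproducible signal.

The population under assessment is the **filtered PETs**: unique
(clonal-duplicate-collapsed) intra-chromosomal PETs whose anchors are
separated by more than a span threshold (default 10 kb). The span filter
removes the short-range diagonal, which dominates raw interactomes and
would otherwise swamp the statistics; the duplicate filter removes PCR
clones.

For each sampling density *d* ∈ {0.9, 0.7, 0.5} a subset of exactly
⌊d·N⌋ filtered PETs is drawn uniformly without replacement, the contact
map is rebuilt at the same resolution, and per window:

    recPETcounts = (samPETcounts / oPETcounts) · 100
    ∂PETcounts   = samd − recPETcounts

with `oPETcounts`/`samPETcounts` the original/subsampled window counts
and `samd` the density in percent. Under uniform sampling the
subsampled count of a window with original count *o* is exactly
Hypergeometric(N, o, ⌊d·N⌋), so E[recPETcounts] = samd up to the floor,
and ∂PETcounts is a mean-zero deviation whose spread shrinks as
1/√o — the statistical content of the score.

Global indicators over the window universe (bin pairs with
oPETcounts ≥ `min_window_count`, default 1):

* **denQC.d** — fraction of windows with |∂PETcounts| ≤ threshold
  (default 10%);
* **simQC.d/50 = denQC.d / denQC.50** — similarity of the two sampling
  regimes; 1 at saturation;
* **QCscore_raw = (denQC.50 / simQC.90/50) · (denQC.50 / simQC.70/50)**,
  reported as **QCscore = 10·log10(QCscore_raw)**.

The log form is a design choice of this package: the raw product is a
small positive number, and a decibel-style scale makes the saturation
fixed point 0 and typical desk-scale libraries land in the negative
tens, strictly increasing with denQC.50 at fixed similarity ratios.
Both raw and log values are always emitted so the convention is
transparent.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `resolution_bp` | 5 000 | window (bin) size; 5 kb and 25 kb are the two standard analysis resolutions, run independently |
| `span_threshold_bp` | 10 000 | minimum anchor distance, strict `>`; configurable (25 kb is a common alternative) |
| `dispersion_threshold_pct` | 10 | window passes when \|∂PETcounts\| ≤ this |
| densities | 0.9, 0.7, 0.5 | sub-sampling fractions (s90/s70/s50) |
| `min_window_count` | 1 | windows need this original count to be assessable; singleton windows quantize recovery to {0, 100} |
| `replicates` | 1 | independent sub-sampling replicates; >1 adds the mean and CV of the score |

Numerical conventions, chosen once and documented rather than inferred:

* **Windows are 2-D bin pairs**, not 1-D intervals: every dispersion
  display the score is meant to support is a 2-D interaction heatmap.
* **denQC uses the absolute, non-strict comparison** |∂| ≤ t:
  over-recovery is a deviation too, and the non-strict boundary avoids
  knife-edge behaviour at exactly the threshold.
* **Subset size is ⌊d·N⌋** (floor, not round) for determinism; the three
  densities are drawn independently (s50 is not nested in s90), which
  keeps the per-density statistics exchangeable.
* **Dedup key includes strands** by default: identical coordinates with
  a different strand configuration are distinct ligation products.
  `use_strands=False` relaxes the key to coordinates only.
* **Anchor coordinate** is the 5′-most (start) coordinate of each mate,
  0-based; span = pos2 − pos1 after canonical ordering. Canonical order
  is (chromosome-file order, coordinate), with coordinate ties broken on
  strand so the normal form is unique even for coordinate-identical
  anchors.
* **Seeding** is hierarchical: a `SeedSequence` keyed on
  (master_seed, density, replicate) yields child seeds < 2³¹, so adding
  a replicate or density never perturbs earlier draws and identical
  master seeds give bit-identical results.
* **Degenerate inputs** are explicit errors, never silent numbers: an
  empty window universe, denQC.50 = 0 or a vanishing similarity ratio
  raise an undefined-score error carrying the partial indicators; zero
  filtered PETs raises a nothing-to-score error carrying the library
  statistics.

## The synthetic generator

`petqc.synthetic` generates PET libraries with the features the score is
sensitive to: intra-chromosomal contacts drawn from bin-pair
probabilities p(i,j) ∝ ((j−i)·r)^(−α) multiplied by τ when both bins lie
in the same TAD block (defaults α = 1, τ = 5, two 2 Mb chromosomes with
2–3 TADs each); a Binomial(inter_fraction = 0.1) share of uniform
inter-chromosomal pairs; and a Binomial(duplication_rate = 0.05) share
of records emitted twice to exercise deduplication. Bin pairs are drawn
first and in-bin offsets second, so the binned matrix of a generated
library is exactly a multinomial draw from the configured
probabilities — conservation and goodness-of-fit oracles in the test
suite are therefore exact. Short-range mass is generated (no span floor)
so the 10 kb filter genuinely removes something.

What it does **not** emulate: restriction-fragment boundaries,
dangling-end/self-circle artifacts, mappability gaps, copy-number
variation, or distance-decay shapes beyond a single power law. Passing
tests therefore demonstrate the statistical behaviour of the estimator
under controlled sampling, not the biological realism of any particular
assay; scores on real libraries additionally reflect the upstream
alignment and filtering pipeline.

### Problem sizes used in the checks

The packaged verification runs are desk-scale by design: a 2 Mb
chromosome at 5 kb bins (~78 k possible windows) with raw library sizes
between 2×10⁴ and 8×10⁵ PETs (~1.5×10⁴–5.9×10⁵ filtered). At those
sizes five replicate scorings of the deepest library and a five-point
depth ladder each complete in seconds while leaving tens of thousands of
assessable windows — enough for replicate CVs well below the 10% / 3%
bands being checked. The depth-calibration protocol mirrors the
metafile idea: one large library is generated once and shallower depths
are derived from it by seeded sub-sampling, so depth is the only
variable along the ladder.

## Known limitations

* Scores are comparable only at matched resolution, span threshold and
  genome; the absolute value has no meaning across different window
  universes.
* With singleton-dominated universes (very sparse libraries) denQC.70
  can sit below denQC.50 because recovery is quantized to {0, 50, 100}
  at tiny counts; the expected ordering denQC.90 ≥ denQC.70 ≥ denQC.50
  emerges at moderate per-window counts.
* The 1-D (anchor-marginal) window reading of the indicators is not
  implemented; the 2-D reading is the one consistent with dispersion
  heatmaps.
* BAM mate-pairing is out of scope: convert mapped mates to BEDPE or
  `.pairs` first (e.g. `samtools` + `bedtools bamtobed -bedpe`, or any
  standard pair-extraction tool).
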