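# Methods

## Scope and model

`ppiscorekit` implements the computation that surrounds an external
complex-structure predictor in a high-throughput protein–protein interaction
(PPI) screen. The predictor itself (an AlphaFold-Multimer-class tool driven
through AlphaPulldown-style batch runs) and the programs that produce the
constituent confidence metrics — pi-score, pDockQ, ipTM/pTM — are inputs,
not re-implemented here. What the package owns is:

1. **Sequence preparation.** Signal peptides are trimmed from an annotation
   table (SignalP-style summary: protein id plus 1-based cut site) so the
   mature, post-translocation protein is what gets modelled. Trimming is
   idempotent; a cut site that would empty the sequence is an error, and an
   annotation for an unknown id is a warning.

2. **MSA-depth quality control.** For each query, the per-position depth is
   the number of alignment rows carrying a non-gap residue at that query
   column (A3M lowercase insertion columns do not consume match columns).
   A protein is *shallow* when its **median** depth falls below the
   threshold (default **100 sequences**; median rather than mean because
   ragged alignment ends otherwise dominate). Shallow proteins are listed
   in `shallow_MSA.txt` and all their interactions are marked
   `unreliable_msa` downstream — they are never excluded from prediction,
   because exclusion would silently drop discoveries.

3. **Job planning.** An all-against-all screen of n proteins yields
   C(n, 2) hetero-pair jobs plus, per protein, homo-oligomer jobs for copy
   counts 2..`max_copies` (default 2 during screening). Job size is the sum
   of mature lengths × copy counts. A piecewise-linear capacity map from
   accelerator memory to maximum total residues (defaults
   8 GB→1800, 16→2700, 24→3600, 48→5500, 80→7200; user-overridable, values
   clamp outside the configured range so the map stays monotone) partitions
   jobs into runnable and out-of-memory; OOM jobs go to `OOM_int.txt`. The
   constants are environment-dependent conventions — the mechanism, not the
   numbers, is the contract.

4. **Composite scoring.** Of the five models per job, only the one with the
   highest ipTM is scored (ties break to the lowest model index). The
   composites are

       iQ  = ((pi + 2.63) / 5.26) · 40 + ipTM_pTM · 30 + pDockQ · 30
       hiQ = (((Σᵢ piᵢ) / n + 2.63) / 5.26) · 60 + ipTM_pTM · 40

   with pi-score clamped into [−2.63, 2.63] (warning on clamp: the upstream
   score is unbounded in pathological cases, and the normalisation implies
   the intended range), so both composites live on a 0–100 scale. For
   homo-oligomers the pi-score is averaged over the n distinct chain-pair
   interfaces reported upstream (multiple table rows or a JSON list per
   model are treated as per-interface records; n is their count).
   At the constituent thresholds pi = 0.05, ipTM_pTM = pDockQ = 0.5 the
   composites evaluate to 50.38 and 50.57 — which is why the operational
   retention cutoff is a round **strictly greater than 50**, not those
   derived constants.

5. **PAE gate.** Before any composite is computed, the best model must show
   a supported interface in its predicted-aligned-error matrix. The wording
   "PAE above a threshold" is ambiguous about aggregation; this package
   gates on the **minimum inter-chain PAE ≤ 10 Å** (both orientations of
   every chain pair), because one confidently placed inter-chain region is
   exactly what evidences a physical interface. `--pae-stat {min,median,
   mean}` exposes the alternatives for sensitivity analysis. Gate failures
   keep their constituent scores in the output table (reason recorded) but
   get no composite and cannot be retained. The gate applies to the best
   model only, matching the rule that scores are computed exclusively for
   the best model.

6. **Interface geometry.** Distance matrices are computed per residue pair
   under an atom mode: `CA`, `CB` (default; CA substitutes for glycine) or
   `min-heavy` (minimum over heavy-atom pairs, which lower-bounds the
   single-atom modes). Interface contacts are cross-chain pairs within
   **8.0 Å CB–CB** — the standard contact-prediction convention; no distance
   criterion is inherent to the method, so both cutoff and atom mode are
   parameters. Distograms and contact tables are produced for retained jobs
   only (override with `--all` semantics via the library API). Outputs use
   author residue numbering.

7. **Reporting.** The heatmap holds iQ-scores off-diagonal and the best
   hiQ-score on the diagonal; cells never scored (or gate-failed) are NaN in
   the TSV and hatched in the figure — *absent is not zero*. The network
   contains proteins with ≥1 retained hetero edge plus homo-oligomer-only
   proteins as isolated annotated nodes; layout is a seeded force-directed
   embedding so reruns are comparable. Every figure has a TSV/GraphML
   sidecar; sidecars are the single source of truth.

## Synthetic cohorts

The `fixtures` module generates complete toy inputs: FASTA, SignalP-style
table, A3M alignments, per-job score JSONs, PAE matrices and poly-alanine
PDB structures, plus a ground-truth manifest. Design parameters default to
a mixed cohort of 6 proteins (mature lengths 16–28 residues, every third
protein shallow at ~5 effective rows vs ~130 for deep, alternate proteins
carrying 5-residue signal peptides) with composite scores placed on both
sides of the 50 cutoff, PAE-gate failures, and pairs exceeding a stated
44-residue toy capacity.

Every manifest expectation is computed independently of the modules it
tests: composite scores by straight-line re-evaluation of the formulas
(deliberately duplicated code), alignment depth from the gap masks the A3M
text is rendered from, contacts by a brute-force O(n²) scan of the written
coordinates, and the planted-contact distances verified against the built
geometry to 1e-6 before the PDB is written. A design whose intended
retained flag contradicts its own scores is refused.

Planted contacts are placed at exact CB–CB distances between straight
poly-alanine chains (3.8 Å CA spacing). Because backbone neighbours of a
planted residue can also fall under the 8 Å cutoff — as they would at a
real interface — the manifest stores the full brute-force contact list, and
the planted pairs are asserted present at their exact distances within it.

What the toys do **not** emulate: realistic fold geometry, rotamers,
predictor error correlations between PAE and scores, or MSA diversity
beyond per-column depth. Passing tests therefore demonstrate that the
bookkeeping, formulas, gates and reports are correct — not that the
upstream predictor's confidence metrics are well calibrated on real
complexes.

## Numerical choices

- Chain intervals are 0-based half-open internally; every user-facing table
  is 1-based inclusive with author numbering.
- Best-model ties (equal ipTM) resolve to the lowest model index.
- Contact ties sort by distance, then chain/residue lexicographically.
- PAE matrices are validated square, non-negative, and dimension-matched to
  the chain ranges; two JSON dialects are accepted (a
  `predicted_aligned_error` object and a one-element list wrapping it).
- Missing pDockQ is "absent", never zero; absent heatmap cells are NaN,
  never zero.
- Problem sizes in tests: cohorts of 6 proteins / 14 modelled jobs, score
  oracles over 300 random records, property sweeps over 10,000 random
  score inputs — small enough to run in seconds while exercising every
  branch.

## Known limitations

- The shallow-MSA threshold (100) and capacity-map constants are
  conventions, not measured quantities; both are configurable and should be
  calibrated to the user's MSA pipeline and accelerator.
- hiQ averaging assumes the upstream tool emits one pi-score per distinct
  interface; if it emits a single pooled value, n = 1 and the average is a
  no-op.
- Sensitivity/specificity benchmarking of the composite against its
  constituents requires curated positive/negative interaction sets and
  real predicted structures, and is out of scope.
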