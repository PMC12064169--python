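# ppiscorekit

Pre- and post-processing for high-throughput protein–protein interaction
(PPI) screening with structure predictors. Large-scale screens — every pair
in a secretion system, a proteome slice against itself — spend most of
their effort not on the fold prediction itself but on everything around it:
trimming signal peptides so the mature protein is modelled, checking that
alignments are deep enough to carry co-evolutionary signal, planning jobs
that fit on the accelerator, and turning five models × three confidence
metrics per complex into a defensible yes/no. `ppiscorekit` automates that
layer for researchers running AlphaFold-Multimer-class predictors through
batch tools, without re-implementing the predictor or its metrics.

## The scoring model

Each predicted complex arrives with three partially redundant confidence
metrics: the interface-quality **pi-score** (≈ [−2.63, 2.63]), **ipTM_pTM**
(0–1) and **pDockQ** (0–1). Any one alone misclassifies near-threshold
cases, so they are combined into composites on a 0–100 scale:

    iQ-score  = ((pi + 2.63) / 5.26) × 40 + ipTM_pTM × 30 + pDockQ × 30
    hiQ-score = (((Σ pi_i) / n + 2.63) / 5.26) × 60 + ipTM_pTM × 40

where the homo-oligomer score averages pi over the *n* distinct interfaces.
Scoring applies only to the best of the five models (highest ipTM) and only
when the minimum inter-chain predicted aligned error (PAE) is ≤ 10 Å — an
unsupported interface cannot be rescued by good global scores. Interactions
with a composite **strictly above 50** are retained; at the constituent
thresholds (pi = 0.05, others = 0.5) the composites evaluate to 50.38 and
50.57, which motivates the round cutoff.

## Worked example

```bash
python examples/01_composite_scores.py
```

```
iQ(0.05, 0.5, 0.5)   = 50.38
hiQ([0.05], 0.5)     = 50.57
iQ(1.0, 0.8, 0.7)    = 72.60
hiQ 3 interfaces     = 42.58
```

The first two lines are the composites exactly at the constituent score
thresholds — just above the retention cutoff of 50. The third is a
confidently predicted pair (retained); the last is a trimer whose three
interfaces average a weak pi-score (rejected).

The full pipeline on a generated toy cohort:

```bash
python examples/05_end_to_end.py
```

```
shallow MSAs: ['P03', 'P06']
  P01_and_P03              iQ=62.80  RETAINED
  P02_and_P03              iQ=50.38  RETAINED
  P05_and_P06              iQ=48.65  rejected (iQ-score 48.65 <= cutoff 50.0)
  P01_and_P04              iQ=  n/a  rejected (PAE gate failed (min inter-chain PAE 25.00 > 10.0))
  ...
```

Gate-failed jobs get no composite score but keep their constituent scores
in `predictions_scored.tsv`; proteins with shallow alignments are flagged
unreliable but never dropped. The other examples cover job planning with
out-of-memory exclusion (`02`), MSA-depth QC (`03`) and interface contact
maps (`04`). A thin CLI mirrors the library
(`ppiscorekit qc|plan|ingest|score|make-fixtures`).

## Layout

- `src/ppiscorekit/model_io.py` — FASTA / PDB / mmCIF / PAE-JSON / score-table readers
- `src/ppiscorekit/preprocess_qc.py` — signal-peptide trimming, MSA depth, shallow flagging
- `src/ppiscorekit/batch_planner.py` — all-against-all + homo-oligomer job lists, capacity map
- `src/ppiscorekit/scoring.py` — best-model selection, iQ/hiQ, PAE gate, retention
- `src/ppiscorekit/structure_analysis.py` — distance matrices, interface contacts, distograms
- `src/ppiscorekit/reporting.py` — heatmap, interaction network, report bundle
- `src/ppiscorekit/fixtures.py` — synthetic cohorts with ground-truth manifests
- `docs/methods.md` — model, defaults, numerical choices, limitations
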