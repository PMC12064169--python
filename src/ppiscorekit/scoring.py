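"""Composite interaction confidence: iQ-score, hiQ-score, PAE gate, retention.

The upstream predictor emits several partially redundant confidence metrics
per complex — pi-score (interface quality, roughly in [-2.63, 2.63]),
ipTM_pTM (0..1) and pDockQ (0..1).  Each alone misclassifies near-threshold
cases, so they are combined into a single 0..100 composite:

    iQ  = ((pi + 2.63) / 5.26) * 40 + iptm_ptm * 30 + pdockq * 30
    hiQ = (((sum pi_i) / n + 2.63) / 5.26) * 60 + iptm_ptm * 40

where hiQ averages the pi-score over the n distinct interfaces of a
homo-oligomer.  Scoring applies only to the best of the five predicted
models (highest ipTM), and only when the complex passes the predicted-
aligned-error gate: by default, minimum inter-chain PAE <= 10 Å, i.e. at
least one confidently placed inter-chain region.  Retention then requires a
composite score strictly greater than 50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .batch_planner import parse_job_id
from .model_io import ModelResult, ScoreRecord

__all__ = [
    "PI_SCORE_BOUND",
    "DEFAULT_PAE_THRESHOLD",
    "DEFAULT_CUTOFF",
    "ScoredInteraction",
    "HomoOligomerResult",
    "select_best_model",
    "compute_iq_score",
    "compute_hiq_score",
    "pae_gate",
    "score_and_filter",
    "write_scored_tables",
]

#: pi-score bound implied by the composite formula's normalisation.
PI_SCORE_BOUND = 2.63
#: Inter-chain PAE (Å) above which an interface is considered unsupported.
DEFAULT_PAE_THRESHOLD = 10.0
#: Retention cutoff: composite score must be strictly greater than this.
DEFAULT_CUTOFF = 50.0


@dataclass
class ScoredInteraction:
    """A hetero pair with its constituent scores and derived iQ-score.

    ``iq_score`` is ``None`` when the PAE gate failed (the composite is not
    computed for gate failures); ``reason`` records why a job was rejected.
    """

    protein_a: str
    protein_b: str
    pi_score: float
    iptm_ptm: float
    pdockq: float
    min_interchain_pae: float | None = None
    iq_score: float | None = None
    retained: bool = False
    unreliable_msa: bool = False
    reason: str = ""

    @property
    def job_id(self) -> str:
        return f"{self.protein_a}_and_{self.protein_b}"


@dataclass
class HomoOligomerResult:
    """A homo-oligomer with per-interface pi-scores and derived hiQ-score."""

    protein: str
    n_copies: int
    interface_pi_scores: tuple[float, ...]
    iptm_ptm: float
    min_interchain_pae: float | None = None
    hiq_score: float | None = None
    retained: bool = False
    unreliable_msa: bool = False
    reason: str = ""

    @property
    def job_id(self) -> str:
        return f"{self.protein}_homo_{self.n_copies}mer"


def select_best_model(models: Sequence[ModelResult]) -> ModelResult:
    """Pick the model with maximal ipTM; ties go to the lowest model index."""
    if not models:
        raise ValueError("no models to select from")
    return max(models, key=lambda m: (m.iptm, -m.model_index))


def _clamp_pi(pi: float, context: str) -> float:
    if not -PI_SCORE_BOUND <= pi <= PI_SCORE_BOUND:
        warnings.warn(
            f"{context}: pi-score {pi} outside [-{PI_SCORE_BOUND}, {PI_SCORE_BOUND}]; clamped"
        )
        return float(np.clip(pi, -PI_SCORE_BOUND, PI_SCORE_BOUND))
    return pi


def _check_unit(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


def compute_iq_score(pi_score: float, iptm_ptm: float, pdockq: float) -> float:
    """Hetero-pair composite: 40% normalised pi-score, 30% ipTM_pTM, 30% pDockQ.

    pi-score is clamped into [-2.63, 2.63] (with a warning) before the
    formula; the result lies in [0, 100].
    """
    _check_unit(iptm_ptm, "iptm_ptm")
    _check_unit(pdockq, "pdockq")
    pi = _clamp_pi(pi_score, "compute_iq_score")
    return ((pi + PI_SCORE_BOUND) / (2 * PI_SCORE_BOUND)) * 40 + iptm_ptm * 30 + pdockq * 30


def compute_hiq_score(interface_pi_scores: Sequence[float], iptm_ptm: float) -> float:
    """Homo-oligomer composite: 60% mean normalised interface pi-score, 40% ipTM_pTM.

    The mean over the n distinct interfaces is clamped into [-2.63, 2.63];
    the result lies in [0, 100].
    """
    if not len(interface_pi_scores):
        raise ValueError("interface_pi_scores must be non-empty")
    _check_unit(iptm_ptm, "iptm_ptm")
    mean_pi = _clamp_pi(float(np.mean(interface_pi_scores)), "compute_hiq_score")
    return ((mean_pi + PI_SCORE_BOUND) / (2 * PI_SCORE_BOUND)) * 60 + iptm_ptm * 40


def pae_gate(
    model: ModelResult,
    threshold: float = DEFAULT_PAE_THRESHOLD,
    stat: str = "min",
) -> tuple[bool, float]:
    """Gate a complex on its inter-chain predicted aligned error.

    Aggregates PAE over all inter-chain residue pairs (both orientations)
    with ``stat`` in {min, median, mean} and passes when the aggregate is
    <= ``threshold``.  The default (min) passes complexes with at least one
    confidently placed inter-chain region.
    """
    if model.pae is None:
        raise ValueError(f"{model.job_id}: model has no PAE matrix")
    spans = list(model.chain_ranges.values())
    if len(spans) < 2:
        raise ValueError(
            f"{model.job_id}: PAE gate needs >=2 chains, got {len(spans)}"
        )
    inter = []
    for i, (a0, a1) in enumerate(spans):
        for b0, b1 in spans[i + 1:]:
            inter.append(model.pae[a0:a1, b0:b1].ravel())
            inter.append(model.pae[b0:b1, a0:a1].ravel())
    values = np.concatenate(inter)
    agg = {"min": np.min, "median": np.median, "mean": np.mean}[stat](values)
    return bool(agg <= threshold), float(agg)


def score_and_filter(
    best_models: Mapping[str, ModelResult],
    score_records: Iterable[ScoreRecord],
    shallow_ids: Iterable[str] = (),
    iq_cutoff: float = DEFAULT_CUTOFF,
    hiq_cutoff: float = DEFAULT_CUTOFF,
    pae_threshold: float = DEFAULT_PAE_THRESHOLD,
    pae_stat: str = "min",
) -> tuple[list[ScoredInteraction], list[HomoOligomerResult]]:
    """Score every best model, gate on PAE, and apply the retention cutoffs.

    ``best_models`` maps job_id to that job's best model (with PAE matrix);
    ``score_records`` carries one record per best model.  Composite scores
    are computed only for models passing the PAE gate; gate failures are
    recorded with a reason and no composite score.  Retention requires
    composite > cutoff AND a passed gate.  Jobs touching a shallow-MSA
    protein carry ``unreliable_msa=True`` regardless of retention.  Both
    output lists contain every job (retained and rejected) with retained
    entries first, sorted by composite score descending.
    """
    shallow = set(shallow_ids)
    hetero: list[ScoredInteraction] = []
    homo: list[HomoOligomerResult] = []
    for rec in score_records:
        kind, proteins, copies = parse_job_id(rec.job_id)
        model = best_models.get(rec.job_id)
        if model is None:
            raise KeyError(f"no best model provided for job {rec.job_id!r}")
        passed, min_pae = pae_gate(model, threshold=pae_threshold, stat=pae_stat)
        unreliable = any(p in shallow for p in proteins)
        if kind == "hetero-pair":
            if rec.pdockq is None:
                raise ValueError(
                    f"{rec.job_id}: pdockq missing but required for the iQ-score "
                    "of a hetero pair"
                )
            item = ScoredInteraction(
                protein_a=proteins[0],
                protein_b=proteins[1],
                pi_score=rec.pi_score,
                iptm_ptm=rec.iptm_ptm,
                pdockq=rec.pdockq,
                min_interchain_pae=min_pae,
                unreliable_msa=unreliable,
            )
            if not passed:
                item.reason = f"PAE gate failed ({pae_stat} inter-chain PAE {min_pae:.2f} > {pae_threshold})"
            else:
                item.iq_score = compute_iq_score(rec.pi_score, rec.iptm_ptm, rec.pdockq)
                item.retained = item.iq_score > iq_cutoff
                if not item.retained:
                    item.reason = f"iQ-score {item.iq_score:.2f} <= cutoff {iq_cutoff}"
            hetero.append(item)
        else:
            item = HomoOligomerResult(
                protein=proteins[0],
                n_copies=copies,
                interface_pi_scores=rec.pi_scores,
                iptm_ptm=rec.iptm_ptm,
                min_interchain_pae=min_pae,
                unreliable_msa=unreliable,
            )
            if not passed:
                item.reason = f"PAE gate failed ({pae_stat} inter-chain PAE {min_pae:.2f} > {pae_threshold})"
            else:
                item.hiq_score = compute_hiq_score(rec.pi_scores, rec.iptm_ptm)
                item.retained = item.hiq_score > hiq_cutoff
                if not item.retained:
                    item.reason = f"hiQ-score {item.hiq_score:.2f} <= cutoff {hiq_cutoff}"
            homo.append(item)

    def sort_key_h(x: ScoredInteraction):
        return (not x.retained, -(x.iq_score if x.iq_score is not None else -np.inf))

    def sort_key_o(x: HomoOligomerResult):
        return (not x.retained, -(x.hiq_score if x.hiq_score is not None else -np.inf))

    hetero.sort(key=sort_key_h)
    homo.sort(key=sort_key_o)
    return hetero, homo


def write_scored_tables(
    hetero: Sequence[ScoredInteraction],
    homo: Sequence[HomoOligomerResult],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the full transparency table plus retained-only tables as TSV.

    ``predictions_scored.tsv`` keeps every job with all constituent scores,
    gate status and rejection reasons so near-misses can be audited;
    ``retained_interactions.tsv`` / ``retained_homooligomers.tsv`` hold the
    retained subsets sorted by composite score descending.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    het_rows = [
        {
            "job_id": s.job_id,
            "protein_a": s.protein_a,
            "protein_b": s.protein_b,
            "pi_score": s.pi_score,
            "iptm_ptm": s.iptm_ptm,
            "pdockq": s.pdockq,
            "min_interchain_pae": s.min_interchain_pae,
            "iq_score": s.iq_score,
            "retained": s.retained,
            "unreliable_msa": s.unreliable_msa,
            "reason": s.reason,
        }
        for s in hetero
    ]
    homo_rows = [
        {
            "job_id": h.job_id,
            "protein": h.protein,
            "n_copies": h.n_copies,
            "interface_pi_scores": ";".join(f"{v:g}" for v in h.interface_pi_scores),
            "iptm_ptm": h.iptm_ptm,
            "min_interchain_pae": h.min_interchain_pae,
            "hiq_score": h.hiq_score,
            "retained": h.retained,
            "unreliable_msa": h.unreliable_msa,
            "reason": h.reason,
        }
        for h in homo
    ]
    paths = {
        "all": out_dir / "predictions_scored.tsv",
        "retained_het": out_dir / "retained_interactions.tsv",
        "retained_homo": out_dir / "retained_homooligomers.tsv",
    }
    all_rows = [dict(r, job_kind="hetero-pair") for r in het_rows] + [
        dict(r, job_kind="homo-oligomer") for r in homo_rows
    ]
    het_cols = ["job_id", "protein_a", "protein_b", "pi_score", "iptm_ptm",
                "pdockq", "min_interchain_pae", "iq_score", "retained",
                "unreliable_msa", "reason"]
    homo_cols = ["job_id", "protein", "n_copies", "interface_pi_scores",
                 "iptm_ptm", "min_interchain_pae", "hiq_score", "retained",
                 "unreliable_msa", "reason"]
    pd.DataFrame(all_rows, columns=sorted({*het_cols, *homo_cols, "job_kind"},
                                          key=lambda c: (c != "job_id", c))).to_csv(
        paths["all"], sep="\t", index=False
    )
    pd.DataFrame([r for r in het_rows if r["retained"]], columns=het_cols).to_csv(
        paths["retained_het"], sep="\t", index=False
    )
    pd.DataFrame([r for r in homo_rows if r["retained"]], columns=homo_cols).to_csv(
        paths["retained_homo"], sep="\t", index=False
    )
    return paths
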