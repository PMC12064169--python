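"""Self-contained toy cohorts with known ground truth.

Generates every input the pipeline consumes — FASTA, a SignalP-style
annotation table, A3M alignments, per-job poly-alanine PDB structures with
planted cross-chain contacts, PAE matrices and per-model score JSONs — at
toy scale, together with a ground-truth manifest stating what the pipeline
must find: the shallow-MSA set, the OOM partition at a stated capacity, the
retained interaction set with composite scores, and the interface contact
lists.

Every expected number in the manifest is computed by an independent route:
composite scores by straight-line evaluation of the formulas (deliberately
duplicated here, not imported from the scoring module), alignment depth from
the gap masks the A3M is rendered from, and contacts by a brute-force
O(n²) scan of the coordinates actually written.  A design whose intended
retained flag contradicts its own scores is refused.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ProteinDesign",
    "PairDesign",
    "HomoDesign",
    "CohortDesign",
    "default_design",
    "generate_cohort",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PI_BOUND = 2.63
_CUTOFF = 50.0
_PAE_THRESHOLD = 10.0
_CONTACT_CUTOFF = 8.0
_CA_SPACING = 3.8
_CB_OFFSET = 1.53


@dataclass
class ProteinDesign:
    """One toy protein: mature length, MSA depth class, optional signal peptide."""

    id: str
    length: int  # mature length, residues
    msa_rows: int  # alignment depth class (rows incl. query)
    signal_peptide_len: int | None = None


@dataclass
class PairDesign:
    """Intended outcome of one hetero-pair job."""

    a: str
    b: str
    pi_score: float
    iptm_ptm: float
    pdockq: float
    min_interchain_pae: float
    retained: bool
    n_contacts: int = 2
    contact_distances: tuple[float, ...] = ()


@dataclass
class HomoDesign:
    """Intended outcome of one homo-oligomer job."""

    protein: str
    n_copies: int
    interface_pi_scores: tuple[float, ...]
    iptm_ptm: float
    min_interchain_pae: float
    retained: bool


@dataclass
class CohortDesign:
    proteins: list[ProteinDesign]
    pairs: list[PairDesign]
    homos: list[HomoDesign] = field(default_factory=list)
    #: Stated residue capacity used for the manifest's expected OOM partition.
    oom_capacity_residues: int = 50
    shallow_threshold: int = 100


# ---------------------------------------------------------------------------
# independent straight-line score evaluation (oracle; do not import scoring)

def _iq_straight_line(pi: float, iptm_ptm: float, pdockq: float) -> float:
    pi = max(-_PI_BOUND, min(_PI_BOUND, pi))
    return ((pi + 2.63) / 5.26) * 40 + iptm_ptm * 30 + pdockq * 30


def _hiq_straight_line(pis: Sequence[float], iptm_ptm: float) -> float:
    mean = sum(pis) / len(pis)
    mean = max(-_PI_BOUND, min(_PI_BOUND, mean))
    return ((mean + 2.63) / 5.26) * 60 + iptm_ptm * 40


def _validate_design(design: CohortDesign) -> None:
    ids = [p.id for p in design.proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in design")
    known = set(ids)
    for pair in design.pairs:
        if pair.a not in known or pair.b not in known or pair.a == pair.b:
            raise ValueError(f"pair ({pair.a}, {pair.b}) is not a valid hetero pair")
        iq = _iq_straight_line(pair.pi_score, pair.iptm_ptm, pair.pdockq)
        would_retain = iq > _CUTOFF and pair.min_interchain_pae <= _PAE_THRESHOLD
        if would_retain != pair.retained:
            raise ValueError(
                f"contradictory design for {pair.a}-{pair.b}: retained="
                f"{pair.retained} but iQ={iq:.2f}, min PAE={pair.min_interchain_pae}"
            )
    for hd in design.homos:
        if hd.protein not in known:
            raise ValueError(f"homo-oligomer design for unknown protein {hd.protein}")
        hiq = _hiq_straight_line(hd.interface_pi_scores, hd.iptm_ptm)
        would_retain = hiq > _CUTOFF and hd.min_interchain_pae <= _PAE_THRESHOLD
        if would_retain != hd.retained:
            raise ValueError(
                f"contradictory design for {hd.protein} homo-{hd.n_copies}mer: "
                f"retained={hd.retained} but hiQ={hiq:.2f}, "
                f"min PAE={hd.min_interchain_pae}"
            )


def default_design(n_proteins: int = 6, seed: int = 0) -> CohortDesign:
    """A mixed cohort: shallow and deep MSAs, signal peptides, scores on both
    sides of the retention cutoff, PAE-gate failures, and pairs exceeding a
    stated memory capacity."""
    rng = np.random.default_rng(seed)
    proteins = []
    for k in range(n_proteins):
        proteins.append(
            ProteinDesign(
                id=f"P{k + 1:02d}",
                length=int(rng.integers(16, 28)),
                msa_rows=6 if k % 3 == 2 else 150,  # every third protein shallow
                signal_peptide_len=5 if k % 2 == 0 else None,
            )
        )
    ids = [p.id for p in proteins]
    # retained, rejected-by-score, rejected-by-gate, plus score values
    # straddling the cutoff in both directions
    pair_specs = [
        # a_idx, b_idx, pi, iptm_ptm, pdockq, min_pae, retained
        (0, 1, 1.00, 0.80, 0.70, 4.0, True),
        (0, 2, 0.50, 0.70, 0.60, 7.5, True),
        (1, 2, 0.05, 0.50, 0.50, 6.0, True),   # iQ 50.38, just above 50
        (1, 3, -0.10, 0.48, 0.45, 6.0, False),  # just below cutoff
        (2, 3, 1.20, 0.85, 0.80, 15.0, False),  # good scores, gate fails
        (0, 3, -1.50, 0.20, 0.10, 25.0, False),
    ]
    if n_proteins >= 5:
        pair_specs += [
            (3, 4, 0.80, 0.75, 0.65, 5.0, True),
            (0, 4, -0.50, 0.30, 0.25, 9.0, False),
        ]
    if n_proteins >= 6:
        pair_specs += [
            (4, 5, 0.02, 0.55, 0.40, 8.0, False),  # iQ 48.65
            (1, 5, 0.90, 0.70, 0.75, 3.0, True),
        ]
    pairs = [
        PairDesign(
            a=min(ids[i], ids[j]), b=max(ids[i], ids[j]),
            pi_score=pi, iptm_ptm=ipt, pdockq=pdq,
            min_interchain_pae=pae, retained=ret,
            n_contacts=2 + (i + j) % 2,
        )
        for i, j, pi, ipt, pdq, pae, ret in pair_specs
    ]
    homos = [
        HomoDesign(ids[0], 2, (0.9, 0.7), 0.8, 5.0, True),
        HomoDesign(ids[1], 2, (0.05,), 0.5, 6.0, True),   # hiQ 50.57
        HomoDesign(ids[2], 3, (-0.4, -0.2, -0.3), 0.4, 7.0, False),
    ]
    if n_proteins >= 4:
        homos.append(HomoDesign(ids[3], 2, (1.1, 0.8), 0.9, 18.0, False))
    return CohortDesign(proteins=proteins, pairs=pairs, homos=homos,
                        oom_capacity_residues=44)


# ---------------------------------------------------------------------------
# geometry

def _build_chain(n_res: int, x0: float, y_ca: float, cb_up: bool) -> list[dict]:
    """A straight poly-alanine chain along x; CB points toward (+y) or away."""
    sgn = 1.0 if cb_up else -1.0
    residues = []
    for i in range(n_res):
        ca = np.array([x0 + _CA_SPACING * i, y_ca, 0.0])
        residues.append(
            {
                "N": ca + np.array([-1.20, sgn * 0.60, 0.0]),
                "CA": ca,
                "CB": ca + np.array([0.0, sgn * _CB_OFFSET, 0.0]),
                "O": ca + np.array([0.60, -sgn * 1.00, 0.0]),
            }
        )
    return residues


def _plant_contacts(
    chain_a: list[dict], chain_b: list[dict], distances: Sequence[float]
) -> list[tuple[int, int, float]]:
    """Move chain-B residues so planted CB-CB distances are exact.

    Returns (resnum_a, resnum_b, distance) with 1-based residue numbers.
    Contact sites are spaced 3 residues apart so planted residues do not
    crowd each other.
    """
    planted = []
    for k, d in enumerate(distances):
        i = 2 + 3 * k
        j = 2 + 3 * k
        if i >= len(chain_a) or j >= len(chain_b):
            raise ValueError("chains too short for the requested contact count")
        target_cb = chain_a[i]["CB"] + np.array([0.0, d, 0.0])
        shift = target_cb - chain_b[j]["CB"]
        chain_b[j] = {name: xyz + shift for name, xyz in chain_b[j].items()}
        planted.append((i + 1, j + 1, float(d)))
    return planted


def _brute_force_contacts(
    chains: dict[str, list[dict]], cutoff: float
) -> list[dict]:
    """Independent O(n²) CB-CB (CA fallback) contact scan of built geometry."""
    flat = []
    for cid, residues in chains.items():
        for idx, res in enumerate(residues):
            flat.append((cid, idx + 1, res.get("CB", res["CA"])))
    out = []
    for x in range(len(flat)):
        ca, na, pa = flat[x]
        for y in range(x + 1, len(flat)):
            cb, nb, pb = flat[y]
            if ca == cb:
                continue
            d = float(np.linalg.norm(pa - pb))
            if d <= cutoff:
                first, second = ((ca, na), (cb, nb))
                if (cb, nb) < (ca, na):
                    first, second = second, first
                out.append(
                    {"chain_a": first[0], "resnum_a": first[1],
                     "chain_b": second[0], "resnum_b": second[1],
                     "distance": round(d, 6)}
                )
    out.sort(key=lambda c: (c["distance"], c["chain_a"], c["resnum_a"]))
    return out


def _write_pdb(chains: dict[str, list[dict]], path: Path) -> None:
    lines = []
    serial = 1
    for cid, residues in chains.items():
        for resnum, res in enumerate(residues, start=1):
            for name in ("N", "CA", "CB", "O"):
                x, y, z = res[name]
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} ALA {cid}{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {name[0]:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      ALA {cid}{len(residues):4d}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-file-type emitters

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def _make_msa_masks(rng: np.random.Generator, n_rows: int, length: int) -> np.ndarray:
    """Row x column gap masks (True = residue present). Query row all True."""
    masks = np.ones((n_rows, length), dtype=bool)
    for r in range(1, n_rows):
        gap_frac = rng.uniform(0.0, 0.25)
        masks[r] = rng.random(length) >= gap_frac
    return masks


def _write_a3m(
    rng: np.random.Generator, path: Path, query_id: str, query_seq: str,
    masks: np.ndarray,
) -> None:
    n_rows, length = masks.shape
    lines = [f">{query_id}", query_seq]
    for r in range(1, n_rows):
        row = "".join(
            rng.choice(list(_AA)) if masks[r, c] else "-" for c in range(length)
        )
        if r % 5 == 3:  # exercise A3M insertion semantics (lowercase columns)
            row = row[:4] + "".join(rng.choice(list(_AA.lower()), size=2)) + row[4:]
        lines.append(f">hit{r}")
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def _make_pae(
    rng: np.random.Generator, chain_lengths: Sequence[int], min_inter: float
) -> np.ndarray:
    dim = sum(chain_lengths)
    pae = rng.uniform(2.0, 6.0, size=(dim, dim))
    np.fill_diagonal(pae, 0.0)
    bounds = np.concatenate([[0], np.cumsum(chain_lengths)])
    spans = list(zip(bounds[:-1], bounds[1:]))
    base = min_inter + 5.0
    for i, (a0, a1) in enumerate(spans):
        for b0, b1 in spans[i + 1:]:
            pae[a0:a1, b0:b1] = rng.uniform(base, base + 8.0, size=(a1 - a0, b1 - b0))
            pae[b0:b1, a0:a1] = rng.uniform(base, base + 8.0, size=(b1 - b0, a1 - a0))
    # exactly one inter-chain cell carries the designed minimum
    (a0, a1), (b0, b1) = spans[0], spans[1]
    pae[a0, b0] = min_inter
    return pae


def _write_job(
    rng: np.random.Generator,
    job_dir: Path,
    chain_lengths: list[int],
    iptm: float,
    iptm_ptm: float,
    pi_scores: float | list[float],
    pdockq: float | None,
    min_inter_pae: float,
    contact_distances: Sequence[float],
) -> dict:
    """Write one job directory (5 score JSONs, best-model PAE + PDB)."""
    job_dir.mkdir(parents=True, exist_ok=True)
    best = int(rng.integers(1, 6))
    for k in range(1, 6):
        if k == best:
            scores = {"iptm": iptm, "iptm_ptm": iptm_ptm, "pi_score": pi_scores}
        else:
            scores = {
                "iptm": round(float(rng.uniform(0.0, max(iptm - 0.05, 0.01))), 4),
                "iptm_ptm": round(float(rng.uniform(0.0, 1.0)), 4),
                "pi_score": round(float(rng.uniform(-2.0, 2.0)), 4),
            }
        if pdockq is not None:
            scores["pdockq"] = pdockq if k == best else round(float(rng.uniform(0, 1)), 4)
        (job_dir / f"scores_model_{k}.json").write_text(json.dumps(scores) + "\n")

    pae = _make_pae(rng, chain_lengths, min_inter_pae)
    (job_dir / f"pae_model_{best}.json").write_text(
        json.dumps({"predicted_aligned_error": pae.tolist()})
    )

    chain_ids = [chr(ord("A") + i) for i in range(len(chain_lengths))]
    chains: dict[str, list[dict]] = {}
    planted_all: list[dict] = []
    prev_id = None
    for idx, (cid, n_res) in enumerate(zip(chain_ids, chain_lengths)):
        up = idx == 0
        chains[cid] = _build_chain(n_res, x0=idx * 1.9, y_ca=idx * 45.0, cb_up=up)
        if prev_id is not None:
            planted = _plant_contacts(chains[prev_id], chains[cid], contact_distances)
            planted_all.extend(
                {"chain_a": prev_id, "resnum_a": i, "chain_b": cid,
                 "resnum_b": j, "distance": d}
                for i, j, d in planted
            )
        prev_id = cid
    # generator self-check: recompute every planted distance independently
    for p in planted_all:
        pa = chains[p["chain_a"]][p["resnum_a"] - 1]["CB"]
        pb = chains[p["chain_b"]][p["resnum_b"] - 1]["CB"]
        if abs(float(np.linalg.norm(pa - pb)) - p["distance"]) > 1e-6:
            raise AssertionError("planted contact distance verification failed")
    _write_pdb(chains, job_dir / f"model_{best}.pdb")
    return {
        "best_model_index": best,
        "chain_lengths": chain_lengths,
        "planted_contacts": planted_all,
        "expected_contacts": _brute_force_contacts(chains, _CONTACT_CUTOFF),
    }


# ---------------------------------------------------------------------------

def generate_cohort(
    out_dir: str | Path,
    design: CohortDesign | None = None,
    n_proteins: int = 6,
    seed: int = 0,
) -> dict:
    """Write a full toy input bundle plus its ground-truth manifest.

    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    Deterministic: the same seed and design produce byte-identical bundles.
    """
    out_dir = Path(out_dir)
    design = design or default_design(n_proteins=n_proteins, seed=seed)
    _validate_design(design)
    rng = np.random.default_rng(seed)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "msas").mkdir(exist_ok=True)
    (out_dir / "models").mkdir(exist_ok=True)

    # --- sequences + signal peptides ---------------------------------------
    fasta_lines, signalp_rows = [], ["ID\tprediction\tCS position"]
    protein_info = {}
    for pd_ in design.proteins:
        mature = _random_seq(rng, pd_.length)
        if pd_.signal_peptide_len:
            sp = _random_seq(rng, pd_.signal_peptide_len)
            full = sp + mature
            cs = pd_.signal_peptide_len
            signalp_rows.append(f"{pd_.id}\tSP(Sec/SPI)\t{cs}-{cs + 1}")
        else:
            full = mature
            signalp_rows.append(f"{pd_.id}\tOTHER\t")
        fasta_lines.append(f">{pd_.id}")
        fasta_lines.append(full)
        protein_info[pd_.id] = {
            "length": len(full),
            "mature_length": pd_.length,
            "signal_peptide_end": pd_.signal_peptide_len,
            "mature_sequence": mature,
        }
    (out_dir / "proteins.fasta").write_text("\n".join(fasta_lines) + "\n")
    (out_dir / "signalp.tsv").write_text("\n".join(signalp_rows) + "\n")

    # --- MSAs with mask-derived ground-truth depth -------------------------
    shallow_ids = []
    for pd_ in design.proteins:
        masks = _make_msa_masks(rng, pd_.msa_rows, pd_.length)
        _write_a3m(
            rng, out_dir / "msas" / f"{pd_.id}.a3m", pd_.id,
            protein_info[pd_.id]["mature_sequence"], masks,
        )
        depth = masks.sum(axis=0)
        protein_info[pd_.id]["expected_depth_profile"] = depth.tolist()
        median = float(np.median(depth))
        protein_info[pd_.id]["expected_median_depth"] = median
        if median < design.shallow_threshold:
            shallow_ids.append(pd_.id)

    # --- OOM partition at the stated capacity ------------------------------
    ids = sorted(protein_info)
    mature_len = {pid: protein_info[pid]["mature_length"] for pid in ids}
    expected_oom = []
    all_pair_jobs = []
    from itertools import combinations

    oom_max_copies = 2  # screening-phase default the planner uses
    for a, b in combinations(ids, 2):
        total = mature_len[a] + mature_len[b]
        job_id = f"{a}_and_{b}"
        all_pair_jobs.append(job_id)
        if total > design.oom_capacity_residues:
            expected_oom.append(job_id)
    for pid in ids:
        for copies in range(2, oom_max_copies + 1):
            if mature_len[pid] * copies > design.oom_capacity_residues:
                expected_oom.append(f"{pid}_homo_{copies}mer")

    # --- modelled jobs ------------------------------------------------------
    jobs_manifest = {}
    for pair in design.pairs:
        job_id = f"{pair.a}_and_{pair.b}"
        distances = pair.contact_distances or tuple(
            round(float(rng.uniform(4.0, 6.5)), 3) for _ in range(pair.n_contacts)
        )
        info = _write_job(
            rng, out_dir / "models" / job_id,
            [mature_len[pair.a], mature_len[pair.b]],
            iptm=round(pair.iptm_ptm, 4), iptm_ptm=pair.iptm_ptm,
            pi_scores=pair.pi_score, pdockq=pair.pdockq,
            min_inter_pae=pair.min_interchain_pae,
            contact_distances=distances,
        )
        info.update(
            job_kind="hetero-pair",
            proteins=[pair.a, pair.b],
            pi_score=pair.pi_score, iptm_ptm=pair.iptm_ptm, pdockq=pair.pdockq,
            min_interchain_pae=pair.min_interchain_pae,
            expected_iq_score=_iq_straight_line(pair.pi_score, pair.iptm_ptm, pair.pdockq)
            if pair.min_interchain_pae <= _PAE_THRESHOLD else None,
            expected_retained=pair.retained,
        )
        jobs_manifest[job_id] = info
    for hd in design.homos:
        job_id = f"{hd.protein}_homo_{hd.n_copies}mer"
        info = _write_job(
            rng, out_dir / "models" / job_id,
            [mature_len[hd.protein]] * hd.n_copies,
            iptm=round(hd.iptm_ptm, 4), iptm_ptm=hd.iptm_ptm,
            pi_scores=list(hd.interface_pi_scores), pdockq=None,
            min_inter_pae=hd.min_interchain_pae,
            contact_distances=(5.0,),
        )
        info.update(
            job_kind="homo-oligomer",
            proteins=[hd.protein], n_copies=hd.n_copies,
            interface_pi_scores=list(hd.interface_pi_scores),
            iptm_ptm=hd.iptm_ptm,
            min_interchain_pae=hd.min_interchain_pae,
            expected_hiq_score=_hiq_straight_line(hd.interface_pi_scores, hd.iptm_ptm)
            if hd.min_interchain_pae <= _PAE_THRESHOLD else None,
            expected_retained=hd.retained,
        )
        jobs_manifest[job_id] = info

    manifest = {
        "seed": seed,
        "shallow_threshold": design.shallow_threshold,
        "contact_cutoff": _CONTACT_CUTOFF,
        "proteins": protein_info,
        "expected_shallow_ids": sorted(shallow_ids),
        "oom_capacity_residues": design.oom_capacity_residues,
        "oom_max_copies": oom_max_copies,
        "expected_oom_jobs": sorted(expected_oom),
        "n_hetero_pair_jobs_planned": len(all_pair_jobs),
        "jobs": jobs_manifest,
        "expected_retained_hetero": sorted(
            j for j, info in jobs_manifest.items()
            if info["job_kind"] == "hetero-pair" and info["expected_retained"]
        ),
        "expected_retained_homo": sorted(
            j for j, info in jobs_manifest.items()
            if info["job_kind"] == "homo-oligomer" and info["expected_retained"]
        ),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
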