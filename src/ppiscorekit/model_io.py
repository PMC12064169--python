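"""Readers and domain types for the external formats the pipeline touches.

Everything downstream works on the types defined here: :class:`ProteinEntry`
(a sequence with optional signal-peptide trim), :class:`MsaRecord` (per-column
alignment depth), :class:`ModelResult` (one predicted complex with its PAE
matrix and chain layout) and :class:`ScoreRecord` (the per-model confidence
scores emitted by the upstream predictor stack).

Conventions: residue intervals are 0-based half-open internally; every
user-facing table is 1-based inclusive.  Chains are keyed by author chain ID,
falling back to the label asym ID when the author ID is blank.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinEntry",
    "MsaRecord",
    "ModelResult",
    "ScoreRecord",
    "Residue",
    "ModelIOError",
    "read_fasta",
    "read_pae_matrix",
    "read_structure",
    "read_score_table",
    "discover_job_scores",
]

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class ModelIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class ProteinEntry:
    """A protein sequence plus its signal-peptide state.

    ``mature_sequence`` is what every downstream module consumes: it equals
    ``sequence`` until a signal peptide is trimmed, after which it is the
    sequence with positions 1..``signal_peptide_end`` removed.
    """

    id: str
    sequence: str
    signal_peptide_end: int | None = None
    mature_sequence: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ModelIOError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ALPHABET
        if bad:
            raise ModelIOError(
                f"protein {self.id!r}: illegal residue character(s) {sorted(bad)}"
            )
        if not self.mature_sequence:
            self.mature_sequence = self.sequence
        if self.signal_peptide_end is not None:
            expected = self.sequence[self.signal_peptide_end:]
            if self.mature_sequence != expected:
                raise ModelIOError(
                    f"protein {self.id!r}: mature_sequence inconsistent with "
                    f"signal_peptide_end={self.signal_peptide_end}"
                )


@dataclass
class MsaRecord:
    """Per-position alignment depth over the query's ungapped coordinates."""

    protein_id: str
    n_rows: int
    depth_profile: np.ndarray

    def __post_init__(self) -> None:
        self.depth_profile = np.asarray(self.depth_profile, dtype=int)
        if self.depth_profile.size and (
            self.depth_profile.min() < 1 or self.depth_profile.max() > self.n_rows
        ):
            raise ModelIOError(
                f"MSA {self.protein_id!r}: depth profile outside [1, n_rows]"
            )

    @property
    def median_depth(self) -> float:
        return float(np.median(self.depth_profile))


@dataclass
class ModelResult:
    """One predicted model of a complex.

    ``chain_ranges`` maps chain id -> (start, stop) half-open residue interval
    within the PAE matrix; intervals are disjoint and cover the full dimension.
    """

    job_id: str
    model_index: int
    iptm: float
    iptm_ptm: float
    structure_path: Path | None = None
    pae: np.ndarray | None = None
    chain_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            _validate_pae(self.pae, self.chain_ranges)

    @property
    def n_residues(self) -> int:
        return sum(stop - start for start, stop in self.chain_ranges.values())


@dataclass
class ScoreRecord:
    """Per-model scores from the upstream predictor stack.

    ``pi_score`` holds one value per distinct chain-pair interface (a single
    float for hetero pairs, possibly several for homo-oligomers).  ``pdockq``
    is ``None`` when absent — homo-oligomer jobs do not receive one.
    """

    job_id: str
    model_index: int
    iptm: float
    iptm_ptm: float
    pi_scores: tuple[float, ...]
    pdockq: float | None = None

    @property
    def pi_score(self) -> float:
        """Single interface pi-score (hetero-pair convenience accessor)."""
        if len(self.pi_scores) != 1:
            raise ValueError(
                f"{self.job_id}: {len(self.pi_scores)} interface pi-scores; "
                "use .pi_scores"
            )
        return self.pi_scores[0]


@dataclass
class Residue:
    """One residue of a parsed structure: author numbering plus heavy atoms."""

    number: int
    name: str
    atoms: dict[str, np.ndarray]


def _validate_pae(pae: np.ndarray, chain_ranges: Mapping[str, tuple[int, int]]) -> None:
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ModelIOError(f"PAE matrix is not square: shape {pae.shape}")
    if (pae < 0).any():
        raise ModelIOError("PAE matrix contains negative values")
    if chain_ranges:
        total = sum(stop - start for start, stop in chain_ranges.values())
        if total != pae.shape[0]:
            raise ModelIOError(
                f"PAE dimension {pae.shape[0]} does not match total chain "
                f"length {total}"
            )
        spans = sorted(chain_ranges.values())
        cursor = 0
        for start, stop in spans:
            if start != cursor or stop <= start:
                raise ModelIOError("chain_ranges are not disjoint covering intervals")
            cursor = stop


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a FASTA file into :class:`ProteinEntry` records.

    Ids are the header up to the first whitespace; sequences are upper-cased.
    Duplicate ids and illegal residue characters are rejected with errors that
    name the offending record.
    """
    path = Path(path)
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ModelIOError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        entries.append(ProteinEntry(id=rec.id, sequence=str(rec.seq).upper()))
    if not entries:
        raise ModelIOError(f"no FASTA records found in {path}")
    return entries


def read_pae_matrix(
    path: str | Path, chain_ranges: Mapping[str, tuple[int, int]] | None = None
) -> np.ndarray:
    """Read a predicted-aligned-error JSON file into a square matrix (Å).

    Two dialects are accepted: an object with key ``predicted_aligned_error``
    holding a list of rows, and a one-element list wrapping such an object.
    The matrix dimension is validated against ``chain_ranges`` when given.
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if len(payload) != 1 or not isinstance(payload[0], dict):
            raise ModelIOError(
                f"{path}: unsupported PAE JSON dialect (expected a one-element "
                "list wrapping an object)"
            )
        payload = payload[0]
    if not isinstance(payload, dict) or "predicted_aligned_error" not in payload:
        raise ModelIOError(
            f"{path}: unsupported PAE JSON dialect (no 'predicted_aligned_error' key)"
        )
    pae = np.asarray(payload["predicted_aligned_error"], dtype=float)
    _validate_pae(pae, chain_ranges or {})
    return pae


def read_structure(path: str | Path) -> dict[str, list[Residue]]:
    """Parse a PDB/mmCIF file into ordered per-chain residue lists.

    Only polymer ATOM records are kept (waters and ligands are dropped).
    Residue order follows file order; coordinates are in Å.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise ModelIOError(f"cannot parse structure {path}: {exc}") from exc
    st.setup_entities()
    chains: dict[str, list[Residue]] = {}
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.het_flag == "H" or res.is_water():
                continue
            atoms = {
                atom.name: np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                for atom in res
            }
            if atoms:
                residues.append(Residue(number=res.seqid.num, name=res.name, atoms=atoms))
        if residues:
            key = chain.name or res.subchain
            chains[key] = residues
    if not chains:
        raise ModelIOError(f"{path}: no chain with ATOM records (zero residues)")
    return chains


_REQUIRED_COLUMNS = ("job_id", "model_index", "iptm", "iptm_ptm", "pi_score")


def read_score_table(path: str | Path) -> list[ScoreRecord]:
    """Read an assembled CSV/TSV score table into :class:`ScoreRecord` rows.

    Rows sharing (job_id, model_index) are merged: their pi_score values
    become per-interface entries of one record.  A missing ``pdockq`` column,
    or an empty cell in it, is recorded as absent — never as zero.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    # disable pandas' automatic NA tokens so bad cells are reported, not eaten
    df = pd.read_csv(path, sep=sep, dtype={"job_id": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ModelIOError(f"{path}: missing required column(s) {missing}")
    has_pdockq = "pdockq" in df.columns
    for col in ("model_index", "iptm", "iptm_ptm", "pi_score") + (
        ("pdockq",) if has_pdockq else ()
    ):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ModelIOError(
                f"{path}: non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r}, row {int(bad[0]) + 1}"
            )
        df[col] = coerced
    records: list[ScoreRecord] = []
    for (job_id, model_index), grp in df.groupby(["job_id", "model_index"], sort=False):
        pdq = None
        if has_pdockq:
            vals = grp["pdockq"].dropna().unique()
            if len(vals) > 1:
                raise ModelIOError(
                    f"{path}: conflicting pdockq values for {job_id} model {model_index}"
                )
            if len(vals) == 1:
                pdq = float(vals[0])
        records.append(
            ScoreRecord(
                job_id=str(job_id),
                model_index=int(model_index),
                iptm=float(grp["iptm"].iloc[0]),
                iptm_ptm=float(grp["iptm_ptm"].iloc[0]),
                pi_scores=tuple(float(v) for v in grp["pi_score"]),
                pdockq=pdq,
            )
        )
    return records


def discover_job_scores(
    models_dir: str | Path, pattern: str = "*/scores_model_*.json"
) -> list[ScoreRecord]:
    """Assemble per-model score JSONs scattered across job directories.

    The default layout is ``<models_dir>/<job_id>/scores_model_<k>.json`` with
    keys ``iptm``, ``iptm_ptm``, ``pi_score`` (float or list of floats per
    interface) and optionally ``pdockq``; the glob is configurable because
    upstream tools differ in their on-disk layout.
    """
    models_dir = Path(models_dir)
    records: list[ScoreRecord] = []
    for score_file in sorted(models_dir.glob(pattern)):
        job_id = score_file.parent.name
        stem = score_file.stem
        try:
            model_index = int(stem.rsplit("_", 1)[-1])
        except ValueError as exc:
            raise ModelIOError(
                f"{score_file}: cannot extract model index from filename"
            ) from exc
        with open(score_file) as fh:
            payload = json.load(fh)
        pi = payload["pi_score"]
        pi_scores = tuple(float(v) for v in (pi if isinstance(pi, list) else [pi]))
        pdq = payload.get("pdockq")
        records.append(
            ScoreRecord(
                job_id=job_id,
                model_index=model_index,
                iptm=float(payload["iptm"]),
                iptm_ptm=float(payload["iptm_ptm"]),
                pi_scores=pi_scores,
                pdockq=None if pdq is None else float(pdq),
            )
        )
    return records


def write_score_table(records: Iterable[ScoreRecord], path: str | Path) -> None:
    """Write records to TSV, one row per interface (inverse of read_score_table)."""
    rows = []
    for rec in records:
        for pi in rec.pi_scores:
            rows.append(
                {
                    "job_id": rec.job_id,
                    "model_index": rec.model_index,
                    "iptm": rec.iptm,
                    "iptm_ptm": rec.iptm_ptm,
                    "pi_score": pi,
                    "pdockq": rec.pdockq if rec.pdockq is not None else math.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
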