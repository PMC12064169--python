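"""Sequence cleaning and MSA-depth quality control.

Signal peptides are trimmed from an annotation table (a SignalP-style
summary), so the mature protein — what actually folds after translocation —
is what gets modelled.  Alignment depth is profiled per query position; a
shallow alignment weakens the co-evolutionary signal the structure predictor
relies on, so proteins whose median depth falls below a threshold are flagged
(never dropped) and listed in ``shallow_MSA.txt``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_io import ModelIOError, MsaRecord, ProteinEntry

__all__ = [
    "DEFAULT_DEPTH_THRESHOLD",
    "read_signalp_table",
    "trim_signal_peptides",
    "compute_msa_depth",
    "flag_shallow",
    "plot_msa_depth",
]

#: Median alignment depth below which a protein's MSA is called shallow.
#: A common heuristic for adequate co-evolutionary signal; configurable
#: everywhere it is used.
DEFAULT_DEPTH_THRESHOLD = 100


def read_signalp_table(path: str | Path) -> dict[str, int]:
    """Parse a SignalP-style summary TSV into {protein_id: cleavage_position}.

    Expected columns: ``ID`` and ``CS position`` (the 1-based index of the
    last signal-peptide residue, accepted either as a plain integer or as the
    SignalP "22-23" cut-site form, whose first number is used).  Rows whose
    cut-site field is empty are treated as "no signal peptide".
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = cols.get("id")
    cs_col = cols.get("cs position") or cols.get("cs_position")
    if id_col is None or cs_col is None:
        raise ModelIOError(f"{path}: need columns 'ID' and 'CS position'")
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        raw = row[cs_col]
        if pd.isna(raw) or not str(raw).strip():
            continue
        token = str(raw).strip().split("-")[0]
        out[str(row[id_col]).strip()] = int(token)
    return out


def trim_signal_peptides(
    entries: Sequence[ProteinEntry], annotations: dict[str, int]
) -> list[ProteinEntry]:
    """Apply signal-peptide trims; unannotated entries pass through unchanged.

    ``annotations`` maps protein id to the 1-based position of the last
    signal-peptide residue; positions 1..cleavage are removed.  Idempotent:
    re-trimming an already-trimmed entry with the same annotation is a no-op.
    An annotation for an unknown protein id raises a warning and is skipped;
    a cleavage position that would empty the sequence is an error.
    """
    known = {e.id for e in entries}
    for pid in annotations:
        if pid not in known:
            warnings.warn(f"signal-peptide annotation for unknown protein {pid!r}; skipped")
    out: list[ProteinEntry] = []
    for entry in entries:
        cleave = annotations.get(entry.id)
        if cleave is None:
            out.append(entry)
            continue
        if entry.signal_peptide_end == cleave:
            out.append(entry)  # already trimmed with this annotation
            continue
        if cleave < 1 or cleave >= len(entry.sequence):
            raise ModelIOError(
                f"protein {entry.id!r}: cleavage position {cleave} leaves no "
                f"mature sequence (length {len(entry.sequence)})"
            )
        out.append(
            ProteinEntry(
                id=entry.id,
                sequence=entry.sequence,
                signal_peptide_end=cleave,
                mature_sequence=entry.sequence[cleave:],
            )
        )
    return out


def _parse_alignment(path: Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header, chunks = line[1:].split()[0] if line[1:] else "", []
            elif line and not line.startswith("#"):
                chunks.append(line.strip())
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def compute_msa_depth(msa_file: str | Path, query_id: str | None = None) -> MsaRecord:
    """Profile alignment depth over the query's ungapped positions.

    Accepts A3M or aligned FASTA with the query as the first record.  In A3M,
    lowercase characters are insertions relative to the query and do not
    consume match columns; depth at query position i counts rows with a
    non-gap character aligned to that match column.
    """
    path = Path(msa_file)
    records = _parse_alignment(path)
    if not records:
        raise ModelIOError(f"{path}: empty alignment")
    query_name, query_seq = records[0]
    if query_id is not None and query_name != query_id:
        raise ModelIOError(
            f"{path}: first record is {query_name!r}, expected query {query_id!r}"
        )
    # Match columns are the query's own (uppercase/gap) positions.
    match_cols = [c for c in query_seq if not c.islower()]
    n_match = len(match_cols)
    query_positions = [i for i, c in enumerate(match_cols) if c not in "-."]
    if not query_positions:
        raise ModelIOError(f"{path}: query {query_name!r} has no residues")
    depth = np.zeros(n_match, dtype=int)
    for _, seq in records:
        col = 0
        for ch in seq:
            if ch.islower():
                continue  # insertion relative to the query
            if col >= n_match:
                raise ModelIOError(
                    f"{path}: row longer than query match columns ({n_match})"
                )
            if ch not in "-.":
                depth[col] += 1
            col += 1
        if col != n_match:
            raise ModelIOError(
                f"{path}: row covers {col} match columns, query has {n_match}"
            )
    profile = depth[query_positions]
    return MsaRecord(
        protein_id=query_id or query_name, n_rows=len(records), depth_profile=profile
    )


def flag_shallow(
    records: Iterable[MsaRecord],
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
    out_path: str | Path | None = None,
) -> list[str]:
    """Return ids whose median depth is below ``depth_threshold``.

    The result is sorted, duplicate-free and invariant to record order.  When
    ``out_path`` is given the ids are written one per line (the
    ``shallow_MSA.txt`` convention).  Flagged proteins are annotated as
    unreliable downstream, never excluded from prediction.
    """
    if depth_threshold <= 0:
        raise ValueError("depth_threshold must be a positive integer")
    flagged = sorted({r.protein_id for r in records if r.median_depth < depth_threshold})
    if out_path is not None:
        Path(out_path).write_text("".join(f"{pid}\n" for pid in flagged))
    return flagged


def plot_msa_depth(
    record: MsaRecord,
    out_path: str | Path,
    depth_threshold: int = DEFAULT_DEPTH_THRESHOLD,
) -> Path:
    """Plot per-position depth with the shallow threshold as a horizontal line.

    The underlying (position, depth) pairs are also written as a TSV sidecar
    next to the image, so the figure is never the only record of the numbers.
    Returns the sidecar path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    positions = np.arange(1, record.depth_profile.size + 1)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(positions, record.depth_profile, lw=1.0, color="#1f77b4")
    ax.axhline(depth_threshold, color="crimson", ls="--", lw=0.8,
               label=f"shallow threshold ({depth_threshold})")
    ax.set_xlabel("query position")
    ax.set_ylabel("alignment depth (sequences)")
    ax.set_title(f"MSA depth: {record.protein_id} (median {record.median_depth:.0f})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    sidecar = out_path.with_suffix(".tsv")
    pd.DataFrame({"position": positions, "depth": record.depth_profile}).to_csv(
        sidecar, sep="\t", index=False
    )
    return sidecar
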