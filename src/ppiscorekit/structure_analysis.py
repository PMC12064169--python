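"""Distograms and interface residue contacts from predicted complex structures.

Distances are computed per residue pair under a chosen atom mode: CA, CB
(standard contact-prediction convention; CA stands in for glycine, which has
no CB) or min-heavy (minimum over all heavy-atom pairs).  Interface contacts
are cross-chain residue pairs within a distance cutoff — the default 8 Å CB
criterion is the field's usual contact definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import Residue

__all__ = [
    "DEFAULT_CONTACT_CUTOFF",
    "DistanceMatrix",
    "ContactRecord",
    "compute_distance_matrix",
    "interface_contacts",
    "render_distogram",
]

#: CB-CB contact cutoff in Å (standard contact-prediction convention).
DEFAULT_CONTACT_CUTOFF = 8.0


@dataclass
class DistanceMatrix:
    """Square symmetric residue-pair distance matrix with chain bookkeeping.

    ``residue_labels[i]`` is (chain, author residue number, residue name) for
    matrix row i; ``chain_boundaries`` are the row indices where chain
    identity changes (excluding 0 and the dimension).
    """

    residue_labels: list[tuple[str, int, str]]
    values: np.ndarray
    chain_boundaries: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for chain, _, _ in self.residue_labels:
            if not seen or seen[-1] != chain:
                seen.append(chain)
        return seen


@dataclass(frozen=True)
class ContactRecord:
    """One cross-chain residue pair within the contact cutoff."""

    chain_a: str
    residue_a: int
    resname_a: str
    chain_b: str
    residue_b: int
    resname_b: str
    distance: float


def _residue_coords(res: Residue, atom_mode: str, chain: str) -> np.ndarray:
    if atom_mode == "CA":
        if "CA" not in res.atoms:
            raise ValueError(f"chain {chain} residue {res.number} ({res.name}): no CA atom")
        return res.atoms["CA"][None, :]
    if atom_mode == "CB":
        if "CB" in res.atoms:
            return res.atoms["CB"][None, :]
        if "CA" in res.atoms:  # glycine (and CB-less models) fall back to CA
            return res.atoms["CA"][None, :]
        raise ValueError(
            f"chain {chain} residue {res.number} ({res.name}): neither CB nor CA atom"
        )
    if atom_mode == "min-heavy":
        coords = [xyz for name, xyz in res.atoms.items() if not name.startswith("H")]
        if not coords:
            raise ValueError(f"chain {chain} residue {res.number} ({res.name}): no heavy atoms")
        return np.vstack(coords)
    raise ValueError(f"unknown atom_mode {atom_mode!r}")


def compute_distance_matrix(
    structure: Mapping[str, Sequence[Residue]], atom_mode: str = "CB"
) -> DistanceMatrix:
    """Pairwise residue distances (Å) for a parsed structure.

    ``atom_mode``: "CA" (alpha carbons), "CB" (beta carbons, CA for glycine)
    or "min-heavy" (minimum over heavy-atom pairs, which lower-bounds the
    single-atom modes).  The result is symmetric with a zero diagonal.
    """
    labels: list[tuple[str, int, str]] = []
    coord_sets: list[np.ndarray] = []
    boundaries: list[int] = []
    for chain, residues in structure.items():
        if labels:
            boundaries.append(len(labels))
        for res in residues:
            labels.append((chain, res.number, res.name))
            coord_sets.append(_residue_coords(res, atom_mode, chain))
    n = len(labels)
    values = np.zeros((n, n))
    if atom_mode == "min-heavy":
        for i in range(n):
            for j in range(i + 1, n):
                d = cdist(coord_sets[i], coord_sets[j]).min()
                values[i, j] = values[j, i] = d
    else:
        pts = np.vstack(coord_sets)
        values = cdist(pts, pts)
        np.fill_diagonal(values, 0.0)
    return DistanceMatrix(residue_labels=labels, values=values, chain_boundaries=boundaries)


def interface_contacts(
    matrix: DistanceMatrix, cutoff_A: float = DEFAULT_CONTACT_CUTOFF
) -> list[ContactRecord]:
    """All cross-chain residue pairs with distance <= cutoff, nearest first.

    Each unordered pair appears once, chains in lexicographic order.  A
    single-chain matrix yields an empty list with a warning (multi-copy
    structures should present one chain per copy, so this signals malformed
    input).
    """
    if len(matrix.chains) < 2:
        warnings.warn("single-chain structure: no interface to scan")
        return []
    labels = matrix.residue_labels
    contacts: list[ContactRecord] = []
    n = len(labels)
    for i in range(n):
        chain_i, num_i, name_i = labels[i]
        for j in range(i + 1, n):
            chain_j, num_j, name_j = labels[j]
            if chain_i == chain_j:
                continue
            d = matrix.values[i, j]
            if d <= cutoff_A:
                a, b = ((chain_i, num_i, name_i), (chain_j, num_j, name_j))
                if (chain_j, num_j) < (chain_i, num_i):
                    a, b = b, a
                contacts.append(
                    ContactRecord(
                        chain_a=a[0], residue_a=a[1], resname_a=a[2],
                        chain_b=b[0], residue_b=b[1], resname_b=b[2],
                        distance=float(d),
                    )
                )
    contacts.sort(key=lambda c: (c.distance, c.chain_a, c.residue_a, c.chain_b, c.residue_b))
    return contacts


def contacts_to_frame(contacts: Sequence[ContactRecord]) -> pd.DataFrame:
    cols = ["chain_a", "resnum_a", "resname_a", "chain_b", "resnum_b", "resname_b", "distance_A"]
    rows = [
        [c.chain_a, c.residue_a, c.resname_a, c.chain_b, c.residue_b, c.resname_b, c.distance]
        for c in contacts
    ]
    return pd.DataFrame(rows, columns=cols)


def render_distogram(matrix: DistanceMatrix, out_path: str | Path) -> Path:
    """Render the distance matrix as a heat map with chain-block outlines.

    Darker colours mean shorter distances; black squares outline the
    intra-chain diagonal blocks, so points outside them are inter-chain
    contacts.  Axes are annotated with per-chain lengths and the matrix is
    written as a TSV sidecar (the figure is never the only record).
    Returns the sidecar path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    out_path = Path(out_path)
    n = matrix.values.shape[0]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(matrix.values, cmap="Blues_r", origin="upper")
    fig.colorbar(im, ax=ax, label="distance (Å)")
    bounds = [0] + matrix.chain_boundaries + [n]
    for chain, start, stop in zip(matrix.chains, bounds[:-1], bounds[1:]):
        ax.add_patch(
            Rectangle((start - 0.5, start - 0.5), stop - start, stop - start,
                      fill=False, edgecolor="black", lw=1.2)
        )
        ax.text(start + (stop - start) / 2, -0.02 * n - 1,
                f"{chain} ({stop - start} aa)", ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    sidecar = out_path.with_suffix(".tsv")
    names = [f"{c}:{num}:{name}" for c, num, name in matrix.residue_labels]
    pd.DataFrame(matrix.values, index=names, columns=names).to_csv(sidecar, sep="\t")
    return sidecar
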