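"""Report bundle: iQ-score heatmap, interaction network, retained tables.

The network shows every protein with at least one retained hetero
interaction (edges weighted by iQ-score) plus proteins whose only retained
result is a homo-oligomer, shown isolated with their self-annotation (best
copy number by hiQ-score).  The heatmap distinguishes "absent" (never
scored, or PAE-gate-failed) from a genuine score of 0 — absent cells are
NaN in the TSV sidecar and hatched in the figure.  Every number on a figure
also exists in a TSV/GraphML sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .scoring import HomoOligomerResult, ScoredInteraction

__all__ = [
    "InteractionNetwork",
    "build_heatmap_matrix",
    "build_network",
    "render_heatmap",
    "render_network",
    "render_report",
]


@dataclass
class InteractionNetwork:
    """Retained interactions as an undirected weighted graph.

    ``self_annotations`` maps protein -> (best copy number, hiQ-score) for
    retained homo-oligomers; ``shallow`` marks nodes whose MSA was flagged.
    """

    graph: nx.Graph
    self_annotations: dict[str, tuple[int, float]] = field(default_factory=dict)
    shallow: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(a, b), max(a, b), d["iq_score"]) for a, b, d in self.graph.edges(data=True)
        )


def build_heatmap_matrix(
    all_scored: Sequence[ScoredInteraction],
    proteins: Sequence[str],
    homo: Sequence[HomoOligomerResult] = (),
) -> pd.DataFrame:
    """Symmetric protein x protein matrix of iQ-scores.

    Cell (a, b) holds the pair's iQ-score (both orientations); the diagonal
    holds the best hiQ-score where one exists.  Unscored or gate-failed
    cells are NaN — absent, as distinct from a score of 0.
    """
    proteins = list(proteins)
    known = set(proteins)
    mat = pd.DataFrame(np.nan, index=proteins, columns=proteins)
    for s in all_scored:
        if s.protein_a not in known or s.protein_b not in known:
            raise ValueError(
                f"scored pair {s.job_id} references protein outside the given list"
            )
        if s.iq_score is not None:
            mat.loc[s.protein_a, s.protein_b] = s.iq_score
            mat.loc[s.protein_b, s.protein_a] = s.iq_score
    for h in homo:
        if h.protein not in known:
            raise ValueError(f"homo-oligomer {h.job_id} references unknown protein")
        if h.hiq_score is not None:
            current = mat.loc[h.protein, h.protein]
            if np.isnan(current) or h.hiq_score > current:
                mat.loc[h.protein, h.protein] = h.hiq_score
    return mat


def build_network(
    retained_het: Sequence[ScoredInteraction],
    retained_homo: Sequence[HomoOligomerResult],
    shallow_ids: Sequence[str] = (),
) -> InteractionNetwork:
    """Build the interaction network from retained results only.

    Self-annotations keep, per protein, the copy number with the highest
    hiQ-score among its retained homo-oligomers.
    """
    g = nx.Graph()
    for s in retained_het:
        if not s.retained or s.iq_score is None:
            continue
        g.add_edge(s.protein_a, s.protein_b, iq_score=round(s.iq_score, 2))
    annotations: dict[str, tuple[int, float]] = {}
    for h in retained_homo:
        if not h.retained or h.hiq_score is None:
            continue
        best = annotations.get(h.protein)
        if best is None or h.hiq_score > best[1]:
            annotations[h.protein] = (h.n_copies, round(h.hiq_score, 2))
    for protein in annotations:
        g.add_node(protein)  # isolated homo-oligomer-only proteins stay visible
    return InteractionNetwork(
        graph=g,
        self_annotations=annotations,
        shallow=set(shallow_ids) & set(g.nodes),
    )


def render_heatmap(matrix: pd.DataFrame, out_path: str | Path) -> Path:
    """Heat-render the score matrix; absent (NaN) cells are hatched grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(6, 5))
    masked = np.ma.masked_invalid(matrix.to_numpy(dtype=float))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad(color="0.85")
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=100)
    fig.colorbar(im, ax=ax, label="iQ / hiQ score")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    for (i, j), is_bad in np.ndenumerate(masked.mask if masked.mask is not np.ma.nomask
                                         else np.zeros(masked.shape, bool)):
        if is_bad:
            ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                       hatch="///", edgecolor="0.6", lw=0))
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    sidecar = out_path.with_suffix(".tsv")
    matrix.to_csv(sidecar, sep="\t", na_rep="NA")
    return sidecar


def render_network(
    network: InteractionNetwork, out_path: str | Path, layout_seed: int = 0
) -> Path:
    """Draw the network with a seeded force-directed layout; write GraphML.

    Shallow-MSA proteins get a distinct dashed outline and a footnote.
    Returns the GraphML sidecar path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    g = network.graph
    fig, ax = plt.subplots(figsize=(6, 5))
    if g.number_of_nodes():
        pos = nx.spring_layout(g, seed=layout_seed)
        ordinary = [n for n in g.nodes if n not in network.shallow]
        flagged = [n for n in g.nodes if n in network.shallow]
        nx.draw_networkx_nodes(g, pos, nodelist=ordinary, node_color="#87bdd8",
                               node_size=700, ax=ax)
        if flagged:
            nx.draw_networkx_nodes(g, pos, nodelist=flagged, node_color="#87bdd8",
                                   node_size=700, edgecolors="crimson",
                                   linewidths=2.0, ax=ax)
        nx.draw_networkx_edges(g, pos, ax=ax)
        labels = {}
        for n in g.nodes:
            ann = network.self_annotations.get(n)
            labels[n] = f"{n}\n{ann[0]}-mer {ann[1]:.2f}" if ann else n
        nx.draw_networkx_labels(g, pos, labels=labels, font_size=7, ax=ax)
        edge_labels = {(a, b): f"{d['iq_score']:.2f}" for a, b, d in g.edges(data=True)}
        nx.draw_networkx_edge_labels(g, pos, edge_labels=edge_labels, font_size=6, ax=ax)
        if flagged:
            ax.text(0.0, -0.05, "red outline: shallow MSA (unreliable)",
                    transform=ax.transAxes, fontsize=7, color="crimson")
    else:
        ax.text(0.5, 0.5, "no retained interactions", ha="center", va="center")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    sidecar = out_path.with_suffix(".graphml")
    export = g.copy()
    for n, (copies, hiq) in network.self_annotations.items():
        export.nodes[n]["best_n_copies"] = copies
        export.nodes[n]["hiq_score"] = hiq
    for n in network.shallow:
        export.nodes[n]["shallow_msa"] = True
    nx.write_graphml(export, sidecar)
    return sidecar


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def render_report(
    network: InteractionNetwork,
    heatmap: pd.DataFrame,
    hetero: Sequence[ScoredInteraction],
    homo: Sequence[HomoOligomerResult],
    out_dir: str | Path,
    contacts: Mapping[str, pd.DataFrame] | None = None,
    distograms: Mapping[str, Path] | None = None,
    config: Mapping | None = None,
    input_files: Sequence[str | Path] = (),
    layout_seed: int = 0,
) -> dict[str, Path]:
    """Assemble the full report bundle in ``out_dir``.

    Writes: network figure + GraphML + edge-list TSV, heatmap figure + TSV,
    per-interaction contact tables, the retained-interaction TSVs (sorted by
    score descending) and a JSON run manifest (config, thresholds, versions,
    input checksums).  When nothing was retained the tables are empty and
    the manifest says so explicitly.
    """
    from . import __version__
    from .scoring import write_scored_tables

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_scored_tables(hetero, homo, out_dir)
    paths["heatmap_tsv"] = render_heatmap(heatmap, out_dir / "iq_heatmap.png")
    paths["heatmap_png"] = out_dir / "iq_heatmap.png"
    paths["network_graphml"] = render_network(
        network, out_dir / "interaction_network.png", layout_seed=layout_seed
    )
    paths["network_png"] = out_dir / "interaction_network.png"
    edge_df = pd.DataFrame(network.edges, columns=["protein_a", "protein_b", "iq_score"])
    paths["edges_tsv"] = out_dir / "network_edges.tsv"
    edge_df.to_csv(paths["edges_tsv"], sep="\t", index=False)
    if contacts:
        contact_dir = out_dir / "contacts"
        contact_dir.mkdir(exist_ok=True)
        for job_id, frame in contacts.items():
            frame.to_csv(contact_dir / f"{job_id}_contacts.tsv", sep="\t", index=False)
        paths["contacts_dir"] = contact_dir
    n_retained = sum(s.retained for s in hetero) + sum(h.retained for h in homo)
    manifest = {
        "package_version": __version__,
        "config": dict(config or {}),
        "n_hetero_jobs": len(hetero),
        "n_homo_jobs": len(homo),
        "n_retained": n_retained,
        "note": "" if n_retained else "no retained interactions",
        "input_checksums": {str(p): _checksum(Path(p)) for p in input_files},
        "distograms": {k: str(v) for k, v in (distograms or {}).items()},
    }
    paths["manifest"] = out_dir / "run_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
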