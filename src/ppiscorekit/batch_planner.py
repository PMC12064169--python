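"""Job planning: all-against-all pairs, homo-oligomers, memory-aware exclusion.

The screen enumerates every unordered hetero pair plus homo-oligomer jobs up
to a copy count, then partitions jobs into runnable and out-of-memory (OOM)
against a capacity map from accelerator memory (GB) to the largest total
residue count it can fold.  OOM jobs are listed in ``OOM_int.txt`` rather
than silently dropped.  Job sizes use mature (signal-peptide-trimmed)
sequence lengths — that is what the predictor would fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model_io import ProteinEntry

__all__ = [
    "CandidateJob",
    "CapacityMap",
    "DEFAULT_CAPACITY_POINTS",
    "plan_hetero_pairs",
    "plan_homo_oligomers",
    "apply_memory_limit",
    "format_job_line",
    "parse_job_id",
    "write_job_list",
]

#: Default map from accelerator memory (GB) to maximum foldable residues.
#: Environment-dependent; the mechanism, not these constants, is the contract.
DEFAULT_CAPACITY_POINTS: dict[float, float] = {
    8: 1800, 16: 2700, 24: 3600, 48: 5500, 80: 7200,
}


@dataclass(frozen=True)
class CandidateJob:
    """One prediction job: ordered (protein_id, copy_count) members."""

    members: tuple[tuple[str, int], ...]
    total_residues: int
    job_kind: str  # "hetero-pair" | "homo-oligomer"

    def __post_init__(self) -> None:
        if self.job_kind == "hetero-pair":
            if len(self.members) != 2 or any(c != 1 for _, c in self.members):
                raise ValueError("hetero-pair jobs need exactly 2 members, 1 copy each")
        elif self.job_kind == "homo-oligomer":
            if len(self.members) != 1 or self.members[0][1] < 2:
                raise ValueError("homo-oligomer jobs need 1 member with >=2 copies")
        else:
            raise ValueError(f"unknown job_kind {self.job_kind!r}")
        if self.total_residues <= 0:
            raise ValueError("total_residues must be positive")

    @property
    def job_id(self) -> str:
        if self.job_kind == "hetero-pair":
            return "_and_".join(pid for pid, _ in self.members)
        pid, n = self.members[0]
        return f"{pid}_homo_{n}mer"

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(pid for pid, _ in self.members)


def parse_job_id(job_id: str) -> tuple[str, tuple[str, ...], int]:
    """Invert :attr:`CandidateJob.job_id` -> (kind, protein ids, copy count)."""
    if "_homo_" in job_id:
        pid, suffix = job_id.rsplit("_homo_", 1)
        if not suffix.endswith("mer"):
            raise ValueError(f"malformed homo-oligomer job id {job_id!r}")
        return "homo-oligomer", (pid,), int(suffix[:-3])
    if "_and_" in job_id:
        a, b = job_id.split("_and_", 1)
        return "hetero-pair", (a, b), 1
    raise ValueError(f"cannot parse job id {job_id!r}")


def plan_hetero_pairs(entries: Sequence[ProteinEntry]) -> list[CandidateJob]:
    """One job per unordered distinct pair: n proteins -> C(n,2) jobs.

    Pair members are ordered lexicographically by id within each job.
    """
    if len(entries) < 2:
        warnings.warn("fewer than 2 proteins: no hetero pairs to plan")
        return []
    lengths = {e.id: len(e.mature_sequence) for e in entries}
    jobs = []
    for a, b in combinations(sorted(lengths), 2):
        jobs.append(
            CandidateJob(
                members=((a, 1), (b, 1)),
                total_residues=lengths[a] + lengths[b],
                job_kind="hetero-pair",
            )
        )
    return jobs


def plan_homo_oligomers(
    entries: Sequence[ProteinEntry], max_copies: int = 2
) -> list[CandidateJob]:
    """For each protein, one job per copy count in 2..max_copies."""
    if max_copies < 2:
        raise ValueError("max_copies must be >= 2")
    jobs = []
    for entry in sorted(entries, key=lambda e: e.id):
        n_res = len(entry.mature_sequence)
        for copies in range(2, max_copies + 1):
            jobs.append(
                CandidateJob(
                    members=((entry.id, copies),),
                    total_residues=n_res * copies,
                    job_kind="homo-oligomer",
                )
            )
    return jobs


class CapacityMap:
    """Piecewise-linear map from accelerator memory (GB) to residue capacity.

    Linear interpolation between configured points; outside the configured
    range the capacity clamps to the nearest end value, keeping the map
    monotonically non-decreasing everywhere.
    """

    def __init__(self, points: dict[float, float] | None = None) -> None:
        pts = dict(points or DEFAULT_CAPACITY_POINTS)
        if not pts:
            raise ValueError("capacity map needs at least one point")
        self._mem = np.array(sorted(pts), dtype=float)
        self._cap = np.array([pts[m] for m in sorted(pts)], dtype=float)
        if np.any(np.diff(self._cap) < 0):
            raise ValueError("capacity must be non-decreasing in memory")

    def __call__(self, gpu_memory_gb: float) -> float:
        if gpu_memory_gb <= 0:
            raise ValueError("gpu memory must be positive")
        return float(np.interp(gpu_memory_gb, self._mem, self._cap))


def apply_memory_limit(
    jobs: Iterable[CandidateJob],
    gpu_memory_gb: float = 24.0,
    capacity_map: CapacityMap | None = None,
    oom_path: str | Path | None = None,
) -> tuple[list[CandidateJob], list[CandidateJob]]:
    """Partition jobs into (runnable, oom) against the capacity map.

    Order-stable: both outputs preserve the input order.  When ``oom_path``
    is given, excluded jobs are written one per line (``OOM_int.txt``).
    """
    capacity_map = capacity_map or CapacityMap()
    capacity = capacity_map(gpu_memory_gb)
    runnable, oom = [], []
    for job in jobs:
        (oom if job.total_residues > capacity else runnable).append(job)
    if oom_path is not None:
        Path(oom_path).write_text("".join(format_job_line(j) + "\n" for j in oom))
    return runnable, oom


def format_job_line(job: CandidateJob) -> str:
    """Render one job in the upstream tool's custom-mode line syntax.

    Members are ";"-separated; a copy count > 1 is rendered as ``id,count``.
    """
    return ";".join(
        pid if count == 1 else f"{pid},{count}" for pid, count in job.members
    )


def write_job_list(jobs: Iterable[CandidateJob], path: str | Path) -> None:
    Path(path).write_text("".join(format_job_line(j) + "\n" for j in jobs))
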