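"""Plan an all-against-all screen with memory-aware exclusion.

Builds a small proteome, enumerates every unordered pair plus homo-dimer
jobs, and partitions them against the 24 GB capacity point (3600 residues).
"""

from ppiscorekit import (
    CapacityMap,
    ProteinEntry,
    apply_memory_limit,
    plan_hetero_pairs,
    plan_homo_oligomers,
)

proteins = [
    ProteinEntry(id="VirB8", sequence="M" * 230),
    ProteinEntry(id="VirB9", sequence="M" * 290),
    ProteinEntry(id="VirB10", sequence="M" * 380),
    ProteinEntry(id="VirB4", sequence="M" * 2400),  # large ATPase
]

pairs = plan_hetero_pairs(proteins)           # C(4,2) = 6 jobs
homos = plan_homo_oligomers(proteins, max_copies=2)
runnable, oom = apply_memory_limit(pairs + homos, gpu_memory_gb=24)

print(f"planned {len(pairs)} hetero pairs + {len(homos)} homo-dimers")
print(f"capacity at 24 GB: {CapacityMap()(24):.0f} residues")
print("runnable:", [j.job_id for j in runnable])
print("excluded (OOM):", [j.job_id for j in oom])
# VirB4 homo-dimer (4800 residues) exceeds the 24 GB capacity and is listed
# for the user instead of being attempted and crashing the accelerator.
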