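"""Distance matrix and interface contacts for a predicted complex.

Uses a generated toy complex with contacts planted at known distances, then
recovers them with the 8 Å CB-CB contact criterion.
"""

import tempfile
from pathlib import Path

from ppiscorekit import compute_distance_matrix, interface_contacts, read_structure
from ppiscorekit.fixtures import generate_cohort
from ppiscorekit.structure_analysis import render_distogram

with tempfile.TemporaryDirectory() as td:
    manifest = generate_cohort(Path(td) / "cohort", seed=7)
    job_id = manifest["expected_retained_hetero"][0]
    info = manifest["jobs"][job_id]
    pdb = Path(td) / "cohort" / "models" / job_id / f"model_{info['best_model_index']}.pdb"

    chains = read_structure(pdb)
    dm = compute_distance_matrix(chains, atom_mode="CB")
    contacts = interface_contacts(dm, cutoff_A=8.0)
    render_distogram(dm, Path(td) / "distogram.png")

    print(f"{job_id}: chains {dm.chains}, {dm.values.shape[0]} residues")
    for c in contacts[:5]:
        print(f"  {c.chain_a}/{c.resname_a}{c.residue_a} -- "
              f"{c.chain_b}/{c.resname_b}{c.residue_b}: {c.distance:.2f} Å")
    print(f"{len(contacts)} cross-chain contacts <= 8 Å; planted pairs:",
          [(p['resnum_a'], p['resnum_b'], p['distance'])
           for p in info["planted_contacts"]])
# The planted residue pairs appear at exactly their designed distances;
# their immediate sequence neighbours also fall under the 8 Å cutoff, as
# they would at a real interface.
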