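"""End-to-end orchestration over a directory of predictor outputs.

Glue only — each step lives in its own module.  The expected layout is the
one the fixtures module writes and the ingest conventions in model_io
assemble:

    <input>/proteins.fasta
    <input>/signalp.tsv                  (optional)
    <input>/msas/<protein>.a3m           (optional)
    <input>/models/<job_id>/scores_model_<k>.json
    <input>/models/<job_id>/pae_model_<k>.json   (best model)
    <input>/models/<job_id>/model_<k>.pdb        (best model)
"""

from __future__ import annotations

from pathlib import Path

from . import batch_planner, model_io, preprocess_qc, reporting, scoring, structure_analysis

__all__ = ["assemble_best_models", "run_pipeline"]


def assemble_best_models(
    models_dir: str | Path,
) -> tuple[dict[str, model_io.ModelResult], list[model_io.ScoreRecord]]:
    """Select each job's best model (highest ipTM) and load its PAE + layout.

    Returns the best model per job together with that model's score record.
    """
    models_dir = Path(models_dir)
    records = model_io.discover_job_scores(models_dir)
    by_job: dict[str, list[model_io.ScoreRecord]] = {}
    for rec in records:
        by_job.setdefault(rec.job_id, []).append(rec)
    best_models: dict[str, model_io.ModelResult] = {}
    best_records: list[model_io.ScoreRecord] = []
    for job_id, recs in sorted(by_job.items()):
        best = max(recs, key=lambda r: (r.iptm, -r.model_index))
        kind, proteins, copies = batch_planner.parse_job_id(job_id)
        structure_path = models_dir / job_id / f"model_{best.model_index}.pdb"
        chains = model_io.read_structure(structure_path)
        chain_ranges: dict[str, tuple[int, int]] = {}
        cursor = 0
        for cid, residues in chains.items():
            chain_ranges[cid] = (cursor, cursor + len(residues))
            cursor += len(residues)
        pae = model_io.read_pae_matrix(
            models_dir / job_id / f"pae_model_{best.model_index}.json", chain_ranges
        )
        best_models[job_id] = model_io.ModelResult(
            job_id=job_id,
            model_index=best.model_index,
            iptm=best.iptm,
            iptm_ptm=best.iptm_ptm,
            structure_path=structure_path,
            pae=pae,
            chain_ranges=chain_ranges,
        )
        best_records.append(best)
    return best_models, best_records


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    gpu_memory_gb: float = 24.0,
    max_copies: int = 2,
    depth_threshold: int = preprocess_qc.DEFAULT_DEPTH_THRESHOLD,
    iq_cutoff: float = scoring.DEFAULT_CUTOFF,
    hiq_cutoff: float = scoring.DEFAULT_CUTOFF,
    pae_threshold: float = scoring.DEFAULT_PAE_THRESHOLD,
    pae_stat: str = "min",
    contact_cutoff: float = structure_analysis.DEFAULT_CONTACT_CUTOFF,
    atom_mode: str = "CB",
    capacity_map: batch_planner.CapacityMap | None = None,
    layout_seed: int = 0,
) -> dict:
    """Run QC, planning, scoring, interface analysis and reporting.

    Returns a results dict with the intermediate objects; the report bundle
    (tables, figures, sidecars, manifest) is written under ``out_dir``.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    entries = model_io.read_fasta(input_dir / "proteins.fasta")
    signalp_path = input_dir / "signalp.tsv"
    if signalp_path.exists():
        annotations = preprocess_qc.read_signalp_table(signalp_path)
        entries = preprocess_qc.trim_signal_peptides(entries, annotations)

    msa_records = []
    msa_dir = input_dir / "msas"
    if msa_dir.is_dir():
        for entry in entries:
            a3m = msa_dir / f"{entry.id}.a3m"
            if a3m.exists():
                msa_records.append(preprocess_qc.compute_msa_depth(a3m, entry.id))
    shallow_ids = preprocess_qc.flag_shallow(
        msa_records, depth_threshold, out_path=out_dir / "shallow_MSA.txt"
    )

    pair_jobs = batch_planner.plan_hetero_pairs(entries)
    homo_jobs = batch_planner.plan_homo_oligomers(entries, max_copies=max_copies)
    runnable, oom = batch_planner.apply_memory_limit(
        pair_jobs + homo_jobs, gpu_memory_gb, capacity_map,
        oom_path=out_dir / "OOM_int.txt",
    )
    batch_planner.write_job_list(
        [j for j in runnable if j.job_kind == "hetero-pair"],
        out_dir / "all_against_all.txt",
    )
    batch_planner.write_job_list(
        [j for j in runnable if j.job_kind == "homo-oligomer"],
        out_dir / "homo_oligomers.txt",
    )

    results: dict = {
        "entries": entries,
        "msa_records": msa_records,
        "shallow_ids": shallow_ids,
        "runnable_jobs": runnable,
        "oom_jobs": oom,
        "hetero": [],
        "homo": [],
    }
    models_dir = input_dir / "models"
    if not models_dir.is_dir():
        return results

    best_models, best_records = assemble_best_models(models_dir)
    hetero, homo = scoring.score_and_filter(
        best_models, best_records, shallow_ids,
        iq_cutoff=iq_cutoff, hiq_cutoff=hiq_cutoff,
        pae_threshold=pae_threshold, pae_stat=pae_stat,
    )
    results["hetero"], results["homo"] = hetero, homo
    results["best_models"] = best_models

    # interface geometry for retained jobs only
    contacts: dict = {}
    distograms: dict = {}
    geometry_dir = out_dir / "distograms"
    retained_jobs = [s.job_id for s in hetero if s.retained] + [
        h.job_id for h in homo if h.retained
    ]
    if retained_jobs:
        geometry_dir.mkdir(exist_ok=True)
    for job_id in retained_jobs:
        model = best_models[job_id]
        chains = model_io.read_structure(model.structure_path)
        dm = structure_analysis.compute_distance_matrix(chains, atom_mode=atom_mode)
        contacts[job_id] = structure_analysis.contacts_to_frame(
            structure_analysis.interface_contacts(dm, contact_cutoff)
        )
        distograms[job_id] = geometry_dir / f"{job_id}_distogram.png"
        structure_analysis.render_distogram(dm, distograms[job_id])
    results["contacts"] = contacts

    proteins = sorted(e.id for e in entries)
    heatmap = reporting.build_heatmap_matrix(hetero, proteins, homo)
    network = reporting.build_network(hetero, homo, shallow_ids)
    results["heatmap"] = heatmap
    results["network"] = network
    results["report_paths"] = reporting.render_report(
        network, heatmap, hetero, homo, out_dir,
        contacts=contacts, distograms=distograms,
        config={
            "gpu_memory_gb": gpu_memory_gb,
            "max_copies": max_copies,
            "depth_threshold": depth_threshold,
            "iq_cutoff": iq_cutoff,
            "hiq_cutoff": hiq_cutoff,
            "pae_threshold": pae_threshold,
            "pae_stat": pae_stat,
            "contact_cutoff": contact_cutoff,
            "atom_mode": atom_mode,
        },
        input_files=[input_dir / "proteins.fasta"],
        layout_seed=layout_seed,
    )
    return results
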