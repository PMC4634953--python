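"""End-to-end orchestration: filter -> intersect -> assemble -> normalise ->
concatenate -> compare -> maximum-likelihood tree.

``run_simulate`` writes a complete synthetic study to disk in the same text
formats the analysis consumes; ``run_full`` executes the analysis from those
files (or any files with the same layout) and writes the report bundle:
per-specimen filter reports, consensus FASTA, variation and shared-peak
matrices, the rooted ML tree with bootstrap supports, and a run manifest
with content digests so identical runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import (
    ConsensusSequence,
    assemble_consensus,
    concatenate_chains,
    normalize_isobaric,
    variation_matrix,
)
from .io import read_fasta, write_fasta, write_tree
from .pmf import PeakList, pairwise_shared_matrix, read_peaklist, write_peaklist
from .phylo import Alignment, bootstrap_support, ml_pipeline
from .psm import PSM, make_filter_report, read_psm_table, replicate_intersection, write_psm_table
from .simulate import SimulationConfig, simulate_dataset, split_chains

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, config: dict, seed: int,
                   timings: dict[str, float]) -> Path:
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {
            p.name: _digest_file(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_simulate(config: SimulationConfig, outdir) -> Path:
    """Generate and write a synthetic dataset directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    data = simulate_dataset(config)
    write_tree(data.tree, outdir / "true_tree.nwk")
    write_fasta(data.true_sequences, outdir / "true_alignment.fasta")
    write_fasta(
        {t: data.true_sequences[t] for t in data.reference_taxa},
        outdir / "reference_alignment.fasta",
    )
    for specimen_id, psms in data.psm_tables.items():
        write_psm_table(psms, outdir / f"psms_{specimen_id}.tsv")
    for taxon, pl in data.peak_lists.items():
        write_peaklist(pl, outdir / f"pmf_{taxon}.txt")
    (outdir / "specimens.tsv").write_text(
        "specimen_id\ttaxon\n"
        + "".join(f"{s}\t{t}\n" for s, t in data.specimen_taxon.items())
    )
    timings = {"simulate": time.perf_counter() - t0}
    write_manifest(outdir, config.to_dict(), config.seed, timings)
    return outdir


@dataclass
class FullRunResult:
    filter_reports: pd.DataFrame
    consensus: dict[str, str]          # fossil taxon -> concatenated consensus
    variation_matrix: pd.DataFrame
    shared_peak_matrix: pd.DataFrame | None
    ml_tree: "object"
    log_likelihood: float
    outdir: Path


def run_full(
    psm_tables: dict[str, Path | str],
    specimen_taxon: dict[str, str],
    reference_alignment: Path | str,
    outdir: Path | str,
    peaklists: dict[str, Path | str] | None = None,
    chain_lengths: tuple[int, int] = (1056, 1041),
    chain_mode: str = "concat",
    outgroup: str | None = None,
    seed: int = 0,
    bootstrap_reps: int = 100,
    alpha: float = 1.0,
    p_inv: float = 0.1,
    optimize_params: bool = True,
    isobaric_normalize: bool = True,
    intersect_by_position: bool = True,
    tolerance_da: float = 0.2,
    top_n: int = 100,
) -> FullRunResult:
    """Run the whole analysis from PSM tables + reference alignment.

    ``psm_tables`` maps specimen id to a PSM TSV path; ``specimen_taxon``
    assigns each specimen to its (extinct) taxon — every taxon must have at
    least two specimens (the both-specimens replication rule). The reference
    alignment holds the extant concatenated chain1+R+chain2 sequences.
    ``chain_mode`` is "concat" (both chains) or "a2-only" (second chain
    block alone, for comparison with datasets lacking chain-1 references).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    references = read_fasta(reference_alignment)
    expected_length = sum(chain_lengths) + 1
    for name, seq in references.items():
        if len(seq) != expected_length:
            raise PipelineError(
                f"reference {name!r} has length {len(seq)}, expected "
                f"{expected_length} (= {chain_lengths[0]}+{chain_lengths[1]}+1)"
            )

    # -- stage 1: HFPS filtering per specimen ------------------------------
    t0 = time.perf_counter()
    by_taxon: dict[str, list[tuple[str, list[PSM]]]] = {}
    report_rows = []
    chain_len_map = {"COL1A1": chain_lengths[0], "COL1A2": chain_lengths[1]}
    for specimen_id, path in psm_tables.items():
        taxon = specimen_taxon.get(specimen_id)
        if taxon is None:
            raise PipelineError(f"specimen {specimen_id!r} has no taxon assignment")
        psms = read_psm_table(path)
        report, kept = make_filter_report(psms, chain_len_map)
        report_rows.append(report.to_row())
        by_taxon.setdefault(taxon, []).append((specimen_id, kept))
    reports = pd.DataFrame(report_rows)
    reports.to_csv(outdir / "filter_reports.tsv", sep="\t", index=False)
    timings["filter"] = time.perf_counter() - t0

    # -- stage 2: replicate intersection and consensus assembly ------------
    t0 = time.perf_counter()
    consensus_concat: dict[str, str] = {}
    for taxon, specimens in by_taxon.items():
        if len(specimens) < 2:
            raise PipelineError(
                f"taxon {taxon!r} has {len(specimens)} filtered specimen(s); "
                "the replication rule requires peptide matches found in both "
                "of (at least) two specimens"
            )
        (id_a, kept_a), (id_b, kept_b) = specimens[:2]
        if len(specimens) > 2:
            logger.warning("taxon %s: using first two specimens (%s, %s) of %d",
                           taxon, id_a, id_b, len(specimens))
        shared = replicate_intersection(kept_a, kept_b,
                                        include_position=intersect_by_position)
        chains = {}
        for chain_id, length in chain_len_map.items():
            matches = [p for p in shared if p.chain_id == chain_id]
            chains[chain_id] = assemble_consensus(matches, length, taxon=taxon)
        concat = concatenate_chains(chains["COL1A1"], chains["COL1A2"])
        consensus_concat[taxon] = concat.residues
        write_psm_table(shared, outdir / f"intersected_{taxon}.tsv")
    timings["assemble"] = time.perf_counter() - t0

    # -- stage 3: isobaric normalisation and matrices ----------------------
    t0 = time.perf_counter()
    if isobaric_normalize and consensus_concat:
        consensus_concat = normalize_isobaric(consensus_concat, references)
    all_sequences = {**references, **consensus_concat}
    write_fasta(consensus_concat, outdir / "consensus.fasta")
    var_mat = variation_matrix(all_sequences)
    var_mat.to_csv(outdir / "variation_matrix.tsv", sep="\t")
    shared_mat = None
    if peaklists:
        pls = {t: read_peaklist(p) for t, p in peaklists.items()}
        shared_mat = pairwise_shared_matrix(pls, n=top_n, tol=tolerance_da)
        shared_mat.to_csv(outdir / "shared_peak_matrix.tsv", sep="\t")
    timings["compare"] = time.perf_counter() - t0

    # -- stage 4: maximum-likelihood phylogeny -----------------------------
    t0 = time.perf_counter()
    if chain_mode == "a2-only":
        start = chain_lengths[0] + 1
        phylo_sequences = {t: s[start:] for t, s in all_sequences.items()}
    elif chain_mode == "concat":
        phylo_sequences = all_sequences
    else:
        raise PipelineError(f"unknown chain_mode {chain_mode!r}")
    alignment = Alignment(phylo_sequences)
    from .phylo import SubstitutionModel

    model = SubstitutionModel.jtt(alpha=alpha, p_inv=p_inv)
    result, fitted_model = ml_pipeline(alignment, model,
                                       optimize_params=optimize_params)
    tree = result.tree
    if bootstrap_reps > 0:
        tree = bootstrap_support(alignment, fitted_model, n_reps=bootstrap_reps,
                                 seed=seed, ml_tree=tree)
    if outgroup is not None:
        tree = tree.root_at_outgroup(outgroup)
    write_tree(tree, outdir / "ml_tree.nwk", include_support=bootstrap_reps > 0)
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"log_likelihood\t{result.log_likelihood:.6f}\n")
        fh.write(f"alpha\t{fitted_model.alpha:.6f}\n")
        fh.write(f"p_inv\t{fitted_model.p_inv:.6f}\n")
        fh.write(f"nni_swaps\t{result.n_swaps}\n")
        fh.write(f"seed\t{seed}\n")
    timings["phylo"] = time.perf_counter() - t0

    config_snapshot = {
        "chain_lengths": list(chain_lengths), "chain_mode": chain_mode,
        "outgroup": outgroup, "bootstrap_reps": bootstrap_reps,
        "alpha": alpha, "p_inv": p_inv, "optimize_params": optimize_params,
        "isobaric_normalize": isobaric_normalize,
        "intersect_by_position": intersect_by_position,
        "tolerance_da": tolerance_da, "top_n": top_n,
    }
    write_manifest(outdir, config_snapshot, seed, timings)
    return FullRunResult(
        filter_reports=reports,
        consensus=consensus_concat,
        variation_matrix=var_mat,
        shared_peak_matrix=shared_mat,
        ml_tree=tree,
        log_likelihood=result.log_likelihood,
        outdir=outdir,
    )


def run_full_from_directory(datadir, outdir, **kwargs) -> FullRunResult:
    """Run the analysis on a directory laid out like ``run_simulate`` output."""
    datadir = Path(datadir)
    spec_map = {}
    for line in (datadir / "specimens.tsv").read_text().splitlines()[1:]:
        specimen_id, taxon = line.split("\t")
        spec_map[specimen_id] = taxon
    psm_tables = {s: datadir / f"psms_{s}.tsv" for s in spec_map}
    peaklists = {
        p.stem.removeprefix("pmf_"): p for p in sorted(datadir.glob("pmf_*.txt"))
    }
    return run_full(
        psm_tables=psm_tables,
        specimen_taxon=spec_map,
        reference_alignment=datadir / "reference_alignment.fasta",
        outdir=outdir,
        peaklists=peaklists or None,
        **kwargs,
    )
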