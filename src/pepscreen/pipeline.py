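"""Config-driven orchestration of the peptide-screening funnel.

Stages: enumerate the subpeptide library from the parent region, score
every candidate against the target sequence, keep those scoring above
the reference, cap the length, import (or synthesize) a docking-pose
ensemble per surviving candidate, cluster the poses, apply the
contact-fraction and occupancy selection rules, annotate solubility,
and emit a candidate report plus a reproducibility manifest.  Docking
is an import boundary: the pipeline consumes pose ensembles, it never
runs an engine.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional

import yaml

from . import __version__
from .peptide_library import (
    ParentProtein,
    PeptideCandidate,
    candidate_table,
    enumerate_subpeptides,
)
from .poses import (
    PoseEnsemble,
    contact_analysis,
    kmedoids_cluster,
    select_candidates,
)
from .scoring import ScorerSpec, filter_by_reference, length_cap, score_peptides

logger = logging.getLogger(__name__)

# Kyte-Doolittle hydropathy for the solubility rule
from .scoring import _CHARGE, _KD


def solubility_heuristic(sequence: str) -> str:
    """Rule-based water-solubility flag: ``good`` or ``poor``.

    A peptide is flagged good when its mean Kyte-Doolittle hydropathy
    (GRAVY) is negative, or when more than 25 % of its residues are
    charged (D, E, K, R; H counts half).  This is a transparent
    heuristic on sequence composition, NOT a trained solubility
    predictor, and is labelled as such wherever it is reported.
    """
    if not sequence:
        raise ValueError("empty sequence")
    gravy = sum(_KD[aa] for aa in sequence) / len(sequence)
    charged = sum(abs(_CHARGE[aa]) for aa in sequence) / len(sequence)
    return "good" if (gravy < 0.0 or charged > 0.25) else "poor"


@dataclass
class PipelineConfig:
    """All knobs of the screening funnel, loadable from YAML."""

    parent_id: str = "parent"
    parent_sequence: str = ""
    numbering_offset: int = 1
    parent_fasta: Optional[str] = None
    min_len: int = 21
    max_len: Optional[int] = None
    scorer: str = "propensity"
    target_sequence: str = ""
    reference_sequence: Optional[str] = None    # defaults to the parent
    filter_mode: str = "greater"
    length_cap: int = 30
    k_clusters: int = 10
    seed: int = 0
    contact_cutoff_A: float = 10.0
    fraction_threshold_pct: float = 50.0
    solubility: bool = True
    pose_paths: dict = field(default_factory=dict)  # peptide name -> PDB path
    receptor_chain: str = "A"
    peptide_chain: str = "B"
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


PoseProvider = Callable[[PeptideCandidate], Optional[PoseEnsemble]]


def _path_pose_provider(config: PipelineConfig) -> PoseProvider:
    from .poses import read_pose_ensemble

    def provider(pep: PeptideCandidate) -> Optional[PoseEnsemble]:
        path = config.pose_paths.get(pep.name) or config.pose_paths.get(pep.sequence)
        if path is None:
            return None
        return read_pose_ensemble(
            path, receptor_chain=config.receptor_chain,
            peptide_chain=config.peptide_chain,
        )

    return provider


def run_funnel(
    config: PipelineConfig,
    pose_provider: Optional[PoseProvider] = None,
):
    """Run the full screening funnel; returns (report DataFrame, manifest).

    ``pose_provider`` maps a candidate to its docked pose ensemble
    (``None`` when no docking data exists for it); by default ensembles
    are read from the multi-model PDB paths in the config.  Candidates
    without poses are carried through unannotated.  Stage counts are
    logged and recorded in the manifest; the manifest's seed and config
    hash suffice to reproduce the run.
    """
    t0 = time.time()
    if config.parent_fasta:
        from .peptide_library import read_parent_fasta

        parent = read_parent_fasta(config.parent_fasta)[0]
    else:
        if not config.parent_sequence:
            raise ValueError("config needs parent_sequence or parent_fasta")
        parent = ParentProtein(
            id=config.parent_id, sequence=config.parent_sequence,
            numbering_offset=config.numbering_offset,
        )
    if pose_provider is None:
        pose_provider = _path_pose_provider(config)

    counts: dict[str, int] = {}
    library = enumerate_subpeptides(parent, config.min_len, config.max_len)
    counts["library"] = len(library)
    logger.info("library: %d candidates", len(library))

    scorer = ScorerSpec(name=config.scorer)
    target = config.target_sequence
    if not target:
        raise ValueError("config.target_sequence is required for scoring")
    reference = config.reference_sequence or parent.sequence
    scorer.calibrate(reference, target)
    library = score_peptides(library, target, scorer)
    accepted = filter_by_reference(library, scorer.reference_score, config.filter_mode)
    counts["score_accepted"] = len(accepted)
    logger.info("score filter: %d accepted (reference %.4f)",
                len(accepted), scorer.reference_score)

    capped = length_cap(accepted, config.length_cap)
    counts["length_capped"] = len(capped)
    logger.info("length cap <= %d: %d remain", config.length_cap, len(capped))

    n_with_poses = 0
    n_selected = 0
    for pep in capped:
        ensemble = pose_provider(pep)
        if ensemble is None:
            continue
        n_with_poses += 1
        clusters = kmedoids_cluster(ensemble, k=config.k_clusters, seed=config.seed)
        reports = [
            contact_analysis(ensemble.receptor, ensemble.pose(int(m)),
                             cutoff_A=config.contact_cutoff_A)
            for m in clusters.medoids
        ]
        result = select_candidates(clusters, reports)
        pep.contacts = result.report.contacts
        pep.fraction_pct = result.report.fraction_pct
        pep.occupancy = result.occupancy
        pep.selected = result.selected
        if result.selected:
            n_selected += 1
    counts["with_poses"] = n_with_poses
    counts["contact_selected"] = n_selected

    if config.solubility:
        n_soluble = 0
        for pep in capped:
            pep.solubility_flag = solubility_heuristic(pep.sequence)
            n_soluble += pep.solubility_flag == "good"
        counts["soluble_flagged"] = n_soluble

    report = candidate_table(capped)
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "scorer": config.scorer,
        "reference_score": scorer.reference_score,
        "stage_counts": counts,
        "solubility_note": "heuristic flag (GRAVY/charge rule), "
                           "not an external solubility predictor",
        "elapsed_s": round(time.time() - t0, 3),
    }
    if not capped:
        logger.warning("empty candidate report after filtering")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "candidates.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report, manifest
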