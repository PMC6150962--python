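"""End-to-end orchestration: embed -> refine -> detect -> classify -> evaluate.

A single global seed fans out to per-stage seeds (CRC32 of the stage name and
the global seed), so any stage can be re-run independently yet reproducibly.
``run_pipeline`` works on in-memory objects; ``run_pipeline_files`` wraps it
for the command line, reading/writing the standard text formats and a JSON
run report that records every parameter and count needed to re-execute the
run.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import networkx as nx

from . import ppi_io, synth
from .classify import ClassifierConfig, build_training_matrix, filter_candidates, \
    train_classifier
from .embedding import EmbeddingMatrix, Node2VecParams, simulate_walks, \
    train_embeddings
from .evaluate import match_and_score
from .ppi_io import Complex
from .refine import RefinementConfig, refine, weight_edges
from .slpc import LabeledComplexSet, detect_candidates, sample_negative_subgraphs, \
    train_scorer

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "stage_seed", "run_pipeline",
           "run_pipeline_files"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a reproducible, stage-specific 31-bit seed from the global seed."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """All knobs of a full detection run."""

    node2vec: Node2VecParams = field(default_factory=Node2VecParams)
    refinement: Optional[RefinementConfig] = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scorer_model: str = "quadratic"
    min_size: Optional[int] = None  # default: size of the smallest positive
    max_size: Optional[int] = None
    tol: float = 1e-6
    n_negatives: Optional[int] = None  # default: one per positive
    intermediate_noise: float = 0.3    # when intermediates are fabricated
    na_thres: float = 0.25
    seed: int = 0


@dataclass
class PipelineResult:
    predicted: List[Complex]
    candidates: List[Complex]
    embeddings: EmbeddingMatrix
    network: nx.Graph
    report: dict

    @property
    def f_score(self) -> float:
        return self.report["evaluate"]["final"]["f_score"]


def run_pipeline(net: nx.Graph, positives: Sequence[Complex],
                 intermediates: Optional[Sequence[Complex]] = None,
                 gold: Optional[Sequence[Complex]] = None,
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full detection pipeline on in-memory inputs.

    ``positives`` are the known complexes used both for training and (unless
    ``gold`` is given) for evaluation.  ``intermediates`` default to the
    positives with 30% of members resampled — the stand-in for an external
    intermediate-quality predictor's output.
    """
    if config is None:
        config = PipelineConfig()
    if gold is None:
        gold = list(positives)
    report: dict = {"config": _config_dict(config)}

    # Stage 1: node embeddings on the original network.
    emb_seed = stage_seed(config.seed, "embed")
    walks = simulate_walks(net, config.node2vec, emb_seed)
    emb = train_embeddings(walks, config.node2vec, emb_seed)
    report["embed"] = {"seed": emb_seed, "n_walks": len(walks),
                       "n_embedded": len(emb), "d": emb.d}

    # Stage 2: similarity weighting and optional filter/augment.
    if config.refinement is not None:
        work_net, refine_report = refine(net, emb, config.refinement)
    else:
        work_net = weight_edges(net, emb)
        refine_report = {"n_edges_in": net.number_of_edges(),
                         "n_edges_removed": 0, "n_edges_added": 0,
                         "n_edges_out": net.number_of_edges()}
    report["refine"] = refine_report

    # Stage 3: SLPC training set and candidate detection.
    if intermediates is None:
        mid_seed = stage_seed(config.seed, "intermediates")
        intermediates = synth.degrade_gold(positives, config.intermediate_noise,
                                           sorted(work_net.nodes()), mid_seed)
    neg_seed = stage_seed(config.seed, "negatives")
    n_neg = config.n_negatives if config.n_negatives is not None else len(positives)
    negatives = sample_negative_subgraphs(
        work_net, size_pool=[len(cx) for cx in positives], count=n_neg,
        seed=neg_seed, positives=positives)
    labeled = LabeledComplexSet(positives=list(positives),
                                intermediates=list(intermediates),
                                negatives=negatives)
    scorer = train_scorer(labeled, work_net, seed=stage_seed(config.seed, "slpc"),
                          model=config.scorer_model)
    # The minimum reportable size follows the gold standard, as the size cap
    # does: nothing smaller than the smallest known complex is a candidate.
    min_size = config.min_size
    if min_size is None:
        min_size = min(len(cx) for cx in positives)
    candidates = detect_candidates(work_net, scorer, min_size=min_size,
                                   max_size=config.max_size, tol=config.tol)
    report["slpc"] = {
        "n_positives": len(positives), "n_intermediates": len(intermediates),
        "n_negatives": len(negatives), "train_r2": scorer.train_r2,
        "n_candidates": len(candidates),
    }

    # Stage 4: RF filtering on complex vectors.
    rows, labels = build_training_matrix(labeled, emb,
                                         config.classifier.vector_strategy)
    clf_config = ClassifierConfig(
        model=config.classifier.model, n_trees=config.classifier.n_trees,
        seed=stage_seed(config.seed, "classify"),
        vector_strategy=config.classifier.vector_strategy)
    model = train_classifier(rows, labels, clf_config)
    predicted = filter_candidates(candidates, emb, model,
                                  clf_config.vector_strategy)
    report["classify"] = {"model": clf_config.model,
                          "n_trees": clf_config.n_trees,
                          "seed": clf_config.seed,
                          "n_predicted": len(predicted)}

    # Stage 5: evaluation against the gold standard.
    eval_slpc = match_and_score(candidates, gold, config.na_thres)
    eval_final = match_and_score(predicted, gold, config.na_thres)
    report["evaluate"] = {
        "na_thres": config.na_thres,
        "slpc_only": _eval_summary(eval_slpc),
        "final": _eval_summary(eval_final),
    }
    return PipelineResult(predicted=predicted, candidates=candidates,
                          embeddings=emb, network=work_net, report=report)


def _eval_summary(rep) -> dict:
    d = rep.to_dict()
    d.pop("pair_matches")
    return d


def _config_dict(config: PipelineConfig) -> dict:
    d = {
        "node2vec": asdict(config.node2vec),
        "refinement": asdict(config.refinement) if config.refinement else None,
        "classifier": asdict(config.classifier),
        "scorer_model": config.scorer_model,
        "min_size": config.min_size,
        "max_size": config.max_size,
        "tol": config.tol,
        "n_negatives": config.n_negatives,
        "intermediate_noise": config.intermediate_noise,
        "na_thres": config.na_thres,
        "seed": config.seed,
    }
    return d


def run_pipeline_files(edges_path, pos_path, out_dir, mid_path=None,
                       gold_path=None, config: Optional[PipelineConfig] = None
                       ) -> PipelineResult:
    """File-based pipeline run: reads text inputs, writes outputs + report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net = ppi_io.read_edge_list(edges_path)
    positives = ppi_io.read_complexes(pos_path)
    intermediates = ppi_io.read_complexes(mid_path) if mid_path else None
    gold = ppi_io.read_complexes(gold_path) if gold_path else None
    result = run_pipeline(net, positives, intermediates=intermediates,
                          gold=gold, config=config)
    ppi_io.write_complexes(result.predicted, out_dir / "predicted.txt")
    ppi_io.write_complexes(result.candidates, out_dir / "candidates.txt")
    result.embeddings.save(out_dir / "embeddings.txt")
    with (out_dir / "report.json").open("w") as fh:
        json.dump(result.report, fh, indent=2)
    return result
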