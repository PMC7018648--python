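"""End-to-end sweep: corpus -> network -> per-threshold communities ->
consensus matrix -> core set -> candidate ranking."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import __version__
from .commdetect import DetectionConfig, Partition, detect_communities
from .consensus import (
    CooccurrenceMatrix,
    CoreSet,
    cooccurrence_matrix,
    extract_core,
)
from .corpus import RecipeCorpus
from .netbuild import (
    NormalizationParams,
    ThresholdSchedule,
    WeightedNetwork,
    apply_threshold,
    build_network,
    fragmentation_profile,
    normalize_weights,
    select_thresholds,
)
from .rank import RecipeRanking, rank_recipes


@dataclass
class PipelineResult:
    """Everything a sweep produces, plus a provenance record."""

    network: WeightedNetwork
    schedule: ThresholdSchedule
    partitions: List[Partition]
    matrix: CooccurrenceMatrix
    core: CoreSet
    ranking: Optional[RecipeRanking]
    provenance: Dict = field(default_factory=dict)

    def write_provenance(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def run_pipeline(
    corpus: RecipeCorpus,
    min_recipes: int = 2,
    epsilon: float = 0.01,
    thresholds: Optional[Sequence[float]] = None,
    stop_min_nodes: int = 10,
    n_runs: int = 100,
    seed: int = 0,
    single_top_fraction: float = 0.05,
    min_score: Optional[int] = 1,
) -> PipelineResult:
    """Run the full analysis on a corpus.

    If ``thresholds`` is None a schedule is selected from the fragmentation
    profile (0 plus every point where nonisolated nodes drop, stopping
    before fewer than ``stop_min_nodes`` remain).  Each threshold's network
    gets an independent best-of-``n_runs`` community detection; seeds are
    derived per threshold so runs are reproducible and independent.
    """
    net = normalize_weights(
        build_network(corpus, min_recipes=min_recipes),
        NormalizationParams(epsilon=epsilon),
    )
    if thresholds is None:
        profile = fragmentation_profile(net)
        schedule = select_thresholds(profile, stop_min_nodes=stop_min_nodes)
    else:
        schedule = ThresholdSchedule(thresholds=tuple(thresholds))

    partitions = []
    for k, t in enumerate(schedule):
        sub = apply_threshold(net, t)
        cfg = DetectionConfig(n_runs=n_runs, seed=seed + 7919 * (k + 1))
        partitions.append(detect_communities(sub, cfg))

    matrix = cooccurrence_matrix(partitions, net.nodes)
    core = extract_core(matrix, single_top_fraction=single_top_fraction)
    ranking = (
        rank_recipes(corpus, core, min_score=min_score)
        if min_score is not None
        else None
    )
    provenance = {
        "remedynet_version": __version__,
        "python": platform.python_version(),
        "n_recipes": len(corpus),
        "min_recipes": min_recipes,
        "epsilon": epsilon,
        "thresholds": list(schedule),
        "n_runs": n_runs,
        "seed": seed,
        "single_top_fraction": single_top_fraction,
        "min_score": min_score,
        "modularity_per_threshold": [p.q for p in partitions],
        "n_communities_per_threshold": [p.n_communities for p in partitions],
    }
    return PipelineResult(
        network=net,
        schedule=schedule,
        partitions=partitions,
        matrix=matrix,
        core=core,
        ranking=ranking,
        provenance=provenance,
    )
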