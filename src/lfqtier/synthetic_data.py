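"""Synthetic LFQ data with the structure the tier statistics assume.

The generator emulates a bait-vs-control pull-down experiment: protein
log2 baselines are Gaussian between proteins, replicate noise is Gaussian
within proteins, a minority of truly enriched proteins receive an
additive log2 effect in the bait samples, and each cell can drop out with
a probability that rises logistically as the underlying intensity falls
(missing-not-at-random, the dominant missingness mechanism of label-free
MS). Optionally one enriched protein is spiked at twice the enrichment
effect to emulate the bait fusion protein dominating the ranking.

A companion generator builds miniature random ontologies and annotation
maps with one deliberately enriched term, for exercising the GO stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from lfqtier.errors import ValidationError
from lfqtier.go_enrichment import GoDag
from lfqtier.io import LfqMatrix, SampleDesign


@dataclass
class SimulationConfig:
    """Parameters of the synthetic LFQ experiment.

    Defaults mirror a 6+6 replicate pull-down with log2 intensities
    centred at 25 (typical MaxQuant LFQ magnitudes), between-protein SD
    2, replicate noise SD 0.5, and a +4 log2 enrichment effect. The MNAR
    logistic has its midpoint two between-protein SDs below the baseline
    (21 log2 units) with slope 0.8 per log2 unit, concentrating dropout
    in the low-intensity tail at a realistic overall rate.
    """

    n_proteins: int = 2000
    n_replicates: int = 6
    n_enriched: int = 100
    effect_log2: float = 4.0
    base_mean_log2: float = 25.0
    base_sd_log2: float = 2.0
    noise_sd_log2: float = 0.5
    missing_midpoint_log2: float = 21.0
    missing_slope: float = 0.8
    bait_protein: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enriched > self.n_proteins:
            raise ValidationError("n_enriched must be <= n_proteins")
        if self.n_enriched < 0 or self.n_proteins < 1:
            raise ValidationError("protein counts must be non-negative")
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates per group")
        if min(self.base_sd_log2, self.noise_sd_log2) <= 0:
            raise ValidationError("standard deviations must be > 0")
        if self.bait_protein and self.n_enriched == 0:
            raise ValidationError(
                "bait_protein requires n_enriched >= 1 (the bait is one "
                "of the enriched proteins)"
            )


@dataclass
class GroundTruth:
    """Truth labels of the simulation: which proteins carry the effect."""

    enriched_ids: set[str]
    bait_id: str | None = None

    def __post_init__(self) -> None:
        if self.bait_id is not None and self.bait_id not in self.enriched_ids:
            raise ValidationError("bait must be one of the enriched proteins")


def simulate_lfq(
    config: SimulationConfig,
) -> tuple[LfqMatrix, SampleDesign, GroundTruth]:
    """Draw one synthetic LFQ experiment.

    Per-protein baseline mu_p ~ N(base_mean, base_sd); observed log2
    intensity = mu_p + effect * 1[enriched and bait sample]
    + N(0, noise_sd); the spiked bait (first enriched protein) uses
    2 * effect. Each cell is independently missing with probability
    logistic((midpoint - intensity) * slope). Intensities are exported
    on the linear scale; identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, r = config.n_proteins, config.n_replicates

    protein_ids = [f"SYN{i:05d}" for i in range(n)]
    gene_symbols = [f"Gsyn{i}" for i in range(n)]

    enriched_idx = rng.choice(n, size=config.n_enriched, replace=False)
    effect = np.zeros(n)
    effect[enriched_idx] = config.effect_log2
    bait_id = None
    if config.bait_protein:
        bait_idx = int(enriched_idx[0])
        effect[bait_idx] = 2.0 * config.effect_log2
        bait_id = protein_ids[bait_idx]

    baseline = rng.normal(config.base_mean_log2, config.base_sd_log2, size=n)
    noise = rng.normal(0.0, config.noise_sd_log2, size=(n, 2 * r))
    log2_int = baseline[:, None] + noise
    log2_int[:, :r] += effect[:, None]  # bait columns first

    p_missing = 1.0 / (
        1.0
        + np.exp(
            -(config.missing_midpoint_log2 - log2_int) * config.missing_slope
        )
    )
    missing = rng.random(size=log2_int.shape) < p_missing

    intensities = np.exp2(log2_int)
    intensities[missing] = np.nan

    bait_names = [f"bait_{i + 1}" for i in range(r)]
    ctrl_names = [f"control_{i + 1}" for i in range(r)]
    design = SampleDesign(
        assignments={
            **{name: ("bait", i + 1) for i, name in enumerate(bait_names)},
            **{name: ("control", i + 1) for i, name in enumerate(ctrl_names)},
        }
    )
    matrix = LfqMatrix(
        protein_ids=protein_ids,
        gene_symbols=gene_symbols,
        intensities=intensities,
        sample_names=bait_names + ctrl_names,
    )
    truth = GroundTruth(
        enriched_ids={protein_ids[i] for i in enriched_idx},
        bait_id=bait_id,
    )
    return matrix, design, truth


def write_protein_groups(matrix: LfqMatrix, path) -> None:
    """Export a matrix as the proteinGroups-style TSV that the reader accepts.

    Missing intensities are written as 0, following the MaxQuant
    convention the reader reverses.
    """
    data = {"Protein IDs": matrix.protein_ids,
            "Gene names": matrix.gene_symbols}
    filled = np.nan_to_num(matrix.intensities, nan=0.0)
    for j, name in enumerate(matrix.sample_names):
        data[f"LFQ intensity {name}"] = filled[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format="%.8g")


def write_design(design: SampleDesign, path) -> None:
    """Export a design as the 3-column TSV the reader accepts."""
    rows = [
        {"sample": name, "group": grp, "replicate": idx}
        for name, (grp, idx) in design.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(truth: GroundTruth, path) -> None:
    """Export truth labels as a 2-column TSV (protein_id, role)."""
    rows = [
        {"protein_id": pid,
         "role": "bait" if pid == truth.bait_id else "enriched"}
        for pid in sorted(truth.enriched_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def simulate_ontology(
    n_terms: int,
    n_genes: int,
    enriched_term_fraction: float,
    seed: int = 0,
    background_rate: float = 0.1,
    study_fraction: float = 0.2,
) -> tuple[GoDag, dict[str, set[str]], set[str]]:
    """Random tree-shaped mini-ontology with one enriched term.

    Builds a single-namespace rooted tree of ``n_terms`` terms (each
    non-root term gets a uniformly random parent among earlier terms) and
    annotates genes directly to random terms at ``background_rate``. One
    designated non-root term annotates study-set genes at
    ``background_rate + enriched_term_fraction``, so with
    enriched_term_fraction = 0 the study set matches the background in
    expectation. Deterministic under the seed.
    """
    if n_terms < 3:
        raise ValidationError("need n_terms >= 3")
    if n_genes < 2:
        raise ValidationError("need n_genes >= 2")
    if not 0 <= enriched_term_fraction <= 1 - background_rate:
        raise ValidationError(
            "enriched_term_fraction must lie in [0, 1 - background_rate]"
        )
    rng = np.random.default_rng(seed)

    terms = [f"SYNGO:{i:07d}" for i in range(n_terms)]
    graph = nx.MultiDiGraph()
    graph.add_node(
        terms[0], name="synthetic root", namespace="biological_process"
    )
    for i in range(1, n_terms):
        parent = terms[int(rng.integers(0, i))]
        graph.add_node(
            terms[i], name=f"synthetic term {i}",
            namespace="biological_process",
        )
        graph.add_edge(terms[i], parent, key="is_a")
    dag = GoDag(graph=graph)

    genes = [f"g{i:04d}" for i in range(n_genes)]
    n_study = max(2, int(round(study_fraction * n_genes)))
    study = set(rng.choice(genes, size=n_study, replace=False).tolist())
    enriched_term = terms[1 + int(rng.integers(0, n_terms - 1))]

    direct: dict[str, set[str]] = {g: set() for g in genes}
    for g in genes:
        for t in terms[1:]:
            rate = background_rate
            if t == enriched_term and g in study:
                rate += enriched_term_fraction
            if rng.random() < rate:
                direct[g].add(t)
        if not direct[g]:
            direct[g].add(terms[0])  # every gene annotated somewhere
    return dag, direct, study
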