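"""GO-term over-representation with classic per-term Fisher tests.

The ontology is loaded from OBO 1.2 (is_a and part_of edges only),
annotations are propagated up the graph under the true-path rule, and
each term is tested independently with the one-sided upper hypergeometric
tail ("classic" algorithm). Terms annotating fewer than ``min_node_size``
population genes are excluded before testing; raw Fisher p-values are
filtered at alpha with no multiple-testing correction. The enrichment
ratio (study annotation frequency over population annotation frequency)
accompanies each tested term for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from lfqtier.errors import ValidationError

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")
_KEPT_RELATIONS = ("is_a", "part_of")


@dataclass
class GoDag:
    """Ontology term graph with child -> parent is_a / part_of edges."""

    graph: nx.MultiDiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValidationError("ontology graph contains a cycle")

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", "")

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via child -> parent edges."""
        if term not in self.graph:
            raise ValidationError(f"unknown ontology term {term!r}")
        return nx.descendants(self.graph, term)


@dataclass
class AnnotationMap:
    """Direct and ancestry-closed gene -> term annotations."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    """Per-term over-representation statistics."""

    term: str
    name: str
    namespace: str
    study_count: int
    pop_count: int
    fisher_p: float
    enrichment_ratio: float


def hypergeom_upper_tail(k, N: int, K: int, n: int):
    """P(X >= k) for X ~ Hypergeom(N, K, n): the one-sided Fisher p-value.

    ``k`` may be a scalar or an array of counts; the result matches.
    """
    import numpy as np

    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(
            f"invalid hypergeometric parameters N={N}, K={K}, n={n}"
        )
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValidationError("count k must be >= 0")
    tail = np.minimum(hypergeom.sf(k_arr - 1, N, K, n), 1.0)
    return float(tail) if np.isscalar(k) else tail


def load_obo(path) -> GoDag:
    """Parse an OBO 1.2 ontology, keeping is_a and part_of edges.

    Obsolete terms are excluded. An edge pointing at a term id with no
    [Term] stanza of its own is a referential-integrity error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    pruned = nx.MultiDiGraph()
    pruned.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        if key in _KEPT_RELATIONS:
            pruned.add_edge(child, parent, key=key)
    for node, data in pruned.nodes(data=True):
        if "name" not in data:
            raise ValidationError(
                f"edge references undeclared ontology term {node!r}"
            )
    return GoDag(graph=pruned)


def load_annotations(path, gaf: bool | None = None) -> dict[str, set[str]]:
    """Read gene -> term annotations from GAF 2.x or a 2-column TSV.

    For GAF input, columns 2 (gene symbol) and 5 (GO id) are used and
    comment lines starting with ``!`` are skipped. When ``gaf`` is None
    the format is sniffed from the first non-empty line.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if gaf is None:
        gaf = bool(lines) and (
            lines[0].startswith("!") or len(lines[0].split("\t")) > 4
        )
    direct: dict[str, set[str]] = {}
    for ln in lines:
        if ln.startswith("!") or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if gaf:
            gene, term = parts[2], parts[4]
        else:
            gene, term = parts[0], parts[1]
        direct.setdefault(gene, set()).add(term)
    return direct


def propagate(direct: dict[str, set[str]], dag: GoDag) -> AnnotationMap:
    """Close annotations under ancestry (the true-path rule)."""
    ancestor_cache: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for term in terms:
            if term not in dag.graph:
                raise ValidationError(
                    f"gene {gene!r} annotated to unknown term {term!r}"
                )
            if term not in ancestor_cache:
                ancestor_cache[term] = dag.ancestors(term)
            closed.add(term)
            closed |= ancestor_cache[term]
        propagated[gene] = closed
    return AnnotationMap(direct={g: set(t) for g, t in direct.items()},
                         propagated=propagated)


def fisher_enrichment(
    study: set[str],
    population: set[str],
    annotations: AnnotationMap,
    dag: GoDag,
    min_node_size: int = 3,
    alpha: float = 0.05,
    namespace: str | None = None,
    return_all: bool = False,
) -> list[EnrichmentResult]:
    """Classic per-term one-sided Fisher (hypergeometric) enrichment.

    For each term with at least ``min_node_size`` annotated population
    genes, the p-value is P(X >= study_count) with
    X ~ Hypergeom(N=|population|, K=pop_count, n=|study|). Unannotated
    population genes stay in N. Results are sorted by ascending p and,
    unless ``return_all``, filtered to fisher_p <= alpha.
    """
    study = set(study)
    population = set(population)
    if not study:
        raise ValidationError("study set is empty")
    if not study <= population:
        extra = sorted(study - population)[:5]
        raise ValidationError(
            f"study set is not contained in the population; e.g. {extra}"
        )
    if min_node_size < 1:
        raise ValidationError("min_node_size must be >= 1")

    pop_genes_per_term: dict[str, int] = {}
    study_genes_per_term: dict[str, int] = {}
    for gene in population:
        for term in annotations.propagated.get(gene, ()):
            pop_genes_per_term[term] = pop_genes_per_term.get(term, 0) + 1
            if gene in study:
                study_genes_per_term[term] = (
                    study_genes_per_term.get(term, 0) + 1
                )

    N, n = len(population), len(study)
    results = []
    for term, K in pop_genes_per_term.items():
        if K < min_node_size:
            continue
        if namespace is not None and dag.namespace(term) != namespace:
            continue
        k = study_genes_per_term.get(term, 0)
        p = hypergeom_upper_tail(k, N, K, n)
        ratio = (k / n) / (K / N)
        results.append(
            EnrichmentResult(
                term=term,
                name=dag.name(term),
                namespace=dag.namespace(term),
                study_count=k,
                pop_count=K,
                fisher_p=min(p, 1.0),
                enrichment_ratio=ratio,
            )
        )
    results.sort(key=lambda r: (r.fisher_p, r.term))
    if not return_all:
        results = [r for r in results if r.fisher_p <= alpha]
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results for TSV export."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "name": [r.name for r in results],
            "namespace": [r.namespace for r in results],
            "study_count": [r.study_count for r in results],
            "pop_count": [r.pop_count for r in results],
            "fisher_p": [r.fisher_p for r in results],
            "enrichment_ratio": [r.enrichment_ratio for r in results],
        }
    )
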