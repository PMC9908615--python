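"""Cross-study overlap scoring of a candidate list against reference gene lists.

A candidate protein's evidence count is the number of reference datasets
(published ciliary screens, each a set of human gene symbols) that
contain it; the headline summary is the fraction of candidates found in
at least one dataset. Mouse candidates are first translated to human
symbols through an explicit homolog table — matching is by exact
upper-cased gene symbol, so identifier-type mixing must be resolved
upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from lfqtier.errors import ValidationError


@dataclass
class ReferenceCatalog:
    """Named reference gene lists (dataset name -> set of upper-cased symbols)."""

    datasets: dict[str, set[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.datasets = {
            name: {s.upper() for s in genes}
            for name, genes in self.datasets.items()
        }

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @classmethod
    def from_directory(cls, path) -> "ReferenceCatalog":
        """Load one dataset per ``*.tsv`` file; filename stem = dataset name.

        Each file is a single-column gene list (optional ``gene`` header,
        ``#`` comments ignored).
        """
        path = Path(path)
        files = sorted(path.glob("*.tsv"))
        if not files:
            raise ValidationError(f"no .tsv gene lists found in {path}")
        datasets = {}
        for f in files:
            genes = set()
            for ln in f.read_text().splitlines():
                ln = ln.strip()
                if not ln or ln.startswith("#") or ln.lower() == "gene":
                    continue
                genes.add(ln.split("\t")[0].upper())
            datasets[f.stem] = genes
        return cls(datasets=datasets)


@dataclass
class HomologMap:
    """Cross-species symbol translation table (source -> target symbol)."""

    pairs: dict[str, str]
    source_species: str = "mouse"

    @classmethod
    def from_tsv(cls, path, source_species: str = "mouse") -> "HomologMap":
        """Load a 3-column TSV (source_symbol, target_symbol, species)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["source", "target", "species"],
            dtype=str,
            comment="#",
        )
        if df["source"].str.lower().iloc[0:1].eq("source_symbol").any():
            df = df.iloc[1:]
        df = df[df["species"].str.lower() == source_species.lower()]
        return cls(
            pairs=dict(zip(df["source"], df["target"])),
            source_species=source_species,
        )


@dataclass
class OverlapReport:
    """Per-candidate evidence counts and the previously-identified fraction."""

    candidates: list[str]
    evidence_count: list[int]
    previously_identified: list[bool]
    fraction_previously_identified: float
    most_frequent: list[str]
    max_evidence: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate": self.candidates,
                "evidence_count": self.evidence_count,
                "previously_identified": self.previously_identified,
            }
        )


def translate_homologs(
    genes: list[str], homolog_map: HomologMap
) -> tuple[list[str], list[bool]]:
    """Substitute mapped symbols; keep unmapped verbatim with a flag.

    Output order equals input order; the second return value flags the
    symbols that had no entry in the table.
    """
    translated, unmapped = [], []
    for g in genes:
        if g in homolog_map.pairs:
            translated.append(homolog_map.pairs[g])
            unmapped.append(False)
        else:
            translated.append(g)
            unmapped.append(True)
    return translated, unmapped


def overlap_report(
    candidates: list[str], catalog: ReferenceCatalog
) -> OverlapReport:
    """Score candidates against the catalog.

    evidence_count = number of datasets containing the (upper-cased)
    candidate; previously_identified = evidence_count >= 1. The
    most-frequent sub-report lists all candidates at the maximum
    evidence count (ties included).
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    counts = [
        sum(1 for genes in catalog.datasets.values() if c.upper() in genes)
        for c in candidates
    ]
    prev = [c >= 1 for c in counts]
    fraction = sum(prev) / len(candidates)
    max_evidence = max(counts) if counts else 0
    most_frequent = (
        [c for c, n in zip(candidates, counts) if n == max_evidence]
        if max_evidence > 0
        else []
    )
    return OverlapReport(
        candidates=list(candidates),
        evidence_count=counts,
        previously_identified=prev,
        fraction_previously_identified=fraction,
        most_frequent=most_frequent,
        max_evidence=max_evidence,
    )
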