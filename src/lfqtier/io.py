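"""Reading and writing protein-group quantification tables.

Consumes MaxQuant-style ``proteinGroups.txt`` layouts: one row per protein
group, one ``LFQ intensity <sample>`` column per sample, and the
conventional QC marker columns (``Reverse``, ``Potential contaminant``,
``Only identified by site``). Zero or empty intensity cells are treated as
missing — MaxQuant writes 0 for proteins it could not quantify in a run,
and a true zero abundance is not observable on the log-intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lfqtier.errors import FormatError, ValidationError

#: marker columns recognised by read_protein_groups, in (column, flag) form
_QC_COLUMNS = {
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
    "Only identified by site": "site_only",
}

DEFAULT_INTENSITY_PREFIX = "LFQ intensity "


@dataclass
class LfqMatrix:
    """Proteins x samples LFQ intensity table.

    Attributes
    ----------
    protein_ids : list of str
        Unique protein-group identifiers (one per row).
    gene_symbols : list of str
        One gene symbol per protein; may be the empty string.
    intensities : ndarray of float, shape (n_proteins, n_samples)
        Linear-scale intensities; missing values are NaN. Stored values
        are either NaN or strictly positive.
    sample_names : list of str
        Ordered, unique sample names (intensity column suffixes).
    qc_flags : DataFrame
        Boolean columns ``reverse``, ``contaminant``, ``site_only``
        indexed like ``protein_ids``.
    """

    protein_ids: list[str]
    gene_symbols: list[str]
    intensities: np.ndarray
    sample_names: list[str]
    qc_flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, m = len(self.protein_ids), len(self.sample_names)
        if self.qc_flags is None:
            self.qc_flags = pd.DataFrame(
                False,
                index=range(n),
                columns=["reverse", "contaminant", "site_only"],
            )
        if self.intensities.shape != (n, m):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not "
                f"match {n} proteins x {m} samples"
            )
        if len(self.gene_symbols) != n:
            raise ValidationError("one gene symbol per protein required")
        if len(set(self.protein_ids)) != n:
            dup = _first_duplicate(self.protein_ids)
            raise ValidationError(f"duplicate protein identifier: {dup!r}")
        if len(set(self.sample_names)) != m:
            raise ValidationError("sample names must be unique")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities <= 0):
                raise ValidationError(
                    "stored intensities must be missing (NaN) or > 0"
                )

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def sample_index(self, name: str) -> int:
        try:
            return self.sample_names.index(name)
        except ValueError:
            raise ValidationError(f"sample {name!r} not in matrix") from None

    def subset(self, row_mask: np.ndarray) -> "LfqMatrix":
        """Return a new matrix keeping rows where ``row_mask`` is true."""
        row_mask = np.asarray(row_mask, dtype=bool)
        keep = np.flatnonzero(row_mask)
        return LfqMatrix(
            protein_ids=[self.protein_ids[i] for i in keep],
            gene_symbols=[self.gene_symbols[i] for i in keep],
            intensities=self.intensities[keep],
            sample_names=list(self.sample_names),
            qc_flags=self.qc_flags.iloc[keep].reset_index(drop=True),
        )


@dataclass(frozen=True)
class SampleDesign:
    """Assignment of samples to the bait and control groups.

    ``assignments`` maps sample name -> (group, replicate_index) where
    group is ``"bait"`` or ``"control"`` and replicate indices within a
    group run 1..n without gaps.
    """

    assignments: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        groups: dict[str, list[int]] = {"bait": [], "control": []}
        for sample, (group, idx) in self.assignments.items():
            if group not in groups:
                raise ValidationError(
                    f"sample {sample!r}: group must be 'bait' or 'control', "
                    f"got {group!r}"
                )
            if idx < 1:
                raise ValidationError(
                    f"sample {sample!r}: replicate index must be >= 1"
                )
            groups[group].append(idx)
        for group, indices in groups.items():
            if not indices:
                raise ValidationError(f"group {group!r} has no samples")
            if sorted(indices) != list(range(1, len(indices) + 1)):
                raise ValidationError(
                    f"replicate indices in group {group!r} must be 1..n "
                    f"with no gaps, got {sorted(indices)}"
                )

    def samples(self, group: str) -> list[str]:
        """Sample names of one group, ordered by replicate index."""
        members = [
            (idx, name)
            for name, (g, idx) in self.assignments.items()
            if g == group
        ]
        return [name for _, name in sorted(members)]

    @property
    def bait_samples(self) -> list[str]:
        return self.samples("bait")

    @property
    def control_samples(self) -> list[str]:
        return self.samples("control")


def _first_duplicate(items) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


def read_protein_groups(
    path,
    intensity_prefix: str = DEFAULT_INTENSITY_PREFIX,
    id_column: str = "Protein IDs",
    gene_column: str = "Gene names",
) -> LfqMatrix:
    """Read a MaxQuant-style proteinGroups table into an :class:`LfqMatrix`.

    Intensity columns are every column whose name starts with
    ``intensity_prefix``; the remainder of the column name is the sample
    name. Cells equal to 0, empty, or non-numeric become missing (NaN).
    QC flags are populated from the conventional marker columns when
    present (a non-empty cell, typically ``+``, sets the flag).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    if df.columns.size == 0:
        raise FormatError(f"{path}: missing header row")

    intensity_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not intensity_cols:
        raise FormatError(
            f"{path}: no column starts with intensity prefix "
            f"{intensity_prefix!r}"
        )
    if id_column not in df.columns:
        raise FormatError(f"{path}: missing identifier column {id_column!r}")

    protein_ids = df[id_column].tolist()
    dup = _first_duplicate(protein_ids)
    if dup:
        raise ValidationError(f"duplicate protein identifier: {dup!r}")

    genes = (
        df[gene_column].tolist()
        if gene_column in df.columns
        else [""] * len(df)
    )

    raw = df[intensity_cols].apply(pd.to_numeric, errors="coerce")
    intensities = raw.to_numpy(dtype=float)
    intensities[~(intensities > 0)] = np.nan  # 0, negative, NaN -> missing

    flags = pd.DataFrame(
        False,
        index=range(len(df)),
        columns=["reverse", "contaminant", "site_only"],
    )
    for col, flag in _QC_COLUMNS.items():
        if col in df.columns:
            flags[flag] = df[col].str.strip().ne("").to_numpy()

    sample_names = [c[len(intensity_prefix):] for c in intensity_cols]
    return LfqMatrix(
        protein_ids=protein_ids,
        gene_symbols=genes,
        intensities=intensities,
        sample_names=sample_names,
        qc_flags=flags,
    )


def read_sample_design(path) -> SampleDesign:
    """Read a 3-column TSV (sample, group, replicate) into a design."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: design file needs columns {sorted(required)}"
        )
    assignments = {}
    for _, row in df.iterrows():
        assignments[row["sample"]] = (row["group"], int(row["replicate"]))
    if len(assignments) != len(df):
        raise ValidationError(f"{path}: duplicate sample name in design")
    return SampleDesign(assignments=assignments)


def apply_qc_filter(matrix: LfqMatrix) -> LfqMatrix:
    """Drop rows with any true QC flag (reverse / contaminant / site-only).

    Survivor order is preserved; the operation is idempotent. An
    all-flagged input yields a valid empty matrix which downstream
    statistics reject explicitly.
    """
    flagged = matrix.qc_flags.any(axis=1).to_numpy()
    return matrix.subset(~flagged)


_TIER_COLUMNS = [
    "protein_id",
    "gene_symbol",
    "mean_log2_ratio",
    "signa_p",
    "signa_q",
    "welch_p",
    "welch_q",
    "tier",
]


def write_tier_table(table, path) -> None:
    """Serialise a tier table to TSV with >= 6 significant digits.

    One row per protein: identifier, gene symbol, mean log2 ratio,
    Significance A p and q, Welch p and q, tier label. Round-trips
    through :func:`read_tier_table` without loss of tier labels.
    """
    df = table.to_frame() if hasattr(table, "to_frame") else table
    df = df[_TIER_COLUMNS]
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    except OSError as exc:
        raise IOError(f"cannot write tier table to {path}: {exc}") from exc


def read_tier_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_tier_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "tier": str})
    missing = set(_TIER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing tier-table columns {missing}")
    df["gene_symbol"] = df["gene_symbol"].fillna("").astype(str)
    return df
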