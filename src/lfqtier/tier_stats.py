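"""Per-protein enrichment statistics and the nested tier classification.

The workflow mirrors standard bait-vs-control label-free proteomics
practice:

1. *Presence filter*: a protein must be quantified in at least a fraction
   (default 2/3) of the bait replicates; control samples are never counted.
   With six replicates the threshold resolves to four.
2. *Significance A*: each protein's summary log2(bait/control) ratio is
   standardised against the asymmetric robust spread of the whole ratio
   distribution — the 15.87th, 50th and 84.13th percentiles, which for a
   Gaussian sit at the mean and +/- one standard deviation — and converted
   to a one-sided upper normal tail probability. Ratios at or below the
   median get p = 1: only enrichment can reach significance.
3. *Welch stage*: a one-sided t-test of the per-replicate ratios against
   zero (the default, equivalent to a paired t-test on log intensities),
   or alternatively a one-sided two-sample Welch test on the log
   intensities.
4. Both p-vectors are Benjamini-Hochberg adjusted over the
   presence-passing set, and the nested tiers assigned: Tier 3 = presence
   only, Tier 2 = presence + Significance A q <= alpha, Tier 1 = Tier 2 +
   Welch q <= alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from lfqtier.errors import DegeneracyError, ValidationError
from lfqtier.io import LfqMatrix, SampleDesign

TIER_LABELS = ("tier1", "tier2", "tier3", "none")

# percentile anchors: Phi(-1), median, Phi(1) of a standard normal
_P_LO, _P_MID, _P_HI = 15.87, 50.0, 84.13


@dataclass
class RatioTable:
    """Per-protein log2(bait/control) ratios.

    ``replicate_log2_ratios`` has one column per replicate pair (pairing
    by replicate index) or per bait sample (ratio-of-means pairing keeps
    the per-pair matrix for the Welch stage); missing entries are NaN.
    ``summary_ratio`` is the scalar ratio fed to Significance A.
    """

    protein_ids: list[str]
    replicate_log2_ratios: np.ndarray
    summary_ratio: np.ndarray
    n_present_bait: np.ndarray
    bait_log2: np.ndarray
    control_log2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        if not (
            len(self.summary_ratio)
            == len(self.n_present_bait)
            == self.replicate_log2_ratios.shape[0]
            == n
        ):
            raise ValidationError("ratio table field lengths disagree")


@dataclass(frozen=True)
class SignAParams:
    """Percentile anchors of the Significance A statistic.

    r_minus1, r0, r1 are the 15.87th, 50th and 84.13th percentiles of the
    finite summary ratios: the robust analogues of (mean - sd), mean, and
    (mean + sd).
    """

    r_minus1: float
    r0: float
    r1: float

    def __post_init__(self) -> None:
        if not (self.r_minus1 <= self.r0 <= self.r1):
            raise ValidationError(
                "percentile anchors must satisfy r_minus1 <= r0 <= r1"
            )


@dataclass
class TierTable:
    """Per-protein statistics and exclusive tier labels."""

    protein_ids: list[str]
    gene_symbols: list[str]
    mean_log2_ratio: np.ndarray
    presence_pass: np.ndarray
    signa_p: np.ndarray
    signa_q: np.ndarray
    welch_p: np.ndarray
    welch_q: np.ndarray
    tier: np.ndarray  # array of str, one of TIER_LABELS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "gene_symbol": self.gene_symbols,
                "mean_log2_ratio": self.mean_log2_ratio,
                "presence_pass": self.presence_pass,
                "signa_p": self.signa_p,
                "signa_q": self.signa_q,
                "welch_p": self.welch_p,
                "welch_q": self.welch_q,
                "tier": self.tier,
            }
        )

    def tier_ids(self, label: str) -> list[str]:
        return [
            pid
            for pid, t in zip(self.protein_ids, self.tier)
            if t == label
        ]

    def tier_genes(self, label: str) -> list[str]:
        return [
            g
            for g, t in zip(self.gene_symbols, self.tier)
            if t == label and g
        ]

    def counts(self) -> dict[str, int]:
        return {
            label: int(np.sum(self.tier == label)) for label in TIER_LABELS
        }


def _group_intensities(
    matrix: LfqMatrix, design: SampleDesign, group: str
) -> np.ndarray:
    samples = design.samples(group)
    missing = [s for s in samples if s not in matrix.sample_names]
    if missing:
        raise ValidationError(
            f"design references samples absent from matrix: {missing}"
        )
    cols = [matrix.sample_index(s) for s in samples]
    return matrix.intensities[:, cols]


def presence_filter(
    matrix: LfqMatrix, design: SampleDesign, fraction: float = 2.0 / 3.0
) -> np.ndarray:
    """Boolean mask: quantified in >= ceil(fraction * n_bait) bait samples.

    Control samples are never counted. With the default 2/3 and six bait
    replicates the threshold is four.
    """
    if matrix.n_proteins == 0:
        raise ValidationError("empty matrix: nothing to filter")
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    bait = _group_intensities(matrix, design, "bait")
    n_bait = bait.shape[1]
    # small epsilon guards float artefacts like (2/3)*6 = 3.9999999999999996
    threshold = math.ceil(fraction * n_bait - 1e-9)
    return np.sum(~np.isnan(bait), axis=1) >= threshold


def compute_ratios(
    matrix: LfqMatrix,
    design: SampleDesign,
    pairing: str = "by_index",
    imputation: str = "none",
) -> RatioTable:
    """Per-replicate and summary log2(bait/control) ratios.

    pairing="by_index" pairs bait replicate i with control replicate i;
    a replicate ratio is missing if either side is missing (after the
    imputation policy) and the summary ratio is the mean of the present
    replicate ratios. pairing="ratio_of_means" sets the summary to
    mean(log2 bait present) - mean(log2 control present).

    imputation="global_min_shift" deterministically replaces missing
    cells with (per-sample minimum log2 intensity - 1) before pairing.
    """
    if pairing not in ("by_index", "ratio_of_means"):
        raise ValidationError(f"unknown pairing {pairing!r}")
    if imputation not in ("none", "global_min_shift"):
        raise ValidationError(f"unknown imputation {imputation!r}")

    bait = _group_intensities(matrix, design, "bait")
    control = _group_intensities(matrix, design, "control")

    with np.errstate(divide="ignore", invalid="ignore"):
        bait_log2 = np.log2(bait)
        control_log2 = np.log2(control)
    n_present_bait = np.sum(~np.isnan(bait_log2), axis=1)

    if imputation == "global_min_shift":
        bait_log2 = _impute_min_shift(bait_log2)
        control_log2 = _impute_min_shift(control_log2)

    n_pairs = min(bait_log2.shape[1], control_log2.shape[1])
    replicate = bait_log2[:, :n_pairs] - control_log2[:, :n_pairs]

    with np.errstate(invalid="ignore"):
        if pairing == "by_index":
            any_pair = np.any(~np.isnan(replicate), axis=1)
            summary = np.full(matrix.n_proteins, np.nan)
            summary[any_pair] = np.nanmean(replicate[any_pair], axis=1)
        else:
            bait_mean = _nanmean_or_nan(bait_log2)
            ctrl_mean = _nanmean_or_nan(control_log2)
            summary = bait_mean - ctrl_mean

    return RatioTable(
        protein_ids=list(matrix.protein_ids),
        replicate_log2_ratios=replicate,
        summary_ratio=summary,
        n_present_bait=n_present_bait,
        bait_log2=bait_log2,
        control_log2=control_log2,
    )


def _impute_min_shift(log2_block: np.ndarray) -> np.ndarray:
    out = log2_block.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        miss = np.isnan(col)
        if miss.all():
            continue
        col[miss] = np.nanmin(col) - 1.0
    return out


def _nanmean_or_nan(block: np.ndarray) -> np.ndarray:
    present = ~np.isnan(block)
    out = np.full(block.shape[0], np.nan)
    rows = present.any(axis=1)
    out[rows] = np.nanmean(block[rows], axis=1)
    return out


def signa_params(ratios: RatioTable | np.ndarray) -> SignAParams:
    """Percentile anchors (15.87 / 50 / 84.13) of the finite summary ratios.

    Percentiles use linear interpolation between closest ranks (the
    numpy default); the anchors are interpolation-sensitive, so the
    convention is pinned here.
    """
    values = (
        ratios.summary_ratio
        if isinstance(ratios, RatioTable)
        else np.asarray(ratios, dtype=float)
    )
    finite = values[np.isfinite(values)]
    if finite.size < 3:
        raise ValidationError(
            f"Significance A needs >= 3 finite summary ratios, "
            f"got {finite.size}"
        )
    lo, mid, hi = np.percentile(finite, [_P_LO, _P_MID, _P_HI])
    return SignAParams(r_minus1=float(lo), r0=float(mid), r1=float(hi))


def significance_a(
    ratios: RatioTable | np.ndarray, params: SignAParams
) -> np.ndarray:
    """One-sided (enrichment-only) Significance A p-values.

    For a summary ratio r at or above the median, z = (r - r0) / (r1 - r0)
    and p = erfc(z / sqrt(2)) / 2, the upper tail of a standard normal
    (so p = 0.5 exactly at the median). Strictly below the median p = 1;
    a missing ratio yields NaN.
    """
    if params.r1 <= params.r0:
        raise DegeneracyError(
            "ratio distribution has no upper spread (r1 == r0); "
            "Significance A cannot standardise outliers — check that the "
            "summary ratios are not constant"
        )
    values = (
        ratios.summary_ratio
        if isinstance(ratios, RatioTable)
        else np.asarray(ratios, dtype=float)
    )
    p = np.full(values.shape, np.nan)
    finite = np.isfinite(values)
    z = (values[finite] - params.r0) / (params.r1 - params.r0)
    upper = special.erfc(np.maximum(z, 0.0) / math.sqrt(2.0)) / 2.0
    p[finite] = np.where(z >= 0, upper, 1.0)
    return p


def welch_stage(
    ratios: RatioTable, mode: str = "one_sample_on_ratios"
) -> np.ndarray:
    """One-sided second-stage t-test p-values, one per protein.

    mode="one_sample_on_ratios" (default): upper one-sided one-sample t
    of the per-replicate log2 ratios against 0 with df = k - 1 —
    algebraically a paired t-test on the log intensities. Requires >= 2
    present replicate ratios, else NaN.

    mode="two_sample_welch": upper one-sided Welch two-sample t on the
    log2 bait vs control intensities with Welch-Satterthwaite df.
    Requires >= 2 present values per group, else NaN.

    Zero variance is resolved by the sign of the effect: positive mean
    difference -> p = 0, otherwise p = 1.
    """
    if mode == "one_sample_on_ratios":
        return _one_sample_upper(ratios.replicate_log2_ratios)
    if mode == "two_sample_welch":
        return _welch_upper(ratios.bait_log2, ratios.control_log2)
    raise ValidationError(f"unknown welch mode {mode!r}")


def _one_sample_upper(replicate: np.ndarray) -> np.ndarray:
    n = replicate.shape[0]
    p = np.full(n, np.nan)
    for i in range(n):
        x = replicate[i][~np.isnan(replicate[i])]
        if x.size < 2:
            continue
        mean = x.mean()
        sd = x.std(ddof=1)
        if sd == 0:
            p[i] = 0.0 if mean > 0 else 1.0
            continue
        t = mean / (sd / math.sqrt(x.size))
        p[i] = stats.t.sf(t, df=x.size - 1)
    return p


def _welch_upper(bait: np.ndarray, control: np.ndarray) -> np.ndarray:
    n = bait.shape[0]
    p = np.full(n, np.nan)
    for i in range(n):
        x = bait[i][~np.isnan(bait[i])]
        y = control[i][~np.isnan(control[i])]
        if x.size < 2 or y.size < 2:
            continue
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if vx == 0 and vy == 0:
            p[i] = 0.0 if x.mean() > y.mean() else 1.0
            continue
        res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        p[i] = res.pvalue
    return p


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order.

    NaN (undefined) entries are excluded before correction and returned
    NaN; the effective number of tests m is the number of defined
    p-values. q_i = min over j with p_j >= p_i of (m * p_j / rank_j),
    clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    defined = ~np.isnan(p)
    with np.errstate(invalid="ignore"):
        if np.any((p[defined] < 0) | (p[defined] > 1)):
            raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if defined.sum() > 0:
        q[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return q


def assign_tiers(
    presence: np.ndarray,
    signa_q: np.ndarray,
    welch_q: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Exclusive nested tier labels from the gate sequence.

    none: presence fails. tier3: presence only. tier2: presence and
    Significance A q <= alpha. tier1: additionally Welch q <= alpha.
    Undefined (NaN) q-values never qualify.
    """
    presence = np.asarray(presence, dtype=bool)
    signa_q = np.asarray(signa_q, dtype=float)
    welch_q = np.asarray(welch_q, dtype=float)
    if not (len(presence) == len(signa_q) == len(welch_q)):
        raise ValidationError("tier inputs must have equal length")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    with np.errstate(invalid="ignore"):
        signa_pos = presence & (signa_q <= alpha)
        welch_pos = signa_pos & (welch_q <= alpha)
    tier = np.where(
        welch_pos,
        "tier1",
        np.where(signa_pos, "tier2", np.where(presence, "tier3", "none")),
    )
    return tier.astype(object)


def classify_tiers(
    matrix: LfqMatrix,
    design: SampleDesign,
    presence_fraction: float = 2.0 / 3.0,
    alpha: float = 0.05,
    pairing: str = "by_index",
    welch_mode: str = "one_sample_on_ratios",
    imputation: str = "none",
) -> TierTable:
    """Run the full presence -> SignA -> Welch -> BH -> tier sequence.

    Both p-vectors are BH-corrected over the presence-passing subset
    only, mirroring the sequential gate definition; proteins failing
    presence carry NaN statistics and tier "none".
    """
    presence = presence_filter(matrix, design, presence_fraction)
    ratios = compute_ratios(matrix, design, pairing, imputation)

    # Significance A anchors come from presence-passing proteins: the
    # population whose outliers the statistic is meant to flag.
    passing_summary = np.where(presence, ratios.summary_ratio, np.nan)
    params = signa_params(passing_summary)

    signa_p_all = significance_a(ratios, params)
    welch_p_all = welch_stage(ratios, welch_mode)

    signa_p = np.where(presence, signa_p_all, np.nan)
    welch_p = np.where(presence, welch_p_all, np.nan)
    signa_q = benjamini_hochberg(signa_p)
    welch_q = benjamini_hochberg(welch_p)

    tier = assign_tiers(presence, signa_q, welch_q, alpha)
    return TierTable(
        protein_ids=list(matrix.protein_ids),
        gene_symbols=list(matrix.gene_symbols),
        mean_log2_ratio=ratios.summary_ratio,
        presence_pass=presence,
        signa_p=signa_p,
        signa_q=signa_q,
        welch_p=welch_p,
        welch_q=welch_q,
        tier=tier,
    )
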