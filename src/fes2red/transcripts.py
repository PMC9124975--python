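"""Differential-expression screen for mineral-grown cultures.

The screen asks which genes are up-regulated during growth on pyrite
relative to BOTH soluble-substrate reference conditions.  A gene passes
when, against each reference, p < 0.05 and log2 fold change > 0.5 (strict
inequalities), and its mean normalized abundance in the focal condition
exceeds 0.005 % of the focal total.  Genes are further categorized
four ways for locus-map coloring, and recovered gene sets are tallied for
homolog conservation across reference genomes.

Only the size-factor normalization needed for the abundance threshold is
implemented here (the DESeq2-style median-of-ratios estimator); the DE test
itself is an input boundary — records arrive with LFCs and p-values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

__all__ = [
    "CountMatrix",
    "DERecord",
    "FilterCriteria",
    "median_of_ratios_normalize",
    "abundance_fractions",
    "abundance_fraction",
    "upregulated_screen",
    "categorize_gene",
    "conservation_tally",
    "read_de_records",
    "records_to_frame",
    "read_presence_matrix",
    "read_count_matrix",
]


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample raw counts with sample condition labels."""

    counts: pd.DataFrame  # genes (index) x samples (columns)
    conditions: Mapping[str, str]  # sample -> condition

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        unknown = set(self.counts.columns) - set(self.conditions)
        if unknown:
            raise ValueError(f"samples without condition labels: {sorted(unknown)}")

    def samples_for(self, condition: str) -> list[str]:
        return [
            s for s in self.counts.columns if self.conditions[s] == condition
        ]


@dataclass(frozen=True)
class DERecord:
    """Per-gene DE summary of the focal condition against two references."""

    gene: str
    mean_norm_abundance: float
    lfc_vs_ref1: float
    p_vs_ref1: float
    lfc_vs_ref2: float
    p_vs_ref2: float

    def __post_init__(self) -> None:
        for label, p in (("p_vs_ref1", self.p_vs_ref1),
                         ("p_vs_ref2", self.p_vs_ref2)):
            if math.isnan(p) or not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"record for gene {self.gene!r}: {label}={p} not in [0, 1]"
                )
        if math.isnan(self.mean_norm_abundance) or self.mean_norm_abundance < 0:
            raise ValueError(
                f"record for gene {self.gene!r}: abundance must be >= 0"
            )
        if math.isnan(self.lfc_vs_ref1) or math.isnan(self.lfc_vs_ref2):
            raise ValueError(f"record for gene {self.gene!r}: LFC is NaN")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the up-regulation screen (strict inequalities).

    ``adjust_p=True`` applies a Benjamini-Hochberg correction to each
    reference's p-values across the record set before thresholding; the
    default leaves p-values as given.
    """

    p_max: float = 0.05
    lfc_min: float = 0.5
    abundance_fraction_min: float = 5e-5  # 0.005 %
    adjust_p: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must lie in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not 0.0 <= self.abundance_fraction_min < 1.0:
            raise ValueError("abundance_fraction_min must lie in [0, 1)")


def median_of_ratios_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    Per sample, the size factor is the median over reference genes (those
    with positive counts in every sample) of count / per-gene geometric
    mean across samples; normalized counts are raw / size factor.  Size
    factors are rescaled to unit geometric mean, which leaves ratios
    between samples untouched and makes the estimator exactly idempotent
    (renormalizing a normalized matrix returns all-unit factors).
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "normalization impossible: no gene has positive counts in "
            "every sample"
        )
    log_ref = np.log(arr[positive])
    log_gmean = log_ref.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ref - log_gmean, axis=0)
    log_sf = log_sf - log_sf.mean()  # unit geometric mean
    size_factors = pd.Series(np.exp(log_sf), index=counts.columns)
    normalized = counts / size_factors
    return size_factors, normalized


def abundance_fractions(
    normalized: pd.DataFrame, focal_samples: Sequence[str]
) -> pd.Series:
    """Each gene's share of total mean normalized counts in the focal condition.

    Fractions sum to one across genes.
    """
    focal_means = normalized[list(focal_samples)].mean(axis=1)
    total = focal_means.sum()
    if total <= 0:
        raise ValueError("undefined abundance fraction: focal total is zero")
    return focal_means / total


def abundance_fraction(
    normalized: pd.DataFrame, focal_samples: Sequence[str], gene: str
) -> float:
    fractions = abundance_fractions(normalized, focal_samples)
    if gene not in fractions.index:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    return float(fractions.loc[gene])


def _effective_pvalues(
    records: Sequence[DERecord], criteria: FilterCriteria
) -> dict[str, tuple[float, float]]:
    if not criteria.adjust_p:
        return {r.gene: (r.p_vs_ref1, r.p_vs_ref2) for r in records}
    p1 = false_discovery_control([r.p_vs_ref1 for r in records], method="bh")
    p2 = false_discovery_control([r.p_vs_ref2 for r in records], method="bh")
    return {r.gene: (p1[i], p2[i]) for i, r in enumerate(records)}


def upregulated_screen(
    records: Iterable[DERecord],
    criteria: FilterCriteria = FilterCriteria(),
    fractions: Mapping[str, float] | None = None,
) -> set[str]:
    """Genes up-regulated versus both references that clear the abundance bar.

    A gene passes iff p < p_max AND LFC > lfc_min against each reference
    AND its focal abundance fraction > abundance_fraction_min, all strict.
    ``fractions`` maps gene -> abundance fraction; if omitted, fractions are
    derived by normalizing the records' own mean abundances (valid when the
    records cover every gene of the experiment).
    """
    records = list(records)
    if fractions is None:
        total = sum(r.mean_norm_abundance for r in records)
        if total <= 0:
            raise ValueError("cannot derive abundance fractions: zero total")
        fractions = {r.gene: r.mean_norm_abundance / total for r in records}
    pvals = _effective_pvalues(records, criteria)
    hits: set[str] = set()
    for r in records:
        if r.gene not in fractions:
            raise KeyError(f"no abundance fraction for gene {r.gene!r}")
        p1, p2 = pvals[r.gene]
        if (
            p1 < criteria.p_max
            and r.lfc_vs_ref1 > criteria.lfc_min
            and p2 < criteria.p_max
            and r.lfc_vs_ref2 > criteria.lfc_min
            and fractions[r.gene] > criteria.abundance_fraction_min
        ):
            hits.add(r.gene)
    return hits


def categorize_gene(
    record: DERecord, criteria: FilterCriteria = FilterCriteria()
) -> str:
    """Four-way locus-map category for one gene.

    blue   - p < p_max and LFC > lfc_min against both references;
    green  - p < p_max against both, but LFC <= lfc_min for at least one;
    yellow - positive LFC against both, but p >= p_max for at least one;
    white  - everything else.
    """
    sig1 = record.p_vs_ref1 < criteria.p_max
    sig2 = record.p_vs_ref2 < criteria.p_max
    big1 = record.lfc_vs_ref1 > criteria.lfc_min
    big2 = record.lfc_vs_ref2 > criteria.lfc_min
    if sig1 and sig2 and big1 and big2:
        return "blue"
    if sig1 and sig2:
        return "green"
    if record.lfc_vs_ref1 > 0 and record.lfc_vs_ref2 > 0:
        return "yellow"
    return "white"


def conservation_tally(
    genes: Iterable[str], presence: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Per-gene genome counts and the number conserved in every genome.

    ``presence`` is a gene x genome 0/1 matrix; genes absent from its index
    raise KeyError.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in presence.index]
    if missing:
        raise KeyError(f"genes absent from presence matrix: {missing}")
    sub = presence.loc[genes]
    counts = sub.sum(axis=1).astype(int)
    n_all = int((sub == 1).all(axis=1).sum()) if genes else 0
    return counts, n_all


def read_de_records(path) -> list[DERecord]:
    """Read DE records from TSV
    (`gene  mean_norm_abundance  lfc_ref1  p_ref1  lfc_ref2  p_ref2`)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {
        "gene", "mean_norm_abundance", "lfc_ref1", "p_ref1", "lfc_ref2",
        "p_ref2",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return [
        DERecord(
            gene=str(row["gene"]),
            mean_norm_abundance=float(row["mean_norm_abundance"]),
            lfc_vs_ref1=float(row["lfc_ref1"]),
            p_vs_ref1=float(row["p_ref1"]),
            lfc_vs_ref2=float(row["lfc_ref2"]),
            p_vs_ref2=float(row["p_ref2"]),
        )
        for _, row in frame.iterrows()
    ]


def records_to_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "mean_norm_abundance": r.mean_norm_abundance,
                "lfc_ref1": r.lfc_vs_ref1,
                "p_ref1": r.p_vs_ref1,
                "lfc_ref2": r.lfc_vs_ref2,
                "p_ref2": r.p_vs_ref2,
            }
            for r in records
        ]
    )


def read_presence_matrix(path) -> pd.DataFrame:
    """Gene x genome 0/1 TSV with gene ids in the first column."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence matrix entries must be 0 or 1")
    return frame


def read_count_matrix(counts_path, conditions_path) -> CountMatrix:
    """Counts TSV (genes x samples) plus sidecar JSON sample->condition map."""
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    with open(conditions_path) as fh:
        conditions = json.load(fh)
    return CountMatrix(counts=counts, conditions=conditions)
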