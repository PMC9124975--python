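"""Seeded synthetic-data generators for every pipeline input.

Two generators stand in for the study's raw measurements so that every
stage is testable without any download:

* negative-binomial RNA-seq count matrices for 3 conditions x 4 replicates
  with a planted set of up-regulated genes (plus matching DE records with
  planted p-values), and
* reactor time series with logistic product accumulation, multiplicative
  Gaussian noise and detection-limit censoring, in triplicate.

All generators are pure functions of (spec, seed): the same spec and seed
reproduce output bit for bit.  Parameters are documented defaults chosen to
be realistic for a bulk culture experiment, not claims about the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reactor import ANALYTE_MODES, Measurement
from .transcripts import CountMatrix, DERecord, median_of_ratios_normalize

__all__ = [
    "CountGenSpec",
    "ReactorGenSpec",
    "gen_counts",
    "gen_de_records",
    "gen_reactor_series",
]


@dataclass(frozen=True)
class CountGenSpec:
    """Synthetic count-matrix design.

    Three conditions in quadruplicate by default (focal condition first).
    Baseline per-gene means are log-normal; counts are negative-binomial
    with gamma-Poisson overdispersion ``dispersion`` (variance
    m + dispersion * m^2).  Planted genes have their focal-condition mean
    scaled by 2^lfc relative to both references.
    """

    n_genes: int = 500
    conditions: tuple[str, ...] = ("FeS2", "FeCys", "FeHS")
    n_replicates: int = 4
    baseline_log_mean: float = 5.0  # ln scale; e^5 ~ 150 counts
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    n_planted: int = 12
    planted_lfc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.planted_lfc <= 0:
            raise ValueError("planted effects must be positive")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ValueError("n_planted must lie in [0, n_genes]")
        if len(self.conditions) < 3:
            raise ValueError("need the focal plus two reference conditions")


@dataclass(frozen=True)
class ReactorGenSpec:
    """Synthetic reactor experiment design.

    ``plateaus`` maps condition -> analyte -> plateau in the analyte's
    measurement units (aqueous mol L^-1 for sulfide/fe2, headspace ppm for
    h2/ch4).  Products accumulate logistically,
    ``plateau / (1 + exp(-rate (t - t0)))``, with multiplicative Gaussian
    noise of relative SD ``noise_sd``; values below the analyte's detection
    limit are flagged censored (never zeroed).  Default plateaus mirror a
    mineral-grown culture (~30.5 uM aqueous sulfide, ~2.65 uM aqueous-
    equivalent H2, vigorous CH4), a soluble-substrate control and a no-Fe/S
    blank, in triplicate.
    """

    plateaus: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "FeS2": {"sulfide": 30.5e-6, "h2": 1340.0, "ch4": 52000.0},
            "FeHS": {"sulfide": 2.0e-3, "h2": 1340.0, "ch4": 52000.0},
            "NoFeS": {"sulfide": 0.0, "h2": 0.0, "ch4": 2000.0},
        }
    )
    rate: float = 1.2  # d^-1
    t0: float = 4.0  # d, logistic midpoint
    noise_sd: float = 0.05  # relative
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    n_replicates: int = 3
    detection_limits: Mapping[str, float] = field(
        default_factory=lambda: {"sulfide": 1.5e-6, "h2": 50.0, "ch4": 10.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, analytes in self.plateaus.items():
            for analyte, plateau in analytes.items():
                if analyte not in ANALYTE_MODES:
                    raise ValueError(
                        f"unknown analyte {analyte!r} in condition {cond!r}"
                    )
                if plateau < 0:
                    raise ValueError("plateaus must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def gen_counts(spec: CountGenSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts plus the planted-gene truth table.

    Returns ``(matrix, truth)`` where ``truth`` has one row per gene with
    columns ``planted`` (bool) and ``lfc`` (the planted effect, 0 for
    nulls).  The focal condition is ``spec.conditions[0]``.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes - 1)))
    genes = [f"gene{i:0{width}d}" for i in range(spec.n_genes)]
    baseline = rng.lognormal(
        mean=spec.baseline_log_mean, sigma=spec.baseline_log_sd,
        size=spec.n_genes,
    )
    planted_idx = rng.choice(spec.n_genes, size=spec.n_planted, replace=False)
    planted = np.zeros(spec.n_genes, dtype=bool)
    planted[planted_idx] = True
    lfc = np.where(planted, spec.planted_lfc, 0.0)

    samples: list[str] = []
    conditions: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    shape = 1.0 / spec.dispersion
    for ci, cond in enumerate(spec.conditions):
        means = baseline * (2.0**lfc) if ci == 0 else baseline
        for rep in range(spec.n_replicates):
            name = f"{cond}_r{rep + 1}"
            lam = rng.gamma(shape, scale=means * spec.dispersion)
            columns[name] = rng.poisson(lam)
            samples.append(name)
            conditions[name] = cond
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame(
        {"planted": planted, "lfc": lfc}, index=counts.index
    )
    return CountMatrix(counts=counts, conditions=conditions), truth


def gen_de_records(
    matrix: CountMatrix,
    truth: pd.DataFrame,
    seed: int = 0,
    planted_p: float = 1e-4,
    pseudocount: float = 0.5,
) -> list[DERecord]:
    """DE records with empirical LFCs and planted p-values.

    LFCs are log2 ratios of mean normalized focal counts over each
    reference's means (pseudocount-stabilized); p-values are planted rather
    than derived from a test: ``planted_p`` for planted genes against both
    references, independent uniform(0, 1) draws for nulls.
    """
    rng = np.random.default_rng(seed)
    _, normalized = median_of_ratios_normalize(matrix.counts)
    cond_names = list(dict.fromkeys(matrix.conditions.values()))
    focal, ref1, ref2 = cond_names[0], cond_names[1], cond_names[2]
    m_focal = normalized[matrix.samples_for(focal)].mean(axis=1)
    m_ref1 = normalized[matrix.samples_for(ref1)].mean(axis=1)
    m_ref2 = normalized[matrix.samples_for(ref2)].mean(axis=1)
    lfc1 = np.log2((m_focal + pseudocount) / (m_ref1 + pseudocount))
    lfc2 = np.log2((m_focal + pseudocount) / (m_ref2 + pseudocount))
    u1 = rng.uniform(size=len(normalized))
    u2 = rng.uniform(size=len(normalized))
    records = []
    for i, gene in enumerate(normalized.index):
        is_planted = bool(truth.loc[gene, "planted"])
        records.append(
            DERecord(
                gene=str(gene),
                mean_norm_abundance=float(m_focal.iloc[i]),
                lfc_vs_ref1=float(lfc1.iloc[i]),
                p_vs_ref1=planted_p if is_planted else float(u1[i]),
                lfc_vs_ref2=float(lfc2.iloc[i]),
                p_vs_ref2=planted_p if is_planted else float(u2[i]),
            )
        )
    return records


def _logistic(t: float, plateau: float, rate: float, t0: float) -> float:
    return plateau / (1.0 + np.exp(-rate * (t - t0)))


def gen_reactor_series(spec: ReactorGenSpec) -> list[Measurement]:
    """Raw reactor measurements for every (condition, replicate, time, analyte)."""
    rng = np.random.default_rng(spec.seed)
    out: list[Measurement] = []
    for cond in spec.plateaus:
        for rep in range(spec.n_replicates):
            reactor_id = f"{cond}-{rep + 1}"
            for t in spec.times:
                for analyte, plateau in spec.plateaus[cond].items():
                    clean = _logistic(t, plateau, spec.rate, spec.t0)
                    noisy = clean * (1.0 + rng.normal(0.0, spec.noise_sd))
                    value = max(0.0, float(noisy))
                    limit = spec.detection_limits.get(analyte, 0.0)
                    out.append(
                        Measurement(
                            reactor_id=reactor_id,
                            condition=cond,
                            time=float(t),
                            analyte=analyte,
                            mode=ANALYTE_MODES[analyte],
                            value=value,
                            below_detection=value < limit,
                        )
                    )
    return out
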