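"""Per-sample diet composition and population-level diet statistics.

The pipeline's end product is a samples x species matrix of assigned
amplicon counts with an age class per sample. Samples without any prey DNA
("negative" samples) are kept in the matrix but excluded from occurrence
denominators, mirroring the convention of reporting frequency of occurrence
over the positive samples only. Richness differences between age classes are
tested with one-way ANOVA, composition differences with a permutation
multivariate ANOVA (Anderson's pseudo-F on a Jaccard or Bray-Curtis
distance matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f as f_dist

__all__ = [
    "DietMatrix",
    "OccurrenceSummary",
    "AnovaResult",
    "PermanovaResult",
    "build_diet_matrix",
    "occurrence",
    "amplicon_proportions",
    "anova_richness",
    "permanova",
]

AGE_CLASSES = ("hatchling", "juvenile", "subadult", "adult")


@dataclass
class DietMatrix:
    """Samples x species amplicon counts plus per-sample age class."""

    counts: pd.DataFrame  # samples x species, integer
    age_class: pd.Series  # indexed like counts

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.age_class.index):
            raise ValueError("age_class index must match the sample axis")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    @property
    def positive_samples(self) -> pd.Index:
        return self.counts.index[self.counts.sum(axis=1) > 0]

    @property
    def negative_samples(self) -> pd.Index:
        return self.counts.index[self.counts.sum(axis=1) == 0]

    @property
    def richness(self) -> pd.Series:
        """Number of species detected per sample."""
        return self.presence.sum(axis=1)


@dataclass
class OccurrenceSummary:
    occurrence: pd.Series  # per-species fraction of positive samples
    mean_richness: float
    richness_se: float
    n_positive: int


@dataclass
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int
    seed: int
    distance: str = "jaccard"


def build_diet_matrix(
    results,
    sample_metadata: dict[str, str] | pd.Series,
    species: list[str] | None = None,
) -> DietMatrix:
    """Aggregate assignment results into a DietMatrix.

    ``sample_metadata`` maps every sample id (including expected-negative
    ones) to its age class; the matrix covers all of these samples. The
    species axis covers ``species`` (e.g. the full library cluster list)
    plus any novel species seen, keeping all-zero columns. Counts from
    unassigned amplicons are ignored; an amplicon count for an unknown
    sample id is an error.
    """
    meta = pd.Series(dict(sample_metadata)) if not isinstance(
        sample_metadata, pd.Series
    ) else sample_metadata
    samples = sorted(meta.index)
    all_species = list(species or [])
    for res in results:
        if res.status in ("assigned", "novel") and res.species not in all_species:
            all_species.append(res.species)
    counts = pd.DataFrame(0, index=samples, columns=all_species, dtype=int)
    for res in results:
        if res.status not in ("assigned", "novel"):
            continue
        for sample, c in res.per_sample_counts.items():
            if sample not in counts.index:
                raise ValueError(f"unknown sample id {sample!r}")
            counts.loc[sample, res.species] += c
    return DietMatrix(counts, meta.loc[samples].rename("age_class"))


def occurrence(matrix: DietMatrix, denominator: str = "positive") -> OccurrenceSummary:
    """Frequency of occurrence per species, plus mean richness (+- SE).

    The denominator is the number of positive samples by default (the
    samples in which any prey DNA was found); ``denominator="all"`` uses
    every sample instead.
    """
    positive = matrix.positive_samples
    if len(positive) == 0:
        raise ValueError("no positive samples")
    base = matrix.counts.index if denominator == "all" else positive
    pres = matrix.presence.loc[base]
    frac = pres.sum(axis=0) / len(base)
    richness = matrix.richness.loc[positive].to_numpy(dtype=float)
    mean = float(richness.mean())
    se = float(richness.std(ddof=1) / math.sqrt(len(richness))) if len(richness) > 1 else 0.0
    return OccurrenceSummary(frac, mean, se, len(positive))


def amplicon_proportions(matrix: DietMatrix) -> pd.Series:
    """Fraction of all assigned amplicons contributed by each species."""
    totals = matrix.counts.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("no assigned amplicons")
    return totals / grand


def anova_richness(
    matrix: DietMatrix, positive_only: bool = True
) -> AnovaResult:
    """One-way fixed-effects ANOVA of per-sample richness across age classes."""
    idx = matrix.positive_samples if positive_only else matrix.counts.index
    y = matrix.richness.loc[idx].to_numpy(dtype=float)
    labels = matrix.age_class.loc[idx]
    groups = [y[(labels == g).to_numpy()] for g in labels.unique()]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n = len(y)
    a = len(groups)
    df1, df2 = a - 1, n - a
    if df2 < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(math.inf, df1, df2, 0.0, degenerate=True)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(f_dist.sf(f, df1, df2))
    return AnovaResult(float(f), df1, df2, p)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = (labels == g).astype(float)
        n_g = mask.sum()
        ss_within += mask @ d2 @ mask / (2 * n_g)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    matrix: DietMatrix,
    distance: str = "jaccard",
    permutations: int = 999,
    seed: int = 0,
    positive_only: bool = True,
) -> PermanovaResult:
    """Permutation MANOVA of diet composition across age classes.

    Partitions the squared-distance sum of the samples x samples matrix into
    among- and within-group components (Anderson's method); the pseudo-F is
    tested by permuting age-class labels. Jaccard works on presence/absence,
    Bray-Curtis on counts. p = (1 + #{F_perm >= F_obs}) / (1 + P). Samples
    are ordered canonically by id so the result does not depend on input
    order.
    """
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    idx = matrix.positive_samples if positive_only else matrix.counts.index
    idx = sorted(idx)
    if distance == "jaccard":
        data = matrix.presence.loc[idx].to_numpy(dtype=bool)
        d = pdist(data, metric="jaccard")
    elif distance == "bray-curtis":
        data = matrix.counts.loc[idx].to_numpy(dtype=float)
        d = pdist(data, metric="braycurtis")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    labels_raw = matrix.age_class.loc[idx]
    uniq = sorted(labels_raw.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = labels_raw.value_counts()
    if (sizes == 0).any():
        raise ValueError("empty group")
    labels = np.array([uniq.index(v) for v in labels_raw])
    d2 = squareform(d**2)
    f_obs = _pseudo_f(d2, labels, len(uniq))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, len(uniq)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + permutations)
    return PermanovaResult(float(f_obs), float(p), permutations, seed, distance)
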