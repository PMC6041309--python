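"""Cross-sample and cross-group similarity analyses.

Covers pairwise Spearman correlations of genus-level compositions,
blocked nonparametric comparisons (Friedman rank sum test with the
Nemenyi post hoc for unreplicated blocked data), Bray–Curtis
dissimilarities with classical-scaling PCoA, shared-taxa Venn
partitions, and the dam–calf taxon co-existence matrix.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as _sp_braycurtis

from .tables import DAM_SITES, FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    p: float
    method: str
    df: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"p-value out of (0, 1]: {self.p}")


# -- rank correlation --------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson on average-assigned ranks).

    Returns NaN (with a warning) when either vector has zero rank
    variance, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class PairedCorrelations:
    """Spearman ρ between each calf and its own dam's body sites.

    ``rho`` is blocks (dam–calf pairs) × conditions (dam sites); blocks
    missing any condition are dropped whole.
    """

    rho: pd.DataFrame
    medians: pd.Series = field(init=False)
    sds: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        arr = self.rho.to_numpy()
        if np.isnan(arr).any() or (np.abs(arr) > 1).any():
            raise ValueError("rho matrix must be complete with |rho| <= 1")
        self.medians = self.rho.median(axis=0)
        self.sds = self.rho.std(axis=0, ddof=1).fillna(0.0)


def paired_group_correlations(
    table: FeatureTable,
    metadata: SampleMetadata,
    calf_group: str = "newborn",
    dam_sites=DAM_SITES,
) -> PairedCorrelations:
    """Per dam–calf pair, ρ between the calf's composition and each dam site.

    Compositions are taken over the table's full feature list (the union of
    genera with zeros filled), which makes ρ comparable across pairs.
    """
    rel = table.relative_abundance()
    md = metadata.frame
    calf_sample = {
        md.loc[i, "animal_id"]: md.loc[i, "sample_id"]
        for i in md.index[md["group"] == calf_group]
        if md.loc[i, "sample_id"] in rel.columns
    }
    rows = {}
    dams = md[md["dam_of"].notna()]
    for calf_animal in sorted(set(dams["dam_of"])):
        if calf_animal not in calf_sample:
            continue
        block = {}
        for site in dam_sites:
            hit = dams[(dams["dam_of"] == calf_animal) & (dams["group"] == site)]
            sids = [s for s in hit["sample_id"] if s in rel.columns]
            if sids:
                block[site] = sids[0]
        if len(block) < len(dam_sites):
            logger.info("dropping incomplete dam–calf block for %s", calf_animal)
            continue
        rows[calf_animal] = {
            site: spearman_rho(rel[calf_sample[calf_animal]], rel[sid])
            for site, sid in block.items()
        }
    if len(rows) < 2:
        raise ValueError("fewer than 2 complete dam–calf blocks")
    rho = pd.DataFrame.from_dict(rows, orient="index")[list(dam_sites)]
    return PairedCorrelations(rho)


# -- blocked nonparametric tests ---------------------------------------

def _block_ranks(blocked: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, blocked)


def friedman_test(blocked) -> TestResult:
    """Friedman rank sum test on an n blocks × k conditions matrix.

    Average ranks within blocks handle ties, with the standard tie
    correction of the chi-squared statistic; df = k − 1.
    """
    blocked = np.asarray(blocked, dtype=float)
    if blocked.ndim != 2 or blocked.shape[0] < 2 or blocked.shape[1] < 2:
        raise ValueError("need an n>=2 blocks x k>=2 conditions matrix")
    if np.isnan(blocked).any():
        raise ValueError("incomplete blocks are not allowed")
    n, k = blocked.shape
    ranks = _block_ranks(blocked)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n (k^3 - k))
    ties = 0.0
    for row in blocked:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction <= 0:  # every block fully tied
        return TestResult(0.0, 1.0, "friedman", df=k - 1)
    stat /= correction
    p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return TestResult(float(stat), max(min(p, 1.0), np.nextafter(0, 1)), "friedman", df=k - 1)


def nemenyi_posthoc(blocked) -> pd.DataFrame:
    """Nemenyi pairwise comparisons after Friedman (q approximation).

    For each condition pair, q = (R̄_i − R̄_j) / sqrt(k(k+1)/(12n)) is
    referred to the studentized-range distribution with k groups and
    infinite df.  Returns a symmetric k × k matrix of p-values with a
    unit diagonal.
    """
    blocked = np.asarray(blocked, dtype=float)
    if blocked.ndim != 2 or blocked.shape[0] < 2 or blocked.shape[1] < 2:
        raise ValueError("need an n>=2 blocks x k>=2 conditions matrix")
    if np.isnan(blocked).any():
        raise ValueError("incomplete blocks are not allowed")
    n, k = blocked.shape
    mean_ranks = _block_ranks(blocked).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        q = abs(mean_ranks[i] - mean_ranks[j]) / se
        pij = float(sps.studentized_range.sf(q, k, np.inf)) if q > 0 else 1.0
        p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return pd.DataFrame(p)


# -- dissimilarity and ordination --------------------------------------

def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity: 1 − 2·Σ min(x, y) / (Σx + Σy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray–Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(x, y))


def bray_curtis_matrix(table: FeatureTable, sample_ids=None) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities of per-sample compositions."""
    sample_ids = list(sample_ids) if sample_ids is not None else table.sample_ids
    rel = table.relative_abundance()[sample_ids].to_numpy().T
    n = len(sample_ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = bray_curtis(rel[i], rel[j])
    return pd.DataFrame(d, index=sample_ids, columns=sample_ids)


@dataclass
class OrdinationResult:
    """Classical-scaling (PCoA) embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # samples × positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # % per positive axis
    negative_eigenvalues: bool


def pcoa(dissimilarity: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Principal coordinates analysis by classical scaling.

    Double-centers −½D², eigendecomposes, and scales eigenvectors by the
    square roots of their eigenvalues.  Axes are ordered by descending
    eigenvalue; negative eigenvalues (which arise for non-Euclidean inputs
    such as Bray–Curtis) are excluded from the coordinates and from the
    variance-explained denominator, and flagged.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        labels = list(dissimilarity.index)
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        labels = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    positive = eigvals > tol
    has_negative = bool((eigvals < -tol).any())
    if has_negative:
        logger.warning("non-Euclidean input: negative eigenvalues excluded from coordinates")
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    prop = 100.0 * eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
        negative_eigenvalues=has_negative,
    )


# -- shared taxa and co-existence --------------------------------------

@dataclass
class VennPartition:
    """Exclusive intersection-region counts of per-group taxon sets."""

    region_counts: dict[tuple[str, ...], int]
    universe: int
    presence: dict[str, frozenset]


def shared_taxa_partition(
    table: FeatureTable, metadata: SampleMetadata, groups
) -> VennPartition:
    """Venn partition of taxa present in each group.

    A taxon is present in a group iff its median relative abundance across
    the group's samples is > 0 — equivalently, iff it is detected in a
    strict majority of the group's samples.  Region counts sum to the size
    of the taxon universe (taxa present in at least one group).
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rel = table.relative_abundance()
    presence: dict[str, frozenset] = {}
    for g in groups:
        sids = [s for s in metadata.samples_in_group(g) if s in rel.columns]
        med = rel[sids].median(axis=1)
        presence[g] = frozenset(med.index[med > 0])
    universe = frozenset().union(*presence.values())
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = set(universe)
            for g in combo:
                inside &= presence[g]
            for g in groups:
                if g not in combo:
                    inside -= presence[g]
            region_counts[tuple(combo)] = len(inside)
    return VennPartition(region_counts, len(universe), presence)


@dataclass
class CoexistenceResult:
    """Dam-site occurrence of taxa conditioned on presence in the own calf."""

    matrix: pd.DataFrame  # taxon × dam site, fraction of dams
    calf_occurrence: pd.Series  # per-taxon fraction of calves with the taxon


def coexistence_matrix(
    table: FeatureTable,
    metadata: SampleMetadata,
    hit_cutoff: int = 20,
    calf_prevalence_min: float = 0.5,
    calf_group: str = "newborn",
    dam_sites=DAM_SITES,
) -> CoexistenceResult:
    """Taxon co-existence between calves and their own dams' body sites.

    A taxon qualifies if detected at ≥ ``hit_cutoff`` reads in more than
    ``calf_prevalence_min`` of the calves.  Each cell then gives, for one
    taxon and one dam site, the fraction of dams reaching ≥ ``hit_cutoff``
    reads among the dams whose own calf carries the taxon.
    """
    md = metadata.frame
    counts = table.counts
    calf_samples = {
        md.loc[i, "animal_id"]: md.loc[i, "sample_id"]
        for i in md.index[md["group"] == calf_group]
        if md.loc[i, "sample_id"] in counts.columns
    }
    if not calf_samples:
        raise ValueError(f"no {calf_group} samples in the table")
    calf_hits = counts[list(calf_samples.values())] >= hit_cutoff
    prevalence = calf_hits.mean(axis=1)
    taxa = prevalence.index[prevalence > calf_prevalence_min]
    if len(taxa) == 0:
        logger.warning("no taxa pass the co-existence prevalence cutoff")
        return CoexistenceResult(
            pd.DataFrame(index=[], columns=list(dam_sites), dtype=float),
            pd.Series(dtype=float),
        )
    dams = md[md["dam_of"].notna()]
    site_samples: dict[str, dict[str, str]] = {site: {} for site in dam_sites}
    for i in dams.index:
        site = dams.loc[i, "group"]
        if site in site_samples and dams.loc[i, "sample_id"] in counts.columns:
            site_samples[site][dams.loc[i, "dam_of"]] = dams.loc[i, "sample_id"]
    matrix = pd.DataFrame(np.nan, index=taxa, columns=list(dam_sites))
    for site in dam_sites:
        links = site_samples[site]
        for taxon in taxa:
            eligible = [
                calf
                for calf, dam_sid in links.items()
                if calf in calf_samples and counts.at[taxon, calf_samples[calf]] >= hit_cutoff
            ]
            if eligible:
                hits = sum(
                    counts.at[taxon, links[calf]] >= hit_cutoff for calf in eligible
                )
                matrix.at[taxon, site] = hits / len(eligible)
    return CoexistenceResult(matrix, prevalence.loc[taxa])
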