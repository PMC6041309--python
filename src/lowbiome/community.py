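"""Alpha diversity, phylum summaries and core-taxa tables.

Diversity is computed from OTU/genotype-level counts as the Shannon index
(natural log) and as Hill numbers — the effective number of equally
abundant taxa at order q, with q=0 giving richness, q=1 the exponential
of Shannon (by the limit definition) and q=2 the inverse Simpson index.
Core taxa of a sample group are genus-level taxa exceeding a median
relative abundance threshold (strict >) in at least a given fraction of
the group's samples (inclusive ≥ prevalence).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata, aggregate

MAJOR_PHYLA = ("Actinobacteria", "Bacteroidetes", "Firmicutes", "Proteobacteria")


def _props(counts) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("counts must be a non-negative vector")
    total = counts.sum()
    if total == 0:
        raise ValueError("diversity undefined for an all-zero vector")
    return counts[counts > 0] / total


def shannon(counts) -> float:
    """Shannon diversity, −Σ pᵢ ln pᵢ over positive abundances."""
    p = _props(counts)
    return float(-(p * np.log(p)).sum())


def hill(counts, q: float) -> float:
    """Hill number of order q: (Σ pᵢ^q)^(1/(1−q)), with limits at q=1.

    q=0 is richness, q=1 is exp(Shannon) (evaluated by the limit, not at
    q=1−ε), q=2 the inverse Simpson index.
    """
    if q < 0:
        raise ValueError("Hill order q must be non-negative")
    p = _props(counts)
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def alpha_diversity(table: FeatureTable, orders=(0, 1, 2)) -> pd.DataFrame:
    """Per-sample Shannon index and Hill numbers (NaN for empty samples)."""
    rows = {}
    for sid in table.sample_ids:
        v = table.counts[sid].to_numpy()
        if v.sum() == 0:
            rows[sid] = {"shannon": np.nan, **{f"hill_q{q:g}": np.nan for q in orders}}
        else:
            rows[sid] = {"shannon": shannon(v), **{f"hill_q{q:g}": hill(v, q) for q in orders}}
    return pd.DataFrame.from_dict(rows, orient="index")


def _group_rel(table: FeatureTable, metadata: SampleMetadata, group: str) -> pd.DataFrame:
    sids = [s for s in metadata.samples_in_group(group) if s in table.sample_ids]
    if not sids:
        raise ValueError(f"no samples of group {group!r} in the table")
    return table.relative_abundance()[sids]


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def core_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    group: str,
    abund_min: float = 0.001,
    prev_min: float = 0.75,
) -> pd.DataFrame:
    """Core taxa of a group: median abundance > abund_min AND prevalence ≥ prev_min.

    Medians and SDs are taken over within-sample relative abundances
    across ALL of the group's samples (absences contribute zeros);
    prevalence counts samples with ≥ 1 read.  Rows are sorted by lineage;
    ``prevalence_pct`` is rounded to the nearest integer percent.
    """
    rel = _group_rel(table, metadata, group)
    sids = rel.columns
    counts = table.counts[list(sids)]
    n = len(sids)
    rows = []
    for feat in table.feature_ids:
        vals = rel.loc[feat].to_numpy(float)
        med = float(np.median(vals))
        n_pos = int((counts.loc[feat] >= 1).sum())
        prevalence = n_pos / n
        if med > abund_min and prevalence >= prev_min:
            rows.append(
                {
                    "taxon": ";".join(table.lineages[feat]),
                    "feature_id": feat,
                    "median_abundance": med,
                    "sd": _sd(vals),
                    "prevalence_pct": int(round(100.0 * prevalence)),
                }
            )
    out = pd.DataFrame(rows, columns=["taxon", "feature_id", "median_abundance", "sd", "prevalence_pct"])
    return out.sort_values("taxon").reset_index(drop=True)


def phylum_summary(
    table: FeatureTable, metadata: SampleMetadata, phyla=MAJOR_PHYLA
) -> pd.DataFrame:
    """Per-group median and SD of major-phylum relative abundances.

    Phyla outside ``phyla`` are pooled under "other".  Group medians are
    not additive, so they need not sum to 1 within a group.
    """
    ptable = aggregate(table, "phylum")
    phylum_of = {f: ptable.lineages[f][1] for f in ptable.feature_ids}
    rel = ptable.relative_abundance()
    rows = []
    for group in sorted(set(metadata.frame["group"])):
        sids = [s for s in metadata.samples_in_group(group) if s in rel.columns]
        if not sids:
            continue
        sub = rel[sids]
        buckets: dict[str, np.ndarray] = {p: np.zeros(len(sids)) for p in (*phyla, "other")}
        for f in ptable.feature_ids:
            name = phylum_of[f] if phylum_of[f] in phyla else "other"
            buckets[name] += sub.loc[f].to_numpy(float)
        for name, vals in buckets.items():
            rows.append(
                {
                    "group": group,
                    "phylum": name,
                    "median_abundance": float(np.median(vals)),
                    "sd": _sd(vals),
                }
            )
    return pd.DataFrame(rows)


def core_read_coverage(
    core: pd.DataFrame, table: FeatureTable, metadata: SampleMetadata, group: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Share of each sample's taxa and reads captured by the core set.

    Per sample: (fraction of the taxa detected in that sample that are
    core, fraction of the sample's reads belonging to core taxa).  Returns
    the per-sample table and the group medians.
    """
    sids = [s for s in metadata.samples_in_group(group) if s in table.sample_ids]
    if not sids:
        raise ValueError(f"no samples of group {group!r} in the table")
    core_ids = set(core["feature_id"]) if len(core) else set()
    counts = table.counts[sids]
    rows = {}
    for sid in sids:
        v = counts[sid]
        detected = v.index[v >= 1]
        reads = v.sum()
        taxon_frac = (
            sum(f in core_ids for f in detected) / len(detected) if len(detected) else 0.0
        )
        read_frac = float(v.loc[[f for f in v.index if f in core_ids]].sum() / reads) if reads else 0.0
        rows[sid] = {"core_taxon_fraction": taxon_frac, "core_read_fraction": read_frac}
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    return per_sample, per_sample.median(axis=0)
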