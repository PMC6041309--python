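"""Negative-control-based removal of contaminant sequences.

Low-biomass specimens carry genuine microbial DNA at levels comparable to
the background DNA present in sampling devices, extraction kits and PCR
reagents.  Sequencing empty-device negative controls captures that
background, and each denoised sequence ("genotype") observed in a sample
is then classified per sample:

* ``sample_only``     — never seen in any negative control; accepted.
* ``accepted_shared`` — present in controls, but its relative abundance in
  the sample is more than ``ratio_threshold`` times (default 4×, strict)
  its relative abundance in the controls; accepted.
* ``rejected``        — shared with controls at a ratio at or below the
  threshold; removed as a probable reagent/instrument contaminant.

The decision is made against each sample's own relative abundances, so a
shared genotype may be accepted in one sample and rejected in another.
After decontamination, features observed fewer than ``rarity_min_total``
times (default 250, strict <) across the analyzed (non-control) dataset
are dropped as rare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

VERDICTS = ("sample_only", "accepted_shared", "rejected")


@dataclass
class DecontamConfig:
    """Tuning knobs of the ratio filter.

    ratio_threshold : sample/control relative-abundance ratio a shared
        genotype must strictly exceed to be accepted (default 4).
    control_pooling : ``pooled`` sums counts over all negative controls
        into one profile; ``max_per_control`` takes each feature's maximum
        per-control relative abundance.
    rarity_min_total : minimum dataset-wide count for a feature to survive
        the post-decontamination rarity filter (default 250, strict <).
    """

    ratio_threshold: float = 4.0
    control_pooling: str = "pooled"
    rarity_min_total: int = 250

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        if self.rarity_min_total < 0:
            raise ValueError("rarity_min_total must be non-negative")
        if self.control_pooling not in ("pooled", "max_per_control"):
            raise ValueError(f"unknown control_pooling {self.control_pooling!r}")


@dataclass
class DecontaminationResult:
    """Per-(feature, sample) verdicts plus the filtered table and report inputs."""

    verdicts: pd.DataFrame  # features × non-control samples, verdict labels
    filtered: FeatureTable  # rejected counts zeroed; controls untouched
    read_fractions: pd.DataFrame  # non-control samples × verdict classes
    control_profile: pd.Series  # per-feature relative abundance in controls
    original: FeatureTable = field(repr=False, default=None)
    config: DecontamConfig = field(default_factory=DecontamConfig)


def control_relative_abundance(
    table: FeatureTable, control_ids, pooling: str = "pooled"
) -> pd.Series:
    """Per-feature relative abundance in the negative controls.

    ``pooled`` divides each feature's summed control count by the total
    reads over all controls (the vector then sums to 1); ``max_per_control``
    takes the maximum of the per-control relative abundances.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids must be nonempty")
    missing = set(control_ids) - set(table.sample_ids)
    if missing:
        raise ValueError(f"control ids not in table: {sorted(missing)}")
    ctrl = table.counts[control_ids]
    if int(ctrl.to_numpy().sum()) == 0:
        raise ValueError(
            "all negative controls are empty; the control relative-abundance "
            "profile (and hence decontamination) is undefined"
        )
    if pooling == "pooled":
        return ctrl.sum(axis=1) / ctrl.to_numpy().sum()
    if pooling == "max_per_control":
        totals = ctrl.sum(axis=0).astype(float).replace(0, np.nan)
        return ctrl.div(totals, axis=1).fillna(0.0).max(axis=1)
    raise ValueError(f"unknown pooling {pooling!r}")


def classify_feature(sample_rel_abund: float, control_rel_abund: float, threshold: float) -> str:
    """Verdict for one (feature, sample) pair.

    Absent from controls → ``sample_only``; strictly more than
    ``threshold`` times the control abundance → ``accepted_shared``;
    otherwise (including a ratio exactly at the threshold) → ``rejected``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if control_rel_abund == 0:
        return "sample_only"
    if sample_rel_abund > threshold * control_rel_abund:
        return "accepted_shared"
    return "rejected"


def decontaminate(
    table: FeatureTable, metadata: SampleMetadata, config: DecontamConfig | None = None
) -> DecontaminationResult:
    """Apply the ratio filter to every non-control sample of a table.

    Control samples pass through unfiltered (they are retained for
    reporting only).  ``read_fractions`` gives, per sample, the fraction
    of reads in each verdict class (all zeros for an empty sample).
    """
    config = config or DecontamConfig()
    metadata.validate_against(table, require_controls=True)
    control_ids = [s for s in metadata.control_ids if s in table.sample_ids]
    if not control_ids:
        raise ValueError("no control samples present in the table")
    sample_ids = [s for s in table.sample_ids if s not in set(control_ids)]

    ctrl_profile = control_relative_abundance(table, control_ids, config.control_pooling)
    rel = table.relative_abundance()[sample_ids]

    c = ctrl_profile.to_numpy()[:, None]
    r = rel.to_numpy()
    verdict_codes = np.where(c == 0, 0, np.where(r > config.ratio_threshold * c, 1, 2))
    verdicts = pd.DataFrame(
        np.array(VERDICTS)[verdict_codes], index=table.counts.index, columns=sample_ids
    )

    filtered_counts = table.counts.copy()
    rejected = verdicts == "rejected"
    filtered_counts.loc[:, sample_ids] = filtered_counts[sample_ids].where(~rejected, 0)
    filtered = FeatureTable(filtered_counts, dict(table.lineages), table.level)

    counts = table.counts[sample_ids].to_numpy()
    totals = counts.sum(axis=0).astype(float)
    fracs = {}
    for code, name in enumerate(VERDICTS):
        mass = np.where(verdict_codes == code, counts, 0).sum(axis=0)
        fracs[name] = np.divide(mass, totals, out=np.zeros_like(totals), where=totals > 0)
    read_fractions = pd.DataFrame(fracs, index=sample_ids)

    return DecontaminationResult(
        verdicts=verdicts,
        filtered=filtered,
        read_fractions=read_fractions,
        control_profile=ctrl_profile,
        original=table,
        config=config,
    )


def rarity_filter(
    table: FeatureTable, min_total: int = 250, exclude_samples=()
) -> FeatureTable:
    """Drop features observed fewer than ``min_total`` times in the dataset.

    The total is summed over all samples except ``exclude_samples``
    (typically the negative controls, which are not part of the analyzed
    dataset).  The boundary is strict: a feature totalling exactly
    ``min_total`` reads is kept.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    excluded = set(exclude_samples)
    cols = [s for s in table.sample_ids if s not in excluded]
    totals = table.counts[cols].sum(axis=1)
    keep = totals[totals >= min_total].index
    if len(keep) == 0:
        logger.warning("rarity filter removed every feature (min_total=%d)", min_total)
    return table.subset_features(keep)


def decontamination_report(result: DecontaminationResult) -> pd.DataFrame:
    """Per-sample read fractions and per-class feature counts.

    Feature counts tally, for each sample, the features with at least one
    read falling in each verdict class; read fractions sum to 1 per
    non-empty sample.
    """
    counts = result.original.counts[result.verdicts.columns]
    present = counts > 0
    rows = {}
    for name in VERDICTS:
        rows[f"features_{name}"] = (present & (result.verdicts == name)).sum(axis=0)
    report = result.read_fractions.copy()
    report.columns = [f"frac_{c}" for c in report.columns]
    feat = pd.DataFrame(rows)
    report = report.join(feat)
    report["reads_raw"] = counts.sum(axis=0)
    report["reads_decontaminated"] = result.filtered.counts[result.verdicts.columns].sum(axis=0)
    return report


def group_summary(result: DecontaminationResult, metadata: SampleMetadata) -> pd.DataFrame:
    """Per-group medians (and SDs) of raw vs decontaminated reads and
    feature counts — the layout of a study-characteristics table.

    Control samples are reported from their raw column (controls are never
    filtered), with the decontaminated column showing the reads that would
    survive the shared-feature criterion applied to them: for controls the
    raw values are simply repeated, since no verdicts are computed.
    """
    raw = result.original
    dec = result.filtered
    rows = []
    for group in sorted(set(metadata.frame["group"])):
        sids = [s for s in metadata.samples_in_group(group) if s in raw.sample_ids]
        if not sids:
            continue
        raw_reads = raw.counts[sids].sum(axis=0)
        dec_reads = dec.counts[sids].sum(axis=0)
        raw_feats = (raw.counts[sids] > 0).sum(axis=0)
        dec_feats = (dec.counts[sids] > 0).sum(axis=0)
        sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append(
            {
                "group": group,
                "n": len(sids),
                "reads_raw_median": float(np.median(raw_reads)),
                "reads_raw_sd": sd(raw_reads),
                "reads_decont_median": float(np.median(dec_reads)),
                "reads_decont_sd": sd(dec_reads),
                "features_raw_median": float(np.median(raw_feats)),
                "features_raw_sd": sd(raw_feats),
                "features_decont_median": float(np.median(dec_feats)),
                "features_decont_sd": sd(dec_feats),
            }
        )
    return pd.DataFrame(rows).set_index("group")
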