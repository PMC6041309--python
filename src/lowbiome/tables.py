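"""Count-table, taxonomy and sample-metadata I/O.

The pipeline operates on a feature-by-sample table of non-negative integer
read counts.  Features are denoised 16S sequences ("genotypes"), OTUs, or
taxa produced by aggregating either of those to a taxonomic rank.  Each
feature carries a lineage of up to six ordered ranks (domain ... genus);
ranks that the upstream classifier could not resolve are filled with an
explicit ``unclassified_<deepest known taxon>`` placeholder so that, e.g.,
"unclassified Lachnospiraceae" and "unclassified Ruminococcaceae" remain
distinct genus-level taxa after aggregation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered taxonomic ranks, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Valid sample groups in the perinatal study design.
GROUPS = frozenset(
    {"newborn", "calf_24h", "calf_7d", "dam_feces", "dam_oral", "dam_vestibule", "control"}
)
CONTROL_GROUP = "control"
CALF_GROUPS = ("newborn", "calf_24h", "calf_7d")
DAM_SITES = ("dam_feces", "dam_oral", "dam_vestibule")

# Feature levels ordered fine -> coarse.  Sequence-derived levels sit below
# every taxonomic rank; rank levels are comparable among themselves.
_LEVEL_DEPTH = {"genotype": 7, "otu": 7, "genus": 6, "family": 5, "order": 4, "class": 3, "phylum": 2}

_BOOTSTRAP_RE = re.compile(r"\(\d+(\.\d+)?\)")


def _normalize_lineage(raw: str, n_ranks: int = len(RANKS)) -> tuple[str, ...]:
    """Parse one semicolon-delimited lineage string into a padded rank tuple.

    Strips mothur-style bootstrap suffixes ``(NN)``, quotes and trailing
    semicolons; converts bare ``unclassified`` / ``X_unclassified`` tokens
    into the canonical ``unclassified_X`` placeholder form.
    """
    cleaned = _BOOTSTRAP_RE.sub("", raw).strip().strip('"').rstrip(";")
    tokens = [t.strip() for t in cleaned.split(";")] if cleaned else []
    ranks: list[str] = []
    for tok in tokens:
        if not tok:
            break
        low = tok.lower()
        if low == "unclassified" or low == "unknown":
            break  # padded below from the deepest resolved taxon
        if low.endswith("_unclassified"):
            ranks.append("unclassified_" + tok[: -len("_unclassified")])
            break
        ranks.append(tok)
        if len(ranks) == n_ranks:
            break
    # pad with placeholders anchored at the deepest known taxon
    if len(ranks) < n_ranks:
        if ranks:
            deepest = ranks[-1]
            placeholder = deepest if deepest.startswith("unclassified_") else "unclassified_" + deepest
        else:
            placeholder = "unclassified_root"
        ranks.extend([placeholder] * (n_ranks - len(ranks)))
    return tuple(ranks)


@dataclass
class FeatureTable:
    """Feature-by-sample count matrix with per-feature taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, features as rows, samples as columns.
    lineages : dict
        Maps each feature id to an ordered tuple of taxonomic ranks
        (≤ 6, domain → genus), placeholders allowed but never empty strings.
    level : str
        Resolution of the features: ``genotype``, ``otu``, or a taxonomic
        rank name after aggregation.
    """

    counts: pd.DataFrame
    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)
    level: str = "genotype"

    def __post_init__(self) -> None:
        if self.level not in _LEVEL_DEPTH:
            raise ValueError(f"unknown feature level {self.level!r}")
        self.counts.index = self.counts.index.astype(str).rename("feature_id")
        self.counts.columns = self.counts.columns.astype(str).rename(None)
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
                raise ValueError(
                    f"non-integer count at feature {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at feature {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing = [f for f in self.counts.index if f not in self.lineages]
        if missing:
            logger.warning(
                "%d features missing from taxonomy; assigning placeholder lineages", len(missing)
            )
            for f in missing:
                self.lineages[f] = ("unclassified_root",) * len(RANKS)
        for f, lin in self.lineages.items():
            if len(lin) > len(RANKS) or any(r == "" for r in lin):
                raise ValueError(f"invalid lineage for feature {f!r}: {lin!r}")
        empty = self.counts.columns[self.sample_totals() == 0]
        if len(empty):
            logger.warning("samples with zero total reads: %s", list(empty))

    # -- basic views ---------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples map to all zeros."""
        totals = self.sample_totals().astype(float)
        safe = totals.replace(0, np.nan)
        rel = self.counts.div(safe, axis=1).fillna(0.0)
        return rel

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts[list(sample_ids)].copy(), dict(self.lineages), self.level)

    def subset_features(self, feature_ids) -> "FeatureTable":
        keep = list(feature_ids)
        return FeatureTable(
            self.counts.loc[keep].copy(), {f: self.lineages[f] for f in keep}, self.level
        )


def aggregate(table: FeatureTable, target_level: str) -> FeatureTable:
    """Sum counts of features sharing the lineage prefix down to a rank.

    Placeholder ranks aggregate by their full placeholder string, keeping
    e.g. ``unclassified_Lachnospiraceae`` distinct from
    ``unclassified_Ruminococcaceae`` at genus level.  Per-sample totals are
    conserved exactly, and aggregation is idempotent at the same rank.
    """
    if target_level not in RANKS:
        raise ValueError(f"target level must be one of {RANKS}, got {target_level!r}")
    if _LEVEL_DEPTH[target_level] > _LEVEL_DEPTH[table.level]:
        raise ValueError(f"cannot aggregate {table.level!r} table down to {target_level!r}")
    depth = RANKS.index(target_level) + 1
    prefixes = {f: tuple(table.lineages[f][:depth]) for f in table.feature_ids}
    key = pd.Series({f: ";".join(p) for f, p in prefixes.items()})
    grouped = table.counts.groupby(key.reindex(table.counts.index)).sum()
    lineages = {";".join(p): p for p in prefixes.values()}
    grouped = grouped.sort_index()
    return FeatureTable(grouped, lineages, target_level)


# -- file I/O ----------------------------------------------------------

def _read_taxonomy(path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    if "taxonomy" in cols:  # mothur cons.taxonomy: OTU  Size  Taxonomy
        feat_col, tax_col = df.columns[0], df.columns[cols.index("taxonomy")]
    else:
        feat_col, tax_col = df.columns[0], df.columns[1]
    out: dict[str, tuple[str, ...]] = {}
    for f, raw in zip(df[feat_col], df[tax_col].fillna("")):
        out[str(f)] = _normalize_lineage(raw)
    return out


def _read_counts(path) -> tuple[pd.DataFrame, str | None]:
    """Read a plain TSV (features × samples) or mothur shared file.

    Returns the count matrix and the feature level recorded in a leading
    ``# level: <x>`` comment, if any.
    """
    level = None
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            m = re.match(r"#\s*level\s*[:=]\s*(\w+)", first)
            if m:
                level = m.group(1)
            first = fh.readline()
    header = first.rstrip("\n").split("\t")
    if [h.lower() for h in header[:3]] == ["label", "group", "numotus"]:
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.drop(columns=[df.columns[0], df.columns[2]])
        df = df.set_index(df.columns[0]).T  # transpose: samples were rows
        df.index.name = "feature_id"
        counts = df
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return counts, level


def read_feature_table(path, taxonomy_path=None, level: str = "genotype") -> FeatureTable:
    """Read a count TSV (plain features×samples or mothur shared dialect)
    plus an optional taxonomy TSV (plain two-column or mothur
    cons.taxonomy; bootstrap ``(NN)`` suffixes are stripped)."""
    counts, stored_level = _read_counts(path)
    if counts.size == 0:
        counts = counts.astype(np.int64)
    raw = counts.to_numpy()
    if raw.dtype == object or not np.issubdtype(raw.dtype, np.number):
        raise ValueError(f"non-numeric counts in {path}")
    lineages = _read_taxonomy(taxonomy_path) if taxonomy_path else {}
    return FeatureTable(counts, lineages, stored_level or level)


def write_feature_table(table: FeatureTable, path, taxonomy_path=None) -> None:
    """Write counts (with a ``# level:`` header) and optionally taxonomy.

    ``read_feature_table(write(t))`` round-trips counts, ids, level and
    lineages bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# level: {table.level}\n")
        out = table.counts.copy()
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            fh.write("feature_id\tlineage\n")
            for f in table.feature_ids:
                fh.write(f"{f}\t{';'.join(table.lineages[f])}\n")


@dataclass
class SampleMetadata:
    """Sample annotations: group membership, animal identity, dam–calf links."""

    frame: pd.DataFrame  # columns: sample_id, animal_id, group, dam_of, preamp_cycles

    def __post_init__(self) -> None:
        df = self.frame
        required = {"sample_id", "animal_id", "group"}
        if not required.issubset(df.columns):
            raise ValueError(f"metadata must contain columns {sorted(required)}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        bad = set(df["group"]) - GROUPS
        if bad:
            raise ValueError(f"unknown groups in metadata: {sorted(bad)}")
        for col in ("dam_of", "preamp_cycles"):
            if col not in df.columns:
                df[col] = pd.NA
        links = df["dam_of"].dropna()
        if len(links):
            animals = set(df["animal_id"])
            dangling = set(links) - animals
            if dangling:
                raise ValueError(f"dam_of links point to unknown animals: {sorted(dangling)}")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == CONTROL_GROUP, "sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["group"].iloc[0]

    def animal_of(self, sample_id: str) -> str:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["animal_id"].iloc[0]

    def validate_against(self, table: FeatureTable, require_controls: bool = False) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        if require_controls and not self.control_ids:
            raise ValueError("no control samples in metadata; decontamination undefined")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "animal_id": str})
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)
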