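"""Ground-truthed synthetic low-biomass 16S datasets.

Every observed sample is modeled as a copy-number-proportional mixture of
two communities: the animal's true community and a reagent/instrument
contaminant community shared across the whole batch.  With T true and C
contaminant 16S copies on a swab, reads are drawn multinomially from
w·true_profile + (1−w)·contaminant_profile with w = T/(T+C); negative
controls have T = 0 and therefore sequence the contaminant community
alone.  The default parameters reproduce the perinatal-study design: 21
calves sampled at birth, 24 h and 7 d; 10 dams sampled at three body
sites; 3 empty-swab controls; a contamination background of 1.3·10⁵
copies per swab against a newborn load of 5.7·10⁵, with the total load
rising ~7000× by 24 h and a further ~14× by 7 d.

Newborn communities are drawn from their own dam's site communities with
oral-weighted mixing (planted vertical transmission); 24 h communities
collapse onto a few facultative anaerobes dominated by an
*Escherichia/Shigella* genotype; 7 d communities shift to an
anaerobe-rich profile.  Each feature carries an origin label
(``true_only`` / ``contaminant_only`` / ``shared``) so decontamination
performance can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .qpcr import QPCRTable
from .tables import CALF_GROUPS, DAM_SITES, FeatureTable, SampleMetadata

# (phylum, class, order, family, genus); domain is always Bacteria.
_CATALOG = [
    ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Lactococcus"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Leuconostocaceae", "Leuconostoc"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae-1", "Clostridium-sensu-stricto"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Clostridium-XlVa"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "unclassified_Lachnospiraceae"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", "Clostridium-XI"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", "Romboutsia"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", "Terrisporobacter"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Butyricicoccus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "unclassified_Ruminococcaceae"),
    ("Firmicutes", "Clostridia", "Clostridiales", "unclassified_Clostridiales", "unclassified_Clostridiales"),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Veillonellaceae", "Dialister"),
    ("Proteobacteria", "Alphaproteobacteria", "Caulobacterales", "Caulobacteraceae", "Brevundimonas"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhodobacterales", "Rhodobacteraceae", "Paracoccus"),
    ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Bradyrhizobiaceae", "Bradyrhizobium"),
    ("Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Methylobacteriaceae", "Methylobacterium"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae", "Comamonas"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae", "Delftia"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae", "Massilia"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae", "Herbaspirillum"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Burkholderia"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Ralstonia"),
    ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "unclassified_Neisseriaceae"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "Escherichia/Shigella"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", "unclassified_Enterobacteriaceae"),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "unclassified_Pasteurellaceae"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    ("Proteobacteria", "Gammaproteobacteria", "Xanthomonadales", "Xanthomonadaceae", "Stenotrophomonas"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Corynebacteriaceae", "Corynebacterium"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Dermabacteraceae", "Brachybacterium"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae", "Kocuria"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae", "Micrococcus"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae", "Rothia"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Propionibacteriaceae", "Propionibacterium"),
    ("Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Parabacteroides"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes"),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Chryseobacterium"),
    ("Bacteroidetes", "unclassified_Bacteroidetes", "unclassified_Bacteroidetes", "unclassified_Bacteroidetes", "unclassified_Bacteroidetes"),
]

#: Genera typical of reagent/water backgrounds; the contaminant pool is
#: biased toward these (origin flags, not names, remain authoritative).
_CONTAMINANT_GENERA = (
    "Ralstonia", "Burkholderia", "Bradyrhizobium", "Methylobacterium", "Delftia",
    "Herbaspirillum", "Stenotrophomonas", "Sphingomonas", "Pseudomonas",
    "Acinetobacter", "Propionibacterium", "Comamonas", "Chryseobacterium",
    "Brevundimonas", "Paracoccus", "Massilia",
)

# Genera guaranteed a genotype in the true pool, so that group profiles can
# be anchored on them.
_ANCHOR_GENERA = (
    "Staphylococcus", "Lactobacillus", "Streptococcus", "Enterococcus",
    "Clostridium-sensu-stricto", "Clostridium-XlVa", "Clostridium-XI",
    "Romboutsia", "Terrisporobacter", "Faecalibacterium", "Butyricicoccus",
    "unclassified_Lachnospiraceae", "unclassified_Ruminococcaceae",
    "Escherichia/Shigella", "unclassified_Enterobacteriaceae", "Acinetobacter",
    "Pseudomonas", "Sphingomonas", "Corynebacterium", "Kocuria", "Micrococcus",
    "Bacteroides", "Parabacteroides", "Bifidobacterium", "Collinsella",
)


def _default_loads() -> dict[str, float]:
    newborn = 5.7e5
    h24 = 7000 * newborn
    return {
        "newborn": newborn,
        "calf_24h": h24,
        "calf_7d": 14 * h24,
        "dam_feces": 1e10,
        "dam_oral": 1e9,
        "dam_vestibule": 1e8,
        "control": 0.0,
    }


def _default_depths() -> dict[str, int]:
    # per-group medians of raw reads in the emulated study
    return {
        "newborn": 21342,
        "calf_24h": 76993,
        "calf_7d": 47755,
        "dam_feces": 25579,
        "dam_oral": 51539,
        "dam_vestibule": 39464,
        "control": 4486,
    }


def _default_mixture() -> dict[str, dict[str, float]]:
    return {"newborn": {"dam_oral": 0.7, "dam_vestibule": 0.2, "dam_feces": 0.1}}


@dataclass
class SyntheticConfig:
    """Study-design and generative parameters; defaults emulate the
    perinatal cattle design (see module docstring)."""

    seed: int = 0
    n_calves: int = 21
    n_dams: int = 10
    n_controls: int = 3
    taxon_pool_size: int = 120
    contaminant_pool_size: int = 40
    shared_pool_fraction: float = 0.1
    contamination_copies: float = 1.3e5
    load_by_group: dict[str, float] = field(default_factory=_default_loads)
    depth_by_group: dict[str, int] = field(default_factory=_default_depths)
    community_log_sigma: float = 1.5  # log-normal σ of true community profiles
    contaminant_log_sigma: float = 1.0  # log-normal σ of the reagent profile
    dam_concentration: float = 50.0  # Dirichlet concentration for dam-to-dam variation
    load_log_sd: float = 0.2  # multiplicative (ln-scale) noise on per-swab loads
    depth_log_sd: float = 0.3  # multiplicative noise on sequencing depth
    qpcr_log_sd: float = 0.1  # qPCR measurement noise
    carryover: float = 0.05  # weight of the previous time point in 24 h / 7 d profiles
    source_mixture: dict[str, dict[str, float]] = field(default_factory=_default_mixture)

    def __post_init__(self) -> None:
        if min(self.n_calves, self.n_dams, self.n_controls) < 1:
            raise ValueError("study arms must have at least one animal")
        if self.n_dams > self.n_calves:
            raise ValueError("cannot have more sampled dams than calves")
        if min(self.taxon_pool_size, self.contaminant_pool_size) < 1:
            raise ValueError("pool sizes must be >= 1")
        if not 0 <= self.shared_pool_fraction <= 1:
            raise ValueError("shared_pool_fraction must be in [0, 1]")
        if self.contamination_copies <= 0:
            raise ValueError("contamination_copies must be positive")
        n_shared = round(self.shared_pool_fraction * self.contaminant_pool_size)
        if n_shared > min(self.taxon_pool_size, self.contaminant_pool_size):
            raise ValueError("shared fraction demands more shared taxa than the smaller pool")
        for group, weights in self.source_mixture.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"source mixture for {group!r} must sum to 1, got {total}")


@dataclass
class TaxonPools:
    """True and contaminant genotype pools with lineages and origin labels."""

    feature_ids: list[str]
    lineages: dict[str, tuple[str, ...]]
    origin: pd.Series  # feature -> true_only / contaminant_only / shared
    true_ids: list[str]
    contaminant_ids: list[str]
    anchor: dict[str, str]  # genus -> one genotype id in the true pool


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    origin: pd.Series
    true_profiles: pd.DataFrame  # features × samples, true community compositions
    contaminant_profile: pd.Series
    contamination_fraction: pd.Series  # per sample, C/(T+C)
    true_copies: pd.Series
    contaminant_copies: pd.Series
    source_attribution: dict[str, dict[str, float]]


class StudyData(NamedTuple):
    table: FeatureTable
    metadata: SampleMetadata
    qpcr: QPCRTable
    truth: SyntheticGroundTruth


def _pools(config: SyntheticConfig, rng: np.random.Generator) -> TaxonPools:
    by_genus = {entry[4]: entry for entry in _CATALOG}
    lineage_of = lambda entry: ("Bacteria",) + entry

    true_entries = [by_genus[g] for g in _ANCHOR_GENERA]
    while len(true_entries) < config.taxon_pool_size:
        true_entries.append(_CATALOG[rng.integers(len(_CATALOG))])
    true_entries = true_entries[: config.taxon_pool_size]

    feature_ids: list[str] = []
    lineages: dict[str, tuple[str, ...]] = {}
    anchor: dict[str, str] = {}
    true_ids = []
    for i, entry in enumerate(true_entries):
        fid = f"gt{i + 1:04d}"
        feature_ids.append(fid)
        true_ids.append(fid)
        lineages[fid] = lineage_of(entry)
        anchor.setdefault(entry[4], fid)

    n_shared = round(config.shared_pool_fraction * config.contaminant_pool_size)
    shared_ids: list[str] = []
    if n_shared:
        # the dominant facultative genotype is the canonical shared case
        pref = [anchor["Escherichia/Shigella"]] if "Escherichia/Shigella" in anchor else []
        others = [f for f in true_ids if f not in pref]
        picks = list(rng.choice(others, size=max(0, n_shared - len(pref)), replace=False))
        shared_ids = (pref + picks)[:n_shared]

    contaminant_ids = list(shared_ids)
    cont_entries = [by_genus[g] for g in _CONTAMINANT_GENERA]
    j = len(true_ids)
    while len(contaminant_ids) < config.contaminant_pool_size:
        entry = (
            cont_entries[rng.integers(len(cont_entries))]
            if rng.random() < 0.8
            else _CATALOG[rng.integers(len(_CATALOG))]
        )
        fid = f"gt{j + 1:04d}"
        j += 1
        feature_ids.append(fid)
        contaminant_ids.append(fid)
        lineages[fid] = lineage_of(entry)

    origin = pd.Series("true_only", index=feature_ids)
    origin.loc[[f for f in contaminant_ids if f not in set(true_ids)]] = "contaminant_only"
    origin.loc[shared_ids] = "shared"
    return TaxonPools(feature_ids, lineages, origin, true_ids, contaminant_ids, anchor)


def generate_pools(config: SyntheticConfig) -> TaxonPools:
    """Deterministic (under ``config.seed``) true/contaminant taxon pools."""
    return _pools(config, np.random.default_rng(config.seed))


def _lognormal_profile(ids, sigma: float, rng: np.random.Generator, index) -> pd.Series:
    w = pd.Series(0.0, index=index)
    w.loc[list(ids)] = rng.lognormal(mean=0.0, sigma=sigma, size=len(ids))
    return w / w.sum()


def _dirichlet_perturb(base: pd.Series, conc: float, rng: np.random.Generator) -> pd.Series:
    out = pd.Series(0.0, index=base.index)
    support = base.index[base > 0]
    out.loc[support] = rng.dirichlet(base.loc[support].to_numpy() * conc)
    return out


def generate_sample(
    true_profile,
    contaminant_profile,
    true_copies: float,
    contaminant_copies: float,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Multinomial read counts from the copy-number mixture of two profiles."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if true_copies == 0 and contaminant_copies == 0:
        raise ValueError("at least one of the copy numbers must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(true_profile, dtype=float)
    c = np.asarray(contaminant_profile, dtype=float)
    w = true_copies / (true_copies + contaminant_copies)
    mix = w * t + (1.0 - w) * c
    mix = mix / mix.sum()
    return rng.multinomial(depth, mix)


def generate_study(config: SyntheticConfig | None = None) -> StudyData:
    """Generate a full ground-truthed study under the configured design."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    pools = _pools(config, rng)
    index = pd.Index(pools.feature_ids)

    contaminant_profile = _lognormal_profile(
        pools.contaminant_ids, config.contaminant_log_sigma, rng, index
    )

    # dam site communities: a site-level base profile, perturbed per dam
    site_base: dict[str, pd.Series] = {}
    for site in DAM_SITES:
        available = [f for f in pools.true_ids if rng.random() < 0.6]
        if len(available) < 10:
            available = list(pools.true_ids[:10])
        site_base[site] = _lognormal_profile(available, config.community_log_sigma, rng, index)
    dam_profiles: list[dict[str, pd.Series]] = [
        {site: _dirichlet_perturb(site_base[site], config.dam_concentration, rng) for site in DAM_SITES}
        for _ in range(config.n_calves)
    ]

    mixture = config.source_mixture.get("newborn", _default_mixture()["newborn"])
    newborn_profiles = []
    for j in range(config.n_calves):
        prof = sum(w * dam_profiles[j][site] for site, w in mixture.items())
        newborn_profiles.append(prof / prof.sum())

    a = pools.anchor
    base24 = pd.Series(0.0, index=index)
    for genus, weight in (
        ("Escherichia/Shigella", 0.77),
        ("Clostridium-sensu-stricto", 0.082),
        ("Enterococcus", 0.008),
        ("Streptococcus", 0.002),
        ("Terrisporobacter", 0.004),
        ("unclassified_Enterobacteriaceae", 0.004),
    ):
        base24.loc[a[genus]] += weight
    base24 /= base24.sum()

    base7d = pd.Series(0.0, index=index)
    for genus, weight in (
        ("Faecalibacterium", 0.275),
        ("Bacteroides", 0.116),
        ("Lactobacillus", 0.083),
        ("Butyricicoccus", 0.038),
        ("Bifidobacterium", 0.026),
        ("Clostridium-XlVa", 0.02),
        ("Parabacteroides", 0.001),
    ):
        base7d.loc[a[genus]] += weight
    tail = rng.choice(pools.true_ids, size=15, replace=False)
    tail_w = _lognormal_profile(tail, 1.0, rng, index)
    base7d = base7d + (1.0 - base7d.sum()) * tail_w

    profiles: dict[str, pd.Series] = {}
    meta_rows = []
    calves = [f"calf{j + 1:02d}" for j in range(config.n_calves)]
    preamp = {"newborn": 21, "control": 21, "calf_7d": 15, "dam_feces": 15}
    for j, calf in enumerate(calves):
        p_nb = newborn_profiles[j]
        p_24 = (1 - config.carryover) * _dirichlet_perturb(base24, 100.0, rng) + config.carryover * p_nb
        p_7d = (1 - config.carryover) * _dirichlet_perturb(base7d, 60.0, rng) + config.carryover * p_24
        for group, prof in zip(CALF_GROUPS, (p_nb, p_24, p_7d)):
            sid = f"{group}.{calf}"
            profiles[sid] = prof / prof.sum()
            meta_rows.append(
                {"sample_id": sid, "animal_id": calf, "group": group,
                 "dam_of": pd.NA, "preamp_cycles": preamp.get(group, 18)}
            )
    for j in range(config.n_dams):
        dam = f"dam{j + 1:02d}"
        for site in DAM_SITES:
            sid = f"{site}.{dam}"
            profiles[sid] = dam_profiles[j][site]
            meta_rows.append(
                {"sample_id": sid, "animal_id": dam, "group": site,
                 "dam_of": calves[j], "preamp_cycles": preamp.get(site, 18)}
            )
    for j in range(config.n_controls):
        sid = f"control.swab{j + 1:02d}"
        profiles[sid] = pd.Series(0.0, index=index)
        meta_rows.append(
            {"sample_id": sid, "animal_id": f"swab{j + 1:02d}", "group": "control",
             "dam_of": pd.NA, "preamp_cycles": preamp.get("control", 21)}
        )

    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    counts = {}
    true_copies, cont_copies, qpcr_copies = {}, {}, {}
    for row in meta_rows:
        sid, group = row["sample_id"], row["group"]
        t_load = config.load_by_group[group]
        t = t_load * np.exp(rng.normal(0, config.load_log_sd)) if t_load > 0 else 0.0
        c = config.contamination_copies * np.exp(rng.normal(0, config.load_log_sd))
        depth = max(1, int(round(config.depth_by_group[group] * np.exp(rng.normal(0, config.depth_log_sd)))))
        counts[sid] = generate_sample(
            profiles[sid].to_numpy() if t > 0 else np.zeros(len(index)),
            contaminant_profile.to_numpy(), t, c, depth, rng,
        )
        true_copies[sid] = t
        cont_copies[sid] = c
        qpcr_copies[sid] = (t + c) * np.exp(rng.normal(0, config.qpcr_log_sd))

    sample_ids = [row["sample_id"] for row in meta_rows]
    table = FeatureTable(
        pd.DataFrame(counts, index=index, columns=sample_ids).astype(np.int64),
        dict(pools.lineages),
        "genotype",
    )
    qpcr = QPCRTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": [row["group"] for row in meta_rows],
                "copies_per_swab": [qpcr_copies[s] for s in sample_ids],
            }
        )
    )
    tc = pd.Series(true_copies)
    cc = pd.Series(cont_copies)
    truth = SyntheticGroundTruth(
        origin=pools.origin,
        true_profiles=pd.DataFrame(profiles)[sample_ids],
        contaminant_profile=contaminant_profile,
        contamination_fraction=cc / (tc + cc),
        true_copies=tc,
        contaminant_copies=cc,
        source_attribution={calf: dict(mixture) for calf in calves},
    )
    return StudyData(table, metadata, qpcr, truth)


def evaluate_recovery(truth: SyntheticGroundTruth, result) -> pd.DataFrame:
    """Score a decontamination run against the planted origin labels.

    Per non-control sample: the fraction of ``contaminant_only`` reads
    rejected (specificity proxy), the fraction of ``true_only`` reads
    retained (sensitivity proxy), and the fate of ``shared``-origin reads.
    Columns are NaN where a sample has no reads of that origin.
    """
    counts = result.original.counts
    if not counts.index.equals(truth.origin.index):
        raise ValueError("feature sets of truth and decontamination result differ")
    verdicts = result.verdicts
    rows = {}
    for sid in verdicts.columns:
        v = counts[sid]
        rejected = verdicts[sid] == "rejected"
        row = {}
        for label, col, of_rejected in (
            ("contaminant_only", "contaminant_reads_rejected", True),
            ("true_only", "true_reads_retained", False),
            ("shared", "shared_reads_rejected", True),
        ):
            mask = truth.origin == label
            total = int(v[mask].sum())
            if total == 0:
                row[col] = np.nan
            else:
                hit = int(v[mask & rejected].sum())
                row[col] = (hit if of_rejected else total - hit) / total
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")
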