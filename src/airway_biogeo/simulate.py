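"""Synthetic paired multi-site airway cohort generator.

Emulates a 45-subject adult cohort (22 atopic asthmatic, 12 atopic
non-asthmatic, 11 healthy control) with bronchial brush (BB), induced
sputum (IS) and oral wash (OW) samples for every subject and nasal
brush (NB) samples for a 27-subject subset.  The community model is a
three-pool source/mixture model:

* an *oral* pool (Prevotella, Streptococcus, Veillonella, ...),
* a *nasal* pool (Corynebacterium, Staphylococcus, Moraxella, ...),
* a small *lung-specific* pool (Pseudomonas, Sphingomonas, ...).

Each subject draws a personal realization of each pool from a Dirichlet
around the pool's base composition.  True site compositions are then

    OW  = oral
    NB  = nasal (with a planted dominance state: Corynebacterium-
          dominated with a group-specific probability; Moraxella-
          dominated NB occurs only in asthmatic subjects)
    BB  = f_oral * oral + f_nasal * nasal + f_lung * lung
    IS  = f_sal * OW + (1 - f_sal) * BB        (salivary admixture)

Observed counts are Dirichlet-multinomial around the true composition at
a log-normal sequencing depth floored above the rarefaction depth, so no
sample is lost at rarefaction.  Clinical covariates are generated with
planted links (e.g. BAL eosinophil fraction rises with the logit of
nasal Moraxella relative abundance; pro-inflammatory BAL cytokines fall
with nasal Corynebacterium), and a configurable limit of detection
censors cytokines to exercise the half-LOD imputation rule.  Everything
planted is recorded in a GroundTruth sidecar that the analysis pipeline
never reads.

All randomness flows from one master seed through named
``numpy.random.SeedSequence`` child streams (tree, pools, subjects,
counts, clinical), so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import (
    ClinicalTable,
    CountTable,
    Phylogeny,
    TaxonomyMap,
    RANKS,
    write_counts_tsv,
    write_taxonomy_tsv,
)

__all__ = ["SimulationParams", "GroundTruth", "simulate_phylogeny",
           "simulate_cohort", "write_dataset"]

POOLS = ("oral", "nasal", "lung")

# Genus roster: (genus or None, family, phylum, pool, fraction of taxa,
# prominence = share of the pool's base mass).  Genera appearing in two
# pools (Streptococcus, Haemophilus, Lactobacillus) contribute distinct
# OTUs to each but form a single clade in the tree.
_ROSTER = [
    ("Prevotella",      "Prevotellaceae",     "Bacteroidetes",   "oral", 0.130, 0.30),
    ("Streptococcus",   "Streptococcaceae",   "Firmicutes",      "oral", 0.095, 0.22),
    ("Veillonella",     "Veillonellaceae",    "Firmicutes",      "oral", 0.055, 0.12),
    ("Actinomyces",     "Actinomycetaceae",   "Actinobacteria",  "oral", 0.045, 0.08),
    ("Porphyromonas",   "Porphyromonadaceae", "Bacteroidetes",   "oral", 0.040, 0.06),
    ("Fusobacterium",   "Fusobacteriaceae",   "Fusobacteria",    "oral", 0.040, 0.05),
    ("Neisseria",       "Neisseriaceae",      "Proteobacteria",  "oral", 0.035, 0.04),
    ("Haemophilus",     "Pasteurellaceae",    "Proteobacteria",  "oral", 0.030, 0.03),
    ("Leptotrichia",    "Leptotrichiaceae",   "Fusobacteria",    "oral", 0.030, 0.04),
    ("Rothia",          "Micrococcaceae",     "Actinobacteria",  "oral", 0.025, 0.03),
    ("Gemella",         "Gemellaceae",        "Firmicutes",      "oral", 0.020, 0.01),
    ("Treponema",       "Spirochaetaceae",    "Spirochaetes",    "oral", 0.020, 0.005),
    ("Aggregatibacter", "Pasteurellaceae",    "Proteobacteria",  "oral", 0.015, 0.005),
    (None,              "Neisseriaceae",      "Proteobacteria",  "oral", 0.015, 0.01),
    ("Corynebacterium", "Corynebacteriaceae", "Actinobacteria",  "nasal", 0.080, 0.38),
    ("Staphylococcus",  "Staphylococcaceae",  "Firmicutes",      "nasal", 0.065, 0.22),
    ("Moraxella",       "Moraxellaceae",      "Proteobacteria",  "nasal", 0.045, 0.12),
    ("Alloiococcus",    "Carnobacteriaceae",  "Firmicutes",      "nasal", 0.040, 0.10),
    ("Dolosigranulum",  "Carnobacteriaceae",  "Firmicutes",      "nasal", 0.030, 0.06),
    ("Streptococcus",   "Streptococcaceae",   "Firmicutes",      "nasal", 0.030, 0.12),
    ("Pseudomonas",     "Pseudomonadaceae",   "Proteobacteria",  "lung", 0.045, 0.35),
    ("Sphingomonas",    "Sphingomonadaceae",  "Proteobacteria",  "lung", 0.040, 0.25),
    ("Haemophilus",     "Pasteurellaceae",    "Proteobacteria",  "lung", 0.030, 0.15),
    ("Lactobacillus",   "Lactobacillaceae",   "Firmicutes",      "lung", 0.025, 0.10),
    (None,              "Microbacteriaceae",  "Actinobacteria",  "lung", 0.045, 0.15),
]

# 21-analyte BAL cytokine panel; 'lod' is the assay detection limit and
# 'detectable' marks the analytes generated at concentrations the assay
# usually resolves (the remainder exercise the <20%-detection drop rule).
_CYTOKINES = {
    "bal_gmcsf":       dict(log_mean=5.8, log_sd=0.8, lod=3.0,  detectable=True),
    "bal_il6":         dict(log_mean=4.6, log_sd=0.9, lod=1.0,  detectable=True),
    "bal_il7":         dict(log_mean=1.6, log_sd=1.3, lod=0.6,  detectable=True),
    "bal_il8":         dict(log_mean=7.2, log_sd=0.8, lod=3.0,  detectable=True),
    "bal_cxcl11":      dict(log_mean=6.0, log_sd=0.8, lod=3.0,  detectable=True),
    "bal_mip1a":       dict(log_mean=4.5, log_sd=0.7, lod=2.0,  detectable=True),
    "bal_mip1b":       dict(log_mean=5.6, log_sd=0.8, lod=2.0,  detectable=True),
    "bal_mip3a":       dict(log_mean=5.9, log_sd=1.0, lod=2.0,  detectable=True),
    "bal_tnf":         dict(log_mean=4.0, log_sd=0.9, lod=1.0,  detectable=True),
    "bal_il1b":        dict(log_mean=0.5, log_sd=1.6, lod=0.08, detectable=True),
    "bal_il21":        dict(log_mean=1.0, log_sd=1.8, lod=0.08, detectable=True),
    "bal_il2":         dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_il4":         dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_il5":         dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_il10":        dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_il12":        dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_il13":        dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_il17a":       dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_il23":        dict(log_mean=-2.0, log_sd=0.8, lod=1.0, detectable=False),
    "bal_ifng":        dict(log_mean=-3.0, log_sd=0.8, lod=0.3, detectable=False),
    "bal_fractalkine": dict(log_mean=-1.0, log_sd=0.8, lod=5.0, detectable=False),
}


def _default_n_subjects():
    return {"AA": 22, "ANA": 12, "HC": 11}


def _default_nb_subset():
    return {"AA": 18, "ANA": 3, "HC": 6}


def _default_mixing():
    # (f_oral, f_nasal, f_lung) for the bronchial community, per group;
    # asthmatics carry a larger nasal contribution (planted NB-BB sharing)
    return {"AA": (0.835, 0.045, 0.12),
            "ANA": (0.86, 0.04, 0.10),
            "HC": (0.895, 0.025, 0.08)}


def _default_cory_dominance():
    # probability a subject's nasal community is Corynebacterium-dominated
    return {"AA": 0.5, "ANA": 1.0, "HC": 1.0}


@dataclass
class SimulationParams:
    """Knobs of the cohort generator; defaults encode the study design."""

    n_subjects: dict = field(default_factory=_default_n_subjects)
    nb_subset: dict = field(default_factory=_default_nb_subset)
    n_taxa: int = 300
    pool_concentration: dict = field(
        default_factory=lambda: {"oral": 40.0, "nasal": 25.0, "lung": 15.0})
    mixing_weights: dict = field(default_factory=_default_mixing)
    f_sal: float = 0.45
    bronchial_prevotella_boost: float = 1.8
    bronchial_oral_retention: float = 0.4
    cory_dominance_prob: dict = field(default_factory=_default_cory_dominance)
    moraxella_dominance_prob_aa: float = 1.0 / 6.0
    dominance_mass_range: tuple = (0.50, 0.80)
    # clinical link slopes on the standardized logit-abundance scale
    beta_moraxella_eos: float = 1.8
    beta_cory_cytokine: float = 1.4
    clinical_noise_sd: float = 1.0
    # planted differential abundance (AA vs HC, NB site)
    da_fold_change: float = 4.0
    n_da_taxa: int = 5
    # counting model
    dm_concentration: float = 150.0
    depth_log_mean: float = np.log(20_000.0)
    depth_log_sd: float = 0.5
    depth_floor: int = 26_185
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (fo, fn, fl) in self.mixing_weights.items():
            if min(fo, fn, fl) < 0 or abs(fo + fn + fl - 1.0) > 1e-9:
                raise ValueError(f"mixing weights for {g} must be >= 0 and sum to 1")
        for g, p in self.cory_dominance_prob.items():
            if not 0 <= p <= 1:
                raise ValueError("dominance probabilities must lie in [0, 1]")
        if not 0 <= self.f_sal <= 1:
            raise ValueError("f_sal must lie in [0, 1]")
        for g in self.n_subjects:
            if self.nb_subset.get(g, 0) > self.n_subjects[g]:
                raise ValueError(f"nb_subset exceeds group size for {g}")
        if self.depth_floor < 1:
            raise ValueError("depth_floor must be >= 1")


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    true_compositions: pd.DataFrame          # samples x taxa, rows sum to 1
    pool_membership: pd.Series               # taxon -> pool
    dominance_state: pd.Series               # NB subject -> {cory, moraxella, other}
    planted_slopes: dict                     # link name -> slope
    planted_da_taxa: dict                    # taxon -> fold change (AA vs HC, NB)
    nasal_moraxella: pd.Series               # subject -> true NB Moraxella abundance
    nasal_corynebacterium: pd.Series         # subject -> true NB Corynebacterium abundance

    def __post_init__(self) -> None:
        sums = self.true_compositions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("true compositions must sum to 1 per sample")


# ----------------------------------------------------------------------
# taxon allocation and phylogeny


def _allocate_taxa(n_taxa: int, rng: np.random.Generator) -> pd.DataFrame:
    """Assign OTU ids to roster blocks with base weights.

    Returns one row per OTU: taxon, genus (may be None), family, phylum,
    pool, base_weight (normalized within pool).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    fracs = np.array([row[4] for row in _ROSTER])
    counts = np.maximum(1, np.round(fracs / fracs.sum() * n_taxa).astype(int))
    while counts.sum() > n_taxa:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_taxa:
        counts[np.argmax(fracs)] += 1
    rows = []
    k = 0
    for (genus, family, phylum, pool, _frac, prom), m in zip(_ROSTER, counts):
        w = rng.lognormal(0.0, 1.0, size=m)
        w = w / w.sum() * prom
        for j in range(m):
            rows.append({"taxon": f"OTU_{k:04d}", "genus": genus,
                         "family": family, "phylum": phylum, "pool": pool,
                         "base_weight": w[j]})
            k += 1
    alloc = pd.DataFrame(rows).set_index("taxon")
    for pool in POOLS:
        mask = alloc["pool"] == pool
        alloc.loc[mask, "base_weight"] /= alloc.loc[mask, "base_weight"].sum()
    return alloc


def _coalescent_join(subtrees: list[TreeNode], rng: np.random.Generator,
                     scale: float) -> TreeNode:
    """Random coalescent over a list of lineages with exponential
    inter-coalescence heights."""
    nodes = [(t, 0.0) for t in subtrees]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(scale / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = height - ha
        b.length = height - hb
        parent = TreeNode(children=[a, b])
        nodes = [nodes[m] for m in range(k) if m not in (i, j)]
        nodes.append((parent, height))
    root, _ = nodes[0]
    root.length = None
    return root


def _build_tree(alloc: pd.DataFrame, rng: np.random.Generator) -> Phylogeny:
    """Genus-clade tree: coalescent within each genus (keyed by family
    for genus-unassigned blocks), then a coalescent across clades."""
    clades = []
    key = alloc["genus"].where(alloc["genus"].notna(), alloc["family"])
    # nasal-niche genera form tight shallow radiations relative to the
    # broad oral clades, keeping the nasal community branch-length-sparse
    nasal_genera = {"Corynebacterium", "Staphylococcus", "Moraxella",
                    "Alloiococcus", "Dolosigranulum"}
    for name, members in alloc.groupby(key, sort=True):
        scale = 0.12 if name in nasal_genera else 0.3
        tips = [TreeNode(name=t) for t in members.index]
        if len(tips) == 1:
            tip = tips[0]
            tip.length = float(rng.exponential(scale))
            clades.append(tip)
        else:
            clades.append(_coalescent_join(tips, rng, scale=scale))
    tree = _coalescent_join(clades, rng, scale=0.4)
    return Phylogeny(tree)


def simulate_phylogeny(n_taxa: int, seed: int) -> Phylogeny:
    """Rooted binary tree over ``n_taxa`` genus-structured OTUs with
    exponential coalescence times; deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    alloc = _allocate_taxa(n_taxa, np.random.default_rng(
        np.random.SeedSequence(seed).spawn(2)[1]))
    return _build_tree(alloc, rng)


def _taxonomy_from_alloc(alloc: pd.DataFrame) -> TaxonomyMap:
    frame = pd.DataFrame(index=alloc.index, columns=list(RANKS), dtype=object)
    frame["kingdom"] = "Bacteria"
    frame["phylum"] = alloc["phylum"]
    frame["class"] = alloc["phylum"] + "ia"
    frame["order"] = alloc["family"].str.replace("aceae", "ales", regex=False)
    frame["family"] = alloc["family"]
    frame["genus"] = alloc["genus"]
    frame["species"] = None
    frame.index.name = "taxon"
    return TaxonomyMap(frame.where(frame.notna(), None))


# ----------------------------------------------------------------------
# cohort simulation


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    alpha = np.clip(alpha, 1e-8, None)
    x = rng.standard_gamma(alpha)
    total = x.sum()
    if total <= 0:
        x = alpha
        total = x.sum()
    return x / total


def _boost(weights: np.ndarray, mask: np.ndarray, factor: float) -> np.ndarray:
    out = weights.copy()
    out[mask] *= factor
    return out / out.sum()


def _impose_dominance(comp: np.ndarray, genus_mask: np.ndarray, mass: float
                      ) -> np.ndarray:
    """Rescale a composition so the masked genus carries ``mass`` total."""
    g = comp[genus_mask].sum()
    rest = comp.sum() - g
    if g <= 0 or rest <= 0:
        return comp
    out = comp.copy()
    out[genus_mask] *= mass / g
    out[~genus_mask] *= (1.0 - mass) / rest
    return out


def simulate_cohort(params: SimulationParams | None = None
                    ) -> tuple[CountTable, TaxonomyMap, Phylogeny,
                               ClinicalTable, GroundTruth]:
    """Generate one synthetic paired cohort (see module docstring)."""
    params = params or SimulationParams()
    streams = np.random.SeedSequence(params.seed).spawn(5)
    rng_tree = np.random.default_rng(streams[0])
    rng_pool = np.random.default_rng(streams[1])
    rng_subj = np.random.default_rng(streams[2])
    rng_count = np.random.default_rng(streams[3])
    rng_clin = np.random.default_rng(streams[4])

    alloc = _allocate_taxa(params.n_taxa, rng_pool)
    phylogeny = _build_tree(alloc, rng_tree)
    taxonomy = _taxonomy_from_alloc(alloc)
    taxa = list(alloc.index)
    n = len(taxa)

    pool_mask = {p: (alloc["pool"] == p).values for p in POOLS}
    genus_mask = {g: (alloc["genus"] == g).values
                  for g in alloc["genus"].dropna().unique()}
    base = {p: np.where(pool_mask[p], alloc["base_weight"].values, 0.0)
            for p in POOLS}

    # planted differential abundance: Staphylococcus-analog OTUs enriched
    # in asthmatic nasal communities
    staph_idx = np.flatnonzero(genus_mask["Staphylococcus"] & pool_mask["nasal"])
    da_idx = staph_idx[np.argsort(-alloc["base_weight"].values[staph_idx])
                       ][: params.n_da_taxa]
    da_mask = np.zeros(n, dtype=bool)
    da_mask[da_idx] = True
    # asthma-associated lung-pool sharing: Haemophilus-analog OTUs carried
    # in the bronchial (hence IS) but not oral/nasal communities of AAs
    haem_lung = genus_mask["Haemophilus"] & pool_mask["lung"]

    subjects = []
    for group in ("AA", "ANA", "HC"):
        for i in range(params.n_subjects[group]):
            subjects.append((f"S{group}{i:02d}", group,
                             i < params.nb_subset.get(group, 0)))

    sample_rows, comp_rows, meta_rows = [], [], []
    dominance, morax_nb, cory_nb = {}, {}, {}
    for subject_id, group, has_nb in subjects:
        conc = params.pool_concentration
        pools = {}
        for p in POOLS:
            w = base[p]
            if group == "AA":
                if p == "nasal":
                    w = _boost(w, da_mask, params.da_fold_change)
                if p == "lung":
                    w = _boost(w, haem_lung, params.da_fold_change)
            pools[p] = _dirichlet(rng_subj, conc[p] * w)

        nasal = pools["nasal"]
        if has_nb:
            u = rng_subj.uniform()
            p_cory = params.cory_dominance_prob[group]
            mass = rng_subj.uniform(*params.dominance_mass_range)
            if u < p_cory:
                state = "cory"
                nasal = _impose_dominance(nasal, genus_mask["Corynebacterium"], mass)
            elif group == "AA" and u < p_cory + params.moraxella_dominance_prob_aa:
                state = "moraxella"
                nasal = _impose_dominance(nasal, genus_mask["Moraxella"], mass)
            else:
                state = "other"
            dominance[subject_id] = state
        pools["nasal"] = nasal

        fo, fn, fl = params.mixing_weights[group]
        # bronchial niche filtering: only a fraction of oral taxa establish
        # in the airway, so BB richness sits below OW/IS but above NB
        retain = (rng_subj.uniform(size=len(taxa))
                  < params.bronchial_oral_retention) | ~pool_mask["oral"]
        oral_bb = pools["oral"] * retain
        if oral_bb.sum() <= 0:
            oral_bb = pools["oral"].copy()
        oral_bb = oral_bb / oral_bb.sum()
        oral_bb = _boost(oral_bb, genus_mask["Prevotella"],
                         params.bronchial_prevotella_boost)
        bb = fo * oral_bb + fn * pools["nasal"] + fl * pools["lung"]
        ow = pools["oral"]
        is_ = params.f_sal * ow + (1.0 - params.f_sal) * bb
        site_comps = {"BB": bb, "IS": is_, "OW": ow}
        if has_nb:
            site_comps["NB"] = pools["nasal"]
            morax_nb[subject_id] = float(nasal[genus_mask["Moraxella"]].sum())
            cory_nb[subject_id] = float(nasal[genus_mask["Corynebacterium"]].sum())

        for site, comp in site_comps.items():
            comp = comp / comp.sum()
            sid = f"{subject_id}_{site}"
            depth = params.depth_floor + int(round(rng_count.lognormal(
                params.depth_log_mean, params.depth_log_sd)))
            observed = _dirichlet(rng_count, params.dm_concentration * comp)
            counts = rng_count.multinomial(depth, observed)
            sample_rows.append(pd.Series(counts, index=taxa, name=sid))
            comp_rows.append(pd.Series(comp, index=taxa, name=sid))
            meta_rows.append({
                "sample_id": sid, "subject_id": subject_id, "site": site,
                "group": group,
                "squamous_pct": (float(rng_count.uniform(0.05, 0.60))
                                 if site == "IS" else np.nan),
                "is_control": False,
            })

    counts = pd.DataFrame(sample_rows)
    counts.index.name = "sample_id"
    counts.columns.name = "taxon"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = CountTable(counts, meta).canonicalize()

    clinical, slopes = _simulate_clinical(
        subjects, morax_nb, cory_nb, params, rng_clin)

    truth = GroundTruth(
        true_compositions=pd.DataFrame(comp_rows).loc[table.sample_ids],
        pool_membership=alloc["pool"],
        dominance_state=pd.Series(dominance, dtype=object),
        planted_slopes=slopes,
        planted_da_taxa={taxa[i]: params.da_fold_change for i in da_idx},
        nasal_moraxella=pd.Series(morax_nb),
        nasal_corynebacterium=pd.Series(cory_nb),
    )
    return table, taxonomy, phylogeny, clinical, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _simulate_clinical(subjects, morax_nb, cory_nb, params: SimulationParams,
                       rng: np.random.Generator) -> tuple[ClinicalTable, dict]:
    ids = [s for s, _, _ in subjects]
    group = pd.Series({s: g for s, g, _ in subjects})
    n = len(ids)
    sigma = params.clinical_noise_sd

    # standardized logit abundances where NB exists, 0 (mean) elsewhere
    z_mor = pd.Series(0.0, index=ids)
    z_cor = pd.Series(0.0, index=ids)
    nb_ids = list(morax_nb)
    if nb_ids:
        z_mor[nb_ids] = _zscore(np.log(np.clip(
            [morax_nb[s] for s in nb_ids], 1e-6, 1 - 1e-6)))
        z_cor[nb_ids] = _zscore(np.log(np.clip(
            [cory_nb[s] for s in nb_ids], 1e-6, 1 - 1e-6)))

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-x))

    eps = rng.normal(0, sigma, n)
    bal_eos = logistic(-4.0 + params.beta_moraxella_eos * z_mor.values + eps)
    blood_eos_abs = np.exp(
        5.3 + 0.6 * params.beta_moraxella_eos * z_mor.values
        + rng.normal(0, sigma, n))
    values = pd.DataFrame({"group": group}, index=ids)
    values["age"] = np.round(rng.uniform(24, 50, n))
    values["bmi"] = np.round(rng.normal(26, 3.5, n), 1)
    values["sex_male"] = rng.binomial(1, 0.5, n)
    rhin_p = {"AA": 0.55, "ANA": 0.25, "HC": 0.0}
    values["allergic_rhinitis"] = [rng.binomial(1, rhin_p[g]) for g in group]
    values["acq"] = np.where(group == "AA",
                             np.round(rng.gamma(2.0, 0.35, n), 1), np.nan)
    values["fev1_pre"] = np.round(np.where(
        group == "AA", rng.normal(85, 12, n), rng.normal(101, 9, n)))
    values["fev1_delta"] = np.round(np.where(
        group == "AA", rng.gamma(4, 2.6, n), rng.gamma(2, 1.8, n)), 1)
    values["fev1_post"] = values["fev1_pre"] * (1 + values["fev1_delta"] / 100)
    pc20 = np.where(group == "AA",
                    np.exp(rng.normal(0.1, 1.0, n)), 32.0)
    values["pc20"] = np.minimum(pc20, 32.0)
    pc20_censored = pd.Series(group.values != "AA", index=ids)
    ige_mu = {"AA": 5.1, "ANA": 4.4, "HC": 2.7}
    values["serum_ige"] = np.round(np.exp(
        [rng.normal(ige_mu[g], 0.9) for g in group]), 1)
    values["blood_neut_frac"] = np.clip(rng.normal(0.55, 0.06, n), 0, 1)
    values["blood_eos_frac"] = np.clip(
        logistic(-3.6 + 0.4 * params.beta_moraxella_eos * z_mor.values
                 + rng.normal(0, 0.6, n)), 0, 1)
    values["blood_eos_abs"] = np.round(blood_eos_abs)
    values["sputum_neut_frac"] = np.clip(rng.normal(0.45, 0.15, n), 0, 1)
    values["sputum_eos_frac"] = np.clip(
        logistic(-5.0 + 0.6 * params.beta_moraxella_eos * z_mor.values
                 + rng.normal(0, sigma, n)), 0, 1)
    values["bal_eos_frac"] = np.clip(bal_eos, 0, 1)
    values["bal_neut_frac"] = np.clip(rng.normal(0.25, 0.10, n), 0, 1)

    # cytokine panel with planted Corynebacterium links and LOD censoring
    below = pd.DataFrame(False, index=pd.Index(ids), columns=list(_CYTOKINES))
    planted_cyto = {"bal_il6", "bal_il7", "bal_il21"}
    for name, spec in _CYTOKINES.items():
        shift = (-params.beta_cory_cytokine * z_cor.values
                 if name in planted_cyto else 0.0)
        conc = np.exp(spec["log_mean"] + shift
                      + rng.normal(0, spec["log_sd"], n))
        censored = conc < spec["lod"]
        conc = np.where(censored, spec["lod"], conc)
        values[name] = conc
        below[name] = censored

    slopes = {
        "moraxella_nb->bal_eos_frac": params.beta_moraxella_eos,
        "moraxella_nb->sputum_eos_frac": 0.6 * params.beta_moraxella_eos,
        "moraxella_nb->blood_eos_abs": 0.6 * params.beta_moraxella_eos,
        "corynebacterium_nb->bal_il6": -params.beta_cory_cytokine,
        "corynebacterium_nb->bal_il7": -params.beta_cory_cytokine,
        "corynebacterium_nb->bal_il21": -params.beta_cory_cytokine,
    }
    values.index.name = "subject_id"
    return ClinicalTable(values, below, pc20_censored), slopes


# ----------------------------------------------------------------------
# bundle output


def write_dataset(bundle, out_dir, counts_format: str = "tsv") -> dict:
    """Write a (CountTable, TaxonomyMap, Phylogeny, ClinicalTable[,
    GroundTruth]) bundle into the formats ``core_io.load_dataset`` reads.

    The ground-truth sidecar, when present, is written as JSON next to
    the bundle; the analysis pipeline never reads it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, taxonomy, phylogeny, clinical = bundle[:4]
    truth = bundle[4] if len(bundle) > 4 else None

    if counts_format == "tsv":
        counts_path = out / "counts.tsv"
        write_counts_tsv(table.counts, counts_path)
    elif counts_format == "biom":
        from .core_io import write_counts_biom_json
        counts_path = out / "counts.biom.json"
        write_counts_biom_json(table.counts, counts_path)
    else:
        raise ValueError(f"unknown counts format {counts_format!r}")
    write_taxonomy_tsv(taxonomy, out / "taxonomy.tsv")
    (out / "tree.nwk").write_text(phylogeny.to_newick())

    meta = table.sample_meta.copy()
    clin = clinical.values.drop(columns=["group"])
    joined = meta.join(clin, on="subject_id")
    for analyte in clinical.below_lod.columns:
        joined[f"{analyte}__below_lod"] = clinical.below_lod[analyte].reindex(
            joined["subject_id"]).values
    joined["pc20_censored"] = clinical.pc20_censored.reindex(
        joined["subject_id"]).values
    joined.index.name = "sample_id"
    joined.to_csv(out / "metadata.tsv", sep="\t")

    paths = {"counts": counts_path, "taxonomy": out / "taxonomy.tsv",
             "tree": out / "tree.nwk", "metadata": out / "metadata.tsv"}
    if truth is not None:
        sidecar = {
            "pool_membership": truth.pool_membership.to_dict(),
            "dominance_state": truth.dominance_state.to_dict(),
            "planted_slopes": truth.planted_slopes,
            "planted_da_taxa": truth.planted_da_taxa,
            "nasal_moraxella": truth.nasal_moraxella.to_dict(),
            "nasal_corynebacterium": truth.nasal_corynebacterium.to_dict(),
        }
        (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
        paths["ground_truth"] = out / "ground_truth.json"
    return paths
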