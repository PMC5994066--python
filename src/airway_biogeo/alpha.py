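"""Rarefaction ensembles and per-sample alpha diversity.

Sequencing effort is equalized by multiple rarefaction: each sample's
counts are subsampled without replacement to a common depth D, repeated
R times with independent sub-seeds, and every diversity metric is
averaged over the R draws.  Metrics are the four reported for airway
communities: observed richness S, Shannon diversity H in bits (log2, the
historical QIIME-1 convention), root-inclusive Faith phylogenetic
diversity, and Pielou evenness J = H / log2(S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CountTable, Phylogeny, PipelineConfig
from .stats import two_sample_test

__all__ = [
    "RarefiedEnsemble",
    "rarefy_table",
    "build_ensemble",
    "alpha_metrics",
    "faith_pd",
    "alpha_comparisons",
]

ALPHA_METRICS = ("richness", "shannon", "faith_pd", "pielou")


@dataclass
class RarefiedEnsemble:
    """R rarefied count tables at a common depth with seed provenance."""

    tables: list[CountTable]
    depth: int
    provenance: list[tuple[int, int]]  # (sub-seed, iteration)

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("empty ensemble")
        for t in self.tables:
            totals = t.counts.sum(axis=1)
            if not (totals == self.depth).all():
                raise ValueError("ensemble member with per-sample total != depth")

    @property
    def n_rarefactions(self) -> int:
        return len(self.tables)

    @property
    def sample_meta(self) -> pd.DataFrame:
        return self.tables[0].sample_meta

    @property
    def taxa(self) -> list[str]:
        return self.tables[0].taxa


def _subsample_without_replacement(row: np.ndarray, depth: int,
                                   rng: np.random.Generator) -> np.ndarray:
    return rng.multivariate_hypergeometric(row, depth)


def rarefy_table(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth``
    reads; samples below depth are dropped with a warning."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=1)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(keep) == 0:
        raise ValueError("every sample is below the rarefaction depth")
    if len(dropped):
        warnings.warn(f"{len(dropped)} sample(s) below depth {depth} dropped: "
                      f"{list(dropped[:5])}")
    rng = np.random.default_rng(seed)
    mat = table.counts.loc[keep].values.astype(np.int64)
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = _subsample_without_replacement(mat[i], depth, rng)
    counts = pd.DataFrame(out, index=keep, columns=table.counts.columns)
    return CountTable(counts, table.sample_meta.loc[keep])


def build_ensemble(table: CountTable, config: PipelineConfig) -> RarefiedEnsemble:
    """R independent rarefactions of ``table`` at the configured depth.

    Sub-seeds are spawned deterministically from the master seed so the
    ensemble is bit-reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_rarefactions)
    tables, prov = [], []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        tables.append(rarefy_table(table, config.rarefaction_depth, sub_seed))
        prov.append((sub_seed, i))
    return RarefiedEnsemble(tables, config.rarefaction_depth, prov)


def faith_pd(present_taxa, phylogeny: Phylogeny) -> float:
    """Root-inclusive Faith PD: total branch length of the minimal
    subtree connecting the present tips and the root."""
    taxa = sorted(phylogeny.tip_names)
    return phylogeny.index(taxa).faith_pd_set(present_taxa)


def _alpha_one_table(table: CountTable, tindex) -> pd.DataFrame:
    counts = table.counts.values.astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty sample in rarefied table")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    shannon = -plogp.sum(axis=1)
    richness = (counts > 0).sum(axis=1).astype(float)
    pd_vals = tindex.faith_pd(counts > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(richness >= 2, shannon / np.log2(richness), np.nan)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon,
         "faith_pd": pd_vals, "pielou": pielou},
        index=table.counts.index)


def alpha_metrics(ensemble: RarefiedEnsemble, phylogeny: Phylogeny) -> pd.DataFrame:
    """Per-sample alpha metrics averaged over the rarefaction ensemble.

    Returns a frame indexed by sample with columns richness, shannon,
    faith_pd, pielou (NaN where undefined, i.e. single-taxon samples)
    plus the sample metadata columns.
    """
    tindex = phylogeny.index(ensemble.taxa)
    per_iter = [_alpha_one_table(t, tindex) for t in ensemble.tables]
    stacked = pd.concat(per_iter, keys=range(len(per_iter)))
    mean = stacked.groupby(level=1).mean()
    mean = mean.loc[ensemble.tables[0].counts.index]
    return mean.join(ensemble.sample_meta)


def alpha_comparisons(alpha: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon contrasts of each metric between sample types,
    restricted per contrast to subjects with both sites."""
    rows = []
    sites = sorted(alpha["site"].unique())
    for metric in ALPHA_METRICS:
        wide = alpha.pivot_table(index="subject_id", columns="site",
                                 values=metric, observed=True)
        for i, sa in enumerate(sites):
            for sb in sites[i + 1:]:
                if sa not in wide.columns or sb not in wide.columns:
                    continue
                sub = wide[[sa, sb]].dropna()
                if len(sub) < 3:
                    continue
                res = two_sample_test(sub[sa].values, sub[sb].values,
                                      mode="wilcoxon_signed_rank")
                rows.append({"metric": metric, "site_a": sa, "site_b": sb,
                             "n_pairs": len(sub), "statistic": res.statistic,
                             "p_value": res.p_value,
                             "median_a": float(sub[sa].median()),
                             "median_b": float(sub[sb].median())})
    return pd.DataFrame(rows)
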