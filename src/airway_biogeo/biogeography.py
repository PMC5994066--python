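"""Per-subject shared/exclusive taxon partitioning across paired sites.

For every subject, each detected taxon is assigned to exactly one region
of the presence/absence Venn partition over that subject's sampled
sites ("exclusively shared between IS and BB" = present in IS and BB
and absent from every other site the subject has).  Presence is defined
on a single canonical rarefaction (the first ensemble member) so that
detection effort is equal across samples; a raw-count alternative is
available via ``presence_rule="raw"``.

On top of the partitions: shared richness / phylogenetic-diversity
fractions of the bronchial community, group-level genus frequency
distributions for a region, per-subject genus relative-abundance profile
correlations between sites, prevalent-genus paired tests, and the
subject-level Mantel comparison of the nasal and oral phylogenetic
contributions to the bronchial community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beta import DistanceMatrix, mantel
from .core_io import CountTable, Phylogeny, TaxonomyMap, genus_name
from .stats import TestResult, bh_fdr, chi_square_rxc, correlation, fisher_exact_2x2, two_sample_test

__all__ = [
    "SharedPartition",
    "shared_partitions",
    "shared_pd_fraction",
    "shared_fraction_table",
    "shared_genus_frequency",
    "genus_profile_correlation",
    "profile_correlation_summary",
    "prevalent_genus_tests",
    "shared_taxa_unifrac",
    "mantel_shared_contribution",
]


@dataclass
class SharedPartition:
    """Presence/absence Venn partition of one subject's detected taxa."""

    subject_id: str
    group: str
    presence: pd.DataFrame  # sites x taxa, boolean

    def __post_init__(self) -> None:
        if len(self.presence) < 2:
            raise ValueError("subject needs >= 2 sampled sites")

    @property
    def sites(self) -> list[str]:
        return list(self.presence.index)

    def detected(self, site: str | None = None) -> set[str]:
        if site is None:
            mask = self.presence.any(axis=0)
        else:
            mask = self.presence.loc[site]
        return set(self.presence.columns[mask])

    def region_of(self, taxon: str) -> frozenset[str]:
        col = self.presence[taxon]
        return frozenset(col.index[col])

    def regions(self) -> dict[frozenset, set]:
        """Taxa grouped by their exact site-presence region; regions
        partition the subject's detected taxa."""
        out: dict[frozenset, set] = {}
        arr = self.presence.values
        sites = np.array(self.sites)
        for j, taxon in enumerate(self.presence.columns):
            mask = arr[:, j]
            if mask.any():
                key = frozenset(sites[mask])
                out.setdefault(key, set()).add(taxon)
        return out

    def region(self, sites) -> set:
        return self.regions().get(frozenset(sites), set())

    def intersection(self, site_a: str, site_b: str) -> set[str]:
        """Taxa present in both sites regardless of other sites."""
        mask = self.presence.loc[site_a] & self.presence.loc[site_b]
        return set(self.presence.columns[mask])

    def region_sizes(self) -> dict[str, int]:
        return {"+".join(sorted(k)): len(v) for k, v in self.regions().items()}


def _canonical_presence(table: CountTable, presence_rule: str) -> pd.DataFrame:
    if presence_rule not in ("rarefied", "raw"):
        raise ValueError(f"unknown presence rule {presence_rule!r}")
    return table.counts > 0


def shared_partitions(canonical: CountTable, presence_rule: str = "rarefied"
                      ) -> dict[str, SharedPartition]:
    """Partition every subject's detected taxa by site presence.

    ``canonical`` is the table presence is read from: the first member
    of the rarefaction ensemble under the default rule, or the raw table
    under ``presence_rule="raw"`` (the rule tag is bookkeeping; the
    caller chooses which table to pass).
    Subjects with fewer than two sampled sites are skipped.
    """
    presence = _canonical_presence(canonical, presence_rule)
    meta = canonical.sample_meta
    out = {}
    for subject, sub in meta.groupby("subject_id"):
        if len(sub) < 2:
            continue
        block = presence.loc[sub.index]
        block.index = sub["site"].values
        out[subject] = SharedPartition(subject, sub["group"].iloc[0],
                                       block.sort_index())
    return out


def shared_pd_fraction(partition: SharedPartition, phylogeny: Phylogeny,
                       focal_site: str = "BB") -> pd.DataFrame:
    """Richness and Faith-PD fractions of the focal community shared
    with each other site (plain intersection, not exclusive regions)."""
    if focal_site not in partition.sites:
        raise ValueError(f"subject {partition.subject_id} lacks {focal_site}")
    focal = partition.detected(focal_site)
    if not focal:
        raise ValueError(f"empty {focal_site} community for "
                         f"{partition.subject_id}")
    tindex = phylogeny.index(list(partition.presence.columns))
    focal_pd = tindex.faith_pd_set(focal)
    rows = []
    for site in partition.sites:
        if site == focal_site:
            continue
        shared = partition.intersection(focal_site, site)
        pd_frac = (tindex.faith_pd_set(shared) / focal_pd) if shared else 0.0
        rows.append({
            "subject_id": partition.subject_id, "group": partition.group,
            "site": site, "n_shared": len(shared),
            "richness_fraction": len(shared) / len(focal),
            "pd_fraction": pd_frac,
        })
    return pd.DataFrame(rows)


def shared_fraction_table(partitions: dict[str, SharedPartition],
                          phylogeny: Phylogeny, focal_site: str = "BB"
                          ) -> pd.DataFrame:
    """Concatenated shared richness/PD fractions for all subjects that
    have the focal site."""
    frames = [shared_pd_fraction(p, phylogeny, focal_site)
              for p in partitions.values() if focal_site in p.sites]
    if not frames:
        return pd.DataFrame(columns=["subject_id", "group", "site", "n_shared",
                                     "richness_fraction", "pd_fraction"])
    return pd.concat(frames, ignore_index=True)


def shared_genus_frequency(partitions: dict[str, SharedPartition],
                           tax: TaxonomyMap, region_sites, threshold: float,
                           exclusive: bool = True) -> pd.DataFrame:
    """Per-group fraction of subjects carrying >= 1 OTU of each genus in
    a Venn region, retained at the subject-frequency threshold.

    ``region_sites`` names the region (e.g. ("BB", "IS")); with
    ``exclusive=False`` the plain intersection is used instead of the
    exact region.  Returns genus x group retention fractions along with
    per-genus cross-group Fisher tests and an overall chi-square over
    the retained genus distribution.
    """
    region_sites = tuple(sorted(region_sites))
    counts: dict[str, dict[str, int]] = {}
    group_sizes: dict[str, int] = {}
    for p in partitions.values():
        if not set(region_sites) <= set(p.sites):
            continue
        group_sizes[p.group] = group_sizes.get(p.group, 0) + 1
        if exclusive:
            taxa = p.region(region_sites)
        else:
            taxa = set.intersection(*(p.detected(s) for s in region_sites))
        genera = {tax.genus_label(t) for t in taxa}
        for g in genera:
            counts.setdefault(g, {})
            counts[g][p.group] = counts[g].get(p.group, 0) + 1

    groups = sorted(group_sizes)
    rows = []
    for genus, per_group in sorted(counts.items()):
        frac = {g: per_group.get(g, 0) / group_sizes[g] for g in groups}
        if max(frac.values(), default=0.0) < threshold:
            continue
        row = {"genus": genus, "region": "+".join(region_sites)}
        for g in groups:
            row[f"n_{g}"] = per_group.get(g, 0)
            row[f"frac_{g}"] = frac[g]
            row[f"retained_{g}"] = frac[g] >= threshold
        if len(groups) == 2:
            ga, gb = groups
            res = fisher_exact_2x2(per_group.get(ga, 0),
                                   group_sizes[ga] - per_group.get(ga, 0),
                                   per_group.get(gb, 0),
                                   group_sizes[gb] - per_group.get(gb, 0))
            row["fisher_p"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def shared_genus_chi_square(freq: pd.DataFrame, group_a: str, group_b: str
                            ) -> TestResult:
    """Chi-square comparing two groups' retained-genus count
    distributions over a region."""
    table = freq[[f"n_{group_a}", f"n_{group_b}"]].values
    keep = table.sum(axis=1) > 0
    return chi_square_rxc(table[keep])


def genus_profile_correlation(genus_table: CountTable, subject: str,
                              site_a: str, site_b: str) -> TestResult:
    """Pearson correlation of a subject's genus relative-abundance
    profiles between two sites, over the union of detected genera."""
    meta = genus_table.sample_meta
    rel = genus_table.relative_abundance()
    ids = {}
    for site in (site_a, site_b):
        sel = meta.index[(meta["subject_id"] == subject) & (meta["site"] == site)]
        if len(sel) != 1:
            raise ValueError(f"subject {subject} lacks site {site}")
        ids[site] = sel[0]
    a = rel.loc[ids[site_a]]
    b = rel.loc[ids[site_b]]
    union = (a > 0) | (b > 0)
    if union.sum() < 3:
        return TestResult(np.nan, np.nan, "pearson", (int(union.sum()),),
                          warning="fewer than 3 genera in union")
    return correlation(a[union].values, b[union].values, mode="pearson")


def profile_correlation_summary(genus_table: CountTable,
                                site_pairs=(("BB", "IS"), ("BB", "OW"),
                                            ("BB", "NB"))) -> pd.DataFrame:
    """Median (IQR) of per-subject profile correlations per site pair,
    overall and within groups."""
    meta = genus_table.sample_meta
    rows = []
    for site_a, site_b in site_pairs:
        for subject, sub in meta.groupby("subject_id"):
            if {site_a, site_b} <= set(sub["site"]):
                res = genus_profile_correlation(genus_table, subject,
                                                site_a, site_b)
                rows.append({"subject_id": subject,
                             "group": sub["group"].iloc[0],
                             "pair": f"{site_a}-{site_b}", "r": res.statistic})
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        return per_subject
    out = []
    for (pair, scope), vals in _iter_scopes(per_subject):
        out.append({"pair": pair, "scope": scope, "n": len(vals),
                    "median_r": float(np.nanmedian(vals)),
                    "q1_r": float(np.nanpercentile(vals, 25)),
                    "q3_r": float(np.nanpercentile(vals, 75))})
    return pd.DataFrame(out)


def _iter_scopes(per_subject: pd.DataFrame):
    for pair, sub in per_subject.groupby("pair"):
        yield (pair, "all"), sub["r"].values
        for grp, gsub in sub.groupby("group"):
            yield (pair, grp), gsub["r"].values


def prevalent_genus_tests(genus_table: CountTable, threshold: float = 0.03,
                          site_pairs=(("BB", "IS"), ("BB", "OW"),
                                      ("BB", "NB"), ("IS", "OW"))
                          ) -> pd.DataFrame:
    """Paired Wilcoxon and across-subject Spearman tests per prevalent
    genus and site pair.

    A genus is prevalent when its relative abundance reaches the
    threshold in at least one sample of either site of the pair.  BH q
    values are computed within each test family across the whole scan.
    """
    rel = genus_table.relative_abundance()
    meta = genus_table.sample_meta
    rows = []
    for site_a, site_b in site_pairs:
        ma = meta[meta["site"] == site_a]
        mb = meta[meta["site"] == site_b]
        map_a = pd.Series(ma.index, index=ma["subject_id"].values)
        map_b = pd.Series(mb.index, index=mb["subject_id"].values)
        common = map_a.index.intersection(map_b.index)
        if len(common) < 3:
            continue
        a_block = rel.loc[map_a[common].values]
        b_block = rel.loc[map_b[common].values]
        a_block.index = b_block.index = common
        prevalent = rel.columns[
            (a_block.max(axis=0) >= threshold) | (b_block.max(axis=0) >= threshold)]
        for genus in prevalent:
            x, y = a_block[genus].values, b_block[genus].values
            wres = two_sample_test(x, y, mode="wilcoxon_signed_rank")
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, rho_p = np.nan, np.nan
            else:
                sres = correlation(x, y, mode="spearman")
                rho, rho_p = sres.statistic, sres.p_value
            rows.append({"pair": f"{site_a}-{site_b}", "genus": genus,
                         "n_pairs": len(common),
                         "wilcoxon_p": wres.p_value,
                         "spearman_rho": rho, "spearman_p": rho_p})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    for col in ("wilcoxon_p", "spearman_p"):
        q = np.full(len(table), np.nan)
        ok = table[col].notna().values
        if ok.any():
            q[ok] = bh_fdr(table[col].values[ok]).q_values
        table[col.replace("_p", "_q")] = q
    return table


def shared_taxa_unifrac(partitions: dict[str, SharedPartition],
                        phylogeny: Phylogeny, focal_site: str = "BB",
                        other_site: str = "NB") -> DistanceMatrix:
    """Inter-subject unweighted UniFrac on each subject's focal-site taxa
    shared with ``other_site``.

    Subjects lacking either site or sharing no taxa are dropped (an
    empty community has no UniFrac distance).
    """
    rows, subjects = [], []
    taxa = None
    for subject in sorted(partitions):
        p = partitions[subject]
        if not {focal_site, other_site} <= set(p.sites):
            continue
        if taxa is None:
            taxa = list(p.presence.columns)
        shared = p.presence.loc[focal_site] & p.presence.loc[other_site]
        if shared.any():
            rows.append(shared.values)
            subjects.append(subject)
    if len(subjects) < 3:
        raise ValueError("fewer than 3 subjects with nonempty shared sets")
    tindex = phylogeny.index(taxa)
    mat = tindex.unweighted_unifrac(np.array(rows, dtype=bool))
    return DistanceMatrix(subjects, mat, "unweighted_unifrac_shared")


def mantel_shared_contribution(partitions: dict[str, SharedPartition],
                               phylogeny: Phylogeny, n_perm: int = 999,
                               seed: int = 0, site_a: str = "NB",
                               site_b: str = "OW") -> TestResult:
    """Mantel comparison of the nasal vs oral phylogenetic contribution
    to the bronchial community.

    Matrix A: inter-subject unweighted UniFrac on BB taxa shared with
    ``site_a``; matrix B: the same on BB taxa shared with ``site_b``;
    both restricted to subjects present in both constructions.
    """
    dm_a = shared_taxa_unifrac(partitions, phylogeny, "BB", site_a)
    dm_b = shared_taxa_unifrac(partitions, phylogeny, "BB", site_b)
    common = [s for s in dm_a.labels if s in set(dm_b.labels)]
    if len(common) < 3:
        raise ValueError("fewer than 3 subjects shared between constructions")
    return mantel(dm_a.subset(common), dm_b.subset(common), n_perm, seed)
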