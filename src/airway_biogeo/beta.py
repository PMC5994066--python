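"""Phylogenetic beta diversity, ordination and its significance tests.

UniFrac distances are computed per rarefied table via the edge-incidence
representation and averaged over the rarefaction ensemble; principal
coordinate analysis (classical metric scaling) runs once on the averaged
matrix.  Compositional covariation with sample type is tested by a
linear mixed-effects model on PC1 with a per-subject random intercept
(likelihood-ratio against the intercept-only null), and phylogenetic
contributions of two compartments are compared with a permutation
Mantel test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .alpha import RarefiedEnsemble
from .core_io import CountTable, Phylogeny
from .stats import TestResult, two_sample_test

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "unifrac",
    "unifrac_single",
    "pcoa",
    "paired_site_distances",
    "paired_distance_contrasts",
    "lme_pc1",
    "mantel",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def subset(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.metric)


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame          # samples x retained axes (PC1, PC2, ...)
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues

    @property
    def pc1(self) -> pd.Series:
        return self.coordinates["PC1"]


def unifrac_single(table: CountTable, phylogeny: Phylogeny,
                   mode: str = "unweighted") -> DistanceMatrix:
    """UniFrac on one count table (no ensemble averaging)."""
    tindex = phylogeny.index(table.taxa)
    counts = table.counts.values.astype(float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("sample with zero total")
    if mode == "unweighted":
        mat = tindex.unweighted_unifrac(counts > 0)
    elif mode == "weighted_normalized":
        mat = tindex.weighted_unifrac_normalized(counts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceMatrix(table.sample_ids, mat, f"{mode}_unifrac")


def unifrac(ensemble: RarefiedEnsemble, phylogeny: Phylogeny,
            mode: str = "unweighted") -> DistanceMatrix:
    """Ensemble-averaged UniFrac distance matrix (mean over the R
    rarefied tables; order-invariant)."""
    mats = [unifrac_single(t, phylogeny, mode).values for t in ensemble.tables]
    return DistanceMatrix(ensemble.tables[0].sample_ids,
                          np.mean(mats, axis=0), f"{mode}_unifrac")


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical metric scaling (Gower double-centering).

    Axes with negative eigenvalues are dropped from the coordinates but
    their eigenvalues are reported; each retained axis is sign-fixed so
    its largest-magnitude coordinate is positive.
    """
    d2 = dm.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals).max(initial=1.0))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else evals[pos]
    frame = pd.DataFrame(coords, index=dm.labels,
                         columns=[f"PC{k+1}" for k in range(coords.shape[1])])
    if frame.shape[1] == 0:  # all distances zero
        frame["PC1"] = 0.0
    return PcoaResult(frame, evals, prop)


def paired_site_distances(dm: DistanceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Intra-subject distance for every available site pair.

    Returns one row per (subject, site_a, site_b) with columns subject_id,
    site_a, site_b, pair, distance, group.
    """
    frame = dm.to_frame()
    meta = meta.loc[frame.index]
    rows = []
    for subject, sub in meta.groupby("subject_id"):
        sites = sorted(sub["site"])
        ids = {s: i for i, s in zip(sub.index, sub["site"])}
        for a_i in range(len(sites)):
            for b_i in range(a_i + 1, len(sites)):
                sa, sb = sites[a_i], sites[b_i]
                rows.append({
                    "subject_id": subject, "site_a": sa, "site_b": sb,
                    "pair": f"{sa}-{sb}",
                    "distance": float(frame.loc[ids[sa], ids[sb]]),
                    "group": sub["group"].iloc[0],
                })
    return pd.DataFrame(rows)


def paired_distance_contrasts(paired: pd.DataFrame) -> pd.DataFrame:
    """Standard contrasts on the paired-distance table.

    Within-subject comparisons of two site pairs use the Wilcoxon
    matched-pairs test (overall and per group, plus paired t per group);
    between-group comparisons of one site pair use Welch's t.
    """
    rows = []
    wide = paired.pivot_table(index="subject_id", columns="pair",
                              values="distance", observed=True)
    groups = paired.drop_duplicates("subject_id").set_index("subject_id")["group"]
    pairs = list(wide.columns)
    for i, pa in enumerate(pairs):
        for pb in pairs[i + 1:]:
            sub = wide[[pa, pb]].dropna()
            if len(sub) >= 3:
                res = two_sample_test(sub[pa].values, sub[pb].values,
                                      mode="wilcoxon_signed_rank")
                rows.append({"contrast": f"{pa} vs {pb}", "scope": "all",
                             "test": res.method, "n": len(sub),
                             "statistic": res.statistic, "p_value": res.p_value})
            for grp, gsub in sub.groupby(groups.reindex(sub.index)):
                if len(gsub) >= 3:
                    for mode in ("wilcoxon_signed_rank", "paired_t"):
                        res = two_sample_test(gsub[pa].values, gsub[pb].values,
                                              mode=mode)
                        rows.append({"contrast": f"{pa} vs {pb}", "scope": grp,
                                     "test": res.method, "n": len(gsub),
                                     "statistic": res.statistic,
                                     "p_value": res.p_value})
    glist = sorted(groups.unique())
    for pair in pairs:
        for i, ga in enumerate(glist):
            for gb in glist[i + 1:]:
                xa = wide.loc[groups.reindex(wide.index) == ga, pair].dropna()
                xb = wide.loc[groups.reindex(wide.index) == gb, pair].dropna()
                if len(xa) >= 3 and len(xb) >= 3:
                    res = two_sample_test(xa.values, xb.values, mode="welch_t")
                    rows.append({"contrast": f"{pair}: {ga} vs {gb}",
                                 "scope": "between-group", "test": res.method,
                                 "n": len(xa) + len(xb),
                                 "statistic": res.statistic,
                                 "p_value": res.p_value})
    return pd.DataFrame(rows)


def lme_pc1(pcoa_result: PcoaResult, meta: pd.DataFrame) -> TestResult:
    """Mixed-effects test of sample type on PC1.

    Fits PC1 ~ site with a per-subject random intercept by maximum
    likelihood and compares against the intercept + random-intercept
    null with a likelihood-ratio chi-square (df = number of sites - 1).
    A singular fit (zero between-subject variance) falls back to an OLS
    likelihood-ratio with a warning.
    """
    data = pd.DataFrame({"pc1": pcoa_result.pc1})
    data = data.join(meta[["subject_id", "site"]])
    n_sites = data["site"].nunique()
    if n_sites < 2 or data["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 sites and >= 2 subjects")
    df_diff = n_sites - 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm("pc1 ~ C(site)", data,
                               groups=data["subject_id"]).fit(reml=False)
            null = smf.mixedlm("pc1 ~ 1", data,
                               groups=data["subject_id"]).fit(reml=False)
        singular = not np.isfinite(full.llf) or not np.isfinite(null.llf)
        stat = 2 * (full.llf - null.llf)
        method = "lme_lrt"
    except Exception:
        singular = True
        stat = np.nan
        method = "lme_lrt"
    if singular or stat < -1e-6:
        warnings.warn("singular mixed-model fit; falling back to OLS ANOVA")
        ols_full = smf.ols("pc1 ~ C(site)", data).fit()
        ols_null = smf.ols("pc1 ~ 1", data).fit()
        stat = 2 * (ols_full.llf - ols_null.llf)
        method = "ols_lrt_fallback"
    p = float(sps.chi2.sf(max(stat, 0.0), df_diff))
    return TestResult(float(stat), p, method, (len(data),))


def mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix,
           n_perm: int = 999, seed: int = 0) -> TestResult:
    """Permutation Mantel test (two-sided on |r|).

    The statistic is the Pearson correlation of the off-diagonal
    entries; rows and columns of the second matrix are permuted jointly,
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    """
    if dm_a.labels != dm_b.labels:
        raise ValueError("distance matrices must share labels in order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = len(dm_a.labels)
    iu = np.triu_indices(n, k=1)
    x = dm_a.values[iu]
    b = dm_b.values
    y = b[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, np.nan, "mantel", (n,),
                          warning="zero variance in distances")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = b[np.ix_(perm, perm)][iu]
        if abs(np.corrcoef(x, yp)[0, 1]) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(r_obs, p, "mantel", (n,))
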