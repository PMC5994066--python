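"""Dominant-genus classification and clinical association scans.

A sample is "dominated" by the genus with the highest relative abundance
(argmax, no minimum-share threshold; exact ties break lexicographically
and are flagged).  Dominance frequencies feed Fisher / chi-square
contingency comparisons across sites and groups.  Clinical scans relate
prevalent-genus relative abundances to clinical and inflammatory
covariates by Spearman correlation with Benjamini–Hochberg control, and
the cytokine panel is preprocessed with the half-LOD rule: a value below
the limit of detection is imputed as half the smallest detected value of
that analyte, and analytes detected in too few subjects are dropped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, CountTable, PipelineConfig, genus_name
from .stats import TestResult, bh_fdr, chi_square_rxc, correlation, fisher_exact_2x2, two_sample_test

__all__ = [
    "dominant_genus_calls",
    "dominance_frequency",
    "dominance_contingency",
    "cytokine_preprocess",
    "clinical_associations",
    "dominance_subgroup_compare",
]


def dominant_genus_calls(genus_table: CountTable) -> pd.DataFrame:
    """Argmax-genus call per sample.

    Returns a frame indexed by sample with dominant_label (the collapse
    label), dominant_genus (bare genus), its relative abundance, a tie
    flag, and the sample metadata.  Depends only on relative abundances,
    so rescaling counts cannot change a call.
    """
    rel = genus_table.relative_abundance()
    if (genus_table.counts.sum(axis=1) == 0).any():
        raise ValueError("empty sample in genus table")
    # idxmax on the lexicographically sorted columns breaks ties toward
    # the first label; flag any sample whose maximum is attained twice
    ordered = rel[sorted(rel.columns)]
    label = ordered.idxmax(axis=1)
    top = ordered.max(axis=1)
    tie = (ordered.eq(top, axis=0).sum(axis=1) > 1)
    calls = pd.DataFrame({
        "dominant_label": label,
        "dominant_genus": label.map(genus_name),
        "relative_abundance": top,
        "tie": tie,
    })
    return calls.join(genus_table.sample_meta)


def dominance_frequency(calls: pd.DataFrame, by: str = "site") -> pd.DataFrame:
    """Counts of dominant genera per site (or per site x group)."""
    keys = ["site", "group"] if by == "site_group" else [by]
    return (calls.groupby(keys + ["dominant_genus"], observed=True)
            .size().rename("n_samples").reset_index())


def dominance_contingency(calls: pd.DataFrame, focal_genus: str,
                          grouping: pd.Series) -> TestResult:
    """Fisher (2 categories) or chi-square (more) test of focal-genus
    dominance frequency across the categories of ``grouping`` (a series
    indexed like ``calls``)."""
    grouping = grouping.reindex(calls.index)
    dominated = calls["dominant_genus"] == focal_genus
    cats = sorted(grouping.dropna().unique())
    if len(cats) < 2:
        raise ValueError("grouping must define >= 2 categories")
    table = []
    for cat in cats:
        mask = grouping == cat
        table.append([int((dominated & mask).sum()),
                      int((~dominated & mask).sum())])
    if len(cats) == 2:
        (a, b), (c, d) = table
        return fisher_exact_2x2(a, b, c, d)
    return chi_square_rxc(table)


def cytokine_preprocess(clinical: ClinicalTable,
                        config: PipelineConfig) -> ClinicalTable:
    """Half-LOD imputation and low-detection analyte filtering.

    For each analyte with below-LOD flags: censored entries become half
    the minimum detected value; analytes detected in fewer than
    ``detection_subject_fraction`` of subjects (or never) are dropped
    from both the value table and the flag table.
    """
    values = clinical.values.copy()
    below = clinical.below_lod.copy()
    dropped = []
    for analyte in list(below.columns):
        flags = below[analyte].astype(bool)
        measured = values[analyte].notna()
        detected = measured & ~flags
        n_subjects = int(measured.sum())
        if n_subjects == 0 or detected.sum() == 0:
            warnings.warn(f"analyte {analyte} has no detected values; dropped")
            dropped.append(analyte)
            continue
        if detected.sum() / n_subjects < config.detection_subject_fraction:
            dropped.append(analyte)
            continue
        half_min = values.loc[detected, analyte].min() / 2.0
        values.loc[flags & measured, analyte] = half_min
    values = values.drop(columns=dropped)
    below = below.drop(columns=dropped)
    return ClinicalTable(values, below, clinical.pc20_censored)


def _default_variables(clinical: ClinicalTable) -> list[str]:
    """Numeric clinical columns, excluding binary indicators."""
    out = []
    for col in clinical.numeric_columns():
        vals = clinical.values[col].dropna().unique()
        if len(vals) > 2 or not set(np.unique(vals)) <= {0, 1}:
            out.append(col)
    return out


def clinical_associations(genus_table: CountTable, clinical: ClinicalTable,
                          config: PipelineConfig, group: str = "AA",
                          variables=None, fdr_scope: str = "site") -> pd.DataFrame:
    """Spearman scan of prevalent-genus relative abundance against
    clinical covariates within one subject group.

    Genera are prevalence-filtered per site at the >=3% (configurable)
    relative-abundance threshold; p values are BH-corrected within each
    specimen type's scan (``fdr_scope="site"``, the default — each
    sample type is its own family of hypotheses) or across the whole
    scan (``fdr_scope="all"``), and flagged at q <=
    ``config.fdr_q_assoc``.  Covariates with zero variance among the
    scanned subjects are skipped.
    """
    if variables is None:
        variables = _default_variables(clinical)
    rel = genus_table.relative_abundance()
    meta = genus_table.sample_meta
    rows = []
    for site, msub in meta[meta["group"] == group].groupby("site"):
        block = rel.loc[msub.index]
        prevalent = block.columns[block.max(axis=0) >= config.prevalence_genus_threshold]
        subjects = msub["subject_id"].values
        clin = clinical.values.reindex(subjects)
        for genus in prevalent:
            x = block[genus].values
            for var in variables:
                y = clin[var].values.astype(float)
                ok = ~np.isnan(y)
                if ok.sum() < 3:
                    continue
                if np.ptp(y[ok]) == 0 or np.ptp(x[ok]) == 0:
                    continue
                res = correlation(x[ok], y[ok], mode="spearman")
                rows.append({"genus": genus, "site": site, "variable": var,
                             "rho": res.statistic, "p_value": res.p_value,
                             "n": int(ok.sum())})
    scan = pd.DataFrame(rows)
    if scan.empty:
        return scan
    if fdr_scope == "all":
        fdr = bh_fdr(scan["p_value"].values, config.fdr_q_assoc)
        scan["q_value"] = fdr.q_values
        scan["significant"] = fdr.flags
    elif fdr_scope == "site":
        scan["q_value"] = np.nan
        scan["significant"] = False
        for site in scan["site"].unique():
            mask = (scan["site"] == site).values
            fdr = bh_fdr(scan.loc[mask, "p_value"].values, config.fdr_q_assoc)
            scan.loc[mask, "q_value"] = fdr.q_values
            scan.loc[mask, "significant"] = fdr.flags
    else:
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    return scan.sort_values("q_value", kind="stable").reset_index(drop=True)


def dominance_subgroup_compare(calls: pd.DataFrame, clinical: ClinicalTable,
                               focal_genus: str = "Corynebacterium",
                               site: str = "NB", group: str = "AA",
                               variables=None) -> pd.DataFrame:
    """Compare clinical covariates between subjects whose ``site``
    community is vs is not dominated by ``focal_genus``, within a group.

    Continuous covariates: Mann-Whitney; binary covariates: Fisher
    exact.  Raises if either subgroup is empty.
    """
    sub = calls[(calls["site"] == site) & (calls["group"] == group)]
    if sub.empty:
        raise ValueError(f"no {site} samples in group {group}")
    dominated = sub["dominant_genus"] == focal_genus
    subj_dom = sub.loc[dominated, "subject_id"]
    subj_other = sub.loc[~dominated, "subject_id"]
    if len(subj_dom) == 0 or len(subj_other) == 0:
        raise ValueError("one dominance subgroup is empty")
    clin = clinical.values
    if variables is None:
        variables = [c for c in clin.columns if c != "group"
                     and pd.api.types.is_numeric_dtype(clin[c])]
    rows = []
    for var in variables:
        x = clin.reindex(subj_dom)[var].dropna()
        y = clin.reindex(subj_other)[var].dropna()
        if len(x) < 2 or len(y) < 2:
            continue
        uniq = set(pd.concat([x, y]).unique())
        if uniq <= {0, 1}:
            res = fisher_exact_2x2(int(x.sum()), int((1 - x).sum()),
                                   int(y.sum()), int((1 - y).sum()))
        else:
            res = two_sample_test(x.values, y.values, mode="mann_whitney")
        rows.append({"variable": var, "test": res.method,
                     "n_dominated": len(x), "n_other": len(y),
                     "median_dominated": float(np.median(x)),
                     "median_other": float(np.median(y)),
                     "statistic": res.statistic, "p_value": res.p_value})
    return pd.DataFrame(rows)
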