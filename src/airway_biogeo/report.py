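"""End-to-end pipeline orchestration.

``run_all`` executes the full analysis sequence on a validated bundle —
QC, rarefaction ensemble, alpha diversity, UniFrac/PCoA/mixed-model
beta diversity, shared-taxon biogeography, dominance and clinical
association scans, and three-model differential abundance — and returns
an AnalysisReport of named result tables with provenance (config hash
and seed).  ``write_report`` serializes the report as a directory of
TSVs plus a JSON index; re-running into the same directory with an
unchanged configuration is a no-op.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import biogeography as bio_mod
from . import da as da_mod
from . import dominance as dom_mod
from .core_io import (ClinicalTable, CountTable, Phylogeny, PipelineConfig,
                      TaxonomyMap, apply_qc_filters, collapse_to_genus)

__all__ = ["AnalysisReport", "run_all", "write_report"]


@dataclass
class AnalysisReport:
    """Named result tables with reproducibility provenance."""

    blocks: dict[str, pd.DataFrame]
    absent: dict[str, str]          # block name -> reason it was skipped
    config_hash: str
    seed: int

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.blocks[name]


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(table: CountTable, taxonomy: TaxonomyMap, phylogeny: Phylogeny,
            clinical: ClinicalTable, config: PipelineConfig,
            control_taxa=(), da_sites=("NB", "BB"),
            da_groups=("AA", "HC")) -> AnalysisReport:
    """Run the full analysis in dependency order; deterministic given
    the config seed.  Blocks whose inputs are missing from the bundle
    (e.g. no NB samples) are recorded as absent rather than failing."""
    blocks: dict[str, pd.DataFrame] = {}
    absent: dict[str, str] = {}

    stage = "qc"
    try:
        table = apply_qc_filters(table, config, control_taxa)
        stage = "rarefaction"
        ensemble = alpha_mod.build_ensemble(table, config)
        canonical = ensemble.tables[0]
        meta = canonical.sample_meta
        sites = set(meta["site"])

        stage = "alpha"
        alpha = alpha_mod.alpha_metrics(ensemble, phylogeny)
        blocks["alpha_metrics"] = alpha.reset_index(names="sample_id")
        blocks["alpha_comparisons"] = alpha_mod.alpha_comparisons(alpha)

        stage = "beta"
        dm_u = beta_mod.unifrac(ensemble, phylogeny, "unweighted")
        dm_w = beta_mod.unifrac(ensemble, phylogeny, "weighted_normalized")
        blocks["unweighted_unifrac"] = dm_u.to_frame().reset_index(names="sample_id")
        blocks["weighted_unifrac"] = dm_w.to_frame().reset_index(names="sample_id")
        ord_u = beta_mod.pcoa(dm_u)
        blocks["pcoa_coordinates"] = ord_u.coordinates.reset_index(names="sample_id")
        paired = beta_mod.paired_site_distances(dm_u, meta)
        blocks["paired_distances_unweighted"] = paired
        blocks["paired_distances_weighted"] = beta_mod.paired_site_distances(dm_w, meta)
        blocks["paired_distance_contrasts"] = beta_mod.paired_distance_contrasts(paired)
        lme = beta_mod.lme_pc1(ord_u, meta)
        blocks["lme_pc1"] = pd.DataFrame([lme.to_row()])

        stage = "biogeography"
        partitions = bio_mod.shared_partitions(canonical)
        blocks["region_sizes"] = pd.DataFrame(
            [{"subject_id": s, "group": p.group, **p.region_sizes()}
             for s, p in partitions.items()]).fillna(0)
        blocks["shared_fractions"] = bio_mod.shared_fraction_table(
            partitions, phylogeny)
        genus_table = collapse_to_genus(canonical, taxonomy)
        blocks["profile_correlations"] = bio_mod.profile_correlation_summary(genus_table)
        blocks["prevalent_genus_tests"] = bio_mod.prevalent_genus_tests(
            genus_table, config.prevalence_genus_threshold)
        if {"BB", "IS"} <= sites:
            blocks["shared_genus_frequency_is_bb"] = bio_mod.shared_genus_frequency(
                partitions, taxonomy, ("BB", "IS"),
                config.shared_subject_frequency_threshold)
        else:
            absent["shared_genus_frequency_is_bb"] = "BB or IS absent"
        if {"BB", "NB", "OW"} <= sites:
            try:
                mt = bio_mod.mantel_shared_contribution(
                    partitions, phylogeny, config.mantel_permutations,
                    config.seed)
                blocks["mantel_nasal_vs_oral"] = pd.DataFrame([mt.to_row()])
            except ValueError as exc:
                absent["mantel_nasal_vs_oral"] = str(exc)
        else:
            absent["mantel_nasal_vs_oral"] = "NB or OW absent"

        stage = "dominance"
        calls = dom_mod.dominant_genus_calls(genus_table)
        blocks["dominance_calls"] = calls.reset_index(names="sample_id")
        blocks["dominance_frequency"] = dom_mod.dominance_frequency(
            calls, by="site_group")
        cont_rows = []
        for other in ("IS", "OW", "NB"):
            if {"BB", other} <= sites:
                pair = calls[calls["site"].isin(["BB", other])]
                try:
                    res = dom_mod.dominance_contingency(
                        pair, "Prevotella", pair["site"])
                    cont_rows.append({"comparison": f"Prevotella BB vs {other}",
                                      **res.to_row()})
                except ValueError:
                    pass
        blocks["dominance_contingency"] = pd.DataFrame(cont_rows)

        stage = "clinical_associations"
        clinical_pp = dom_mod.cytokine_preprocess(clinical, config)
        blocks["clinical_associations_aa"] = dom_mod.clinical_associations(
            genus_table, clinical_pp, config, group="AA")
        if "NB" in sites:
            try:
                blocks["dominance_subgroup_nb"] = dom_mod.dominance_subgroup_compare(
                    calls, clinical_pp, "Corynebacterium", "NB", "AA")
            except ValueError as exc:
                absent["dominance_subgroup_nb"] = str(exc)
        else:
            absent["dominance_subgroup_nb"] = "NB absent"

        stage = "differential_abundance"
        for site in da_sites:
            name = f"da_{site.lower()}_{da_groups[0].lower()}_vs_{da_groups[1].lower()}"
            msub = table.sample_meta
            sel = msub.index[(msub["site"] == site)
                             & (msub["group"].isin(da_groups))]
            if len(sel) == 0:
                absent[name] = f"no {site} samples"
                continue
            sub = table.select_samples(sel)
            grouping = sub.sample_meta["group"]
            if grouping.nunique() != 2 or grouping.value_counts().min() < 3:
                absent[name] = "fewer than 3 samples in a group"
                continue
            blocks[name] = da_mod.da_scan(sub, grouping, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return AnalysisReport(blocks, absent, config_hash(config), config.seed)


def write_report(report: AnalysisReport, out_dir) -> Path:
    """Serialize a report as TSVs plus index.json.

    If the directory already holds a report with the same config hash
    and seed, nothing is recomputed or rewritten.
    """
    out = Path(out_dir)
    index_path = out / "index.json"
    if index_path.exists():
        old = json.loads(index_path.read_text())
        if (old.get("config_hash") == report.config_hash
                and old.get("seed") == report.seed):
            return index_path
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in report.blocks.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    index = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "blocks": sorted(report.blocks),
        "absent": report.absent,
    }
    index_path.write_text(json.dumps(index, indent=1, sort_keys=True))
    return index_path
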