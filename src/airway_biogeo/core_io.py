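"""Domain types, file I/O and quality-control filtering.

The analysis operates on a bundle of four objects: an OTU count table
with per-sample metadata, a taxonomy map, a rooted phylogeny over the
OTUs, and a subject-level clinical table.  This module defines those
types, reads/writes them (TSV and BIOM-JSON v1.0 for counts, TSV for
taxonomy/metadata, newick for the tree), validates cross-references,
and applies the study's sample/taxon QC rules: removal of taxa detected
in negative controls and exclusion of induced-sputum samples dominated
by squamous epithelial cells.

Sample identifiers are always ``<subject_id>_<site>``, which guarantees
uniqueness of (subject, site) pairs and makes joins to subject-level
clinical data trivial.  Samples and taxa are canonicalized to
lexicographic order at load so downstream computations are deterministic.
"""

from __future__ import annotations

import io
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._tree import TreeIndex

logger = logging.getLogger("airway_biogeo")

SITES = ("BB", "IS", "OW", "NB")
GROUPS = ("AA", "ANA", "HC")
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_GG_PREFIX = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
              "f": "family", "g": "genus", "s": "species"}

SAMPLE_META_COLUMNS = ("subject_id", "site", "group", "squamous_pct", "is_control")
LOD_SUFFIX = "__below_lod"


# ----------------------------------------------------------------------
# domain types


@dataclass
class CountTable:
    """Samples x taxa nonnegative integer counts plus per-sample metadata.

    ``counts`` is indexed by sample id; ``sample_meta`` shares that index
    and carries subject_id, site, group, squamous_pct (IS only, fraction)
    and is_control.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(c.values, np.round(c.values)):
            raise ValueError("non-integral counts")
        if c.columns.duplicated().any():
            raise ValueError("duplicate taxon identifiers")
        if c.index.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if not c.index.equals(self.sample_meta.index):
            raise ValueError("counts and sample_meta indexes disagree")
        pairs = self.sample_meta[["subject_id", "site"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(f"duplicate (subject, site) pair: {dup}")
        bad = set(self.sample_meta["site"]) - set(SITES)
        if bad:
            raise ValueError(f"unknown sites: {sorted(bad)}")

    # -- convenience ----------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def canonicalize(self) -> "CountTable":
        """Sort samples and taxa lexicographically."""
        counts = self.counts.sort_index(axis=0).sort_index(axis=1)
        meta = self.sample_meta.loc[counts.index]
        return CountTable(counts, meta)

    def select_samples(self, sample_ids) -> "CountTable":
        ids = [s for s in self.sample_ids if s in set(sample_ids)]
        return CountTable(self.counts.loc[ids], self.sample_meta.loc[ids])

    def site_subset(self, site: str) -> "CountTable":
        keep = self.sample_meta.index[self.sample_meta["site"] == site]
        return self.select_samples(keep)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)


@dataclass
class TaxonomyMap:
    """Per-taxon lineage at ranks kingdom..species; NaN = unassigned.

    Ranks must form a prefix: no assigned rank below an unassigned one.
    """

    lineage: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineage.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        self.lineage = self.lineage[list(RANKS)]
        assigned = self.lineage.notna().values
        # prefix property: once unassigned, everything deeper is unassigned
        if (assigned[:, 1:] & ~assigned[:, :-1]).any():
            bad = self.lineage.index[(assigned[:, 1:] & ~assigned[:, :-1]).any(axis=1)]
            raise ValueError(f"non-prefix lineage for taxa: {list(bad[:5])}")

    def covers(self, taxa) -> bool:
        return set(taxa) <= set(self.lineage.index)

    def genus_label(self, taxon: str) -> str:
        """Collapse label: 'Family (Genus)' when genus is assigned, else
        the deepest assigned rank name, else 'Unclassified'."""
        row = self.lineage.loc[taxon]
        genus, family = row["genus"], row["family"]
        if isinstance(genus, str):
            if isinstance(family, str):
                return f"{family} ({genus})"
            return genus
        for rank in reversed(RANKS[:-2]):  # species ruled out by prefix rule
            val = row[rank]
            if isinstance(val, str):
                return val
        return "Unclassified"


@dataclass
class Phylogeny:
    """Rooted tree with nonnegative branch lengths whose tips are taxa."""

    tree: TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if len(set(tips)) != len(tips):
            raise ValueError("duplicate tip labels")
        for node in self.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length")
        self._tip_set = set(tips)
        self._index_cache: dict[tuple[str, ...], TreeIndex] = {}

    @property
    def tip_names(self) -> set[str]:
        return set(self._tip_set)

    def index(self, taxa) -> TreeIndex:
        key = tuple(taxa)
        if key not in self._index_cache:
            self._index_cache[key] = TreeIndex(self.tree, list(key))
        return self._index_cache[key]

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue()


@dataclass
class ClinicalTable:
    """Subject-level clinical and inflammatory variables.

    ``values`` is indexed by subject id and includes a ``group`` column;
    numeric columns hold clinical measurements (fractions in [0, 1],
    concentrations in pg/mL, PC20 in mg/mL).  ``below_lod`` is a boolean
    frame (same index) for analytes with a detection limit: True marks a
    measurement below the limit of detection.  ``pc20_censored`` flags
    subjects whose methacholine challenge stopped at the top dose.
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame = field(default_factory=pd.DataFrame)
    pc20_censored: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    def __post_init__(self) -> None:
        if "group" not in self.values.columns:
            raise ValueError("clinical table requires a 'group' column")
        # canonical subject order so round trips are deterministic
        self.values = self.values.sort_index()
        if not self.below_lod.empty:
            self.below_lod = self.below_lod.reindex(self.values.index)
        if len(self.pc20_censored):
            self.pc20_censored = self.pc20_censored.reindex(self.values.index)
        bad = set(self.values["group"].dropna()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        for col in self.values.columns:
            if col == "group":
                continue
            v = pd.to_numeric(self.values[col], errors="coerce")
            if col.endswith("_pct") or col.endswith("_frac"):
                inrange = v.dropna().between(0, 1).all()
                if not inrange:
                    raise ValueError(f"fraction column {col} outside [0, 1]")
            elif (v.dropna() < 0).any():
                raise ValueError(f"negative values in {col}")
        if not self.below_lod.empty:
            extra = set(self.below_lod.columns) - set(self.values.columns)
            if extra:
                raise ValueError(f"below_lod flags for unknown analytes: {sorted(extra)}")

    @property
    def analytes(self) -> list[str]:
        return list(self.below_lod.columns)

    def numeric_columns(self) -> list[str]:
        return [c for c in self.values.columns
                if c != "group" and pd.api.types.is_numeric_dtype(self.values[c])]


@dataclass(frozen=True)
class PipelineConfig:
    """Global analysis parameters.

    Defaults encode the study's stated thresholds: rarefaction to 26,185
    reads, >=3% prevalent-genus filter, >=20% shared-subject frequency,
    80% squamous-cell exclusion for induced sputum, cytokines kept only
    when detected in >=20% of subjects, q < 0.10 for differential
    abundance and q <= 0.20 for the clinical association scan.
    """

    rarefaction_depth: int = 26_185
    n_rarefactions: int = 10
    seed: int = 0
    prevalence_genus_threshold: float = 0.03
    shared_subject_frequency_threshold: float = 0.20
    squamous_max: float = 0.80
    detection_subject_fraction: float = 0.20
    fdr_q_da: float = 0.10
    fdr_q_assoc: float = 0.20
    mantel_permutations: int = 999

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if self.n_rarefactions < 1:
            raise ValueError("n_rarefactions must be >= 1")
        for name in ("prevalence_genus_threshold", "shared_subject_frequency_threshold",
                     "squamous_max", "detection_subject_fraction",
                     "fdr_q_da", "fdr_q_assoc"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.mantel_permutations < 99:
            raise ValueError("mantel_permutations must be >= 99")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# readers / writers


def read_counts_tsv(path) -> pd.DataFrame:
    """TSV with taxa as rows and samples as columns -> samples x taxa."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df.T
    counts.index.name = "sample_id"
    counts.columns.name = "taxon"
    return counts.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    out = counts.T
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_counts_biom_json(path) -> pd.DataFrame:
    """Minimal BIOM-JSON v1.0 reader (dense or sparse matrix_type),
    returning samples x taxa counts."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]         # observations = taxa
    cols = [c["id"] for c in doc["columns"]]      # samples
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=np.int64)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = int(round(v))
    else:
        raise ValueError(f"unsupported matrix_type {doc['matrix_type']!r}")
    return pd.DataFrame(mat.T, index=pd.Index(cols, name="sample_id"),
                        columns=pd.Index(rows, name="taxon"))


def write_counts_biom_json(counts: pd.DataFrame, path, generated_by="airway-biogeo") -> None:
    mat = counts.T.values  # observations x samples
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": generated_by,
        "date": "1970-01-01T00:00:00",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(mat.shape),
        "rows": [{"id": t, "metadata": None} for t in counts.columns],
        "columns": [{"id": s, "metadata": None} for s in counts.index],
        "data": [[int(i), int(j), int(mat[i, j])]
                 for i, j in zip(*np.nonzero(mat))],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_taxonomy_tsv(path) -> TaxonomyMap:
    """Two-column TSV taxon -> Greengenes lineage string
    ('k__Bacteria; p__...; g__Prevotella; s__')."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lineage_col = df.columns[0]
    records = {}
    for taxon, lineage in df[lineage_col].items():
        records[taxon] = parse_gg_lineage(lineage)
    frame = pd.DataFrame.from_dict(records, orient="index", columns=list(RANKS))
    frame.index.name = "taxon"
    return TaxonomyMap(frame)


def parse_gg_lineage(lineage: str) -> list:
    """Parse 'k__Bacteria; p__Firmicutes; ...' into a rank list; empty
    payloads (e.g. 'g__') are unassigned (None)."""
    out: dict[str, str | None] = {r: None for r in RANKS}
    if isinstance(lineage, str):
        for part in lineage.split(";"):
            part = part.strip()
            if len(part) >= 3 and part[1:3] == "__":
                rank = _GG_PREFIX.get(part[0])
                payload = part[3:].strip()
                if rank and payload:
                    out[rank] = payload
    return [out[r] for r in RANKS]


def format_gg_lineage(row: pd.Series) -> str:
    parts = []
    for rank in RANKS:
        val = row[rank]
        parts.append(f"{rank[0]}__{val if isinstance(val, str) else ''}")
    return "; ".join(parts)


def write_taxonomy_tsv(tax: TaxonomyMap, path) -> None:
    out = pd.DataFrame({
        "lineage": [format_gg_lineage(tax.lineage.loc[t]) for t in tax.lineage.index]
    }, index=tax.lineage.index)
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_tree_newick(path) -> Phylogeny:
    return Phylogeny(TreeNode.read(str(path), format="newick"))


def read_metadata_tsv(path) -> tuple[pd.DataFrame, ClinicalTable]:
    """Read the combined sample/clinical metadata TSV.

    One row per sample.  Sample-level columns: sample_id (index),
    subject_id, site, group, squamous_pct, is_control.  All remaining
    numeric columns are subject-level clinical variables (constant
    within subject); a companion boolean column '<analyte>__below_lod'
    marks censored cytokine measurements.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("subject_id", "site", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if "squamous_pct" not in df.columns:
        df["squamous_pct"] = np.nan
    if "is_control" not in df.columns:
        df["is_control"] = False
    df["is_control"] = df["is_control"].astype(bool)
    meta = df[list(SAMPLE_META_COLUMNS)].copy()

    clinical_cols = [c for c in df.columns
                     if c not in SAMPLE_META_COLUMNS and not c.endswith(LOD_SUFFIX)]
    lod_cols = [c for c in df.columns if c.endswith(LOD_SUFFIX)]
    subj = df[~df["is_control"]].groupby("subject_id").first()
    values = subj[["group"] + clinical_cols].copy()
    for c in clinical_cols:
        values[c] = pd.to_numeric(values[c], errors="coerce")
    below = pd.DataFrame(index=values.index)
    for c in lod_cols:
        below[c[: -len(LOD_SUFFIX)]] = subj[c].astype(bool)
    pc20_cens = (subj["pc20_censored"].astype(bool)
                 if "pc20_censored" in subj.columns
                 else pd.Series(False, index=values.index))
    if "pc20_censored" in values.columns:
        values = values.drop(columns=["pc20_censored"])
    clinical = ClinicalTable(values, below, pc20_cens)
    return meta, clinical


def load_dataset(counts_path, taxonomy_path, tree_path, metadata_path,
                 ) -> tuple[CountTable, TaxonomyMap, Phylogeny, ClinicalTable]:
    """Load and cross-validate a dataset bundle.

    Counts may be TSV or BIOM-JSON v1.0 (auto-detected).  Raises a
    ValueError naming the offending taxon/subject when the bundle is
    internally inconsistent.  Samples and taxa come back in canonical
    (lexicographic) order.
    """
    counts_path = Path(counts_path)
    head = counts_path.read_text()[:1]
    counts = (read_counts_biom_json(counts_path) if head == "{"
              else read_counts_tsv(counts_path))
    tax = read_taxonomy_tsv(taxonomy_path)
    phy = read_tree_newick(tree_path)
    meta, clinical = read_metadata_tsv(metadata_path)

    meta = meta.loc[counts.index.intersection(meta.index)]
    if len(meta) != len(counts):
        missing = set(counts.index) - set(meta.index)
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    table = CountTable(counts, meta).canonicalize()

    for taxon in table.taxa:
        if taxon not in tax.lineage.index:
            raise ValueError(f"taxon {taxon!r} missing from taxonomy")
        if taxon not in phy.tip_names:
            raise ValueError(f"taxon {taxon!r} missing from tree")
    subj_counts = set(table.sample_meta.loc[~table.sample_meta["is_control"],
                                            "subject_id"])
    subj_clin = set(clinical.values.index)
    if not subj_counts <= subj_clin:
        missing = subj_counts - subj_clin
        raise ValueError(f"subjects without clinical rows: {sorted(missing)[:5]}")
    return table, tax, phy, clinical


# ----------------------------------------------------------------------
# QC filters and genus collapse


def derive_control_taxa(table: CountTable) -> set[str]:
    """All taxa with nonzero counts in samples flagged is_control."""
    ctrl = table.sample_meta["is_control"].fillna(False).astype(bool)
    if not ctrl.any():
        return set()
    sub = table.counts.loc[ctrl.values]
    return set(sub.columns[(sub > 0).any(axis=0)])


def apply_qc_filters(table: CountTable, config: PipelineConfig,
                     control_taxa=()) -> CountTable:
    """Remove control samples, control-detected taxa, and IS samples with
    more than ``squamous_max`` squamous epithelial cells.  Idempotent;
    surviving counts are unchanged."""
    control_taxa = set(control_taxa)
    unknown = control_taxa - set(table.taxa)
    if unknown:
        raise ValueError(f"control taxa not in table: {sorted(unknown)[:5]}")

    meta = table.sample_meta
    is_ctrl = meta["is_control"].fillna(False).astype(bool)
    drop_ctrl = meta.index[is_ctrl]
    squam = pd.to_numeric(meta["squamous_pct"], errors="coerce")
    drop_squam = meta.index[(meta["site"] == "IS") & (squam > config.squamous_max)]
    for s in drop_ctrl:
        logger.info("QC: removed control sample %s", s)
    for s in drop_squam:
        logger.info("QC: removed IS sample %s (squamous_pct=%.2f > %.2f)",
                    s, squam[s], config.squamous_max)
    for t in sorted(control_taxa):
        logger.info("QC: removed control-detected taxon %s", t)

    keep_samples = meta.index.difference(drop_ctrl.union(drop_squam), sort=False)
    keep_taxa = [t for t in table.taxa if t not in control_taxa]
    counts = table.counts.loc[keep_samples, keep_taxa]
    if counts.empty:
        warnings.warn("QC filtering removed every sample")
    return CountTable(counts, meta.loc[keep_samples])


def collapse_to_genus(table: CountTable, tax: TaxonomyMap) -> CountTable:
    """Sum OTU counts within genus-level labels.

    Labels are 'Family (Genus)' where the genus is assigned, otherwise
    the deepest assigned rank's name; fully unassigned OTUs pool into
    'Unclassified'.  Per-sample totals are conserved exactly.
    """
    if not tax.covers(table.taxa):
        missing = set(table.taxa) - set(tax.lineage.index)
        raise ValueError(f"taxonomy does not cover: {sorted(missing)[:5]}")
    labels = {t: tax.genus_label(t) for t in table.taxa}
    collapsed = table.counts.T.groupby(
        table.counts.columns.map(labels)).sum().T.sort_index(axis=1)
    collapsed.columns.name = "genus"
    return CountTable(collapsed, table.sample_meta)


def genus_name(label: str) -> str:
    """Genus component of a collapse label ('Prevotellaceae (Prevotella)'
    -> 'Prevotella'; bare labels pass through)."""
    if label.endswith(")") and "(" in label:
        return label[label.rindex("(") + 1: -1]
    return label


def label_matches_genus(label: str, genus: str) -> bool:
    return genus_name(label) == genus
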