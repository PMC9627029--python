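"""Domain types and readers/writers for ASV tables, metadata, taxonomy and trees.

The central object is :class:`AsvTable`, a features x samples count matrix with
aligned identifier lists.  All on-disk formats are plain text: tab-separated
tables and newick trees, so that a whole analysis directory remains diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("gutsampler")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style single-letter rank prefixes, in canonical order.
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class Site(str, Enum):
    """Alimentary-tract sampling locations, plus the negative control."""

    CROP = "crop"
    PROVENTRICULUS = "proventriculus"
    GIZZARD = "gizzard"
    DUODENUM = "duodenum"
    JEJUNUM = "jejunum"
    ILEUM = "ileum"
    CECUM = "cecum"
    COLON = "colon"
    CLOACAL_SWAB = "cloacal_swab"
    NEGATIVE_CONTROL = "negative_control"


#: Anatomical (orad -> aborad) ordinal of each site.  The two cecal pouches
#: share one ordinal; the flow order proventriculus-then-gizzard is used.
SITE_ORDINALS: dict[Site, int] = {
    Site.CROP: 1,
    Site.PROVENTRICULUS: 2,
    Site.GIZZARD: 3,
    Site.DUODENUM: 4,
    Site.JEJUNUM: 5,
    Site.ILEUM: 6,
    Site.CECUM: 7,
    Site.COLON: 8,
    Site.CLOACAL_SWAB: 9,
}


class Pouch(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass
class AsvTable:
    """Non-negative count matrix, features x samples, with aligned id lists."""

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        validate_asv_table(self)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample(self, sample_id: str) -> np.ndarray:
        """Count vector of one sample (a view onto the matrix column)."""
        return self.counts[:, self.sample_ids.index(sample_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AsvTable(self.counts[:, idx], list(self.feature_ids),
                        [self.sample_ids[i] for i in idx], self.normalized)

    def select_features(self, feature_ids: Sequence[str]) -> "AsvTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return AsvTable(self.counts[idx, :], [self.feature_ids[i] for i in idx],
                        list(self.sample_ids), self.normalized)

    def drop_features(self, feature_ids: Iterable[str]) -> "AsvTable":
        drop = set(feature_ids)
        keep = [f for f in self.feature_ids if f not in drop]
        return self.select_features(keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids,
                            columns=self.sample_ids)


def validate_asv_table(table: AsvTable) -> None:
    counts = table.counts
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D matrix")
    if len(table.feature_ids) != counts.shape[0]:
        raise ValueError(
            f"{len(table.feature_ids)} feature ids for {counts.shape[0]} rows")
    if len(table.sample_ids) != counts.shape[1]:
        raise ValueError(
            f"{len(table.sample_ids)} sample ids for {counts.shape[1]} columns")
    for name, ids in (("feature", table.feature_ids), ("sample", table.sample_ids)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate {name} id: {i!r}")
            seen.add(i)
    if not np.all(np.isfinite(counts)):
        bad = np.argwhere(~np.isfinite(counts))[0]
        raise ValueError(f"non-finite count at row {bad[0]}, column {bad[1]}")
    if (counts < 0).any():
        bad = np.argwhere(counts < 0)[0]
        raise ValueError(
            f"negative count at feature {table.feature_ids[bad[0]]!r}, "
            f"sample {table.sample_ids[bad[1]]!r}")
    if not table.normalized and not np.allclose(counts, np.round(counts)):
        bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
        raise ValueError(
            f"non-integer count in unnormalized table at feature "
            f"{table.feature_ids[bad[0]]!r}, sample {table.sample_ids[bad[1]]!r}")


@dataclass
class SampleMetadata:
    """Per-sample study metadata: bird, site, pouch side, DNA concentration."""

    sample_id: str
    bird_id: str
    site: Site
    pouch: Pouch | None = None
    ordinal: int | None = None
    dna_conc: float | None = None
    is_negative: bool = False

    def __post_init__(self) -> None:
        self.site = Site(self.site)
        if self.pouch is not None:
            self.pouch = Pouch(self.pouch)
        if (self.pouch is not None) != (self.site is Site.CECUM):
            if self.site is Site.CECUM:
                raise ValueError(f"cecum sample {self.sample_id!r} lacks a pouch side")
            raise ValueError(
                f"sample {self.sample_id!r} has pouch set but site is {self.site.value}")
        if self.site is Site.NEGATIVE_CONTROL:
            self.is_negative = True
        elif self.is_negative:
            raise ValueError(
                f"sample {self.sample_id!r} flagged negative but site is {self.site.value}")
        if self.ordinal is None and self.site is not Site.NEGATIVE_CONTROL:
            self.ordinal = SITE_ORDINALS[self.site]
        if self.dna_conc is not None and not self.dna_conc > 0:
            raise ValueError(f"dna_conc must be > 0 (sample {self.sample_id!r})")


@dataclass
class TaxonomyTable:
    """feature id -> ordered rank labels (kingdom..species, None = unassigned)."""

    lineages: dict[str, dict[str, str | None]]

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, str | None]] = {}
        for fid, ranks in self.lineages.items():
            row = {r: None for r in RANKS}
            for r, label in ranks.items():
                if r not in RANKS:
                    raise ValueError(f"unknown rank {r!r} for feature {fid!r}")
                if label is not None and str(label).strip():
                    row[r] = str(label).strip()
            clean[fid] = row
        self.lineages = clean

    def label(self, feature_id: str, rank: str) -> str | None:
        row = self.lineages.get(feature_id)
        return None if row is None else row.get(rank)

    def lineage(self, feature_id: str) -> tuple[str | None, ...]:
        row = self.lineages.get(feature_id, {})
        return tuple(row.get(r) for r in RANKS)


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise dissimilarities between samples."""

    data: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.sample_ids = list(self.sample_ids)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError(f"matrix shape {self.data.shape} != ({n}, {n})")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in distance matrix")
        if (self.data < 0).any():
            raise ValueError("negative distance")
        if not np.allclose(self.data, self.data.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric within 1e-9")
        if not np.allclose(np.diag(self.data), 0, atol=1e-9):
            raise ValueError("distance matrix diagonal not zero")
        # exact symmetry / zero diagonal after validation
        self.data = (self.data + self.data.T) / 2.0
        np.fill_diagonal(self.data, 0.0)

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.sample_ids.index(a), self.sample_ids.index(b)])

    def submatrix(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.sample_ids.index(s) for s in sample_ids])
        return DistanceMatrix(self.data[np.ix_(idx, idx)], list(sample_ids))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_asv_table(path, orientation: str = "features_by_samples") -> AsvTable:
    """Read a TSV count table; first column feature ids, header sample ids.

    ``orientation="samples_by_features"`` transposes after parsing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples_by_features":
        df = df.T
    elif orientation != "features_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df.iloc[:, j]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {df.index[i]!r}, "
                        f"column {col!r}: {v!r}") from exc
        raise
    integral = np.allclose(counts, np.round(counts))
    return AsvTable(counts, [str(i) for i in df.index],
                    [str(c) for c in df.columns], normalized=not integral)


def write_asv_table(table: AsvTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (sample_id, bird_id, site required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "bird_id", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        site_label = str(row["site"]).strip()
        try:
            site = Site(site_label)
        except ValueError:
            allowed = ", ".join(s.value for s in Site)
            raise ValueError(
                f"unknown site {site_label!r} for sample {row['sample_id']!r}; "
                f"allowed: {allowed}") from None
        pouch = row.get("pouch")
        pouch = None if pd.isna(pouch) or str(pouch).strip() == "" else str(pouch).strip()
        dna = row.get("dna_conc")
        dna = None if dna is None or pd.isna(dna) or str(dna).strip() == "" else float(dna)
        ordinal = row.get("ordinal")
        ordinal = None if ordinal is None or pd.isna(ordinal) else int(float(ordinal))
        records.append(SampleMetadata(
            sample_id=str(row["sample_id"]), bird_id=str(row["bird_id"]),
            site=site, pouch=pouch, ordinal=ordinal, dna_conc=dna,
            is_negative=site is Site.NEGATIVE_CONTROL))
    seen: set[str] = set()
    for r in records:
        if r.sample_id in seen:
            raise ValueError(f"duplicate sample id in metadata: {r.sample_id!r}")
        seen.add(r.sample_id)
    return records


def write_metadata(meta: Sequence[SampleMetadata], path) -> None:
    rows = [{
        "sample_id": m.sample_id, "bird_id": m.bird_id, "site": m.site.value,
        "pouch": "" if m.pouch is None else m.pouch.value,
        "ordinal": "" if m.ordinal is None else m.ordinal,
        "dna_conc": "" if m.dna_conc is None else m.dna_conc,
        "is_negative": str(m.is_negative).lower(),
    } for m in meta]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_greengenes(lineage: str) -> dict[str, str | None]:
    out: dict[str, str | None] = {}
    for part in lineage.split(";"):
        part = part.strip()
        for rank, prefix in zip(RANKS, _RANK_PREFIXES):
            if part.lower().startswith(prefix):
                label = part[len(prefix):].strip()
                out[rank] = label or None
                break
    return out


def read_taxonomy(path) -> TaxonomyTable:
    """Read taxonomy as per-rank columns or a Greengenes ``k__;p__;...`` string."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "feature_id" not in cols:
        raise ValueError("taxonomy file needs a feature_id column")
    lineages: dict[str, dict[str, str | None]] = {}
    rank_cols = [r for r in RANKS if r in cols]
    lineage_col = cols.get("taxonomy") or cols.get("lineage")
    for _, row in df.iterrows():
        fid = str(row[cols["feature_id"]])
        if fid in lineages:
            raise ValueError(f"duplicate feature id in taxonomy: {fid!r}")
        if rank_cols:
            lineages[fid] = {
                r: (None if pd.isna(row[cols[r]]) else str(row[cols[r]]))
                for r in rank_cols}
        elif lineage_col is not None:
            raw = row[lineage_col]
            lineages[fid] = {} if pd.isna(raw) else _parse_greengenes(str(raw))
        else:
            raise ValueError("taxonomy file needs rank columns or a lineage column")
    return TaxonomyTable(lineages)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    rows = [{"feature_id": fid, **{r: (v or "") for r, v in ranks.items()}}
            for fid, ranks in taxonomy.lineages.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; branch lengths are required on non-root edges."""
    tree = TreeNode.read(str(path), format="newick")
    leaves = [t.name for t in tree.tips()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                f"missing branch length above node {node.name or '<internal>'}")
        if node.length < 0:
            raise ValueError(f"negative branch length above {node.name or '<internal>'}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column ids differ")
    return DistanceMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
        path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Table transforms
# ---------------------------------------------------------------------------

def to_relative_abundance(table: AsvTable) -> AsvTable:
    """Scale each sample to sum 1; all-zero samples are dropped with a warning."""
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("empty table")
    totals = table.counts.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        logger.warning("dropping %d all-zero sample(s): %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("all samples have zero total count")
    counts = table.counts[:, keep] / totals[keep]
    return AsvTable(counts, list(table.feature_ids),
                    [s for s, k in zip(table.sample_ids, keep) if k],
                    normalized=True)


def aggregate_by_rank(table: AsvTable, taxonomy: TaxonomyTable,
                      rank: str) -> AsvTable:
    """Sum features by taxonomy label at ``rank``; column sums are preserved.

    Features unassigned at the rank are pooled per parent label under
    ``unclassified_<parent>`` (``unclassified_unknown`` if no parent is
    assigned either).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rank_i = RANKS.index(rank)
    groups: dict[str, np.ndarray] = {}
    order: list[str] = []
    for i, fid in enumerate(table.feature_ids):
        label = taxonomy.label(fid, rank)
        if label is None:
            parent = "unknown"
            for j in range(rank_i - 1, -1, -1):
                lab = taxonomy.label(fid, RANKS[j])
                if lab is not None:
                    parent = lab
                    break
            label = f"unclassified_{parent}"
        if label not in groups:
            groups[label] = np.zeros(table.n_samples)
            order.append(label)
        groups[label] = groups[label] + table.counts[i]
    counts = np.vstack([groups[g] for g in order])
    return AsvTable(counts, order, list(table.sample_ids), table.normalized)


def check_samples_covered(table: AsvTable, meta: Sequence[SampleMetadata]) -> None:
    """Every table sample must appear in the metadata (silent drops hide bugs)."""
    known = {m.sample_id for m in meta}
    missing = [s for s in table.sample_ids if s not in known]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
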