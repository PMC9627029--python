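"""Contaminant and host-signal filtering plus cumulative sum scaling.

The contaminant score combines two independent signals, following the
frequency/prevalence "combo" strategy used for negative-control-based
decontamination of marker-gene data:

* **frequency** — a true contaminant contributes a roughly fixed number of
  reads per library, so its relative frequency f scales inversely with the
  sample's DNA concentration C.  In log10 space the contaminant model is
  ``log10 f = b0 - log10 C`` (slope fixed at -1) and the null model is a
  constant.  Both models have one free parameter, so the fit-quality ratio
  ``lambda = SSR_contam / SSR_null`` is compared against a permutation null
  obtained by shuffling the concentration labels.
* **prevalence** — contaminants are enriched in sequenced negative controls;
  a one-sided Fisher exact test on the 2x2 presence table scores this.

The two p-values are combined with Fisher's method (chi-square, 4 df).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import AsvTable, SampleMetadata, TaxonomyTable, check_samples_covered

logger = logging.getLogger("gutsampler")

#: Organelle labels removed case-insensitively at any rank.
ORGANELLE_LABELS = ("chloroplast", "mitochondria")


@dataclass
class ContaminantReport:
    feature_id: str
    p_freq: float | None
    p_prev: float
    p_combined: float
    flagged: bool


@dataclass
class CssFactors:
    sample_id: str
    quantile_l: float
    s_j: float
    scale: float


def filter_nonbacterial(table: AsvTable, taxonomy: TaxonomyTable) -> AsvTable:
    """Drop chloroplast/mitochondria features and kingdom-unassigned features."""
    drop = []
    for fid in table.feature_ids:
        lineage = taxonomy.lineage(fid)
        labels = [lab.lower() for lab in lineage if lab is not None]
        organelle = any(org in lab for lab in labels for org in ORGANELLE_LABELS)
        kingdom = taxonomy.label(fid, "kingdom")
        if organelle or kingdom is None:
            drop.append(fid)
    if drop:
        logger.info("filter_nonbacterial: removing %d feature(s)", len(drop))
    return table.drop_features(drop)


def remove_named_taxa(table: AsvTable, taxonomy: TaxonomyTable,
                      names: Sequence[tuple[str, str]]) -> AsvTable:
    """Remove features whose taxonomy matches any (rank, label) pair exactly."""
    drop = []
    for rank, label in names:
        matched = [fid for fid in table.feature_ids
                   if taxonomy.label(fid, rank) == label]
        if not matched:
            logger.warning("remove_named_taxa: no feature labeled %s=%r", rank, label)
        drop.extend(matched)
    if drop:
        logger.info("remove_named_taxa: removing %d feature(s)", len(set(drop)))
    return table.drop_features(drop)


def _frequency_pvalue(freqs: np.ndarray, concs: np.ndarray,
                      n_permutations: int, rng: np.random.Generator) -> float:
    """Permutation p for the inverse-concentration contaminant model.

    Small ``lambda = SSR_contam/SSR_null`` is contaminant-like; the one-sided
    p is the fraction of concentration shufflings with lambda at least as small.
    """
    y = np.log10(freqs)
    x = np.log10(concs)
    ssr_null = float(np.sum((y - y.mean()) ** 2))
    if ssr_null == 0:  # constant frequency: the null model is a perfect fit
        return 1.0

    def ssr_contam(xv: np.ndarray) -> np.ndarray:
        z = y + xv  # residual structure of log10 f = b0 - log10 C
        return np.sum((z - z.mean(axis=-1, keepdims=True)) ** 2, axis=-1)

    lam_obs = ssr_contam(x) / ssr_null
    perms = rng.permuted(np.tile(x, (n_permutations, 1)), axis=1)
    lam_perm = ssr_contam(perms) / ssr_null
    return float((1 + np.sum(lam_perm <= lam_obs)) / (n_permutations + 1))


def _prevalence_pvalue(present: np.ndarray, is_negative: np.ndarray) -> float:
    """One-sided Fisher exact test for presence enrichment in negative controls."""
    neg_present = int(np.sum(present & is_negative))
    neg_absent = int(np.sum(~present & is_negative))
    true_present = int(np.sum(present & ~is_negative))
    true_absent = int(np.sum(~present & ~is_negative))
    table = [[neg_present, neg_absent], [true_present, true_absent]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def fisher_combine(p_values: Sequence[float], df: int | None = None) -> float:
    """Fisher's method: X2 = -2 sum(ln p) against chi-square with 2k df."""
    ps = [max(min(float(p), 1.0), 1e-300) for p in p_values]
    x2 = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x2, df if df is not None else 2 * len(ps)))


def decontam_combo(table: AsvTable, meta: Sequence[SampleMetadata],
                   threshold: float = 0.1, n_permutations: int = 1000,
                   seed: int = 0) -> list[ContaminantReport]:
    """Score every feature for contamination using frequency + prevalence.

    Features present in fewer than 3 concentration-bearing samples get no
    frequency p-value; their combined score falls back to the prevalence test.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    check_samples_covered(table, meta)
    by_id = {m.sample_id: m for m in meta}
    samples = [by_id[s] for s in table.sample_ids]
    is_negative = np.array([m.is_negative for m in samples])
    if int(is_negative.sum()) < 1:
        raise ValueError("decontam_combo needs at least one negative control")
    conc = np.array([m.dna_conc if m.dna_conc is not None else np.nan
                     for m in samples])
    has_conc = ~is_negative & np.isfinite(conc)
    if int(has_conc.sum()) < 2:
        raise ValueError("decontam_combo needs >=2 true samples with dna_conc")

    totals = table.counts.sum(axis=0)
    rng = np.random.default_rng(seed)
    reports = []
    for i, fid in enumerate(table.feature_ids):
        row = table.counts[i]
        present = row >= 1
        p_prev = _prevalence_pvalue(present, is_negative)
        use = present & has_conc & (totals > 0)
        if int(use.sum()) >= 3:
            freqs = row[use] / totals[use]
            p_freq = _frequency_pvalue(freqs, conc[use], n_permutations, rng)
            p_combined = fisher_combine([p_freq, p_prev], df=4)
        else:
            logger.info("decontam_combo: %s present in <3 concentration-bearing "
                        "samples; using prevalence only", fid)
            p_freq = None
            p_combined = p_prev
        reports.append(ContaminantReport(
            feature_id=fid, p_freq=p_freq, p_prev=p_prev,
            p_combined=p_combined, flagged=p_combined < threshold))
    logger.info("decontam_combo: flagged %d / %d features at threshold %g",
                sum(r.flagged for r in reports), len(reports), threshold)
    return reports


def remove_contaminants(table: AsvTable,
                        reports: Sequence[ContaminantReport]) -> AsvTable:
    return table.drop_features([r.feature_id for r in reports if r.flagged])


def _nearest_rank_lower_quantile(sorted_values: np.ndarray, l: float) -> float:
    """The l-th quantile of positive counts, nearest-rank-lower convention."""
    n = len(sorted_values)
    k = max(int(math.ceil(l * n)), 1)
    return float(sorted_values[k - 1])


def css_normalize(table: AsvTable, quantile_l: float = 0.5,
                  scale: float = 1000.0) -> tuple[AsvTable, list[CssFactors]]:
    """Cumulative sum scaling: divide each sample by its cumulative count up
    to the l-th quantile of its positive counts, then multiply by ``scale``.

    Unlike total-sum scaling this is robust to a handful of dominant features:
    counts above the quantile do not influence the scaling factor.
    """
    if not 0 < quantile_l < 1:
        raise ValueError("quantile_l must be in (0, 1)")
    if scale <= 0:
        raise ValueError("scale must be positive")
    normalized = np.zeros_like(table.counts, dtype=float)
    factors = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        positive = np.sort(col[col > 0])
        if positive.size == 0:
            raise ValueError(f"sample {sid!r} has no positive counts")
        q = _nearest_rank_lower_quantile(positive, quantile_l)
        s_j = float(col[col <= q].sum())
        if s_j <= 0:
            raise ValueError(f"CSS scaling factor is zero for sample {sid!r}")
        normalized[:, j] = col / s_j * scale
        factors.append(CssFactors(sample_id=sid, quantile_l=quantile_l,
                                  s_j=s_j, scale=scale))
    out = AsvTable(normalized, list(table.feature_ids), list(table.sample_ids),
                   normalized=True)
    return out, factors
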