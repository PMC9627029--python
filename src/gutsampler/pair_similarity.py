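"""Within-bird cecal-pouch similarity: shared membership, shared abundance,
and nearest-neighbour concordance.

Birds carry two blind cecal pouches; whether one pouch is an adequate
replicate of the other decides whether pouches can be treated as technical
replicates or must be pooled.  Two complementary statistics are computed per
bird: the fraction of read mass on ASVs detected in both pouches (high when
the dominant community is shared) and the Jaccard fraction of shared ASVs
(sensitive to rare, pouch-private ASVs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import (AsvTable, DistanceMatrix, SampleMetadata, Site,
                      check_samples_covered)
from .diversity import nearest_neighbor

logger = logging.getLogger("gutsampler")


@dataclass
class PairSimilarity:
    bird_id: str
    shared_abundance_fraction: float
    shared_asv_fraction: float
    n_shared: int
    n_union: int
    nn_is_mate: bool | None = None


@dataclass
class FlockPairSummary:
    mean_shared_abundance: float
    range_shared_abundance: tuple[float, float]
    mean_shared_asv: float
    range_shared_asv: tuple[float, float]
    nn_mate_fraction: float | None


def shared_abundance_fraction(pouch_a, pouch_b, mode: str = "mean",
                              presence_threshold: float = 1.0) -> float:
    """Fraction of read mass on ASVs present in both pouches.

    ``mode``: "mean" averages the two per-pouch shared-mass fractions;
    "pooled" computes shared mass over the two pouches pooled; "min" takes
    the smaller per-pouch fraction.
    """
    a = np.asarray(pouch_a, dtype=float)
    b = np.asarray(pouch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("pouch vectors must align")
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("empty pouch")
    shared = (a >= presence_threshold) & (b >= presence_threshold)
    fa = float(a[shared].sum() / ta)
    fb = float(b[shared].sum() / tb)
    if mode == "mean":
        return (fa + fb) / 2.0
    if mode == "pooled":
        return float((a[shared].sum() + b[shared].sum()) / (ta + tb))
    if mode == "min":
        return min(fa, fb)
    raise ValueError(f"unknown mode {mode!r}")


def shared_asv_fraction(pouch_a, pouch_b, mode: str = "jaccard",
                        presence_threshold: float = 1.0) -> float:
    """Jaccard fraction of shared ASVs: |A n B| / |A u B| on presence sets."""
    a = np.asarray(pouch_a, dtype=float) >= presence_threshold
    b = np.asarray(pouch_b, dtype=float) >= presence_threshold
    if a.shape != b.shape:
        raise ValueError("pouch vectors must align")
    if not a.any() or not b.any():
        raise ValueError("empty pouch")
    n_shared = int((a & b).sum())
    n_union = int((a | b).sum())
    if mode == "jaccard":
        return n_shared / n_union
    if mode == "mean":  # per-pouch mean of |A n B|/|A|, |A n B|/|B|
        return (n_shared / int(a.sum()) + n_shared / int(b.sum())) / 2.0
    raise ValueError(f"unknown mode {mode!r}")


def pair_report(table: AsvTable, meta: Sequence[SampleMetadata],
                dm: DistanceMatrix | None = None,
                abundance_mode: str = "mean",
                presence_threshold: float = 1.0,
                ) -> tuple[list[PairSimilarity], FlockPairSummary]:
    """Per-bird cecal-pair similarity plus flock-level summary.

    When a distance matrix is supplied, each pouch's nearest neighbour among
    all cecum samples is checked against its pair mate.
    """
    check_samples_covered(table, meta)
    cecum = [m for m in meta if m.site is Site.CECUM
             and m.sample_id in table.sample_ids]
    by_bird: dict[str, list[SampleMetadata]] = {}
    for m in cecum:
        by_bird.setdefault(m.bird_id, []).append(m)
    for bird, ms in by_bird.items():
        if len(ms) != 2:
            raise ValueError(f"bird {bird!r} has {len(ms)} cecum samples, expected 2")

    cecum_ids = [m.sample_id for m in cecum]
    sub_dm = dm.submatrix(cecum_ids) if dm is not None and len(cecum_ids) >= 2 else None

    records = []
    for bird in sorted(by_bird):
        ma, mb = sorted(by_bird[bird], key=lambda m: m.pouch.value)
        a, b = table.sample(ma.sample_id), table.sample(mb.sample_id)
        pres_a = a >= presence_threshold
        pres_b = b >= presence_threshold
        nn_is_mate = None
        if sub_dm is not None:
            nn_a = nearest_neighbor(sub_dm, ma.sample_id)
            nn_b = nearest_neighbor(sub_dm, mb.sample_id)
            nn_is_mate = (nn_a == mb.sample_id) and (nn_b == ma.sample_id)
        records.append(PairSimilarity(
            bird_id=bird,
            shared_abundance_fraction=shared_abundance_fraction(
                a, b, mode=abundance_mode, presence_threshold=presence_threshold),
            shared_asv_fraction=shared_asv_fraction(
                a, b, presence_threshold=presence_threshold),
            n_shared=int((pres_a & pres_b).sum()),
            n_union=int((pres_a | pres_b).sum()),
            nn_is_mate=nn_is_mate))

    sa = [r.shared_abundance_fraction for r in records]
    sj = [r.shared_asv_fraction for r in records]
    nn = [r.nn_is_mate for r in records if r.nn_is_mate is not None]
    summary = FlockPairSummary(
        mean_shared_abundance=float(np.mean(sa)),
        range_shared_abundance=(float(min(sa)), float(max(sa))),
        mean_shared_asv=float(np.mean(sj)),
        range_shared_asv=(float(min(sj)), float(max(sj))),
        nn_mate_fraction=float(np.mean(nn)) if nn else None)
    return records, summary
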