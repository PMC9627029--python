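"""Bird-accumulation curves and intra-flock sample-size sufficiency.

For each sampling site, birds (or cecal pouches, which each count as a
replication unit at the cecum) are added in random order and three collector
statistics are tracked at each step k:

* ``new(k)``      — ASVs in unit k not seen in units 1..k-1
* ``cumulative(k)`` — distinct ASVs across units 1..k
* ``unique(k)``   — ASVs present in exactly one of the first k units

Curves are averaged over orderings (exhaustively when feasible).  A site is
"sufficiently sampled" at n units for threshold t when adding unit n+1
contributes fewer than t x the running cumulative total of new ASVs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import AsvTable, SampleMetadata, Site, check_samples_covered

logger = logging.getLogger("gutsampler")


@dataclass
class AccumulationCurve:
    site: str
    steps: list[tuple[int, float, float, float]]  # (k, mean_new, mean_cum, mean_unique)
    n_orderings: int
    per_ordering_new: np.ndarray | None = None    # orderings x steps

    @property
    def mean_new(self) -> np.ndarray:
        return np.array([s[1] for s in self.steps])

    @property
    def mean_cumulative(self) -> np.ndarray:
        return np.array([s[2] for s in self.steps])

    @property
    def mean_unique(self) -> np.ndarray:
        return np.array([s[3] for s in self.steps])


@dataclass
class SampleSizeResult:
    site: str
    threshold: float
    n_sufficient: int | None          # None = "not reached" within the flock
    new_fraction_series: list[float]  # new_fraction(k) for k = 2..n


def _accumulate_one_ordering(sets: Sequence[frozenset]) -> tuple[list, list, list]:
    seen: set = set()
    once: dict = {}
    new, cum, uniq = [], [], []
    for s in sets:
        new.append(len(s - seen))
        seen |= s
        for a in s:
            once[a] = once.get(a, 0) + 1
        cum.append(len(seen))
        uniq.append(sum(1 for v in once.values() if v == 1))
    return new, cum, uniq


def accumulate(presence: Mapping[str, frozenset] | Mapping[str, set],
               n_orderings: int = 100, seed: int = 0,
               site: str = "") -> AccumulationCurve:
    """Collector curve over replication units, averaged over unit orderings.

    ``presence`` maps unit id -> set of ASV ids present (count >= 1).  When
    ``n_orderings`` >= n! every ordering is enumerated exactly.
    """
    units = sorted(presence)
    if len(units) < 2:
        raise ValueError("need at least 2 replication units")
    sets = [frozenset(presence[u]) for u in units]
    n = len(sets)

    if n_orderings >= math.factorial(n):
        orderings = list(itertools.permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        orderings = [tuple(rng.permutation(n)) for _ in range(n_orderings)]

    news = np.zeros((len(orderings), n))
    cums = np.zeros((len(orderings), n))
    uniqs = np.zeros((len(orderings), n))
    for r, order in enumerate(orderings):
        new, cum, uniq = _accumulate_one_ordering([sets[i] for i in order])
        news[r], cums[r], uniqs[r] = new, cum, uniq

    steps = [(k + 1, float(news[:, k].mean()), float(cums[:, k].mean()),
              float(uniqs[:, k].mean())) for k in range(n)]
    return AccumulationCurve(site=site, steps=steps, n_orderings=len(orderings),
                             per_ordering_new=news)


def presence_by_unit(table: AsvTable, meta: Sequence[SampleMetadata],
                     site: Site) -> dict[str, frozenset]:
    """Per-replication-unit ASV presence sets for one site.

    At the cecum each pouch is its own unit (``<bird>:<pouch>``); elsewhere
    the unit is the bird.
    """
    check_samples_covered(table, meta)
    by_id = {m.sample_id: m for m in meta}
    out: dict[str, frozenset] = {}
    features = np.asarray(table.feature_ids)
    for j, sid in enumerate(table.sample_ids):
        m = by_id[sid]
        if m.site is not site:
            continue
        unit = f"{m.bird_id}:{m.pouch.value}" if site is Site.CECUM else m.bird_id
        if unit in out:
            raise ValueError(f"duplicate replication unit {unit!r} at site {site.value}")
        out[unit] = frozenset(features[table.counts[:, j] >= 1])
    return out


def sample_size_at_threshold(curve: AccumulationCurve, t: float,
                             denominator: str = "running") -> SampleSizeResult:
    """Smallest n such that unit n+1 adds < t new ASVs relative to the total.

    ``denominator="running"`` divides new(k) by the cumulative total after
    k-1 units; ``"final"`` divides by the full-flock cumulative total.
    """
    if not 0 < t < 1:
        raise ValueError("threshold must be in (0, 1)")
    if denominator not in ("running", "final"):
        raise ValueError("denominator must be 'running' or 'final'")
    mean_new = curve.mean_new
    mean_cum = curve.mean_cumulative
    if len(mean_new) < 2:
        raise ValueError("curve needs at least 2 steps")
    if denominator == "running":
        fracs = [float(mean_new[k] / mean_cum[k - 1]) for k in range(1, len(mean_new))]
    else:
        final = float(mean_cum[-1])
        fracs = [float(mean_new[k] / final) for k in range(1, len(mean_new))]
    n_sufficient = None
    for k, frac in enumerate(fracs, start=2):  # frac is new_fraction(k)
        if frac < t:
            n_sufficient = k - 1
            break
    return SampleSizeResult(site=curve.site, threshold=t,
                            n_sufficient=n_sufficient, new_fraction_series=fracs)


@dataclass
class SiteSummary:
    threshold: float
    mean: float | None
    min: int | None
    max: int | None
    per_site: dict[str, int]
    unreached: list[str] = field(default_factory=list)


def summarize_sites(results: Sequence[SampleSizeResult]) -> SiteSummary:
    """Mean and range of n_sufficient over sites that reached the threshold."""
    if not results:
        raise ValueError("no results to summarize")
    thresholds = {r.threshold for r in results}
    if len(thresholds) != 1:
        raise ValueError("summarize_sites expects one threshold at a time")
    reached = {r.site: r.n_sufficient for r in results if r.n_sufficient is not None}
    unreached = [r.site for r in results if r.n_sufficient is None]
    if not reached:
        raise ValueError("no site reached the threshold")
    values = list(reached.values())
    return SiteSummary(threshold=results[0].threshold,
                       mean=float(np.mean(values)), min=int(min(values)),
                       max=int(max(values)), per_site=reached,
                       unreached=unreached)


def flock_sufficiency(table: AsvTable, meta: Sequence[SampleMetadata],
                      thresholds: Sequence[float] = (0.10, 0.01),
                      n_orderings: int = 100, seed: int = 0,
                      denominator: str = "running",
                      ) -> tuple[dict[str, AccumulationCurve], dict[float, SiteSummary]]:
    """Accumulation curves and per-threshold sample-size summaries, all sites."""
    sites = sorted({m.site for m in meta if not m.is_negative},
                   key=lambda s: 0 if s.value is None else list(Site).index(s))
    curves: dict[str, AccumulationCurve] = {}
    for i, site in enumerate(sites):
        presence = presence_by_unit(table, meta, site)
        if len(presence) < 2:
            logger.warning("site %s has <2 replication units; skipped", site.value)
            continue
        curves[site.value] = accumulate(presence, n_orderings=n_orderings,
                                        seed=seed + i, site=site.value)
    summaries: dict[float, SiteSummary] = {}
    for t in thresholds:
        results = [sample_size_at_threshold(c, t, denominator=denominator)
                   for c in curves.values()]
        if all(r.n_sufficient is None for r in results):
            logger.warning("no site reached threshold %g within the flock", t)
            summaries[t] = SiteSummary(threshold=t, mean=None, min=None,
                                       max=None, per_site={},
                                       unreached=[r.site for r in results])
        else:
            summaries[t] = summarize_sites(results)
    return curves, summaries
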