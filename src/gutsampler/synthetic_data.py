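"""Synthetic broiler-flock generator with known ground truth.

Emulates the study design the pipeline targets: a single flock of market-age
broilers, each sampled at ten alimentary-tract (AT) locations (crop through
colon, both cecal pouches, plus a cloacal swab), sequenced to a target depth
of ~30,000 reads per sample, with unused-swab negative controls carrying
planted contaminants.

Generative model
----------------
* **Site gradient** — site base compositions follow a directional log-scale
  random walk along the anatomical ordinal: each feature receives a persistent
  per-feature drift plus per-site noise, so adjacent sites are most similar
  and community distance grows with ordinal separation (distance-decay holds
  by construction).
* **Within-flock clonality** — the feature pool splits into a *core* carried
  by every bird and a *flicker* pool each bird carries with probability drawn
  from ``occupancy_range`` (the U-shaped occupancy-abundance pattern of real
  flocks); each bird additionally perturbs every carried feature by a
  lognormal bird effect (sd ``bird_effect_sd``) shared across its sites and
  owns a small private pool of guaranteed-novel ASVs.  Together these control
  how many new ASVs an additional bird contributes and hence where the
  accumulation thresholds are crossed.
* **Cecal pairs** — the two pouches are Dirichlet-multinomial draws around a
  shared bird-cecum composition; the Dirichlet concentration is calibrated by
  bisection at generation time so the expected shared-abundance fraction hits
  ``pair_overlap`` (no closed form maps concentration to shared mass).
* **Contamination** — planted contaminant features appear in true samples at
  an expected frequency proportional to ``contaminant_strength / dna_conc``
  with lognormal noise (sd 0.3), the signature the frequency-based
  contaminant test assumes, and dominate the negative controls.
* **Enrichment** — ``n_planted_enriched`` mid-abundance features are
  multiplied by ``enrichment_fold`` in cecal samples.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .core_io import (AsvTable, Pouch, SampleMetadata, Site, TaxonomyTable)
from .pair_similarity import shared_abundance_fraction

logger = logging.getLogger("gutsampler")

#: The ten sampled AT locations, orad -> aborad (cecum appears once; both
#: pouches are drawn from it).
DEFAULT_SITES = (Site.CROP, Site.PROVENTRICULUS, Site.GIZZARD, Site.DUODENUM,
                 Site.JEJUNUM, Site.ILEUM, Site.CECUM, Site.COLON,
                 Site.CLOACAL_SWAB)

#: Fixed lineage pool (Greengenes-style ranks) from which features draw their
#: taxonomy; includes Enterobacteriaceae and Lactobacillus so family-level
#: operations and named-taxon removal are exercised.
LINEAGE_POOL: tuple[tuple[str, ...], ...] = (
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
     "Lactobacillaceae", "Lactobacillus", None),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
     "Ruminococcaceae", "Ruminococcus", None),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
     "Ruminococcaceae", "Faecalibacterium", None),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
     "Lachnospiraceae", "Blautia", None),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
     "Lachnospiraceae", None, None),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
     "Clostridiaceae", "Clostridium", None),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales",
     "Enterobacteriaceae", "Escherichia", None),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales",
     "Enterobacteriaceae", None, None),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
     "Bacteroidaceae", "Bacteroides", None),
    ("Bacteria", "Actinobacteria", "Coriobacteriia", "Coriobacteriales",
     "Coriobacteriaceae", None, None),
    ("Bacteria", "Firmicutes", "Bacilli", "Bacillales",
     "Staphylococcaceae", "Staphylococcus", None),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
     "Ruminococcaceae", "Subdoligranulum", None),
)


@dataclass
class FlockModel:
    """Generative parameters for one synthetic flock."""

    n_birds: int = 9
    sites: tuple = DEFAULT_SITES
    n_features: int = 560
    base_log_sd: float = 1.2            # spread of the rank-abundance curve
    gradient_step_sd: float = 0.55      # log-scale drift per ordinal step
    bird_effect_sd: float = 0.45        # lognormal sd of per-bird feature effects
    core_fraction: float = 0.6          # fraction of features carried by every bird
    occupancy_range: tuple = (0.3, 0.6)  # per-bird carriage prob of flicker features
    pair_overlap: float = 0.95          # target cecal shared-abundance fraction
    rare_pool_per_bird: int = 1         # bird-private low-abundance ASVs
    private_mass: float = 0.0016        # total relative abundance of one private pool
    depth_mean: int = 30000
    depth_dispersion: float = 0.1       # CV of per-sample sequencing depth
    n_negatives: int = 2
    n_contaminants: int = 6
    contaminant_strength: float = 0.03  # expected contaminant freq = strength / conc
    n_planted_enriched: int = 10
    enrichment_fold: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.sites = tuple(Site(s) for s in self.sites)
        if self.n_birds < 2:
            raise ValueError("need at least 2 birds")
        if not 0 < self.pair_overlap <= 1:
            raise ValueError("pair_overlap must be in (0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if not 0 <= self.private_mass < 0.5:
            raise ValueError("private_mass must be in [0, 0.5)")
        self.occupancy_range = tuple(self.occupancy_range)
        if not (0 < self.occupancy_range[0] <= self.occupancy_range[1] <= 1):
            raise ValueError("occupancy_range must satisfy 0 < lo <= hi <= 1")
        if not 0 <= self.core_fraction <= 1:
            raise ValueError("core_fraction must be in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites"] = [s.value for s in self.sites]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FlockModel":
        if "seed" not in d:
            raise ValueError("manifest missing seed")
        d = dict(d)
        if "sites" in d:
            d["sites"] = tuple(Site(s) for s in d["sites"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    contaminant_ids: list[str]
    enriched_ids: list[str]
    depleted_ids: list[str]
    private_ids: dict[str, list[str]]         # bird -> private feature ids
    site_base_compositions: dict[str, list[float]]
    realized_pair_overlap: dict[str, float]   # bird -> realized shared mass
    pair_concentration: float | None
    model: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _softmax(log_abund: np.ndarray) -> np.ndarray:
    x = log_abund - log_abund.max()
    e = np.exp(x)
    return e / e.sum()


def _random_tree(feature_ids: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating tree by iterative pair joining, exponential lengths."""
    nodes = [TreeNode(name=fid, length=float(rng.exponential(0.1)))
             for fid in feature_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], length=float(rng.exponential(0.1)))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _calibrate_pair_concentration(compositions: np.ndarray, target: float,
                                  depth: int, rng: np.random.Generator,
                                  n_rep: int = 12) -> float:
    """Bisection on log10 Dirichlet concentration to hit the target expected
    shared-abundance fraction between pouch pairs."""

    def estimate(log10_alpha: float) -> float:
        alpha = 10.0 ** log10_alpha
        vals = []
        for _ in range(n_rep):
            pi = compositions[rng.integers(len(compositions))]
            pa = rng.dirichlet(np.maximum(alpha * pi, 1e-10))
            pb = rng.dirichlet(np.maximum(alpha * pi, 1e-10))
            ca = rng.multinomial(depth, pa)
            cb = rng.multinomial(depth, pb)
            vals.append(shared_abundance_fraction(ca, cb))
        return float(np.mean(vals))

    lo, hi = 0.5, 8.0
    if estimate(hi) < target - 0.02:
        raise ValueError(
            f"pair_overlap {target} is infeasible: even near-identical pouch "
            f"compositions cannot reach it at this depth/feature configuration")
    for _ in range(14):
        mid = (lo + hi) / 2.0
        if estimate(mid) < target:
            lo = mid
        else:
            hi = mid
    return 10.0 ** ((lo + hi) / 2.0)


def generate_flock(model: FlockModel) -> tuple[AsvTable, list[SampleMetadata],
                                               TaxonomyTable, TreeNode, GroundTruth]:
    """Generate one flock: counts, metadata, taxonomy, tree and ground truth."""
    ss = np.random.SeedSequence(model.seed)
    rng, rng_calib, rng_tree = (np.random.default_rng(s) for s in ss.spawn(3))

    n_shared = model.n_features
    shared_ids = [f"ASV_{i + 1:04d}" for i in range(n_shared)]
    private_ids = {f"B{b + 1}": [f"ASV_priv_B{b + 1}_{k + 1:02d}"
                                 for k in range(model.rare_pool_per_bird)]
                   for b in range(model.n_birds)}
    contaminant_ids = [f"ASV_contam_{k + 1:02d}" for k in range(model.n_contaminants)]
    all_ids = shared_ids + [f for ids in private_ids.values() for f in ids] \
        + contaminant_ids
    id_index = {f: i for i, f in enumerate(all_ids)}
    n_total = len(all_ids)

    # --- site gradient: directional log-scale walk along ordinals -----------
    from .core_io import SITE_ORDINALS
    site_order = sorted(set(model.sites), key=lambda s: SITE_ORDINALS[s])

    base0 = rng.normal(0.0, model.base_log_sd, size=n_shared)
    drift = rng.normal(0.0, 1.0, size=n_shared)
    ords = np.array([SITE_ORDINALS[s] for s in site_order], dtype=float)
    mid = float(ords.mean())
    site_logs: dict[Site, np.ndarray] = {}
    for s in site_order:
        # directional drift centred on the mid-tract plus per-site noise:
        # adjacent sites stay most similar while the flock-average
        # rank-abundance spread stays comparable along the tract
        offset = SITE_ORDINALS[s] - mid
        noise = rng.normal(0.0, 1.0, size=n_shared)
        logw = base0 + model.gradient_step_sd * (offset * drift + 0.3 * noise)
        # keep site logs on the log-relative-abundance scale so cross-site
        # contrasts (planted enrichment) are not confounded by each site's
        # normalizing constant
        site_logs[s] = logw - np.log(np.exp(logw - logw.max()).sum()) - logw.max()

    # --- occupancy: core features in every bird, flicker features in some ----
    n_core = int(round(model.core_fraction * n_shared))
    is_core = np.zeros(n_shared, dtype=bool)
    is_core[rng.choice(n_shared, size=n_core, replace=False)] = True
    occupancy = np.where(is_core, 1.0, rng.uniform(*model.occupancy_range,
                                                   size=n_shared))

    # --- planted cecal enrichment on mid/high-abundance core features --------
    core_by_abund = [i for i in np.argsort(base0)[::-1] if is_core[i]]
    planted_idx = np.array(core_by_abund[20:20 + model.n_planted_enriched])
    enriched_ids = [shared_ids[i] for i in planted_idx]
    if Site.CECUM in site_logs and len(planted_idx):
        # enrichment_fold is defined against the rest-of-tract mean so the
        # planted contrast is not confounded by the feature's own drift
        others = np.mean([site_logs[s][planted_idx] for s in site_order
                          if s is not Site.CECUM], axis=0)
        site_logs[Site.CECUM] = site_logs[Site.CECUM].copy()
        site_logs[Site.CECUM][planted_idx] = others + math.log(model.enrichment_fold)

    # --- bird effects and per-bird/site compositions -------------------------
    birds = [f"B{b + 1}" for b in range(model.n_birds)]
    bird_effects = {b: rng.normal(0.0, model.bird_effect_sd, size=n_shared)
                    for b in birds}
    bird_carries = {b: rng.random(n_shared) < occupancy for b in birds}
    private_weights = {b: rng.dirichlet(np.full(max(model.rare_pool_per_bird, 1), 5.0))
                       if model.rare_pool_per_bird else np.array([])
                       for b in birds}

    def bird_site_composition(bird: str, site: Site) -> np.ndarray:
        """Full-length composition: shared gradient + bird effect + privates,
        restricted to the features this bird carries."""
        logw = site_logs[site] + bird_effects[bird]
        shared = np.where(bird_carries[bird], np.exp(logw - logw.max()), 0.0)
        shared = shared / shared.sum()
        full = np.zeros(n_total)
        full[:n_shared] = shared
        priv = private_ids[bird]
        if priv and model.private_mass > 0:
            w = private_weights[bird]
            full[:n_shared] *= (1.0 - model.private_mass)
            for fid, wk in zip(priv, w):
                full[id_index[fid]] = model.private_mass * wk
        return full

    # --- DNA concentrations and depths ---------------------------------------
    site_list = [s for s in site_order]
    n_true = model.n_birds * (len(site_list) + (1 if Site.CECUM in site_list else 0))
    conc_all = rng.lognormal(mean=math.log(12.0), sigma=0.5, size=n_true)
    neg_conc = float(np.quantile(conc_all, 0.05))

    def draw_depth(mean: int) -> int:
        shape = 1.0 / model.depth_dispersion ** 2
        lam = rng.gamma(shape, mean / shape)
        return max(int(rng.poisson(lam)), 1)

    # --- cecal pair concentration (calibrated) --------------------------------
    pair_conc: float | None = None
    if Site.CECUM in site_list and model.pair_overlap < 1.0:
        cecum_comps = np.array([bird_site_composition(b, Site.CECUM) for b in birds])
        pair_conc = _calibrate_pair_concentration(
            cecum_comps, model.pair_overlap, model.depth_mean, rng_calib)

    # --- sample generation ----------------------------------------------------
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta: list[SampleMetadata] = []
    realized_overlap: dict[str, float] = {}
    conc_iter = iter(conc_all)

    def add_contaminants(comp: np.ndarray, conc: float) -> np.ndarray:
        if model.n_contaminants == 0:
            return comp
        freqs = (model.contaminant_strength / conc) * \
            rng.lognormal(0.0, 0.3, size=model.n_contaminants)
        total = min(float(freqs.sum()), 0.3)
        if freqs.sum() > 0:
            freqs = freqs * (total / freqs.sum())
        out = comp * (1.0 - total)
        for fid, f in zip(contaminant_ids, freqs):
            out[id_index[fid]] = f
        return out

    for bird in birds:
        for site in site_list:
            conc = float(next(conc_iter))
            if site is Site.CECUM:
                base = bird_site_composition(bird, site)
                if model.pair_overlap >= 1.0:
                    comp = add_contaminants(base, conc)
                    counts = rng.multinomial(draw_depth(model.depth_mean), comp)
                    pouch_counts = {Pouch.LEFT: counts, Pouch.RIGHT: counts.copy()}
                else:
                    pouch_counts = {}
                    for pouch in (Pouch.LEFT, Pouch.RIGHT):
                        p = rng.dirichlet(np.maximum(pair_conc * base, 1e-10))
                        comp = add_contaminants(p, conc)
                        pouch_counts[pouch] = rng.multinomial(
                            draw_depth(model.depth_mean), comp)
                conc_r = float(next(conc_iter))
                for pouch, tag in ((Pouch.LEFT, "L"), (Pouch.RIGHT, "R")):
                    sid = f"{bird}_cecum_{tag}"
                    sample_ids.append(sid)
                    columns.append(pouch_counts[pouch])
                    meta.append(SampleMetadata(
                        sample_id=sid, bird_id=bird, site=Site.CECUM,
                        pouch=pouch, dna_conc=conc if tag == "L" else conc_r))
                realized_overlap[bird] = shared_abundance_fraction(
                    pouch_counts[Pouch.LEFT], pouch_counts[Pouch.RIGHT])
            else:
                comp = add_contaminants(bird_site_composition(bird, site), conc)
                counts = rng.multinomial(draw_depth(model.depth_mean), comp)
                sid = f"{bird}_{site.value}"
                sample_ids.append(sid)
                columns.append(counts)
                meta.append(SampleMetadata(sample_id=sid, bird_id=bird,
                                           site=site, dna_conc=conc))

    # --- negative controls: contaminant-dominated, low depth ------------------
    mean_true = np.mean(np.array(columns, dtype=float), axis=0)
    mean_true = mean_true / mean_true.sum() if mean_true.sum() > 0 else mean_true
    for k in range(model.n_negatives):
        comp = np.zeros(n_total)
        if model.n_contaminants:
            freqs = (model.contaminant_strength / neg_conc) * \
                rng.lognormal(0.0, 0.3, size=model.n_contaminants)
            freqs = freqs / freqs.sum()
            for fid, f in zip(contaminant_ids, freqs):
                comp[id_index[fid]] = 0.9 * f
            comp += 0.1 * mean_true
        else:
            comp = mean_true.copy()
        comp = comp / comp.sum()
        counts = rng.multinomial(draw_depth(max(model.depth_mean // 10, 500)), comp)
        sid = f"NC{k + 1}"
        sample_ids.append(sid)
        columns.append(counts)
        meta.append(SampleMetadata(sample_id=sid, bird_id="negative",
                                   site=Site.NEGATIVE_CONTROL,
                                   dna_conc=neg_conc * float(rng.uniform(0.8, 1.2))))

    table = AsvTable(np.array(columns, dtype=float).T, all_ids, sample_ids)

    # --- taxonomy and tree -----------------------------------------------------
    lineages: dict[str, dict[str, str | None]] = {}
    rank_names = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
    for i, fid in enumerate(all_ids):
        pool = LINEAGE_POOL[int(rng.integers(len(LINEAGE_POOL)))]
        row = dict(zip(rank_names, pool))
        lineages[fid] = row
    taxonomy = TaxonomyTable(lineages)
    tree = _random_tree(all_ids, rng_tree)

    truth = GroundTruth(
        contaminant_ids=contaminant_ids, enriched_ids=enriched_ids,
        depleted_ids=[], private_ids=private_ids,
        site_base_compositions={s.value: _softmax(v).tolist()
                                for s, v in site_logs.items()},
        realized_pair_overlap=realized_overlap,
        pair_concentration=pair_conc, model=model.to_dict())
    return table, meta, taxonomy, tree, truth


def regenerate_from_manifest(manifest: dict) -> tuple[AsvTable, list[SampleMetadata],
                                                      TaxonomyTable, TreeNode,
                                                      GroundTruth]:
    """Rebuild a flock bit-identically from a ground-truth manifest."""
    params = manifest.get("model", manifest)
    model = FlockModel.from_dict(params)
    return generate_flock(model)


def write_manifest(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
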