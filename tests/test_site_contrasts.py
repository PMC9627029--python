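import itertools
import math

import numpy as np
import pytest

from gutsampler.core_io import (AsvTable, DistanceMatrix, Pouch,
                                SampleMetadata, Site, TaxonomyTable)
from gutsampler.diversity import bray_curtis
from gutsampler.site_contrasts import (cecal_enrichment, distance_decay,
                                       distance_to_swab, family_correlation)


def _bird_meta(bird, sites):
    meta = []
    for s in sites:
        if s is Site.CECUM:
            meta.append(SampleMetadata(f"{bird}_cecum_L", bird, s, Pouch.LEFT))
            meta.append(SampleMetadata(f"{bird}_cecum_R", bird, s, Pouch.RIGHT))
        else:
            meta.append(SampleMetadata(f"{bird}_{s.value}", bird, s))
    return meta


class TestDistanceToSwab:
    def test_hand_averaged_values(self):
        # two birds, colon + crop + swab each
        meta = (_bird_meta("B1", [Site.CROP, Site.COLON, Site.CLOACAL_SWAB]) +
                _bird_meta("B2", [Site.CROP, Site.COLON, Site.CLOACAL_SWAB]))
        ids = [m.sample_id for m in meta]
        d = np.zeros((6, 6))
        def set_d(a, b, v):
            i, j = ids.index(a), ids.index(b)
            d[i, j] = d[j, i] = v
        set_d("B1_crop", "B1_cloacal_swab", 0.8)
        set_d("B1_colon", "B1_cloacal_swab", 0.2)
        set_d("B2_crop", "B2_cloacal_swab", 0.6)
        set_d("B2_colon", "B2_cloacal_swab", 0.4)
        for a, b in itertools.combinations(ids, 2):
            if d[ids.index(a), ids.index(b)] == 0:
                set_d(a, b, 0.5)
        profiles = {p.site: p for p in
                    distance_to_swab(DistanceMatrix(d, ids), meta)}
        assert profiles["crop"].mean_distance_to_swab == pytest.approx(0.7)
        assert profiles["colon"].mean_distance_to_swab == pytest.approx(0.3)
        assert profiles["crop"].sd == pytest.approx(np.std([0.8, 0.6], ddof=1))

    def test_swab_identical_to_colon_gives_zero(self):
        meta = _bird_meta("B1", [Site.COLON, Site.ILEUM, Site.CLOACAL_SWAB])
        counts = np.array([[5, 1, 5], [5, 9, 5]], dtype=float)
        table = AsvTable(counts, ["f1", "f2"], [m.sample_id for m in meta])
        dm = bray_curtis(table)
        profiles = {p.site: p for p in distance_to_swab(dm, meta)}
        assert profiles["colon"].mean_distance_to_swab == pytest.approx(0.0)

    def test_missing_swab_rejected(self):
        meta = _bird_meta("B1", [Site.COLON, Site.ILEUM])
        d = np.array([[0, .5], [.5, 0]])
        with pytest.raises(ValueError, match="B1"):
            distance_to_swab(DistanceMatrix(d, [m.sample_id for m in meta]),
                             meta)

    def test_site_means_decrease_toward_swab(self, flock_true_parts):
        raw, meta, _, _, _ = flock_true_parts
        from gutsampler.preprocessing import css_normalize
        norm, _ = css_normalize(raw)
        profiles = distance_to_swab(bray_curtis(norm), meta)
        means = [p.mean_distance_to_swab for p in profiles]
        assert means == sorted(means, reverse=True)


class TestFamilyCorrelation:
    def _setup(self, site_vals, swab_vals):
        birds = [f"B{i}" for i in range(len(site_vals))]
        meta, cols, ids = [], [], []
        for b, sv, wv in zip(birds, site_vals, swab_vals):
            meta.append(SampleMetadata(f"{b}_colon", b, Site.COLON))
            meta.append(SampleMetadata(f"{b}_cloacal_swab", b, Site.CLOACAL_SWAB))
            ids += [f"{b}_colon", f"{b}_cloacal_swab"]
            cols += [[sv, 1.0], [wv, 1.0]]
        table = AsvTable(np.array(cols, dtype=float).T, ["e1", "other"], ids,
                         normalized=True)
        tax = TaxonomyTable({
            "e1": {"kingdom": "Bacteria", "family": "Enterobacteriaceae"},
            "other": {"kingdom": "Bacteria", "family": "Lachnospiraceae"}})
        return table, tax, meta

    def test_perfect_positive_and_negative(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        table, tax, meta = self._setup(vals, vals)
        out = family_correlation(table, tax, meta, "Enterobacteriaceae")
        assert out["colon"][0] == pytest.approx(1.0)
        table, tax, meta = self._setup(vals, [6 - v for v in vals])
        out = family_correlation(table, tax, meta, "Enterobacteriaceae")
        assert out["colon"][0] == pytest.approx(-1.0)

    def test_matches_closed_form_t_test(self):
        x = [1.0, 3.0, 2.0, 5.0, 4.0]
        y = [2.0, 3.0, 1.0, 6.0, 7.0]
        table, tax, meta = self._setup(x, y)
        r, p, n = family_correlation(table, tax, meta,
                                     "Enterobacteriaceae")["colon"]
        # closed-form oracle: r from products, p from t with n-2 df
        xa, ya = np.array(x), np.array(y)
        rx = ((xa - xa.mean()) * (ya - ya.mean())).sum() / math.sqrt(
            ((xa - xa.mean()) ** 2).sum() * ((ya - ya.mean()) ** 2).sum())
        t = rx * math.sqrt((n - 2) / (1 - rx ** 2))
        from scipy import stats
        p_ref = 2 * stats.t.sf(abs(t), n - 2)
        assert r == pytest.approx(rx, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        table, tax, meta = self._setup([2.0] * 4, [1.0, 2.0, 3.0, 4.0])
        out = family_correlation(table, tax, meta, "Enterobacteriaceae")
        assert out["colon"][0] is None

    def test_unknown_family_rejected(self):
        table, tax, meta = self._setup([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="Bacteroidaceae"):
            family_correlation(table, tax, meta, "Bacteroidaceae")


def _perfect_decay_setup():
    """4 sites; d(i,j) = 0.1 + 0.2 * ordinal gap => sim = 0.9 - 0.2*(gap-1)."""
    sites = [Site.CROP, Site.PROVENTRICULUS, Site.GIZZARD, Site.DUODENUM]
    meta = _bird_meta("B1", sites)
    ids = [m.sample_id for m in meta]
    ords = [m.ordinal for m in meta]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = 0.2 * abs(ords[i] - ords[j])
    # sim = 1 - d = 1 - 0.2*gap: slope -0.2, r = -1
    return DistanceMatrix(d, ids), meta


class TestDistanceDecay:
    def test_hand_least_squares(self):
        dm, meta = _perfect_decay_setup()
        fit = distance_decay(dm, meta, "B1", n_permutations=10**5, seed=0)
        assert fit.slope == pytest.approx(-0.2)
        assert fit.r == pytest.approx(-1.0)
        assert fit.n_pairs == 6

    def test_exhaustive_p_matches_enumeration_oracle(self):
        dm, meta = _perfect_decay_setup()
        fit = distance_decay(dm, meta, "B1", n_permutations=10**5, seed=0)
        # oracle: enumerate all 4! ordinal relabelings directly
        ords = np.array([1.0, 2.0, 3.0, 4.0])
        iu = np.triu_indices(4, k=1)
        sim = 1.0 - dm.data[iu]
        r_obs = np.corrcoef(np.abs(ords[iu[0]] - ords[iu[1]]), sim)[0, 1]
        r_all = []
        for perm in itertools.permutations(ords):
            p = np.asarray(perm)
            r_all.append(np.corrcoef(np.abs(p[iu[0]] - p[iu[1]]), sim)[0, 1])
        p_expected = np.mean([r <= r_obs + 1e-12 for r in r_all])
        assert fit.p == pytest.approx(p_expected)
        assert fit.n_permutations == 24

    def test_too_few_sites_rejected(self):
        meta = _bird_meta("B1", [Site.CROP, Site.ILEUM, Site.COLON])
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="B1"):
            distance_decay(DistanceMatrix(d, [m.sample_id for m in meta]),
                           meta, "B1")

    def test_perfect_decay_on_flock_birds(self, flock_true_parts):
        raw, meta, _, _, _ = flock_true_parts
        dm = bray_curtis(raw)
        fit = distance_decay(dm, meta, "B1", n_permutations=999, seed=0)
        assert fit.slope < 0
        assert fit.r < 0
        # ordinal reversal reproduces the observed gaps, so the effective
        # floor can be 2/(n+1)
        assert fit.p <= 2 / 1000 + 1e-12


def _enrichment_setup(rng, n_features=60, fold=1.0, n_each=12):
    """Two groups of samples; feature 0 multiplied by `fold` in the cecal group."""
    base = rng.integers(50, 150, size=n_features).astype(float)
    meta, cols, ids = [], [], []
    for g, site in (("c", Site.CECUM), ("n", Site.ILEUM)):
        for j in range(n_each):
            lam = base * rng.lognormal(0, 0.2, size=n_features)
            if site is Site.CECUM:
                lam = lam.copy()
                lam[0] *= fold
            col = rng.poisson(lam).astype(float)
            sid = f"{g}{j}"
            ids.append(sid)
            cols.append(col)
            pouch = Pouch.LEFT if site is Site.CECUM else None
            meta.append(SampleMetadata(sid, f"B{g}{j}", site, pouch=pouch))
    table = AsvTable(np.array(cols).T, [f"f{i}" for i in range(n_features)],
                     ids, normalized=True)
    return table, meta


class TestCecalEnrichment:
    def test_two_fold_feature_lfc_near_one(self):
        rng = np.random.default_rng(0)
        table, meta = _enrichment_setup(rng, fold=2.0)
        rec = {r.feature_id: r for r in
               cecal_enrichment(table, meta, alpha=0.05, n_permutations=4999,
                                seed=0)}
        assert rec["f0"].log2_fold_change == pytest.approx(1.0, abs=0.25)
        assert rec["f0"].status == "enriched"

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        table, meta = _enrichment_setup(rng, fold=1.0)
        rec = cecal_enrichment(table, meta, alpha=0.01, n_permutations=999,
                               seed=1)
        assert all(r.status == "ns" for r in rec)
        assert abs(rec[0].log2_fold_change) < 0.3

    def test_q_values_monotone_in_p(self):
        rng = np.random.default_rng(2)
        table, meta = _enrichment_setup(rng, fold=3.0)
        rec = cecal_enrichment(table, meta, n_permutations=499, seed=2)
        ordered = sorted(rec, key=lambda r: r.p)
        qs = [r.q for r in ordered]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))

    def test_status_sign_consistency(self, flock_true_parts):
        raw, meta, _, _, _ = flock_true_parts
        from gutsampler.preprocessing import css_normalize
        norm, _ = css_normalize(raw)
        rec = cecal_enrichment(norm, meta, alpha=0.01, n_permutations=999,
                               seed=3)
        for r in rec:
            if r.status == "enriched":
                assert r.log2_fold_change > 0
            elif r.status == "depleted":
                assert r.log2_fold_change < 0
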