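"""Equal sampling, embedding, KNN hotspot comparison, and region gating."""

import numpy as np
import pytest

from sarmap import io as sio
from sarmap import trex
from sarmap.exceptions import ConfigurationError, SarmapError
from tests.conftest import make_marker_table


def group_of(rng, n, shift=0.0, d=3):
    return make_marker_table(
        {f"m{i}": rng.normal(shift, 1, n) for i in range(d)}, scale="arcsinh"
    )


class TestEqualSample:
    def test_exact_counts_per_group(self, rng):
        groups = {"a": group_of(rng, 100), "b": group_of(rng, 100)}
        pooled = trex.equal_sample(groups, 50, seed=0)
        counts = pooled.data["condition"].value_counts().to_dict()
        assert counts == {"a": 50, "b": 50}

    def test_strict_mode_rejects_small_groups(self, rng):
        groups = {"a": group_of(rng, 30), "b": group_of(rng, 100)}
        with pytest.raises(SarmapError, match="a"):
            trex.equal_sample(groups, 50, seed=0)
        pooled = trex.equal_sample(groups, 50, seed=0, strict=False)
        assert pooled.data["condition"].value_counts().to_dict() == {"a": 30, "b": 30}

    def test_same_seed_same_sample(self, rng):
        groups = {"a": group_of(rng, 200), "b": group_of(rng, 200)}
        p1 = trex.equal_sample(groups, 80, seed=7)
        p2 = trex.equal_sample(groups, 80, seed=7)
        assert p1.data.equals(p2.data)


class TestEmbed:
    def test_default_params_are_the_screening_settings(self):
        p = trex.EmbedParams()
        assert (p.perplexity, p.iterations, p.early_exaggeration, p.learning_rate) == (
            60.0, 10_000, 12.0, "auto",
        )

    def test_output_shape_and_too_few_events(self, rng):
        t = group_of(rng, 200, d=4)
        emb = trex.embed(t, params=trex.EmbedParams(perplexity=20, iterations=260, seed=0))
        assert emb.coords.shape == (200, 2)
        with pytest.raises(SarmapError, match="perplexity"):
            trex.embed(group_of(rng, 30, d=4), params=trex.EmbedParams(perplexity=20))

    def test_separated_blobs_stay_separated(self, rng):
        """Two 11-D Gaussian blobs 6 sigma apart: a 2-means split of the
        embedding recovers the blob labels almost perfectly."""
        from sklearn.cluster import KMeans

        n = 600
        blob_a = {f"m{i}": rng.normal(0, 1, n) for i in range(11)}
        blob_b = {f"m{i}": rng.normal(6, 1, n) for i in range(11)}
        pooled = make_marker_table(
            {k: np.concatenate([blob_a[k], blob_b[k]]) for k in blob_a}, "arcsinh"
        )
        emb = trex.embed(pooled, params=trex.EmbedParams(perplexity=30, iterations=400, seed=0))
        km = KMeans(2, n_init=5, random_state=0).fit_predict(emb.coords)
        truth = np.repeat([0, 1], n)
        agreement = max((km == truth).mean(), (km != truth).mean())
        assert agreement >= 0.99


class TestTRexCompare:
    @staticmethod
    def two_cluster_embedding(n_a=30, n_b=30, n_mixed=140, seed=0):
        rng = np.random.default_rng(seed)
        coords = np.concatenate([
            rng.normal([0, 0], 0.1, (n_a, 2)),        # pure A cluster
            rng.normal([100, 0], 0.1, (n_b, 2)),      # pure B cluster
            rng.normal([50, 50], 5.0, (n_mixed, 2)),  # interleaved region
        ])
        labels = np.array(["A"] * n_a + ["B"] * n_b + ["A", "B"] * (n_mixed // 2))
        return trex.EmbeddingResult(coords, trex.EmbedParams(), labels=labels)

    def test_degree_of_difference_formula(self):
        emb = self.two_cluster_embedding()
        res = trex.trex_compare(emb, "A", "B", k=10, hotspot_cutoff=0.95)
        # the two pure clusters are hotspots; the mixed region is neutral
        assert res.n_red == 30 and res.n_blue == 30
        assert res.degree_of_difference == pytest.approx(100 * 60 / 200)

    def test_label_symmetry(self):
        emb = self.two_cluster_embedding()
        ab = trex.trex_compare(emb, "A", "B", k=10)
        ba = trex.trex_compare(emb, "B", "A", k=10)
        assert (ab.n_red, ab.n_blue) == (ba.n_blue, ba.n_red)
        assert ab.degree_of_difference == ba.degree_of_difference

    def test_monotone_in_hotspot_cutoff(self):
        emb = self.two_cluster_embedding()
        dods = [
            trex.trex_compare(emb, "A", "B", k=10, hotspot_cutoff=c).degree_of_difference
            for c in (0.6, 0.8, 0.95, 1.0)
        ]
        assert all(a >= b for a, b in zip(dods, dods[1:]))

    def test_same_distribution_null_is_tiny(self, rng):
        coords = rng.normal(0, 1, (3000, 2))
        labels = np.array(["A", "B"] * 1500)
        emb = trex.EmbeddingResult(coords, trex.EmbedParams(), labels=labels)
        res = trex.trex_compare(emb, "A", "B", k=60)
        assert res.degree_of_difference <= 1.0

    def test_disjoint_clusters_are_all_hotspots(self, rng):
        coords = np.concatenate([
            rng.normal([0, 0], 1, (500, 2)), rng.normal([1000, 0], 1, (500, 2))
        ])
        labels = np.array(["A"] * 500 + ["B"] * 500)
        emb = trex.EmbeddingResult(coords, trex.EmbedParams(), labels=labels)
        res = trex.trex_compare(emb, "A", "B", k=60)
        assert res.degree_of_difference >= 99.0

    def test_unbalanced_labels_rejected(self, rng):
        coords = rng.normal(0, 1, (300, 2))
        labels = np.array(["A"] * 200 + ["B"] * 100)
        emb = trex.EmbeddingResult(coords, trex.EmbedParams(), labels=labels)
        with pytest.raises(SarmapError, match="unbalanced"):
            trex.trex_compare(emb, "A", "B", k=10)

    def test_knn_fractions_match_brute_force(self, rng):
        """Neighbor fractions agree with an all-pairs distance oracle."""
        n, k = 800, 15
        coords = rng.normal(0, 1, (n, 2))
        is_a = rng.random(n) < 0.5
        fast = trex.knn_fractions(coords, is_a, k)
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        brute = is_a[np.argsort(d, axis=1, kind="stable")[:, :k]].mean(axis=1)
        assert np.allclose(fast, brute)


class TestRegion:
    def make_embedding(self, rng, n=10_000):
        coords = rng.uniform(0, 2, (n, 2))
        return trex.EmbeddingResult(coords, trex.EmbedParams())

    def test_bounding_polygon_contains_everything(self, rng):
        emb = self.make_embedding(rng, 500)
        region = trex.Region2D(((-1, -1), (3, -1), (3, 3), (-1, 3)))
        assert trex.percent_in_region(emb, region) == 100.0

    def test_region_outside_hull_is_empty(self, rng):
        emb = self.make_embedding(rng, 500)
        region = trex.Region2D(((10, 10), (11, 10), (11, 11), (10, 11)))
        assert trex.percent_in_region(emb, region) == 0.0

    def test_area_fraction_of_uniform_points(self, rng):
        emb = self.make_embedding(rng, 10_000)
        region = trex.Region2D(((0, 0), (1, 0), (1, 1), (0, 1)))
        pct = trex.percent_in_region(emb, region)
        se = 100 * np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(pct - 25.0) <= 4 * se

    def test_degenerate_region_rejected(self):
        with pytest.raises(ConfigurationError):
            trex.Region2D(((0, 0), (1, 1)))
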