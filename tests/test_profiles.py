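"""Age-band profiles: frequency matrix, dendrogram, PCA, k-means, silhouette."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch

from syndromic.cohort import default_calibration, generate_cohort_frame
from syndromic.errors import ValidationError
from syndromic.profiles import (
    AGE_BANDS,
    BAND_LABELS,
    KMeansSilhouette,
    band_frequency_matrix,
    hierarchical_clustering,
    kmeans,
    kmeans_with_silhouette,
    pca,
    silhouette_values,
)
from syndromic.scores import SYMPTOMS


def _tiny_cohort(ages, symptom_value=1):
    frame = pd.DataFrame({"age_years": ages})
    for s in SYMPTOMS:
        frame[f"sym_{s}"] = symptom_value
    return frame


class TestBandFrequencyMatrix:
    def test_every_symptom_everywhere_flags_constant_rows(self):
        prof = band_frequency_matrix(_tiny_cohort([20, 30, 40, 50, 60, 70, 80, 90]))
        filled = prof.freq.dropna(how="all")
        assert (filled == 1.0).all().all()
        assert set(prof.constant_rows) == set(BAND_LABELS)
        assert prof.usable_bands == []

    def test_zmat_rows_standardised(self, small_cohort):
        prof = band_frequency_matrix(small_cohort)
        z = prof.usable_z().to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_empty_band_flagged_and_excluded(self):
        prof = band_frequency_matrix(
            pd.DataFrame(
                {
                    "age_years": [20, 21, 40, 41, 90],
                    **{
                        f"sym_{s}": [1, 0, 0, 1, 1] if s == "cough" else [0, 1, 1, 0, 0]
                        for s in SYMPTOMS
                    },
                }
            )
        )
        assert "25-34" in prof.empty_rows
        assert "25-34" not in prof.usable_bands
        assert np.isnan(prof.freq.loc["25-34"]).all()

    def test_default_cohort_cough_breathlessness_lead_below_85(self, default_cohort):
        prof = band_frequency_matrix(default_cohort)
        for band in prof.bands[:-1]:
            top2 = set(prof.freq.loc[band].nlargest(2).index)
            assert top2 == {"cough", "breathlessness"}, band

    def test_band_counts_conserved(self, small_cohort):
        prof = band_frequency_matrix(small_cohort)
        assert prof.band_counts.sum() == len(small_cohort)


class TestHierarchicalClustering:
    def test_two_rows_single_merge_at_their_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = hierarchical_clustering(x)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(5.0)

    def test_collinear_points_merge_closest_pair_first(self):
        x = np.array([[0.0], [1.0], [10.0]])
        dend = hierarchical_clustering(x)
        first = {int(dend.merges[0][0]), int(dend.merges[0][1])}
        assert first == {0, 1}

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_matches_scipy_linkage(self, linkage, rng):
        x = rng.normal(size=(8, 5))
        dend = hierarchical_clustering(x, linkage=linkage)
        ours = np.sort(dend.merges[:, 2])
        theirs = np.sort(sch.linkage(x, method=linkage)[:, 2])
        np.testing.assert_allclose(ours, theirs, atol=1e-10)
        # two-cluster cut agrees up to relabelling
        cut_ours = dend.cut(2)
        cut_scipy = sch.fcluster(sch.linkage(x, method=linkage), 2, "maxclust")
        pairs_ours = (cut_ours[:, None] == cut_ours[None, :])
        pairs_scipy = (cut_scipy[:, None] == cut_scipy[None, :])
        assert (pairs_ours == pairs_scipy).all()

    def test_sharp_shift_at_55_splits_top_level(self, rng):
        """A cohort with a symptom-profile step at 55y clusters <55 vs >=55."""
        ages = rng.integers(18, 101, size=6000)
        young = ages < 55
        frame = pd.DataFrame({"age_years": ages})
        for k, s in enumerate(SYMPTOMS):
            p = 0.7 if k < 5 else 0.15
            frame[f"sym_{s}"] = (
                rng.random(6000) < np.where(young, p, 0.85 - p)
            ).astype(int)
        prof = band_frequency_matrix(frame)
        dend = hierarchical_clustering(prof)
        cut = dict(zip(dend.labels, dend.cut(2)))
        young_bands = {"18-24", "25-34", "35-44", "45-54"}
        young_labels = {cut[b] for b in young_bands}
        old_labels = {cut[b] for b in set(BAND_LABELS) - young_bands}
        assert len(young_labels) == 1 and len(old_labels) == 1
        assert young_labels != old_labels

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_clustering(np.zeros((3, 2)), linkage="median")


class TestPca:
    def test_rank_one_matrix_explains_everything_with_one_component(self):
        x = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, -0.2, 0.8])
        res = pca(x)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self, rng):
        x = rng.normal(size=(8, 11))
        res = pca(x)
        np.testing.assert_allclose(
            res.scores @ res.components + res.mean, x, atol=1e-9
        )

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=(8, 11))
            res = pca(x)
            xc = x - x.mean(axis=0)
            evals, evecs = np.linalg.eigh(xc.T @ xc)
            evals, evecs = evals[::-1], evecs[:, ::-1]
            k = min(x.shape) - 1  # centred matrix rank
            np.testing.assert_allclose(
                (res.components[:k] @ evecs[:, :k]) ** 2,
                np.eye(k),
                atol=1e-8,
            )
            ratio_oracle = evals[:k] / evals[evals > 1e-12].sum()
            np.testing.assert_allclose(
                res.explained_variance_ratio[:k], ratio_oracle, atol=1e-8
            )

    def test_ratios_sum_to_one_and_scores_uncorrelated(self, default_cohort):
        prof = band_frequency_matrix(default_cohort)
        res = pca(prof)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        cov = res.scores.T @ res.scores
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-9

    def test_components_orthonormal(self, rng):
        res = pca(rng.normal(size=(8, 11)))
        gram = res.components @ res.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-9)

    def test_rank_zero_rejected(self):
        with pytest.raises(ValidationError):
            pca(np.ones((4, 3)))


class TestKMeans:
    def test_two_separated_clouds_perfectly_recovered(self, rng):
        x = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(5, 0.2, (10, 2))])
        res = kmeans_with_silhouette(x, seed=3)
        assert res.k == 2
        labels = res.assignments
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_best_of_restarts_no_worse_than_single_restart(self, rng):
        x = rng.normal(size=(12, 3))
        _, _, single = kmeans(x, 3, n_restarts=1, seed=9)
        _, _, best = kmeans(x, 3, n_restarts=50, seed=9)
        assert best <= single + 1e-12

    def test_matches_exhaustive_bipartition_search(self, rng):
        """Best-restart inertia equals the global optimum over all 127
        non-trivial bipartitions of 8 points in >=95% of random instances."""
        wins = 0
        n_instances = 20
        for i in range(n_instances):
            x = rng.normal(size=(8, 2))
            _, _, inertia = kmeans(x, 2, n_restarts=50, seed=i)
            best = np.inf
            for mask in itertools.product([0, 1], repeat=8):
                if len(set(mask)) < 2:
                    continue
                m = np.array(mask, dtype=bool)
                ss = ((x[m] - x[m].mean(axis=0)) ** 2).sum()
                ss += ((x[~m] - x[~m].mean(axis=0)) ** 2).sum()
                best = min(best, ss)
            wins += abs(inertia - best) < 1e-9
        assert wins >= 0.95 * n_instances

    def test_deterministic_for_fixed_seed(self, rng):
        x = rng.normal(size=(10, 2))
        r1 = kmeans_with_silhouette(x, seed=4)
        r2 = kmeans_with_silhouette(x, seed=4)
        assert np.array_equal(r1.assignments, r2.assignments)
        assert r1.inertia == r2.inertia

    def test_silhouette_bounds_and_guards(self, rng):
        x = rng.normal(size=(9, 2))
        labels, _, _ = kmeans(x, 3, seed=0)
        sil = silhouette_values(x, labels)
        assert np.all(sil >= -1) and np.all(sil <= 1)
        with pytest.raises(ValidationError):
            silhouette_values(x, np.arange(9))  # every point its own cluster
        with pytest.raises(ValidationError):
            kmeans(x, 10, seed=0)

    def test_estimator_facade(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (6, 2)), rng.normal(4, 0.3, (6, 2))])
        est = KMeansSilhouette(seed=2).fit(x)
        assert est.k_ == 2
        assert est.inertia_ == est.result_.inertia
        assert len(est.fit_predict(x)) == 12


class TestDefaultCohortClusters:
    def test_extreme_bands_furthest_from_centroid(self, default_cohort):
        prof = band_frequency_matrix(default_cohort)
        res = pca(prof)
        centroid = res.scores.mean(axis=0)
        dist = np.linalg.norm(res.scores - centroid, axis=1)
        top2 = {res.row_labels[i] for i in np.argsort(-dist)[:2]}
        assert top2 == {"18-24", "85+"}

    def test_two_pcs_explain_most_band_variation(self, default_cohort):
        prof = band_frequency_matrix(default_cohort)
        res = pca(prof)
        assert res.explained_variance_ratio[:2].sum() > 0.90
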