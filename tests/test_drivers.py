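from __future__ import annotations

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import ventnet
from ventnet.drivers import DbmemBasis, adjusted_r2, _multivariate_r2
from ventnet.simnet import DissimilarityMatrix

from _oracles import spherical_law_of_cosines_km


def fabricate_basis(ids, scores: np.ndarray, scale: str) -> DbmemBasis:
    """Synthetic stand-in basis (centred columns supplied by the caller)."""
    frame = pd.DataFrame(
        scores,
        index=list(ids),
        columns=[f"{scale}_mem{j + 1}" for j in range(scores.shape[1])],
    )
    return DbmemBasis(
        ids=tuple(ids),
        truncation_km=1.0,
        eigenvalues=np.ones(scores.shape[1]),
        scores=frame,
        scale=scale,
    )


class TestGeodesic:
    def test_identical_coordinates(self, small_metadata):
        small_metadata.loc[1, ["latitude", "longitude"]] = (10.0, 120.0)
        G = ventnet.geodesic_matrix(small_metadata)
        assert G.values[0, 1] == 0.0

    def test_antipodal_closed_form(self):
        meta = pd.DataFrame(
            {"site_id": ["a", "b"], "latitude": [0.0, 0.0], "longitude": [0.0, 180.0]}
        )
        G = ventnet.geodesic_matrix(meta)
        assert G.values[0, 1] == pytest.approx(np.pi * 6371.0, abs=1e-6)

    def test_matches_law_of_cosines_oracle(self):
        meta = pd.DataFrame(
            {
                "site_id": ["DKK", "MEK"],
                "latitude": [26.302, 28.392],
                "longitude": [126.413, 127.642],
            }
        )
        G = ventnet.geodesic_matrix(meta)
        oracle = spherical_law_of_cosines_km(26.302, 126.413, 28.392, 127.642)
        assert G.values[0, 1] == pytest.approx(oracle, abs=0.1)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(2)
        meta = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(6)],
                "latitude": rng.uniform(-60, 60, 6),
                "longitude": rng.uniform(-170, 170, 6),
            }
        )
        G = ventnet.geodesic_matrix(meta).values
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert G[i, j] <= G[i, k] + G[k, j] + 1e-9


class TestDbmem:
    def equilateral(self):
        # three sites at ~equal pairwise great-circle spacing
        meta = pd.DataFrame(
            {
                "site_id": ["a", "b", "c"],
                "latitude": [0.0, 0.0, 0.866],
                "longitude": [0.0, 1.0, 0.5],
            }
        )
        return ventnet.geodesic_matrix(meta)

    def test_equilateral_eigenpair(self):
        G = self.equilateral()
        basis = ventnet.dbmem_basis(
            G, G.values.max() + 1, retain="positive-eigenvalue"
        )
        assert basis.n_vectors == 2
        assert basis.eigenvalues[0] == pytest.approx(basis.eigenvalues[1], rel=1e-2)

    def test_columns_centred_and_orthogonal(self):
        sites = ventnet.load_vent_site_table()
        G = ventnet.geodesic_matrix(sites)
        for retain in ("positive-moran", "positive-eigenvalue"):
            basis = ventnet.dbmem_basis(G, 800.0, retain=retain)
            scores = basis.scores.to_numpy()
            norms = np.linalg.norm(scores, axis=0)
            assert np.abs((scores / norms).sum(axis=0)).max() < 1e-9
            gram = (scores / norms).T @ (scores / norms)
            off = gram - np.diag(np.diag(gram))
            assert np.abs(off).max() < 1e-9
            assert (basis.eigenvalues > 0).all()

    def test_max_truncation_equals_classical_pcoa(self):
        G = self.equilateral()
        basis = ventnet.dbmem_basis(
            G, G.values.max(), retain="positive-eigenvalue"
        )
        D = DissimilarityMatrix(G.ids, G.values / G.values.max())
        axes = ventnet.pcoa_axes(D)
        scaled = basis.scores.to_numpy() / G.values.max()
        assert np.allclose(np.abs(scaled), np.abs(axes.to_numpy()), atol=1e-9)

    def test_isolating_threshold_rejected(self):
        G = self.equilateral()
        with pytest.raises(ValueError, match="isolates all sites"):
            ventnet.dbmem_basis(G, 1.0)


class TestScaleThresholds:
    def two_cluster_meta(self):
        rng = np.random.default_rng(4)
        lat = np.concatenate([rng.uniform(9.5, 10.5, 5), rng.uniform(18.5, 19.5, 5)])
        lon = np.concatenate([rng.uniform(120, 121, 5), rng.uniform(120, 121, 5)])
        return pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(10)],
                "latitude": lat,
                "longitude": lon,
                "region": ["west"] * 5 + ["east"] * 5,
            }
        )

    def test_two_clusters_ordering(self):
        meta = self.two_cluster_meta().set_index(pd.Index(range(10)))
        meta = meta.assign(site_id=meta["site_id"]).set_index("site_id", drop=False)
        G = ventnet.geodesic_matrix(meta)
        t_fine, t_broad = ventnet.make_scale_thresholds(G, meta, "west")
        assert t_fine < t_broad
        assert t_broad >= 800  # the ~1000 km inter-cluster gap

    def test_collinear_equidistant_path(self):
        meta = pd.DataFrame(
            {
                "site_id": ["a", "b", "c", "d"],
                "latitude": [0.0, 1.0, 2.0, 3.0],
                "longitude": [0.0] * 4,
                "region": ["west", "east", "east", "east"],
            }
        ).set_index("site_id", drop=False)
        G = ventnet.geodesic_matrix(meta)
        t_fine, t_broad = ventnet.make_scale_thresholds(G, meta, "west")
        spacing = G.values[0, 1]
        assert t_broad == pytest.approx(spacing)
        assert t_fine == pytest.approx(spacing * (1 - 1e-6))

    def test_published_coordinates_ordering(self):
        sites = ventnet.load_vent_site_table()
        G = ventnet.geodesic_matrix(sites)
        t_fine, t_broad = ventnet.make_scale_thresholds(
            G, sites, {"Okinawa Trough", "Ryukyu Arc"}
        )
        assert 0 < t_fine < t_broad

    def test_missing_region_label(self, small_metadata):
        meta = small_metadata.set_index("site_id", drop=False)
        G = ventnet.geodesic_matrix(meta)
        with pytest.raises(ValueError, match="labelled"):
            ventnet.make_scale_thresholds(G, meta, "nowhere")


class TestVariancePartition:
    def env_driven_setup(self, n=60, seed=7, noise=0.05):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        env = pd.DataFrame(
            rng.normal(size=(n, 2)), index=ids, columns=["depth", "tect_dummy"]
        )
        env -= env.mean()
        # mutually orthogonal centred spatial bases, independent of env
        raw = rng.normal(size=(n, 4))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        fine = fabricate_basis(ids, q[:, :2], "fine")
        broad = fabricate_basis(ids, q[:, 2:], "broad")
        Y = env.to_numpy() @ rng.normal(size=(2, 3)) + noise * rng.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(Y))
        D = DissimilarityMatrix(tuple(ids), dist / (dist.max() * 1.01))
        return D, env, fine, broad

    def test_env_generated_response_attributed_to_env(self):
        D, env, fine, broad = self.env_driven_setup()
        vf = ventnet.variance_partition(D, env, fine, broad)
        total = vf.total_explained
        assert abs(vf.fractions["env"] - total) < 0.05
        for key in ("fine", "broad"):
            assert abs(vf.fractions[key]) < 0.05

    def test_orthogonal_sets_share_nothing(self):
        D, env, fine, broad = self.env_driven_setup()
        vf = ventnet.variance_partition(D, env, fine, broad)
        for key in ("env&fine", "env&broad", "fine&broad", "env&fine&broad"):
            assert abs(vf.fractions[key]) < 0.05

    def test_fractions_sum_to_full_model_adjusted_r2(self):
        D, env, fine, broad = self.env_driven_setup(noise=0.5)
        vf = ventnet.variance_partition(D, env, fine, broad)
        full = vf.union_adjusted_r2["broad+env+fine"]
        assert vf.total_explained == pytest.approx(full, abs=1e-9)
        assert sum(vf.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_set_union_matches_direct_regression(self):
        D, env, fine, broad = self.env_driven_setup(noise=0.3)
        vf = ventnet.variance_partition(D, env, fine, broad)
        Y = ventnet.pcoa_axes(D).to_numpy()
        direct = adjusted_r2(
            _multivariate_r2(Y, env.to_numpy()), len(env), env.shape[1]
        )
        assert vf.union_adjusted_r2["env"] == pytest.approx(direct, abs=1e-9)

    def test_within_block_column_order_irrelevant(self):
        D, env, fine, broad = self.env_driven_setup(noise=0.4)
        shuffled_env = env[list(env.columns[::-1])]
        a = ventnet.variance_partition(D, env, fine, broad)
        b = ventnet.variance_partition(D, shuffled_env, fine, broad)
        for key in a.fractions:
            assert a.fractions[key] == pytest.approx(b.fractions[key], abs=1e-12)

    def test_over_parameterized_union_rejected(self):
        D, env, fine, broad = self.env_driven_setup(n=8)
        big = fabricate_basis(list(D.ids), np.random.default_rng(0).normal(size=(8, 6)), "fine")
        with pytest.raises(ValueError, match="over-parameterized"):
            ventnet.variance_partition(D, env, big, broad)

    def test_adjustment_properties(self):
        assert adjusted_r2(0.5, 30, 0) == pytest.approx(0.5)
        values = [adjusted_r2(0.5, 30, m) for m in range(0, 10)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_matches_vegan_varpart_oracle(self, tmp_path):
        D, env, fine, broad = self.env_driven_setup(n=25, seed=3, noise=0.4)
        Y = ventnet.pcoa_axes(D)
        paths = {}
        for name, frame in {
            "Y": Y,
            "X1": env,
            "X2": fine.scores,
            "X3": broad.scores,
        }.items():
            paths[name] = tmp_path / f"{name}.csv"
            frame.to_csv(paths[name], index=False)
        script = tmp_path / "varpart.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(vegan))
                args <- commandArgs(TRUE)
                Y <- as.matrix(read.csv(args[1]))
                X1 <- read.csv(args[2]); X2 <- read.csv(args[3]); X3 <- read.csv(args[4])
                vp <- varpart(Y, X1, X2, X3)
                fr <- vp$part$indfract$Adj.R.square
                cat(paste(fr, collapse=","))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)]
            + [str(paths[k]) for k in ("Y", "X1", "X2", "X3")],
            capture_output=True,
            text=True,
            check=True,
        )
        vegan = [float(x) for x in out.stdout.strip().split(",")]
        vf = ventnet.variance_partition(D, env, fine, broad)
        ours = [
            vf.fractions[k]
            for k in (
                "env",
                "fine",
                "broad",
                "env&fine",
                "fine&broad",
                "env&broad",
                "env&fine&broad",
                "residual",
            )
        ]
        assert ours == pytest.approx(vegan, abs=1e-6)

    def test_pcoa_eigenvalues_match_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 3))
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(pts))
        D = DissimilarityMatrix(
            tuple(f"s{i}" for i in range(10)), dist / (dist.max() * 1.01)
        )
        ours = ventnet.pcoa_axes(D)
        ref = pcoa(SkbioDM(D.values, ids=list(D.ids)))
        ref_pos = np.sort(ref.eigvals[ref.eigvals > 1e-9].to_numpy())[::-1]
        ours_var = np.sort((ours.to_numpy() ** 2).sum(axis=0))[::-1]
        assert ours_var == pytest.approx(ref_pos, rel=1e-6)


class TestMembershipModels:
    def labelled_setup(self, n=40, seed=3, separation=0.0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        labels = pd.Series(["m1"] * (n // 2) + ["m2"] * (n - n // 2), index=ids)
        env = pd.DataFrame(
            {
                "depth": rng.normal(size=n),
                "tect_dummy": (rng.random(n) < 0.5).astype(float),
            },
            index=ids,
        )
        env.loc[labels == "m2", "depth"] += separation
        broad = fabricate_basis(ids, rng.normal(size=(n, 2)), "broad")
        return labels, env, broad

    def test_tectonic_determined_labels_fully_explained(self):
        labels, env, broad = self.labelled_setup()
        env["tect_dummy"] = (labels == "m2").astype(float)
        out = ventnet.membership_rda(labels, env[["tect_dummy"]], broad)
        assert out["proportion"] == pytest.approx(1.0, abs=1e-9)

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(0)
        labels, env, broad = self.labelled_setup(n=100, seed=1)
        m = env.shape[1] + broad.scores.shape[1]
        props = []
        for _ in range(200):
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            props.append(ventnet.membership_rda(shuffled, env, broad)["proportion"])
        assert np.mean(props) == pytest.approx(m / (len(labels) - 1), abs=0.02)

    def test_single_module_rejected(self):
        labels, env, broad = self.labelled_setup()
        labels[:] = "m1"
        with pytest.raises(ValueError, match="two modules"):
            ventnet.membership_rda(labels, env, broad)

    def test_manova_null_and_strong_separation(self):
        labels, env, broad = self.labelled_setup(separation=0.0, seed=3)
        table = ventnet.manova_modules(labels, env, broad)
        p_null = table.loc[table["responses"] == "all", "p"].iloc[0]
        assert p_null > 0.01
        labels2, env2, broad2 = self.labelled_setup(separation=10.0, seed=3)
        table2 = ventnet.manova_modules(labels2, env2, broad2)
        assert (table2.loc[table2["responses"] == "all", "p"].iloc[0]) < 1e-6
        lam = table2["wilks_lambda"]
        assert ((lam > 0) & (lam <= 1)).all()

    def test_moran_detects_gradient(self):
        sites = ventnet.load_vent_site_table()
        G = ventnet.geodesic_matrix(sites)
        gradient = pd.Series(
            sites["latitude"].to_numpy(), index=sites["site_id"]
        )
        out = ventnet.moran_i(gradient, G, 1200.0, seed=1)
        assert out["moran_i"] > 0.3
        assert out["p"] < 0.05
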