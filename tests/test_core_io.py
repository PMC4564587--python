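"""Domain types, region bookkeeping, and file round-trips."""

import numpy as np
import pytest

from morphokin.core import (
    AgeCategory,
    AgeEncoding,
    BASICRANIUM,
    DistanceMatrix,
    LandmarkConfiguration,
    OCCIPITAL,
    RegionDefinition,
    SPHENOID,
    STRGenotypeTable,
    TEMPORAL,
    filter_complete,
    subset_region,
)
from morphokin.io import (
    read_genotypes,
    read_landmarks,
    read_matrix,
    read_wireframe,
    export_wireframe,
    write_genotypes,
    write_landmarks,
    write_matrix,
)

from conftest import random_config


class TestRegions:
    def test_bundled_region_cardinalities(self):
        # occipital 13, temporal 24, sphenoid 12; union is the full scheme
        assert len(OCCIPITAL) == 13
        assert len(TEMPORAL) == 24
        assert len(SPHENOID) == 12
        union = set(OCCIPITAL.indices) | set(TEMPORAL.indices) | set(SPHENOID.indices)
        assert union == set(range(1, 45))
        assert len(BASICRANIUM) == 44

    def test_suture_landmarks_shared_between_regions(self):
        shared = (
            (set(OCCIPITAL.indices) & set(TEMPORAL.indices))
            | (set(OCCIPITAL.indices) & set(SPHENOID.indices))
            | (set(TEMPORAL.indices) & set(SPHENOID.indices))
        )
        assert shared == {1, 2, 13, 33, 36}

    def test_subset_region_sizes_and_identity(self, rng):
        cfg = random_config(rng)
        assert subset_region(cfg, OCCIPITAL).n_landmarks == 13
        assert subset_region(cfg, TEMPORAL).n_landmarks == 24
        assert subset_region(cfg, SPHENOID).n_landmarks == 12
        full = subset_region(cfg, BASICRANIUM)
        np.testing.assert_array_equal(full.coords, cfg.coords)
        assert full.population == cfg.population

    def test_subset_region_out_of_range(self, rng):
        cfg = random_config(rng, k=10)
        with pytest.raises(IndexError):
            subset_region(cfg, RegionDefinition("big", (1, 11)))

    def test_duplicate_region_indices_rejected(self):
        with pytest.raises(ValueError):
            RegionDefinition("dup", (1, 2, 2))


class TestFilterComplete:
    def test_missing_landmark_excludes_specimen(self, rng):
        complete = [random_config(rng, specimen_id=f"c{i}") for i in range(10)]
        broken = []
        for i in range(2):
            cfg = random_config(rng, specimen_id=f"b{i}")
            cfg.coords[40] = np.nan  # landmark 41 is sphenoid-only
            cfg.present_mask[40] = False
            broken.append(cfg)
        kept = filter_complete(complete + broken, SPHENOID)
        assert len(kept) == 10
        assert all(k.n_landmarks == 12 for k in kept)
        # the same specimens remain usable for the occipital region
        assert len(filter_complete(complete + broken, OCCIPITAL)) == 12

    def test_all_complete_is_identity(self, rng):
        configs = [random_config(rng, specimen_id=f"c{i}") for i in range(5)]
        kept = filter_complete(configs, BASICRANIUM)
        assert [k.specimen_id for k in kept] == [c.specimen_id for c in configs]

    def test_random_missingness_matches_bruteforce(self, rng):
        configs = []
        for i in range(30):
            cfg = random_config(rng, specimen_id=f"r{i}")
            drop = rng.random(44) < 0.05
            cfg.present_mask[drop] = False
            configs.append(cfg)
        for region in (OCCIPITAL, TEMPORAL, SPHENOID):
            kept = {c.specimen_id for c in filter_complete(configs, region)}
            expected = {
                c.specimen_id
                for c in configs
                if all(c.present_mask[i - 1] for i in region.indices)
            }
            assert kept == expected


class TestAgeEncoding:
    def test_default_midpoints(self):
        enc = AgeEncoding()
        assert enc.numeric_age("AC1") == 2.5
        assert enc.numeric_age(AgeCategory.AC3) == 15.5
        assert enc.numeric_age("adult") == 21.0

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            AgeEncoding(
                {
                    AgeCategory.AC1: 5.0,
                    AgeCategory.AC2: 3.0,
                    AgeCategory.AC3: 15.0,
                    AgeCategory.ADULT: 21.0,
                }
            )


class TestLandmarkIO:
    def test_tps_basic_parse(self, tmp_path):
        tps = "LM3=4\n0 0 0\n1 0 0\n0 1 0\n0 0 1\nID=sp1\n"
        path = tmp_path / "t.tps"
        path.write_text(tps)
        (cfg,) = read_landmarks(path, "tps")
        assert cfg.specimen_id == "sp1"
        assert cfg.n_landmarks == 4
        assert cfg.is_complete

    def test_table_blank_cell_marks_missing(self, tmp_path):
        rows = ["specimen_id,population,age_category,landmark,x,y,z"]
        for i in range(4):
            z = "" if i == 2 else "1.0"
            rows.append(f"s1,PopA,AC2,L{i + 1},{float(i)},0.5,{z}")
        path = tmp_path / "t.csv"
        path.write_text("\n".join(rows))
        (cfg,) = read_landmarks(path, "table")
        assert not cfg.present_mask[2]
        assert cfg.present_mask[[0, 1, 3]].all()

    def test_duplicate_specimen_id_rejected(self, tmp_path):
        tps = "LM3=3\n0 0 0\n1 0 0\n0 1 0\nID=dup\n" * 2
        path = tmp_path / "d.tps"
        path.write_text(tps)
        with pytest.raises(ValueError, match="dup"):
            read_landmarks(path, "tps")

    def test_truncated_block_rejected(self, tmp_path):
        path = tmp_path / "bad.tps"
        path.write_text("LM3=4\n0 0 0\n1 0 0\nID=sp1\n")
        with pytest.raises(ValueError):
            read_landmarks(path, "tps")

    @pytest.mark.parametrize("fmt", ["tps", "table"])
    def test_round_trip_to_6_decimals(self, rng, tmp_path, fmt):
        configs = []
        for i in range(4):
            cfg = random_config(
                rng, specimen_id=f"s{i}", population=f"P{i % 2}", age=AgeCategory.AC2
            )
            if i == 1:
                cfg.present_mask[7] = False
            configs.append(cfg)
        path = tmp_path / f"rt.{fmt}"
        write_landmarks(configs, path, format=fmt)
        back = read_landmarks(path, fmt)
        assert len(back) == len(configs)
        for a, b in zip(configs, back):
            assert a.specimen_id == b.specimen_id
            assert a.population == b.population
            assert a.age_category == b.age_category
            np.testing.assert_array_equal(a.present_mask, b.present_mask)
            np.testing.assert_allclose(
                a.coords[a.present_mask], b.coords[b.present_mask], atol=5e-7
            )


class TestMatrixIO:
    def test_small_matrix_round_trip(self, tmp_path):
        m = DistanceMatrix(["a", "b", "c"], [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        back = read_matrix(path)
        assert back.labels == ["a", "b", "c"]
        np.testing.assert_allclose(back.values, m.values, atol=5e-7)

    def test_asymmetric_matrix_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\ta\tb\na\t0\t1\nb\t2\t0\n")
        with pytest.raises(ValueError, match="symmetric"):
            read_matrix(path)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="egative"):
            DistanceMatrix(["a", "b"], [[0, -1], [-1, 0]])

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], [[0.5, 1], [1, 0]])

    def test_random_round_trip_preserves_invariants(self, rng, tmp_path):
        for trial in range(5):
            n = int(rng.integers(3, 9))
            raw = rng.random((n, n))
            values = raw + raw.T
            np.fill_diagonal(values, 0.0)
            m = DistanceMatrix([f"p{i}" for i in range(n)], values)
            path = tmp_path / f"r{trial}.tsv"
            write_matrix(m, path)
            back = read_matrix(path)
            assert np.abs(back.values - back.values.T).max() == 0.0
            assert np.diag(back.values).max() == 0.0
            np.testing.assert_allclose(back.values, m.values, atol=5e-7)

    def test_drop_and_reorder(self):
        m = DistanceMatrix(["a", "b", "c"], [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        d = m.drop("b")
        assert d.labels == ["a", "c"]
        assert d["a", "c"] == 2.0
        r = m.reorder(["c", "a", "b"])
        assert r["c", "b"] == 3.0
        with pytest.raises(KeyError):
            m.drop("zzz")


class TestGenotypeIO:
    def test_round_trip_with_missing(self, rng, tmp_path):
        geno = rng.integers(8, 31, size=(6, 5, 2))
        geno[2, 3] = [-1, -1]
        table = STRGenotypeTable(
            [f"i{i}" for i in range(6)],
            ["A"] * 3 + ["B"] * 3,
            [f"L{j}" for j in range(5)],
            geno,
        )
        path = tmp_path / "g.csv"
        write_genotypes(table, path)
        back = read_genotypes(path)
        assert back.individual_ids == table.individual_ids
        assert back.populations == table.populations
        np.testing.assert_array_equal(back.genotypes, table.genotypes)

    def test_zero_coded_alleles_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            STRGenotypeTable(["i1"], ["A"], ["L1"], np.array([[[0, 5]]]))

    def test_half_missing_rejected(self):
        with pytest.raises(ValueError, match="half-missing"):
            STRGenotypeTable(["i1"], ["A"], ["L1"], np.array([[[-1, 5]]]))


class TestWireframeIO:
    def test_vertices_and_edges_written(self, tmp_path):
        path = tmp_path / "w.obj"
        export_wireframe(np.eye(3), [(1, 2), (2, 3)], path)
        lines = path.read_text().splitlines()
        assert sum(l.startswith("v ") for l in lines) == 3
        assert sum(l.startswith("l ") for l in lines) == 2

    def test_empty_edges_and_round_trip(self, rng, tmp_path):
        shape = rng.normal(size=(7, 3))
        path = tmp_path / "w.obj"
        export_wireframe(shape, [], path)
        verts, edges = read_wireframe(path)
        assert edges == []
        np.testing.assert_allclose(verts, shape, atol=5e-7)

    def test_invalid_edge_rejected(self, tmp_path):
        with pytest.raises(IndexError):
            export_wireframe(np.eye(3), [(1, 4)], tmp_path / "x.obj")
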