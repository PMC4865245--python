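"""PED/MAP parsing, writing, merging and autosome subsetting."""

import numpy as np
import pytest

from capripop.genotype_io import (
    MISSING,
    PedMapError,
    merge_datasets,
    read_ped_map,
    subset_autosomes,
    write_ped_map,
)
from capripop.simulate import inject_missingness, simulate_structured

from conftest import make_dataset


def write_files(tmp_path, map_lines, ped_lines):
    mp = tmp_path / "x.map"
    pp = tmp_path / "x.ped"
    mp.write_text("\n".join(map_lines) + "\n")
    pp.write_text("\n".join(ped_lines) + "\n")
    return pp, mp


class TestReadPedMap:
    def test_major_minor_assignment_and_dosage(self, tmp_path):
        # 3 samples AA, AG, GG at one SNP: A major -> dosage counts G
        ped, mp = write_files(
            tmp_path,
            ["1 snp1 0 1000"],
            ["F1 s1 0 0 0 -9 A A", "F1 s2 0 0 0 -9 A G", "F1 s3 0 0 0 -9 G G"],
        )
        ds = read_ped_map(ped, mp)
        assert ds.genotypes[:, 0].tolist() == [0, 1, 2]
        assert (ds.snps[0].allele_a, ds.snps[0].allele_b) == ("A", "G")

    def test_monomorphic_sample_coded_against_second_cohort_rule(self, tmp_path):
        # one sample AA with a second sample AG: A is major -> first sample 0
        ped, mp = write_files(
            tmp_path, ["1 snp1 0 1000"],
            ["F s1 0 0 0 -9 A A", "F s2 0 0 0 -9 A G"],
        )
        ds = read_ped_map(ped, mp)
        assert ds.genotypes[0, 0] == 0

    def test_missing_and_half_missing(self, tmp_path):
        ped, mp = write_files(
            tmp_path, ["1 snp1 0 1000", "1 snp2 0 2000"],
            ["F s1 0 0 0 -9 0 0 A 0", "F s2 0 0 0 -9 A G G G"],
        )
        ds = read_ped_map(ped, mp)
        assert ds.genotypes[0, 0] == MISSING
        assert ds.genotypes[0, 1] == MISSING  # half-called -> MISSING

    def test_population_label_from_family_id(self, tmp_path):
        ped, mp = write_files(tmp_path, ["1 snp1 0 5"],
                              ["AR goat1 0 0 0 -9 A G"])
        ds = read_ped_map(ped, mp)
        assert ds.samples[0].population == "AR"

    def test_dimension_mismatch_names_line(self, tmp_path):
        ped, mp = write_files(tmp_path, ["1 snp1 0 5", "1 snp2 0 6"],
                              ["F s1 0 0 0 -9 A G"])
        with pytest.raises(PedMapError, match="line 1"):
            read_ped_map(ped, mp)

    def test_triallelic_locus_names_snp(self, tmp_path):
        ped, mp = write_files(
            tmp_path, ["1 badsnp 0 5"],
            ["F s1 0 0 0 -9 A G", "F s2 0 0 0 -9 C C"],
        )
        with pytest.raises(PedMapError, match="badsnp"):
            read_ped_map(ped, mp)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_simulated_roundtrip_identity(self, tmp_path, seed):
        ds, _ = simulate_structured(2, 0.2, 8, 60, seed=seed)
        ds = inject_missingness(ds, 0.3, 0.3, seed=seed)
        write_ped_map(ds, tmp_path / "r.ped", tmp_path / "r.map")
        back = read_ped_map(tmp_path / "r.ped", tmp_path / "r.map")
        assert np.array_equal(ds.genotypes, back.genotypes)
        assert ds.samples == back.samples
        assert [(s.chromosome, s.position_bp, s.snp_id) for s in ds.snps] == \
               [(s.chromosome, s.position_bp, s.snp_id) for s in back.snps]

    def test_empty_dataset_roundtrip(self, tmp_path):
        ds = make_dataset(np.empty((0, 2), dtype=np.int8))
        write_ped_map(ds, tmp_path / "e.ped", tmp_path / "e.map")
        back = read_ped_map(tmp_path / "e.ped", tmp_path / "e.map")
        assert back.n_samples == 0 and back.n_snps == 2

    def test_missing_written_as_zero_tokens(self, tmp_path):
        ds = make_dataset([[MISSING, 1]])
        write_ped_map(ds, tmp_path / "m.ped", tmp_path / "m.map")
        tokens = (tmp_path / "m.ped").read_text().split()
        assert tokens[6:8] == ["0", "0"]


class TestMerge:
    def test_concatenation_identical_maps(self):
        d1 = make_dataset([[0, 1]], populations=["A"])
        d2 = make_dataset([[2, 1]], populations=["B"])
        d2.samples[0] = d2.samples[0].__class__("other", "B")
        merged = merge_datasets([d1, d2])
        assert merged.n_samples == 2
        assert np.array_equal(merged.genotypes, [[0, 1], [2, 1]])
        assert merged.populations == ["A", "B"]

    def test_allele_swap_flips_dosage(self):
        d1 = make_dataset([[0], [1]], alleles=[("A", "G")])
        d2 = make_dataset([[0], [2]], alleles=[("G", "A")])
        for i, s in enumerate(d2.samples):
            d2.samples[i] = s.__class__(f"o{i}", "B")
        merged = merge_datasets([d1, d2])
        # d2 coded dosage of A; after anchoring to d1 (counting G) codes flip
        assert merged.genotypes[:, 0].tolist() == [0, 1, 2, 0]

    def test_flip_preserves_het_count(self):
        d1 = make_dataset([[1], [1], [0]], alleles=[("A", "G")])
        d2 = make_dataset([[1], [2]], alleles=[("G", "A")])
        for i, s in enumerate(d2.samples):
            d2.samples[i] = s.__class__(f"o{i}", "B")
        merged = merge_datasets([d1, d2])
        assert (merged.genotypes == 1).sum() == 3

    def test_snp_intersection(self):
        d1 = make_dataset([[0, 1]], positions=[10, 20])
        d2 = make_dataset([[1]], positions=[10])
        d2.samples[0] = d2.samples[0].__class__("o", "B")
        merged = merge_datasets([d1, d2])
        assert merged.snp_ids == ["snp1"]

    def test_incompatible_alleles_error(self):
        d1 = make_dataset([[0], [1]], alleles=[("A", "G")])
        d2 = make_dataset([[0], [1]], alleles=[("C", "T")])
        for i, s in enumerate(d2.samples):
            d2.samples[i] = s.__class__(f"o{i}", "B")
        with pytest.raises(ValueError, match="snp1"):
            merge_datasets([d1, d2])


class TestAutosomes:
    def test_drops_x_keeps_1_to_29(self):
        ds = make_dataset([[0, 1, 2]], chroms=["1", "29", "X"])
        out = subset_autosomes(ds)
        assert [s.chromosome for s in out.snps] == ["1", "29"]

    def test_identity_on_autosomal_and_empty(self):
        ds = make_dataset([[0, 1]], chroms=["3", "7"])
        assert subset_autosomes(ds).n_snps == 2
        empty = make_dataset(np.empty((1, 0), dtype=np.int8), chroms=[])
        assert subset_autosomes(empty).n_snps == 0
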