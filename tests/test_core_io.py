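"""I/O layer: diagnostic-SNP filtering, allele-depth orientation, round-trips."""

import numpy as np
import pandas as pd
import pytest

from mosaiche import core_io
from mosaiche.core_io import (
    MISSING,
    AlleleDepthMatrix,
    DosageMatrix,
    FormatError,
    GenomeGrid,
    SnpPanel,
    TraitTable,
    empty_he_table,
    read_allele_depths,
    read_dosage,
    read_he_bed,
    read_snp_panel,
    write_dosage,
    write_he_bed,
)

from conftest import make_dosage

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=40000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNPB\t93-11
"""


def _write_vcf(path, lines):
    path.write_text(VCF_HEADER + "".join(lines))


def test_snp_panel_keeps_only_diagnostic_sites(tmp_path):
    """Of five sites, only those with opposite parental homozygotes survive."""
    vcf = tmp_path / "panel.vcf"
    _write_vcf(vcf, [
        "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t1/1\n",   # diagnostic
        "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/0\n",   # both ref
        "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/0\n",   # diagnostic, NPB=ALT
        "chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\t1/1\n",   # het parent
        "chr1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t1/1\t0/0\n",   # diagnostic
    ])
    panel = read_snp_panel(vcf)
    assert len(panel) == 3
    assert panel.df["pos"].tolist() == [99, 299, 499]  # 0-based internally
    # orientation: at 300 the NPB allele is the ALT base
    assert panel.df.loc[1, "npb_allele"] == "A"
    assert panel.df.loc[1, "ind_allele"] == "G"


def test_snp_panel_errors(tmp_path):
    vcf = tmp_path / "p.vcf"
    _write_vcf(vcf, ["chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\n"])
    with pytest.raises(FormatError):
        read_snp_panel(vcf)
    with pytest.raises(FormatError):
        read_snp_panel(vcf, parent_npb="nope")


@pytest.fixture()
def three_snp_panel():
    return SnpPanel(pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "pos": [99, 299, 499],
        "npb_allele": ["A", "A", "C"],
        "ind_allele": ["G", "G", "A"],
    }))


def test_allele_depth_vcf_orientation(tmp_path, three_snp_panel):
    """AD pairs are re-oriented so reads_npb counts the NPB allele whether it
    is REF or ALT."""
    vcf = tmp_path / "depths.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=40000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:AD\t0/1:12,8\n"     # NPB=REF
        "chr1\t300\t.\tG\tA\t.\tPASS\t.\tGT:AD\t0/1:8,12\n"     # NPB=ALT
        "chr1\t700\t.\tT\tC\t.\tPASS\t.\tGT:AD\t0/1:5,5\n"      # not in panel
    )
    with pytest.warns(UserWarning, match="not in panel"):
        adm = read_allele_depths(vcf, three_snp_panel)
    assert adm.npb[0].tolist() == [12, 12, 0]
    assert adm.ind[0].tolist() == [8, 8, 0]


def test_allele_depth_tsv_fills_only_listed_cells(tmp_path, three_snp_panel):
    tsv = tmp_path / "depths.tsv"
    tsv.write_text(
        "individual\tchrom\tpos\treads_npb\treads_ind\n"
        "a\tchr1\t100\t3\t4\n"
        "a\tchr1\t300\t5\t6\n"
        "b\tchr1\t500\t7\t8\n"
        "b\tchr1\t100\t1\t2\n"
    )
    adm = read_allele_depths(tsv, three_snp_panel)
    assert adm.individuals == ["a", "b"]
    assert int((adm.total > 0).sum()) == 4
    assert adm.npb[1].tolist() == [1, 0, 7]


def test_allele_depth_roundtrip(tmp_path, three_snp_panel):
    adm = AlleleDepthMatrix(["x", "y"], np.array([[1, 0, 3], [0, 0, 5]]),
                            np.array([[2, 0, 0], [0, 0, 1]]))
    core_io.write_allele_depths_tsv(adm, three_snp_panel, tmp_path / "d.tsv")
    back = read_allele_depths(tmp_path / "d.tsv", three_snp_panel)
    np.testing.assert_array_equal(back.npb, adm.npb)
    np.testing.assert_array_equal(back.ind, adm.ind)


def test_dosage_roundtrip(tmp_path, tiny_grid):
    rng = np.random.default_rng(7)
    values = rng.integers(0, 5, size=(3, tiny_grid.n_bins_total)).astype(np.int8)
    values[1, 3] = MISSING
    meta = pd.DataFrame(
        {"line": ["L1"] * 3, "generation": ["S4"] * 3, "cross": ["NN99"] * 3},
        index=["i0", "i1", "i2"],
    )
    dm = make_dosage(values, tiny_grid, ["i0", "i1", "i2"], meta)
    write_dosage(dm, tmp_path / "dm.tsv")
    back = read_dosage(tmp_path / "dm.tsv")
    np.testing.assert_array_equal(back.values, dm.values)
    assert back.individuals == dm.individuals
    assert back.grid.chromosomes == tiny_grid.chromosomes
    assert list(back.meta["cross"]) == ["NN99"] * 3


def test_dosage_out_of_range_rejected(tmp_path, tiny_grid):
    dm = make_dosage(np.full((1, tiny_grid.n_bins_total), 2), tiny_grid)
    write_dosage(dm, tmp_path / "dm.tsv")
    text = (tmp_path / "dm.tsv").read_text().replace("\t2\n", "\t5\n", 1)
    (tmp_path / "bad.tsv").write_text(text)
    with pytest.raises(FormatError, match="out of range"):
        read_dosage(tmp_path / "bad.tsv")
    with pytest.raises(ValueError):
        make_dosage(np.full((1, tiny_grid.n_bins_total), 5), tiny_grid)


def test_he_bed_intervals_and_roundtrip(tmp_path):
    he = pd.DataFrame({
        "individual": ["a", "a"],
        "chrom": ["chr1", "chr1"],
        "boundary": [15000, 25000],
        "left_state": np.int8([2, 3]),
        "right_state": np.int8([3, 2]),
        "flagged": [False, True],
    })
    path = tmp_path / "he.bed"
    write_he_bed(he, path, bin_width=5000)
    lines = path.read_text().strip().split("\n")
    assert lines[1].split("\t")[:3] == ["chr1", "10000", "15000"]
    back = read_he_bed(path, 5000)
    pd.testing.assert_frame_equal(
        back.sort_values("boundary").reset_index(drop=True),
        he.sort_values("boundary").reset_index(drop=True),
    )


def test_he_bed_empty_and_clamped(tmp_path):
    write_he_bed(empty_he_table(), tmp_path / "e.bed")
    assert (tmp_path / "e.bed").read_text().startswith("#chrom")
    assert len((tmp_path / "e.bed").read_text().strip().split("\n")) == 1
    he = pd.DataFrame({"individual": ["a"], "chrom": ["chr1"], "boundary": [2000],
                       "left_state": np.int8([2]), "right_state": np.int8([3]),
                       "flagged": [False]})
    with pytest.warns(UserWarning, match="clamped"):
        write_he_bed(he, tmp_path / "c.bed", bin_width=5000)


def test_grid_validation_and_regions():
    with pytest.raises(ValueError):
        GenomeGrid([("c", 0)], {"c": 0})
    with pytest.raises(ValueError):
        GenomeGrid([("c", 10_000)], {"c": 20_000})
    grid = GenomeGrid([("c", 10_000_000)], {"c": 5_000_000},
                      bin_width=5000, region_bin_width=500_000)
    classes = grid.region_classes()
    # 20 coarse windows: 0-3 and 16-19 subtelomeric, 9-11 pericentromeric
    assert classes[0] == 2 and classes[-1] == 2
    assert classes[grid.bin_index("c", 5_000_000)] == 1
    assert classes[grid.bin_index("c", 3_000_000)] == 0


def test_grid_tsv_roundtrip(tmp_path, tiny_grid):
    tiny_grid.to_tsv(tmp_path / "g.tsv")
    back = GenomeGrid.from_tsv(tmp_path / "g.tsv")
    assert back.chromosomes == tiny_grid.chromosomes
    assert back.bin_width == tiny_grid.bin_width
    assert back.centromeres == tiny_grid.centromeres


def test_trait_table_rejects_unknown_group():
    df = pd.DataFrame({"t1": [1.0], "group": ["alien"]}, index=["x"])
    with pytest.raises(FormatError):
        TraitTable(df)
    ok = TraitTable(pd.DataFrame({"t1": [1.0], "group": ["tet_NN99"]}, index=["x"]))
    assert ok.trait_names == ["t1"]
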