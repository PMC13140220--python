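"""Region classification and backbone-donor hybrid design."""

import numpy as np
import pytest

from bblkit.alignment import MSA, build_reference_map, pairwise_identity, translate
from bblkit.errors import InputError
from bblkit.hybrids import HybridSpec, apply_mutations, diff_sequences, hybrid_report
from bblkit.regions import RegionAnnotation, classify_regions
from bblkit.simulate import default_region_table, simulate_protein_pair

from .conftest import make_synthetic_pdb


@pytest.fixture(scope="module")
def synthetic_pdb(tmp_path_factory):
    return make_synthetic_pdb(tmp_path_factory.mktemp("pdb") / "synthetic_bbl.pdb")


class TestClassifyRegions:
    def test_distance_rules(self, synthetic_pdb):
        ann = classify_regions(synthetic_pdb)
        assert ann.region_of(100) == "SBR"  # 3 A from isoalloxazine
        assert ann.region_of(150) == "SBR"  # 5.5 A from ring, inside cutoff 6
        assert ann.region_of(200) == "FBS"  # 3 A from FAD tail, far from ring
        assert ann.region_of(250) == "FBS"  # 3.9 A from FAD, spec of the 4.5 cutoff
        assert ann.region_of(300) == "other"
        assert ann.region_of(360) == "ASA"  # by numbering, 354-380
        assert ann.provenance == "distance-derived"

    def test_region_partition_invariants(self, synthetic_pdb):
        for fad_cut, cav_cut in ((3.0, 4.0), (4.5, 6.0), (8.0, 10.0)):
            ann = classify_regions(synthetic_pdb, fad_cutoff=fad_cut,
                                   cavity_cutoff=cav_cut)
            for pos, region in ann.regions.items():
                if region == "ASA":
                    assert ann.in_sbr(pos)
                assert not (ann.in_sbr(pos) and ann.in_fbs(pos))

    def test_missing_fad_rejected(self, synthetic_pdb, tmp_path):
        text = "\n".join(l for l in synthetic_pdb.read_text().splitlines()
                         if "FAD" not in l) + "\n"
        p = tmp_path / "nofad.pdb"
        p.write_text(text)
        with pytest.raises(InputError):
            classify_regions(p)

    def test_bad_cutoffs_rejected(self, synthetic_pdb):
        with pytest.raises(InputError):
            classify_regions(synthetic_pdb, fad_cutoff=-1)

    def test_table_roundtrip(self, tmp_path):
        ann = default_region_table(540)
        p = tmp_path / "regions.tsv"
        ann.to_tsv(p)
        again = RegionAnnotation.from_tsv(p)
        assert again.regions == ann.regions

    def test_default_table_asa_span(self):
        ann = default_region_table(540)
        asa = [p for p, r in ann.regions.items() if r == "ASA"]
        assert asa == list(range(354, 381))  # 27 positions spanning 354-380


class TestDiffSequences:
    @pytest.fixture()
    def setup(self):
        pair = simulate_protein_pair(seed=3, n_residues=100, n_substitutions=10,
                                     insertion=(50, 4))
        msa = MSA([("bb", pair["backbone_aligned"]), ("dn", pair["donor_aligned"])],
                  alphabet="protein")
        refmap = build_reference_map(msa, "dn")  # donor carries the insertion
        regions = default_region_table(104)
        return pair, msa, refmap, regions

    def test_complete_inventory(self, setup):
        pair, msa, refmap, regions = setup
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, regions,
                              donor_cds=pair["donor_cds"])
        assert mset.n_substitutions == pair["n_substitutions"]
        assert len(mset.indels) == 1
        ins = mset.indels[0]
        assert ins.kind == "insertion" and len(ins.residues) == 4
        assert len(ins.donor_codons) == 4
        assert translate("".join(ins.donor_codons)) == ins.residues

    def test_counts_match_pairwise_identity(self, setup):
        pair, msa, refmap, regions = setup
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, regions)
        ident = pairwise_identity(msa["bb"], msa["dn"])
        assert mset.n_substitutions == ident.substitutions
        assert len(mset.indels) == ident.indel_events

    def test_identical_sequences_empty_set(self, setup):
        _, msa, refmap, regions = setup
        mset = diff_sequences(msa["dn"], msa["dn"], refmap, regions)
        assert mset.n_substitutions == 0 and not mset.indels

    def test_unequal_lengths_rejected(self, setup):
        _, msa, refmap, regions = setup
        with pytest.raises(InputError):
            diff_sequences("MK", "MKL", refmap, regions)


class TestApplyMutations:
    @pytest.mark.parametrize("seed", range(4))
    def test_apply_all_restores_donor(self, seed):
        pair = simulate_protein_pair(seed=seed, n_residues=80, n_substitutions=8,
                                     insertion=(40, 3) if seed % 2 else None)
        msa = MSA([("bb", pair["backbone_aligned"]), ("dn", pair["donor_aligned"])],
                  alphabet="protein")
        refmap = build_reference_map(msa, "dn")
        regions = default_region_table(83)
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, regions,
                              donor_cds=pair["donor_cds"])
        full = mset.select(regions=None, include_indels=True)
        cds, prot = apply_mutations(pair["backbone_cds"], pair["backbone_aligned"], full)
        assert prot == pair["donor_aligned"].replace("-", "")
        # introduced residues carry the donor's codons (nucleotide provenance);
        # untouched positions stay bit-identical to the backbone
        donor_res = {s.column - pair["backbone_aligned"][: s.column].count("-")
                     for s in full.substitutions}
        hybrid_codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        bb_codons = [pair["backbone_cds"][i : i + 3]
                     for i in range(0, len(pair["backbone_cds"]), 3)]
        offset = 0
        ins_start = None
        if pair["insertion"]:
            anchor, k = pair["insertion"]
            ins_start = anchor
        for res in range(len(bb_codons)):
            if ins_start is not None and res == ins_start:
                offset = pair["insertion"][1]
            if res not in donor_res:
                assert hybrid_codons[res + offset] == bb_codons[res]

    def test_empty_subset_is_identity(self):
        pair = simulate_protein_pair(seed=9, insertion=None)
        msa = MSA([("bb", pair["backbone_aligned"]), ("dn", pair["donor_aligned"])],
                  alphabet="protein")
        refmap = build_reference_map(msa, "dn")
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, default_region_table(120))
        empty = mset.select(labels=set())
        cds, _ = apply_mutations(pair["backbone_cds"], pair["backbone_aligned"], empty)
        assert cds == pair["backbone_cds"]

    def test_region_subset_changes_exactly_those_positions(self):
        pair = simulate_protein_pair(seed=5, n_residues=400, n_substitutions=40,
                                     insertion=None)
        msa = MSA([("bb", pair["backbone_aligned"]), ("dn", pair["donor_aligned"])],
                  alphabet="protein")
        refmap = build_reference_map(msa, "dn")
        regions = default_region_table(400)
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, regions,
                              donor_cds=pair["donor_cds"])
        sbr = mset.select(regions={"SBR"})
        _, prot = apply_mutations(pair["backbone_cds"], pair["backbone_aligned"], sbr)
        n_changed = sum(a != b for a, b in zip(prot, pair["backbone_aligned"]))
        assert n_changed == sbr.n_substitutions
        assert all(regions.in_sbr(int(s.label)) for s in sbr.substitutions)

    def test_fallback_codon_when_no_donor_cds(self):
        msa = MSA([("bb", "MKL"), ("dn", "MAL")], alphabet="protein")
        refmap = build_reference_map(msa, "dn")
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, default_region_table(3))
        cds, prot = apply_mutations("ATGAAACTT", "MKL", mset.select())
        assert prot == "MAL" and translate(cds) == "MAL"

    def test_multi_donor_layers_apply_in_order(self):
        # layer 2 overrides layer 1 at the shared position
        msa = MSA([("bb", "MKL"), ("d1", "MAL"), ("d2", "MGL")], alphabet="protein")
        refmap = build_reference_map(msa, "bb")
        regions = default_region_table(3)
        m1 = diff_sequences(msa["bb"], msa["d1"], refmap, regions, donor_id="d1")
        m2 = diff_sequences(msa["bb"], msa["d2"], refmap, regions, donor_id="d2")
        _, prot = apply_mutations("ATGAAACTT", "MKL", [m1.select(), m2.select()])
        assert prot == "MGL"


class TestHybridReport:
    def test_report_rows_and_included_flags(self):
        pair = simulate_protein_pair(seed=13, n_residues=100, n_substitutions=6,
                                     insertion=(50, 4))
        msa = MSA([("bb", pair["backbone_aligned"]), ("dn", pair["donor_aligned"])],
                  alphabet="protein")
        refmap = build_reference_map(msa, "dn")
        regions = default_region_table(104)
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, regions,
                              backbone_id="bb", donor_id="dn",
                              donor_cds=pair["donor_cds"])
        spec = HybridSpec(name="bb_to_dn_SBR_Ins", backbone_id="bb", donor_id="dn",
                          regions={"SBR"}, include_indels=True)
        subset = spec.select(mset)
        report = hybrid_report(mset, subset)
        assert len(report) == mset.n_substitutions + len(mset.indels)
        included = report[report["included"]]
        assert len(included) == subset.n_substitutions + len(subset.indels)
        ins_rows = report[report["backbone_aa"].str.startswith("---")]
        assert len(ins_rows) == 1

    def test_empty_spec_header_only(self):
        msa = MSA([("bb", "MKL"), ("dn", "MKL")], alphabet="protein")
        refmap = build_reference_map(msa, "bb")
        mset = diff_sequences(msa["bb"], msa["dn"], refmap, default_region_table(3))
        report = hybrid_report(mset, mset.select())
        assert list(report.columns) == ["position", "region", "backbone_aa",
                                        "donor_aa", "included"]
        assert report.empty

    def test_mismatched_spec_rejected(self):
        spec = HybridSpec(name="x", backbone_id="A", donor_id="B")
        from bblkit.hybrids import MutationSet

        with pytest.raises(InputError):
            spec.select(MutationSet(backbone_id="A", donor_id="C"))
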