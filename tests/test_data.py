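import numpy as np
import pandas as pd
import pytest

import pepscreen as ps
from pepscreen.data import AMINO_ACIDS, DEFAULT_RANGES
from pepscreen.errors import ConfigurationError, MissingDescriptorError, ParseError


class TestSampler:
    def test_empty_and_shape(self):
        assert len(ps.sample_descriptor_vectors(ps.SamplerConfig(n=0, seed=0))) == 0
        t = ps.sample_descriptor_vectors(ps.SamplerConfig(n=50, seed=0))
        assert t.shape == (50, 9) and list(t.columns) == list(ps.DESCRIPTOR_KEYS)

    def test_deterministic_byte_identical_csv(self, tmp_path):
        cfg = ps.SamplerConfig(n=500, seed=9, stratify_rule="ro5")
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        ps.sample_descriptor_vectors(cfg).to_csv(p1, index=False)
        ps.sample_descriptor_vectors(cfg).to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_values_respect_ranges(self):
        t = ps.sample_descriptor_vectors(ps.SamplerConfig(n=2000, seed=4))
        for key, (lo, hi) in DEFAULT_RANGES.items():
            assert t[key].between(lo, hi).all()

    def test_stratified_minimum_class_counts(self):
        cfg = ps.SamplerConfig(n=5000, seed=2, stratify_rule="ro5")
        table = ps.sample_descriptor_vectors(cfg)
        assert len(table) == 5000
        labels = ps.count_violations_frame(table, ps.builtin_ruleset("ro5"))
        counts = np.bincount(labels, minlength=5)
        assert (counts >= 500).all()

    def test_unsatisfiable_stratification_errors(self):
        # mw range entirely above the Ro5 bound: class 0 is unreachable
        cfg = ps.SamplerConfig(
            n=200,
            seed=0,
            ranges={"mw": (600.0, 700.0)},
            stratify_rule="ro5",
            batch_size=500,
            max_batches=5,
        )
        with pytest.raises(ConfigurationError, match="stratified"):
            ps.sample_descriptor_vectors(cfg)

    def test_negative_n_rejected(self):
        with pytest.raises(ConfigurationError):
            ps.SamplerConfig(n=-1)


class TestDatasetBuilders:
    def test_shape_contract_single_molecule(self):
        ds = ps.build_labelled_dataset(
            [ps.MoleculeRecord("m1", "CCO")], [ps.builtin_ruleset("ro5")]
        )
        assert ds.features.shape == (1, 9)
        assert ds.targets["ro5"].shape == (1,)

    def test_glycine_targets_under_each_rule(self):
        recs = [ps.MoleculeRecord("gly", "NCC(=O)O")]
        rulesets = [
            ps.builtin_ruleset("ro5", logp_lower=False),
            ps.builtin_ruleset("bro5"),
            ps.builtin_ruleset("muegge"),
        ]
        ds = ps.build_labelled_dataset(recs, rulesets)
        # glycine: Mw 75 violates only the Muegge lower Mw bound; its
        # Crippen logP (-0.97) additionally breaks Ro5 when the lower
        # logP bound is counted
        assert ds.targets["ro5"][0] == 0
        assert ds.targets["bro5"][0] == 0
        assert ds.targets["muegge"][0] == 1
        ds_default = ps.build_labelled_dataset(recs, [ps.builtin_ruleset("ro5")])
        assert ds_default.targets["ro5"][0] == 1

    def test_fingerprint_width_and_label_independence(self):
        recs = [ps.MoleculeRecord(f"m{i}", smi) for i, smi in enumerate(["CCO", "NCC(=O)O", "c1ccccc1"])]
        rulesets = [ps.builtin_ruleset("ro5"), ps.builtin_ruleset("bro5")]
        ds_desc = ps.build_labelled_dataset(recs, rulesets, representation="descriptors")
        ds_fp = ps.build_labelled_dataset(recs, rulesets, representation="fingerprints", fp_params=(2, 2048))
        assert ds_fp.features.shape == (3, 2048)
        for rule in ("ro5", "bro5"):
            assert np.array_equal(ds_desc.targets[rule], ds_fp.targets[rule])

    def test_parse_failures_reported_not_dropped(self):
        recs = [ps.MoleculeRecord("ok", "CCO"), ps.MoleculeRecord("bad", "C1CC")]
        with pytest.warns(UserWarning, match="failed to parse"):
            ds = ps.build_labelled_dataset(recs, [ps.builtin_ruleset("ro5")])
        assert ds.n == 1
        assert ds.provenance["parse_failures"][0]["id"] == "bad"

    def test_degenerate_inputs_error(self):
        with pytest.raises(ConfigurationError):
            ps.build_labelled_dataset([], [ps.builtin_ruleset("ro5")])
        with pytest.raises(ParseError):
            ps.build_labelled_dataset(
                [ps.MoleculeRecord("bad", "C1CC")], [ps.builtin_ruleset("ro5")]
            )
        with pytest.raises(ConfigurationError):
            ps.build_dataset_from_descriptor_table(pd.DataFrame(), [ps.builtin_ruleset("ro5")])

    def test_descriptor_table_builder(self):
        ok = pd.DataFrame(
            [dict(mw=300, logp=2, hbd=1, hba=3, tpsa=50, n_rotb=4, n_carbon=10, n_hetero=3, n_rings=1)] * 3
        )
        ds = ps.build_dataset_from_descriptor_table(ok, [ps.builtin_ruleset("ro5")])
        assert ds.targets["ro5"].tolist() == [0, 0, 0]
        allbad = ok.copy()
        allbad.loc[0, ["mw", "logp", "hbd", "hba", "tpsa", "n_rotb"]] = [1200, 11, 7, 16, 260, 21]
        ds2 = ps.build_dataset_from_descriptor_table(allbad, [ps.builtin_ruleset("bro5")])
        assert ds2.targets["bro5"][0] == 6

    def test_missing_column_named(self):
        table = pd.DataFrame([dict(mw=300, logp=2, hbd=1, hba=3)])
        with pytest.raises(MissingDescriptorError, match="tpsa"):
            ps.build_dataset_from_descriptor_table(table, [ps.builtin_ruleset("bro5")])


class TestSplit:
    def test_partition_and_size(self, small_stratified_dataset):
        train, test = ps.split_dataset(small_stratified_dataset, ps.SplitSpec(0.2, 42))
        assert test.n == round(small_stratified_dataset.n * 0.2)
        assert train.n + test.n == small_stratified_dataset.n
        assert set(train.ids).isdisjoint(test.ids)
        assert set(train.ids) | set(test.ids) == set(small_stratified_dataset.ids)

    def test_deterministic(self, small_stratified_dataset):
        a = ps.split_dataset(small_stratified_dataset, ps.SplitSpec(0.2, 42))
        b = ps.split_dataset(small_stratified_dataset, ps.SplitSpec(0.2, 42))
        assert np.array_equal(a[0].ids, b[0].ids) and np.array_equal(a[1].ids, b[1].ids)

    def test_degenerate_inputs(self, small_stratified_dataset):
        one = small_stratified_dataset.subset(np.array([0]))
        with pytest.raises(ConfigurationError):
            ps.split_dataset(one, ps.SplitSpec(0.2, 42))
        with pytest.raises(ConfigurationError):
            ps.split_dataset(small_stratified_dataset, ps.SplitSpec(1.5, 42))


class TestCsvRoundTrip:
    def test_descriptor_dataset(self, tmp_path, small_stratified_dataset):
        path = tmp_path / "ds.csv"
        small_stratified_dataset.write_csv(path)
        back = ps.LabelledDataset.read_csv(path)
        assert back.feature_names == small_stratified_dataset.feature_names
        assert np.allclose(back.features, small_stratified_dataset.features, atol=1e-9)
        for rule in small_stratified_dataset.targets:
            assert np.array_equal(back.targets[rule], small_stratified_dataset.targets[rule])

    def test_fingerprint_dataset_hex_packing(self, tmp_path):
        recs = [ps.MoleculeRecord(f"m{i}", smi) for i, smi in enumerate(["CCO", "c1ccccc1"])]
        ds = ps.build_labelled_dataset(recs, [ps.builtin_ruleset("ro5")],
                                       representation="fingerprints", fp_params=(2, 512))
        path = tmp_path / "fp.csv"
        ds.write_csv(path)
        back = ps.LabelledDataset.read_csv(path)
        assert np.array_equal(back.features, ds.features)
        assert back.representation == "fingerprints"


class TestPeptideAssembler:
    def test_glycine_templates(self):
        assert ps.peptide_smiles("G") == "NCC(=O)O"
        assert ps.peptide_smiles("GG") == "NCC(=O)NCC(=O)O"

    def test_unknown_residue_errors(self):
        with pytest.raises(ConfigurationError):
            ps.peptide_smiles("GXZ")

    def test_all_residues_parse(self):
        for code in AMINO_ACIDS:
            mol = ps.parse_molecule(ps.peptide_smiles(code * 2))
            assert mol.GetNumHeavyAtoms() > 4

    def test_generated_dodecapeptide_parses_and_is_heavy(self):
        for seed in range(5):
            rec = ps.generate_peptide_smiles(12, seed=seed)
            dv = ps.compute_descriptors(ps.parse_molecule(rec.smiles))
            assert dv.mw > 500

    def test_generator_deterministic(self):
        a = ps.generate_peptide_smiles(6, seed=3)
        b = ps.generate_peptide_smiles(6, seed=3)
        assert a.smiles == b.smiles and a.name == b.name
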