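"""Synthetic dataset generation, noise statistics, file round-trips."""

import numpy as np
import pandas as pd
import pytest

import flcdyn as fd
from flcdyn.synthetic import (Dataset, DatasetError, NoiseModel,
                              generate_dataset, read_dataset, write_dataset)

GENS = ("wild_type",)
SHORT_TP = ("NV", "2WT0", "6WT0")


@pytest.fixture(scope="module")
def defaults():
    return fd.ModelParams(), fd.AntisenseParams()


class TestGeneration:
    def test_zero_cv_reproduces_noiseless_observables(self, defaults):
        p, a = defaults
        ds = generate_dataset(p, a, genotypes=GENS, timepoints=SHORT_TP,
                              noise=NoiseModel(cv=0.0, n_reps=3, seed=1))
        wide = ds.data.pivot_table(index=["quantity", "region", "timepoint"],
                                   columns="replicate", values="value")
        assert np.allclose(wide[1], wide[2]) and np.allclose(wide[2], wide[3])

    def test_fixed_seed_is_reproducible(self, defaults):
        p, a = defaults
        kw = dict(genotypes=GENS, timepoints=SHORT_TP,
                  noise=NoiseModel(cv=0.2, n_reps=3, seed=42))
        d1 = generate_dataset(p, a, **kw)
        d2 = generate_dataset(p, a, **kw)
        pd.testing.assert_frame_equal(d1.data, d2.data)

    def test_adding_replicates_preserves_existing_draws(self, defaults):
        p, a = defaults
        d3 = generate_dataset(p, a, genotypes=GENS, timepoints=("NV",),
                              noise=NoiseModel(cv=0.2, n_reps=3, seed=5))
        d5 = generate_dataset(p, a, genotypes=GENS, timepoints=("NV",),
                              noise=NoiseModel(cv=0.2, n_reps=5, seed=5))
        m3 = d3.data.set_index(["quantity", "region", "replicate"])["value"]
        m5 = d5.data.set_index(["quantity", "region", "replicate"])["value"]
        common = m3.index
        assert np.allclose(m3.loc[common], m5.loc[common])

    def test_replicate_mean_converges_to_noiseless(self, defaults):
        # law of large numbers at n_reps = 300
        p, a = defaults
        noiseless = generate_dataset(p, a, genotypes=GENS, timepoints=("6WT0",),
                                     noise=NoiseModel(cv=0.0, n_reps=1, seed=0))
        noisy = generate_dataset(p, a, genotypes=GENS, timepoints=("6WT0",),
                                 noise=NoiseModel(cv=0.2, n_reps=300, seed=0))
        truth = noiseless.data.set_index(["quantity", "region"])["value"]
        means = noisy.cell_means().set_index(["quantity", "region"])["mean"]
        rel = np.abs(means.loc[truth.index].to_numpy()
                     / truth.to_numpy() - 1.0)
        assert np.max(rel) < 0.05

    def test_sem_scales_with_cv_over_sqrt_n(self, defaults):
        p, a = defaults
        n = 1000
        ds = generate_dataset(p, a, genotypes=GENS, timepoints=("NV",),
                              noise=NoiseModel(cv=0.25, n_reps=n, seed=3))
        cells = ds.cell_means()
        expected = 0.25 * cells["mean"] / np.sqrt(n)
        ratio = cells["sem"] / expected
        assert np.all((ratio > 0.85) & (ratio < 1.15))

    def test_simulation_failure_names_the_cell(self, defaults):
        p, a = defaults
        with pytest.raises(DatasetError, match="condition='XX'"):
            generate_dataset(p, a, genotypes=GENS, conditions=("XX",))

    def test_wild_type_cc_signatures_survive_noise(self, defaults):
        p, a = defaults
        ds = generate_dataset(p, a, genotypes=GENS,
                              noise=NoiseModel(cv=0.3, n_reps=3, seed=9))
        cells = ds.cell_means().set_index(["quantity", "region", "timepoint"])
        k27 = cells.loc[("K27", "nucleation")]["mean"]
        k36 = cells.loc[("K36", "nucleation")]["mean"]
        assert k27["6WT0"] > k27["NV"]
        assert k27["6WT20"] > 0.5 * k27["6WT0"]   # stays high post-cold
        assert k36["6WT0"] < k36["NV"]


class TestIO:
    def test_write_read_round_trip(self, defaults, tmp_path):
        p, a = defaults
        ds = generate_dataset(p, a, genotypes=GENS, timepoints=SHORT_TP,
                              noise=NoiseModel(cv=0.2, n_reps=3, seed=2))
        path = tmp_path / "ds.tsv"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert len(back) == len(ds)
        merged = ds.data.merge(
            back.data, on=["genotype", "condition", "quantity", "region",
                           "timepoint", "replicate"], suffixes=("_a", "_b"))
        assert np.allclose(merged["value_a"], merged["value_b"],
                           rtol=1e-9, atol=1e-9)
        assert back.provenance["source"] == "synthetic"

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("genotype\tcondition\tquantity\ttimepoint\t"
                        "replicate\tvalue\nwt\tCC\tK36\tNV\t1\t0.5\n")
        with pytest.raises(DatasetError, match="region"):
            read_dataset(path)

    def test_empty_dataset_round_trips(self, tmp_path):
        empty = Dataset(data=pd.DataFrame(
            columns=["genotype", "condition", "quantity", "region",
                     "timepoint", "replicate", "value"]))
        path = tmp_path / "empty.tsv"
        write_dataset(empty, path)
        back = read_dataset(path)
        assert len(back) == 0

    def test_nonpositive_values_rejected(self):
        df = pd.DataFrame([("wt", "CC", "K36", "body", "NV", 1, -0.5)],
                          columns=["genotype", "condition", "quantity",
                                   "region", "timepoint", "replicate",
                                   "value"])
        with pytest.raises(DatasetError, match="positive"):
            Dataset(data=df)

    def test_non_numeric_values_rejected(self):
        df = pd.DataFrame([("wt", "CC", "K36", "body", "NV", 1, "high")],
                          columns=["genotype", "condition", "quantity",
                                   "region", "timepoint", "replicate",
                                   "value"])
        with pytest.raises(DatasetError, match="non-numeric"):
            Dataset(data=df)
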