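import numpy as np
import pytest

import detext as dx
from detext import signatures as sig


@pytest.fixture(scope="session")
def cosmic_max_table():
    return sig.cosmic_max_synthetic_table()


@pytest.fixture(scope="session")
def synthetic_table():
    return sig.synthetic_signature_table()


@pytest.fixture(scope="session")
def toy_simulation(tmp_path_factory, cosmic_max_table):
    """A small mutated reference with x2-ish reads and its truth set.

    Session-scoped: several pipeline/model tests share it read-only.
    """
    root = tmp_path_factory.mktemp("sim")
    ref = dx.random_reference(20_000, seed=7)
    hap, truth = dx.seed_snvs(ref, 200, 7, cosmic_max_table)
    sim = dx.SimConfig(depth=3, vaf=1.0, seed=7)
    sam = root / "toy.sam"
    dx.simulate_reads(ref, hap, sim, sam)
    truth_vcf = root / "truth.vcf"
    dx.write_vcf(truth, truth_vcf, ref)
    return {
        "ref": ref,
        "hap": hap,
        "truth": truth,
        "truth_set": {(v.chrom, v.pos, v.ref, v.alt) for v in truth},
        "sam": sam,
        "truth_vcf": truth_vcf,
    }


@pytest.fixture(scope="session")
def toy_dataset(toy_simulation, cosmic_max_table):
    return dx.build_dataset(
        toy_simulation["sam"],
        toy_simulation["ref"],
        toy_simulation["truth_set"],
        cosmic_max_table,
        n_per_class=300,
        balance="over",
        seed=7,
    )


@pytest.fixture(scope="session")
def trained_toy_model(toy_dataset):
    config = dx.ModelConfig(max_iters=300, patience=0, seed=5)
    params, history = dx.train(toy_dataset, config)
    return params, config, history
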