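import numpy as np
import pytest

from psmrescore import PSMDataset, PSMRecord, SyntheticConfig, generate_psm_dataset


def make_record(i, cls=1, **overrides):
    """A legal PSMRecord with index-derived defaults."""
    fields = dict(
        spectrum_id=f"s{i}",
        peptide="AAEK" if cls else "LLNR",
        charge=2,
        protein_accession=f"P{i:04d}" if cls else f"REV_P{i:04d}",
        class_label=cls,
        delta_cn=0.2,
        xcorr=2.5,
        delta_m=0.01,
        sp_rank=1,
        perc_ions=0.5,
        rt_pvalue=0.3,
    )
    fields.update(overrides)
    return PSMRecord(**fields)


def labeled_dataset(probs_by_class):
    """Dataset from {0: [probs...], 1: [probs...]} with raw_prob pre-set."""
    recs = []
    i = 0
    for cls, probs in probs_by_class.items():
        for p in probs:
            recs.append(make_record(i, cls=cls, raw_prob=p))
            i += 1
    return PSMDataset(recs)


@pytest.fixture(scope="session")
def small_synthetic():
    """2000-PSM synthetic world with ground truth, shared across tests."""
    cfg = SyntheticConfig(n_targets=1000, n_decoys=1000, frac_correct=0.15, seed=11)
    return generate_psm_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
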