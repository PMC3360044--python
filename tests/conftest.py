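import numpy as np
import pytest

from eivnpr.array_data import ArrayProfile, Condition, Flag, ProbeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_profile(nets, backgrounds=None, flags=None, mirna_ids=None,
                 array_id="A1", condition=Condition.CONTROL):
    """Build a profile from net intensities (signal = net + background)."""
    n = len(nets)
    backgrounds = backgrounds if backgrounds is not None else [100.0] * n
    flags = flags if flags is not None else [Flag.OK] * n
    mirna_ids = mirna_ids if mirna_ids is not None else [f"m{i}" for i in range(n)]
    records = [
        ProbeRecord(probe_id=f"p{i}", mirna_id=mirna_ids[i],
                    signal=max(nets[i] + backgrounds[i], 0.0),
                    background=backgrounds[i], flag=flags[i])
        for i in range(n)
    ]
    return ArrayProfile(array_id=array_id, condition=condition, records=records)


@pytest.fixture
def probe_tsv(tmp_path):
    """Write a small ImaGene-style probe table and return its path."""

    def writer(rows, header="probe_id\tmirna_id\tsignal\tbackground\tflag",
               name="arr.tsv"):
        path = tmp_path / name
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    return writer
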