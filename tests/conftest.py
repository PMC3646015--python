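import pytest

from transannot import synthdata


@pytest.fixture(scope="session")
def truth500():
    """A 500-gene planted truth set with all event types present."""
    return synthdata.generate_truth(
        500,
        isoform_rate=0.08,
        paralog_rate=0.06,
        dup_rate=0.05,
        region_split_rate=0.04,
        seed=42,
    )


@pytest.fixture(scope="session")
def noise_free_tables(truth500):
    return {
        name: synthdata.emulate_hits(truth500, name)
        for name in ("forward", "reverse", "self", "cladeA", "cladeB")
    }
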