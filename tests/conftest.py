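import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from bamcollate.records import serialize
from bamcollate.simulate import SimProfile, simulate_alignments


def make_profile(**kw):
    """A small mixed-content profile; overridable per test."""
    base = dict(
        genome_len=20_000,
        d=10.0,
        l=50,
        t_mean=200.0,
        t_sd=20.0,
        seed=1,
    )
    base.update(kw)
    return SimProfile(**base)


def max_record_bytes(records):
    return max(len(serialize(r)) for r in records)


def list_bytes_for(records, n_records):
    """Overflow-list size holding about n_records of the given stream."""
    per = max_record_bytes(records) + 8
    return n_records * per + 8


@pytest.fixture(scope="session")
def mixed_records():
    """~3400 coordinate-sorted records with orphans, split pairs, singles
    and planted duplicate clusters."""
    profile = make_profile(
        n_refs=2,
        orphan_rate=0.05,
        split_rate=0.05,
        single_rate=0.1,
        dup_rate=0.1,
        seed=11,
    )
    records, truth = simulate_alignments(profile)
    return profile, records, truth


@pytest.fixture(scope="session")
def big_paired_records():
    """~10^5 all-paired coordinate-sorted records (worst-case and memory
    instrumentation runs)."""
    profile = make_profile(genome_len=125_000, d=40.0, l=50, seed=23)
    records, truth = simulate_alignments(profile)
    return profile, records, truth
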