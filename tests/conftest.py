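import numpy as np
import pytest

from miredit.preprocess import CollapsedRead, ReadRecord
from miredit.references import (
    KnownEditSite,
    MatureArm,
    PreMiRNA,
    build_edited_references,
)
from miredit.simulate import SimulationConfig, simulate_references


def make_read(seq: str, qual=35, read_id: str = "r1") -> ReadRecord:
    quals = tuple([qual] * len(seq)) if isinstance(qual, int) else tuple(qual)
    return ReadRecord(read_id=read_id, sequence=seq, qualities=quals)


def make_collapsed(seq: str, count: int = 1, qual: float = 35.0) -> CollapsedRead:
    return CollapsedRead(
        sequence=seq, count=count, mean_base_quality=tuple([qual] * len(seq))
    )


@pytest.fixture
def hairpin() -> PreMiRNA:
    """A 60-nt hairpin with a 21-nt 5p arm at 4..24 (A at arm positions 2, 5)."""
    #         flank  arm (21)               spacer                 tail
    seq = "CCG" + "GACGAUGCUCGGCUCAGUCGA" + "CUCGGAUCCGG" + "GGCUUCGCCAUCGGUGCCCGG"
    arm5 = MatureArm(mature_id="mA-5p", start=4, end=24, arm="5p")
    arm3 = MatureArm(mature_id="mA-3p", start=40, end=56, arm="3p")
    return PreMiRNA(id="hpA", sequence=seq, mature_arms=(arm5, arm3))


@pytest.fixture
def site(hairpin) -> KnownEditSite:
    """Editing site at mature position 2 of the 5p arm (pre_pos 5, base A)."""
    return KnownEditSite(
        site_id="siteA", pre_id="hpA", mature_id="mA-5p", mature_pos=2, pre_pos=5
    )


@pytest.fixture
def edited_ref(hairpin, site):
    return build_edited_references([hairpin], [site])[0]


@pytest.fixture
def sim_bundle():
    """A deterministic 10-hairpin / 5-site reference bundle."""
    cfg = SimulationConfig(seed=7, n_hairpins=10, n_sites=5)
    return cfg, simulate_references(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
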