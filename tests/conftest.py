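"""Shared fixtures: the worked motif reference pair, a scaffold carrying the
guide mature with known downstream context, and simulator bundles."""

import io

import pytest

from shred import (
    AdapterSpec,
    MotifEntry,
    ScaffoldRecord,
    load_scaffolds,
    parse_motif_file,
)

MOTIF_FILE = (
    ">shRNA-guide1 GATACAGATACAT\n"
    "TCAGGATACAGATACATAACTT\n"
    ">shRNA-passenger1 GTAGTAGGTTGTA\n"
    "TGAGGTAGTAGGTTGTATAGAA\n"
)

GUIDE_MATURE = "TCAGGATACAGATACATAACTT"
PASSENGER_MATURE = "TGAGGTAGTAGGTTGTATAGAA"

# guide mature embedded in scaffold context; continuation after its 3' end
# is GTCA
SCAFFOLD_SEQ = "GGCACTTG" + GUIDE_MATURE + "GTCACCTAGT"
SCAFFOLD_FASTA = f">hairpin1\n{SCAFFOLD_SEQ}\n"


@pytest.fixture
def entries() -> list[MotifEntry]:
    return parse_motif_file(io.StringIO(MOTIF_FILE))


@pytest.fixture
def guide_entry(entries) -> MotifEntry:
    return entries[0]


@pytest.fixture
def passenger_entry(entries) -> MotifEntry:
    return entries[1]


@pytest.fixture
def scaffold(entries) -> ScaffoldRecord:
    return load_scaffolds(io.StringIO(SCAFFOLD_FASTA), entries)[0]


@pytest.fixture
def adapter() -> AdapterSpec:
    return AdapterSpec()
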