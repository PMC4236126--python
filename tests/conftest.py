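"""Shared fixtures: a hand-written toy GenBank record and simulated pairs."""
from __future__ import annotations

import pytest

from plastscan.synthetic_data import SimConfig, simulate_pair

# 600 bp toy plastome fragment; hand-computed coordinates (0-based half-open):
#   geneA  [0, 100)  +        geneB  [160, 360)  -
#   trnX   [400, 473) +       geneC  [480, 520) + [540, 580)  (2 exons)
_TOY_SEQ = ("acgtacgtag" * 60)


def _gb_origin(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {groups}")
    return "\n".join(lines)


TOY_GENBANK = f"""LOCUS       TOY00001                 600 bp    DNA     circular PLN 01-JAN-2024
DEFINITION  toy plastome fragment.
ACCESSION   TOY00001
VERSION     TOY00001.1
FEATURES             Location/Qualifiers
     source          1..600
     gene            1..100
                     /gene="geneA"
     gene            complement(161..360)
                     /gene="geneB"
     tRNA            401..473
                     /gene="trnX"
     gene            join(481..520,541..580)
                     /gene="geneC"
ORIGIN
{_gb_origin(_TOY_SEQ)}
//
"""


@pytest.fixture()
def toy_genbank(tmp_path):
    path = tmp_path / "toy.gb"
    path.write_text(TOY_GENBANK)
    return path


@pytest.fixture(scope="session")
def default_pair():
    """One simulated genome pair at the default (study) conditions."""
    return simulate_pair(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced genome for pipeline-speed-sensitive tests; same processes,
    smaller layout."""
    return SimConfig(genome_length=60_000, ir_length=10_000, n_genes=28,
                     n_trnas=12, seed=7)


@pytest.fixture(scope="session")
def small_pair(small_cfg):
    return simulate_pair(small_cfg)
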