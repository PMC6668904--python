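"""Shared fixtures and toy-gene builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from wgdsim.genome import GeneKind, as_genome, scan_genes
from wgdsim.grn import CompiledGRN
from wgdsim.organism import DigitalOrganism
from wgdsim.world import GridWorld

# word constants mirroring the default kind-word table
W_REPL_PLUS = "0001"
W_REPL_MINUS = "0002"
W_MOVE_PLUS = "0003"
W_MOVE_MINUS = "0010"
W_REGULATORY = "0011"
W_POLYMERASE = "0012"
W_SIGNALING = "0013"

# a few safe cis words (not reserved, not TATA)
CIS = ["2231", "3333", "2222", "1111", "3210", "2323", "1331"]


def make_gene(
    kind_word: str,
    cis: list[str] | None = None,
    payload: str = "00000",
) -> str:
    """Digit string of one complete gene: TATA + cis block + kind + payload."""
    cis = CIS[:5] if cis is None else cis
    return "1010" + "".join(cis) + kind_word + payload


def make_signaling_payload(elements: list[tuple[int, int]]) -> str:
    """Signaling payload: 2-digit length field + 8-digit element slots.

    ``elements`` holds (raw address, signed weight); the length field is
    derived so the element count matches (3-18 encodable).
    """
    n = len(elements)
    if not 3 <= n <= 18:
        raise ValueError("encodable element count is 3-18")
    v = n - 3
    length_field = f"{v // 4}{v % 4}"
    slots = []
    for addr, weight in elements:
        slots.append(np.base_repr(addr, 4).zfill(4))
        slots.append(np.base_repr(weight + 128, 4).zfill(4))
    return length_field + "".join(slots)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_world():
    return GridWorld(width=20, height=20)


def make_do(
    genome_str: str,
    world: GridWorld,
    pos=(5, 5),
    energy: float = 10_000.0,
    do_id: int = 0,
    decay: float = 0.1,
) -> DigitalOrganism:
    genome = as_genome(genome_str)
    genes = scan_genes(genome)
    grn = CompiledGRN(genes, np.full(1000, decay))
    do = DigitalOrganism(
        id=do_id, genome=genome, genes=genes, grn=grn,
        energy=energy, position=world.wrap(pos),
    )
    world.place_organism(do.id, do.position)
    return do


def set_product(do: DigitalOrganism, kind: GeneKind, value: float) -> None:
    """Force the concentration of the product(s) of all genes of a kind."""
    idx = do.grn._kind_idx[kind]
    do.grn.conc[idx] = value
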