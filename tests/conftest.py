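"""Shared fixtures: tiny deterministic panels, transcriptomes and read builders."""

from __future__ import annotations

import numpy as np
import pytest

from smmipseq.design import revcomp
from smmipseq.panel import Panel, Probe

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_transcriptome(rng) -> dict[str, str]:
    return {f"TX{i}": random_seq(rng, 400) for i in range(3)}


@pytest.fixture
def tiny_panel(tiny_transcriptome) -> tuple[Panel, dict[str, str]]:
    """Three probes per transcript, 20+20 arms, 112-nt gap-fill."""
    probes = []
    for tx, seq in tiny_transcriptome.items():
        for j, g0 in enumerate([30, 190]):
            probes.append(
                Probe(
                    name=f"{tx}_p{j}",
                    extension_arm=seq[g0 - 20 : g0],
                    ligation_arm=seq[g0 + 112 : g0 + 132],
                    target_id=tx,
                    target_start=g0,
                    target_end=g0 + 112,
                    gene=tx,
                )
            )
    return Panel(probes), tiny_transcriptome


def make_read_pair(probe: Probe, transcriptome: dict[str, str], umi: str, read_length: int = 76):
    """Build an error-free read pair in the simulator/readproc layout."""
    gap = transcriptome[probe.target_id][probe.target_start : probe.target_end]
    seq1 = (probe.ligation_arm + gap)[:read_length]
    seq2 = (umi + revcomp(probe.extension_arm) + revcomp(gap))[:read_length]
    return seq1, seq2


def mutate(seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)
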