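"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pytest

from utrkit.motifs import (
    MotifConsensus,
    consensus_penalty_matrix,
    mex3_consensus,
)


@pytest.fixture(scope="session")
def mex3():
    return mex3_consensus()


@pytest.fixture(scope="session")
def mex3_matrix(mex3):
    return consensus_penalty_matrix(mex3, default_penalty=1.0)


def regex_perfect_sites(seq: str, consensus: MotifConsensus) -> set[tuple[int, int]]:
    """Independent oracle: all (1-based start, spacer) perfect matches via
    per-spacer regex with overlap-permitting lookahead."""
    hits: set[tuple[int, int]] = set()
    for s in range(consensus.spacer_min, consensus.spacer_max + 1):
        pattern = (
            "".join("[" + "".join(sorted(g)) + "]" for g in consensus.left)
            + "." * s
            + "".join("[" + "".join(sorted(g)) + "]" for g in consensus.right)
        )
        for m in re.finditer(f"(?={pattern})", seq):
            hits.add((m.start() + 1, s))
    return hits


def reduce_per_start_shortest(hits: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Per-start reduction used by the scanner: keep the shortest spacer."""
    best: dict[int, int] = {}
    for start, spacer in hits:
        if start not in best or spacer < best[start]:
            best[start] = spacer
    return set(best.items())


def random_rna(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(rng.choice(list("ACGU"), size=length, p=p))
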