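import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from comparonc.cohort import CohortMember
from comparonc.phylo import Phylogeny


def member(entry, exit_, status):
    """Shorthand cohort member from an (entry, exit, status) triple where
    status is 'censored', 'cancer', 'other' or 'unknown'."""
    dead = status != "censored"
    return CohortMember(
        individual_id=f"m{entry}-{exit_}-{status}",
        entry_age=float(entry),
        exit_age=float(exit_),
        event="death" if dead else "censored",
        necropsy_available=dead and status in ("cancer", "other"),
        cause=status if dead else None,
    )


def members_from(triples):
    return [member(*t) for t in triples]


@pytest.fixture
def make_members():
    return members_from


def balanced_tree(depth: int, branch: float = 1.0) -> Phylogeny:
    """Balanced binary ultrametric tree with 2**depth tips."""

    def rec(d, prefix):
        if d == 0:
            return f"{prefix}:{branch}"
        return f"({rec(d - 1, prefix + 'L')},{rec(d - 1, prefix + 'R')}):{branch}"

    inner = f"({rec(depth - 1, 'tL')},{rec(depth - 1, 'tR')});"
    return Phylogeny.from_newick(inner)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
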