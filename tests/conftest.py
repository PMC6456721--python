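"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from seedshift.seedscan import (
    ALL_CLASSES,
    MatureMiRNA,
    SiteClass,
    SitePatternSet,
    derive_site_patterns,
)

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture
def let7_patterns() -> SitePatternSet:
    return derive_site_patterns(MatureMiRNA("let-7-like", LET7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def naive_scan(sequence: str, patterns: SitePatternSet, classes=None):
    """Brute-force window-enumeration oracle for seed-site scanning.

    Checks every window of length 6-8 at every position against the class
    patterns, then keeps one site per 6mer-core locus (strongest class
    wins).  Independent of the production scanner's string-search path.
    Returns a sorted list of (start, end, class_label) 1-based tuples.
    """
    requested = ALL_CLASSES if classes is None else [SiteClass.from_label(c) for c in classes]
    seq = sequence.upper().replace("T", "U")
    per_core: dict[int, tuple[int, int, SiteClass]] = {}
    for cls in requested:
        pat = patterns[cls]
        n = len(pat)
        off = 1 if cls in (SiteClass.EIGHT_MER, SiteClass.SEVEN_MER_M8) else 0
        for i in range(0, len(seq) - n + 1):
            if seq[i : i + n] == pat:
                core = i + off
                prev = per_core.get(core)
                if prev is None or cls.rank > prev[2].rank:
                    per_core[core] = (i + 1, i + n, cls)
    return sorted((s, e, c.value) for s, e, c in per_core.values())


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
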