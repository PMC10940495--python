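"""Shared fixtures: programmatically built proteins, PWMs and pileups."""

from __future__ import annotations

import numpy as np
import pytest

from ppredit import ppr_code as pc


def make_protein(
    pairs: list[tuple[str, str]],
    classes: list[str] | None = None,
    name: str = "toy",
    motif_len: int = 35,
    tail: str = "EEEDYW",
) -> pc.PPRProtein:
    """Build a PLS protein whose motif i has aa6 = pairs[i][0] and whose
    next motif starts with pairs[i][1] (the 1' residue).  The last pair's
    1' residue is placed immediately after the final motif span."""
    classes = classes or [["P", "L", "S"][i % 3] for i in range(len(pairs))]
    parts = []
    for i, (a6, _) in enumerate(pairs):
        first = pairs[i - 1][1] if i > 0 else "M"
        body = "A" * (motif_len - 7)
        parts.append(first + "AAAA" + a6 + body + "A")
        assert len(parts[-1]) == motif_len
    full = "".join(parts) + pairs[-1][1] + tail
    motifs = []
    start = 1
    for i, part in enumerate(parts):
        motifs.append(
            pc.PPRMotif(
                index=i,
                motif_class=classes[i],
                start=start,
                end=start + motif_len - 1,
                sequence=part,
            )
        )
        start += motif_len
    return pc.PPRProtein(name=name, full_sequence=full, motifs=tuple(motifs))


#: 13 specificity pairs, all present in the packaged default table
PAIRS_13 = [
    ("T", "N"), ("T", "D"), ("N", "D"), ("N", "N"), ("S", "N"),
    ("T", "N"), ("N", "S"), ("T", "D"), ("S", "D"), ("N", "D"),
    ("T", "N"), ("N", "N"), ("T", "D"),
]


@pytest.fixture(scope="session")
def code_table() -> pc.CodeTable:
    return pc.default_code_table()


@pytest.fixture(scope="session")
def toy_protein() -> pc.PPRProtein:
    return make_protein(PAIRS_13)


@pytest.fixture(scope="session")
def code_pwm(toy_protein, code_table) -> pc.PWM:
    return pc.build_pwm(toy_protein, code_table)


def sharp_pwm(seed: int = 0, length: int = 13, peak: float = 0.91) -> pc.PWM:
    """High-information PWM: one dominant base per column."""
    rng = np.random.default_rng(seed)
    probs = np.full((length, 4), (1 - peak) / 3)
    probs[np.arange(length), rng.integers(0, 4, size=length)] = peak
    return pc.PWM(probs=probs, source_protein="sharp")


@pytest.fixture(scope="session")
def sharp_pwm_13() -> pc.PWM:
    return sharp_pwm(seed=0, length=13)
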